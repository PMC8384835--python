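"""Donor cohort selection matched to a reference HLA allele spectrum.

Ex vivo T-cell assays run on a small donor cohort generalize to a population
only insofar as the cohort's HLA class II allele spectrum resembles that
population's.  Given a pool of HLA-DRB1-typed donors and a reference
allele-frequency table, this module selects a size-n sub-cohort whose DRB1
allele frequencies minimize the L1 distance to the reference, using
simulated annealing over single-donor swaps.  Only the two DRB1 alleles per
donor are considered, the locus that dominates CD4+ T-cell responses to
protein therapeutics.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

_ALLELE_RE = re.compile(r"^DRB1\*\d{2}:\d{2,3}$")


class CohortError(ValueError):
    """Raised on invalid genotypes or infeasible selection requests."""


@dataclass(frozen=True)
class DonorGenotype:
    """A donor with its two HLA-DRB1 alleles (4-digit; homozygotes repeat one)."""

    donor_id: str
    drb1_alleles: tuple[str, str]

    def __post_init__(self) -> None:
        if len(self.drb1_alleles) != 2:
            raise CohortError(
                f"donor {self.donor_id!r}: exactly two DRB1 alleles required"
            )
        for a in self.drb1_alleles:
            if not _ALLELE_RE.match(a):
                raise CohortError(
                    f"donor {self.donor_id!r}: malformed DRB1 allele name {a!r}"
                )

    @property
    def carried_alleles(self) -> frozenset[str]:
        """The set of distinct alleles the donor carries (homozygotes count once)."""
        return frozenset(self.drb1_alleles)


@dataclass(frozen=True)
class CohortSelection:
    """Result of an annealed cohort search."""

    selected_donor_ids: frozenset[str]
    objective_value: float
    trace: tuple[float, ...]
    seed: int


def cohort_allele_frequencies(donors: Sequence[DonorGenotype]) -> dict[str, float]:
    """Allele frequencies over a donor set: count over 2n chromosomes.

    Frequencies sum to 1 for any non-empty input.
    """
    if not donors:
        raise CohortError("cannot compute allele frequencies of an empty donor set")
    counts: dict[str, int] = {}
    for d in donors:
        for a in d.drb1_alleles:
            counts[a] = counts.get(a, 0) + 1
    denom = 2 * len(donors)
    return {a: c / denom for a, c in sorted(counts.items())}


def cohort_objective(
    cohort_freqs: Mapping[str, float],
    target_freqs: Mapping[str, float],
    metric: str = "l1",
) -> float:
    """Divergence between a cohort spectrum and the reference spectrum.

    Alleles missing from either table are read as frequency 0, so cohort
    alleles absent from the reference contribute their full frequency
    (penalizing unrepresentative alleles).  ``metric`` is ``"l1"`` (sum of
    absolute differences, the default) or ``"l2"`` (Euclidean).
    """
    alleles = set(cohort_freqs) | set(target_freqs)
    diffs = [cohort_freqs.get(a, 0.0) - target_freqs.get(a, 0.0) for a in alleles]
    if metric == "l1":
        return float(sum(abs(d) for d in diffs))
    if metric == "l2":
        return float(math.sqrt(sum(d * d for d in diffs)))
    raise CohortError(f"unknown metric {metric!r}")


@dataclass(frozen=True)
class AnnealingSchedule:
    """Geometric-cooling schedule: T_k = t0 * alpha**k for n_iter iterations."""

    t0: float = 1.0
    alpha: float = 0.995
    n_iter: int = 20_000


def select_cohort(
    pool: Sequence[DonorGenotype],
    n: int,
    target: Mapping[str, float],
    schedule: AnnealingSchedule | None = None,
    seed: int = 0,
    metric: str = "l1",
) -> CohortSelection:
    """Select ``n`` donors from ``pool`` whose DRB1 spectrum best matches ``target``.

    Simulated annealing over size-n subsets; a move swaps one selected donor
    for one unselected donor and is accepted by the Metropolis rule under the
    geometric cooling schedule.  The best-ever subset is returned; runs are
    reproducible given ``seed``.  The trace records the current objective at
    every iteration.
    """
    if schedule is None:
        schedule = AnnealingSchedule()
    if n < 1:
        raise CohortError(f"cohort size must be >= 1, got {n}")
    if n > len(pool):
        raise CohortError(f"cannot select {n} donors from a pool of {len(pool)}")
    ids = [d.donor_id for d in pool]
    if len(set(ids)) != len(ids):
        raise CohortError("duplicate donor ids in pool")

    alleles = sorted(set(target) | {a for d in pool for a in d.drb1_alleles})
    a_index = {a: i for i, a in enumerate(alleles)}
    target_vec = np.array([target.get(a, 0.0) for a in alleles])
    # per-donor allele-count rows (each donor contributes 2 chromosomes)
    counts = np.zeros((len(pool), len(alleles)), dtype=np.int64)
    for i, d in enumerate(pool):
        for a in d.drb1_alleles:
            counts[i, a_index[a]] += 1

    def objective(count_vec: np.ndarray) -> float:
        freqs = count_vec / (2.0 * n)
        if metric == "l1":
            return float(np.abs(freqs - target_vec).sum())
        return float(np.sqrt(((freqs - target_vec) ** 2).sum()))

    rng = np.random.default_rng(seed)
    if n == len(pool):
        obj = objective(counts.sum(axis=0))
        return CohortSelection(frozenset(ids), obj, (obj,), seed)

    selected = list(rng.choice(len(pool), size=n, replace=False))
    unselected = [i for i in range(len(pool)) if i not in set(selected)]
    cur_counts = counts[selected].sum(axis=0)
    cur_obj = objective(cur_counts)
    best_obj = cur_obj
    best_set = frozenset(selected)
    trace: list[float] = []
    temp = schedule.t0
    for _ in range(schedule.n_iter):
        si = int(rng.integers(n))
        ui = int(rng.integers(len(unselected)))
        out_donor, in_donor = selected[si], unselected[ui]
        cand_counts = cur_counts - counts[out_donor] + counts[in_donor]
        cand_obj = objective(cand_counts)
        delta = cand_obj - cur_obj
        if delta <= 0 or (temp > 0 and rng.random() < math.exp(min(0.0, -delta / temp))):
            selected[si], unselected[ui] = in_donor, out_donor
            cur_counts, cur_obj = cand_counts, cand_obj
            if cur_obj < best_obj:
                best_obj = cur_obj
                best_set = frozenset(selected)
        trace.append(cur_obj)
        temp *= schedule.alpha
    return CohortSelection(
        selected_donor_ids=frozenset(ids[i] for i in best_set),
        objective_value=best_obj,
        trace=tuple(trace),
        seed=seed,
    )
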