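"""HLA-DRB1 allele association with stimulus responses, and population coverage.

With HLA-typed donors, per-donor responder calls can be lifted to the allele
level: an allele is associated with a stimulus under the lenient "any" rule
if at least one carrier responds, and under the strict "all" rule if every
carrier responds.  Weighting associated alleles by their reference-population
frequencies gives a promiscuity score per stimulus — an approximation of the
population fraction able to mount a response — and summing frequencies over
a distinct allele set gives cumulative population coverage.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .cohort import DonorGenotype
from .responders import ResponderCall, donor_positive

logger = logging.getLogger(__name__)

RULES = ("any", "all")


class AssociationError(ValueError):
    pass


@dataclass(frozen=True)
class AssociationMap:
    """Binary allele x stimulus association matrix with donor provenance.

    ``matrix`` is a boolean DataFrame (allele rows, stimulus columns);
    ``provenance`` maps each true cell to the positive carriers backing it.
    """

    rule: str
    matrix: pd.DataFrame
    provenance: dict[tuple[str, str], frozenset[str]]


@dataclass(frozen=True)
class PromiscuityProfile:
    """Frequency-weighted (and raw) associated-allele counts per stimulus."""

    scores: dict[str, float]
    allele_counts: dict[str, int]
    population: str = ""


def allele_carriers(genotypes: Sequence[DonorGenotype]) -> dict[str, frozenset[str]]:
    """Map each allele to the set of donors carrying it (homozygotes once)."""
    carriers: dict[str, set[str]] = defaultdict(set)
    for g in genotypes:
        for a in g.carried_alleles:
            carriers[a].add(g.donor_id)
    return {a: frozenset(ds) for a, ds in carriers.items()}


def build_association_map(
    calls: Sequence[ResponderCall],
    genotypes: Sequence[DonorGenotype],
    rule: str = "any",
) -> AssociationMap:
    """Build the allele x stimulus association matrix under ``rule``.

    ``any``: true iff >= 1 carrier of the allele is donor-positive for the
    stimulus.  ``all``: true iff every carrier (among donors with calls) is
    positive.  Only alleles carried by >= 1 donor with calls appear.
    """
    if rule not in RULES:
        raise AssociationError(f"rule must be one of {RULES}, got {rule!r}")
    by_genotype = {g.donor_id: g for g in genotypes}
    call_donors = sorted({c.donor_id for c in calls})
    missing = [d for d in call_donors if d not in by_genotype]
    if missing:
        raise AssociationError(f"donors without genotypes: {missing}")

    per_cell: dict[tuple[str, str], list[ResponderCall]] = defaultdict(list)
    stimuli: set[str] = set()
    for c in calls:
        per_cell[(c.donor_id, c.stimulus)].append(c)
        stimuli.add(c.stimulus)
    positive = {
        (d, s): donor_positive(cs) for (d, s), cs in per_cell.items()
    }

    carriers = allele_carriers([by_genotype[d] for d in call_donors])
    alleles = sorted(carriers)
    stim_order = sorted(stimuli)
    matrix = pd.DataFrame(False, index=alleles, columns=stim_order)
    provenance: dict[tuple[str, str], frozenset[str]] = {}
    for a in alleles:
        for s in stim_order:
            verdicts = {d: positive.get((d, s), False) for d in carriers[a]}
            hit = any(verdicts.values()) if rule == "any" else all(verdicts.values())
            if hit:
                matrix.loc[a, s] = True
                provenance[(a, s)] = frozenset(d for d, v in verdicts.items() if v)
    return AssociationMap(rule=rule, matrix=matrix, provenance=provenance)


def promiscuity_scores(
    amap: AssociationMap,
    freqs: Mapping[str, float],
    population: str = "",
) -> PromiscuityProfile:
    """Frequency-weighted associated-allele score per stimulus.

    ``score(s) = sum of freqs[a] over alleles a associated with s``; alleles
    absent from the frequency table contribute 0 with a logged warning.  The
    raw associated-allele count is reported alongside.
    """
    missing = [a for a in amap.matrix.index if a not in freqs]
    for a in missing:
        logger.warning(
            "allele %s absent from the %s frequency table; weighted as 0",
            a, population or "reference",
        )
    scores: dict[str, float] = {}
    counts: dict[str, int] = {}
    for s in amap.matrix.columns:
        hit = amap.matrix.index[amap.matrix[s]]
        counts[s] = int(len(hit))
        scores[s] = float(sum(freqs.get(a, 0.0) for a in hit))
    return PromiscuityProfile(scores=scores, allele_counts=counts, population=population)


def cumulative_allele_frequency(
    alleles: Iterable[str], freqs: Mapping[str, float]
) -> float:
    """Cumulative reference-population frequency of a distinct allele set, in %.

    A plain sum over distinct alleles (no diploidy/linkage correction); see
    :func:`carrier_coverage` for the genotype-level alternative.
    """
    return 100.0 * sum(freqs.get(a, 0.0) for a in set(alleles))


def carrier_coverage(alleles: Iterable[str], freqs: Mapping[str, float]) -> float:
    """Percent of diploid individuals expected to carry >= 1 of ``alleles``.

    ``100 * (1 - prod(1 - f_a)^2)`` under Hardy-Weinberg; an optional stricter
    alternative to the plain cumulative frequency sum.
    """
    prod = 1.0
    for a in set(alleles):
        prod *= (1.0 - freqs.get(a, 0.0)) ** 2
    return 100.0 * (1.0 - prod)
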