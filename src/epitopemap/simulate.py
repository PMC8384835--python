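"""Synthetic data generation for the full epitope-identification workflow.

Generates, from a single seed, every input the analysis consumes: a random
protein antigen, a reference DRB1 allele-frequency table, Hardy-Weinberg
donor genotypes, intracellular-cytokine cell-count tables with planted
responder structure, and per-donor MAPPs identification sets nested around
planted epitope regions.  The planted ground truth is returned alongside so
recovery of the epitopes by the pipeline can be scored.

The count model is binomial: each sample's cytokine-positive cells are
``Binomial(total, rate)`` with a small background rate, multiplied by a
fold-change for truly responding donor/stimulus/marker combinations.  MAPPs
identifications are emitted as ladders of nested length variants (lengths
7-24, median near 15) around each epitope a donor's alleles present, plus
rare decoy identifications whose Expect Values mostly fail the EV filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cohort import CohortSelection, DonorGenotype, select_cohort
from .library import PeptidePool, ProteinRecord, TiledPeptide, assign_pools, tile_protein
from .mapps import MappsPeptide
from .responders import SEB, UNSTIMULATED, StimulationRecord, pool_stimulus

_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Stimulus label for the full-length protein antigen.
PROTEIN_STIMULUS = "protein"

DEFAULT_MARKERS = ("IFNg", "TNFa", "IL2")


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, with defaults mirroring the assay design.

    Cohort sizes follow the study layout (50-donor typed pool, 21 T-cell
    donors, 18 MAPPs donors over a 1053-residue antigen tiled 15/5 into
    pools of 10).  Count-model defaults (background positive rate 1e-4,
    totals 5e4-1e5 CD4+ cells, 20-fold effect) put the Fisher test in a
    realistically powered regime.
    """

    seed: int = 0
    protein_length: int = 1053
    window: int = 15
    stagger: int = 5
    pool_size: int = 10
    n_pool_donors: int = 50
    n_tcell_donors: int = 21
    n_mapps_donors: int = 18
    n_alleles: int = 20
    dirichlet_concentration: float = 0.5
    markers: tuple[str, ...] = DEFAULT_MARKERS
    background_rate: float = 1e-4
    total_cells: tuple[int, int] = (50_000, 100_000)
    effect_multiplier: float = 20.0
    seb_multiplier: float = 50.0
    marker_response_prob: float = 0.7
    n_epitopes: int = 8
    epitope_length: tuple[int, int] = (12, 20)
    alleles_per_epitope: tuple[int, int] = (1, 3)
    min_epitope_spacing: int = 30
    ladder_size_mean: float = 3.0
    mapps_noise: float = 0.5  # decoy identifications per donor, pre-EV-filter
    true_ev_range: tuple[float, float] = (1e-4, 0.05)
    decoy_ev_range: tuple[float, float] = (0.03, 3.0)
    cohort_annealing_iterations: int = 20_000


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth of a synthetic study."""

    epitopes: tuple[tuple[int, int], ...]
    presentation: dict[tuple[int, int], frozenset[str]]  # epitope span -> alleles
    expected_responders: dict[str, frozenset[str]]  # T-cell donor -> stimuli
    responsive_markers: dict[tuple[str, str], frozenset[str]]  # (donor, stimulus) -> markers


@dataclass(frozen=True)
class RecoveryMetrics:
    precision: float
    recall: float


@dataclass
class SyntheticDataset:
    """A complete synthetic study: every pipeline input plus the truth."""

    config: SimulationConfig
    protein: ProteinRecord
    peptides: list[TiledPeptide]
    pools: list[PeptidePool]
    allele_frequencies: dict[str, float]
    donor_pool: list[DonorGenotype]
    cohort: CohortSelection
    tcell_genotypes: list[DonorGenotype]
    mapps_genotypes: list[DonorGenotype]
    counts: list[StimulationRecord]
    mapps_peptides: list[MappsPeptide]
    truth: SyntheticTruth


def simulate_protein(
    length: int, rng: np.random.Generator, protein_id: str = "synthetic_antigen"
) -> ProteinRecord:
    """A uniform-random protein over the 20 canonical residues."""
    seq = "".join(rng.choice(list(_AA), size=length))
    return ProteinRecord(protein_id, seq)


def simulate_population(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[dict[str, float], list[DonorGenotype], list[DonorGenotype]]:
    """Reference allele frequencies and the two donor cohorts' genotypes.

    Frequencies are a symmetric Dirichlet draw; genotypes are two
    independent allele draws per donor (Hardy-Weinberg, no linkage).
    """
    alleles = [f"DRB1*{i + 1:02d}:01" for i in range(config.n_alleles)]
    fvec = rng.dirichlet([config.dirichlet_concentration] * config.n_alleles)
    freqs = dict(zip(alleles, fvec.tolist()))

    def draw(prefix: str, n: int) -> list[DonorGenotype]:
        out = []
        for i in range(n):
            pair = rng.choice(alleles, size=2, replace=True, p=fvec)
            out.append(DonorGenotype(f"{prefix}{i + 1:03d}", (str(pair[0]), str(pair[1]))))
        return out

    return freqs, draw("P", config.n_pool_donors), draw("M", config.n_mapps_donors)


def plant_epitopes(
    config: SimulationConfig,
    freqs: dict[str, float],
    rng: np.random.Generator,
) -> tuple[tuple[tuple[int, int], ...], dict[tuple[int, int], frozenset[str]]]:
    """Plant non-overlapping epitope spans and their presenting alleles.

    Presenting alleles are drawn proportional to their population frequency
    (epitopes restricted to vanishingly rare alleles are unobservable in a
    small cohort, so frequency-weighted presentation is the observable
    regime the assay operates in).
    """
    alleles = sorted(freqs)
    p = np.array([freqs[a] for a in alleles])
    p = p / p.sum()
    spans: list[tuple[int, int]] = []
    lo, hi = config.epitope_length
    attempts = 0
    while len(spans) < config.n_epitopes:
        attempts += 1
        if attempts > 10_000:
            raise ValueError(
                f"cannot place {config.n_epitopes} epitopes of length {lo}-{hi} "
                f"with spacing {config.min_epitope_spacing} on a "
                f"{config.protein_length}-residue protein"
            )
        length = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(1, config.protein_length - length + 2))
        end = start + length - 1
        if all(
            end < s - config.min_epitope_spacing or start > e + config.min_epitope_spacing
            for s, e in spans
        ):
            spans.append((start, end))
    spans.sort()
    k_lo, k_hi = config.alleles_per_epitope
    presentation = {}
    for span in spans:
        k = int(rng.integers(k_lo, k_hi + 1))
        chosen = rng.choice(alleles, size=min(k, len(alleles)), replace=False, p=p)
        presentation[span] = frozenset(str(a) for a in chosen)
    return tuple(spans), presentation


def _presented_epitopes(
    genotype: DonorGenotype, presentation: dict[tuple[int, int], frozenset[str]]
) -> list[tuple[int, int]]:
    return [
        span for span, alleles in sorted(presentation.items())
        if alleles & genotype.carried_alleles
    ]


def build_truth(
    config: SimulationConfig,
    epitopes: tuple[tuple[int, int], ...],
    presentation: dict[tuple[int, int], frozenset[str]],
    tcell_genotypes: Sequence[DonorGenotype],
    pools: Sequence[PeptidePool],
    rng: np.random.Generator,
) -> SyntheticTruth:
    """Expected responder sets: pools overlapping a presented epitope.

    For each expected (donor, stimulus) the subset of responsive cytokine
    markers is drawn (each marker independently with
    ``marker_response_prob``, at least one forced), mimicking the
    marker-to-marker heterogeneity of real responses.
    """
    expected: dict[str, frozenset[str]] = {}
    responsive: dict[tuple[str, str], frozenset[str]] = {}
    for g in tcell_genotypes:
        presented = _presented_epitopes(g, presentation)
        stimuli: set[str] = set()
        for q in pools:
            if any(s <= q.span_end and e >= q.span_start for s, e in presented):
                stimuli.add(pool_stimulus(q.pool_id))
        if presented:
            stimuli.add(PROTEIN_STIMULUS)
        expected[g.donor_id] = frozenset(stimuli)
        for stim in sorted(stimuli):
            hit = [m for m in config.markers if rng.random() < config.marker_response_prob]
            if not hit:
                hit = [config.markers[int(rng.integers(len(config.markers)))]]
            responsive[(g.donor_id, stim)] = frozenset(hit)
    return SyntheticTruth(
        epitopes=epitopes,
        presentation=presentation,
        expected_responders=expected,
        responsive_markers=responsive,
    )


def simulate_counts(
    config: SimulationConfig,
    truth: SyntheticTruth,
    tcell_genotypes: Sequence[DonorGenotype],
    pools: Sequence[PeptidePool],
    rng: np.random.Generator,
) -> list[StimulationRecord]:
    """Binomial cell-count tables for every donor x stimulus x marker.

    Stimuli are all peptide pools, the full-length protein, the SEB
    positive control (always responding at ``seb_multiplier``) and one
    unstimulated control row per donor and marker.  Totals are drawn
    uniformly per donor x stimulus sample and shared across the markers of
    that sample.
    """
    stimuli = [pool_stimulus(q.pool_id) for q in pools] + [PROTEIN_STIMULUS, SEB]
    lo, hi = config.total_cells
    records: list[StimulationRecord] = []
    for g in tcell_genotypes:
        donor = g.donor_id
        total_unstim = int(rng.integers(lo, hi + 1))
        for marker in config.markers:
            records.append(
                StimulationRecord(
                    donor, UNSTIMULATED, marker,
                    int(rng.binomial(total_unstim, config.background_rate)),
                    total_unstim,
                )
            )
        for stim in stimuli:
            total = int(rng.integers(lo, hi + 1))
            for marker in config.markers:
                rate = config.background_rate
                if stim == SEB:
                    rate *= config.seb_multiplier
                elif stim in truth.expected_responders.get(donor, frozenset()) and \
                        marker in truth.responsive_markers.get((donor, stim), frozenset()):
                    rate *= config.effect_multiplier
                records.append(
                    StimulationRecord(
                        donor, stim, marker,
                        int(rng.binomial(total, min(rate, 1.0))),
                        total,
                    )
                )
    return records


def simulate_mapps(
    config: SimulationConfig,
    presentation: dict[tuple[int, int], frozenset[str]],
    mapps_genotypes: Sequence[DonorGenotype],
    protein: ProteinRecord,
    rng: np.random.Generator,
) -> list[MappsPeptide]:
    """MAPPs identification lists: nested ladders around presented epitopes.

    For every epitope one of the donor's alleles presents, a ladder of
    ``1 + Poisson(ladder_size_mean)`` peptides is emitted whose lengths are
    drawn around 15 (clipped to 7-24) and whose centers jitter around the
    epitope center, producing the nested/staggered length variants typical
    of MHC-II elution data.  Decoy identifications (false MS hits) appear at
    ``mapps_noise`` per donor at uniform positions, with Expect Values drawn
    log-uniformly across the significance threshold so only a minority
    survive filtering.
    """
    def loguniform(a: float, b: float) -> float:
        return float(np.exp(rng.uniform(np.log(a), np.log(b))))

    def draw_length() -> int:
        return int(np.clip(round(rng.normal(15.0, 3.5)), 7, 24))

    length = len(protein)
    out: list[MappsPeptide] = []
    for g in mapps_genotypes:
        for span in _presented_epitopes(g, presentation):
            center = (span[0] + span[1]) // 2
            n_ladder = 1 + int(rng.poisson(config.ladder_size_mean))
            for _ in range(n_ladder):
                plen = draw_length()
                c = center + int(rng.integers(-4, 5))
                start = int(np.clip(c - plen // 2, 1, length - plen + 1))
                end = start + plen - 1
                out.append(
                    MappsPeptide(
                        g.donor_id,
                        protein.subsequence(start, end),
                        loguniform(*config.true_ev_range),
                    )
                )
        for _ in range(int(rng.poisson(config.mapps_noise))):
            plen = draw_length()
            start = int(rng.integers(1, length - plen + 2))
            out.append(
                MappsPeptide(
                    g.donor_id,
                    protein.subsequence(start, start + plen - 1),
                    loguniform(*config.decoy_ev_range),
                )
            )
    return out


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate a complete, seed-deterministic synthetic study."""
    rng = np.random.default_rng(config.seed)
    protein = simulate_protein(config.protein_length, rng)
    peptides = tile_protein(protein, config.window, config.stagger)
    pools = assign_pools(peptides, config.pool_size)
    freqs, donor_pool, mapps_genotypes = simulate_population(config, rng)
    epitopes, presentation = plant_epitopes(config, freqs, rng)
    from .cohort import AnnealingSchedule

    cohort = select_cohort(
        donor_pool,
        config.n_tcell_donors,
        freqs,
        schedule=AnnealingSchedule(n_iter=config.cohort_annealing_iterations),
        seed=int(rng.integers(2**31)),
    )
    tcell_genotypes = [d for d in donor_pool if d.donor_id in cohort.selected_donor_ids]
    truth = build_truth(config, epitopes, presentation, tcell_genotypes, pools, rng)
    counts = simulate_counts(config, truth, tcell_genotypes, pools, rng)
    mapps_peptides = simulate_mapps(config, presentation, mapps_genotypes, protein, rng)
    return SyntheticDataset(
        config=config,
        protein=protein,
        peptides=peptides,
        pools=pools,
        allele_frequencies=freqs,
        donor_pool=donor_pool,
        cohort=cohort,
        tcell_genotypes=tcell_genotypes,
        mapps_genotypes=mapps_genotypes,
        counts=counts,
        mapps_peptides=mapps_peptides,
        truth=truth,
    )


def recovery_metrics(
    candidates: Sequence, truth: SyntheticTruth, min_overlap: int = 9
) -> RecoveryMetrics:
    """Span-overlap precision/recall of candidates against planted epitopes.

    An epitope is recovered if some candidate overlaps it by >=
    ``min_overlap`` residues (or the full epitope, if shorter); a candidate
    is a true positive under the same rule.  With no candidates precision is
    1 by convention (no false claims); with no planted epitopes recall is 1.
    """
    def overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
        return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)

    def hits(span: tuple[int, int], others: Sequence[tuple[int, int]]) -> bool:
        need = min(min_overlap, span[1] - span[0] + 1)
        return any(overlap(span, o) >= need for o in others)

    cand_spans = [(c.start, c.end) for c in candidates]
    recall = (
        sum(hits(e, cand_spans) for e in truth.epitopes) / len(truth.epitopes)
        if truth.epitopes else 1.0
    )
    precision = (
        sum(
            any(
                overlap(c, e) >= min(min_overlap, e[1] - e[0] + 1)
                for e in truth.epitopes
            )
            for c in cand_spans
        ) / len(cand_spans)
        if cand_spans else 1.0
    )
    return RecoveryMetrics(precision=float(precision), recall=float(recall))
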