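"""Integration of T-cell responder calls with MAPPs identifications.

The final epitope list contains protein regions that are both naturally
processed and presented on MHC-II (seen in the MAPPs assay) and stimulate
CD4+ T-cells (positive peptide-pool responses).  Because the two assays use
different donor cohorts, donors are matched across cohorts when they share
at least one DRB1 allele.  For every matched pair, the residues where the
MAPPs donor's identifications intersect the T-cell donor's positive pool
spans are collected; the residue sets are combined across all matches,
decomposed into maximal runs, runs shorter than a minimum epitope length
(default 9, the canonical MHC-II binding core) are discarded, and the
survivors are cross-referenced against the distinct MAPPs regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .association import cumulative_allele_frequency
from .cohort import DonorGenotype
from .library import PeptidePool, ProteinRecord
from .mapps import MappsPeptide, PeptideRegion, merge_regions
from .responders import ResponderCall, pool_stimulus, positive_stimuli

logger = logging.getLogger(__name__)

DEFAULT_MIN_EPITOPE_LENGTH = 9


class IntegrationError(ValueError):
    pass


@dataclass(frozen=True)
class DonorMatch:
    """A MAPPs donor and a T-cell donor sharing >= 1 DRB1 allele."""

    mapps_donor_id: str
    tcell_donor_id: str
    shared_alleles: frozenset[str]

    def __post_init__(self) -> None:
        if not self.shared_alleles:
            raise IntegrationError(
                f"match {self.mapps_donor_id}/{self.tcell_donor_id} shares no allele"
            )


@dataclass(frozen=True)
class EpitopeCandidate:
    """A final epitope: presented on MHC-II and stimulating CD4+ T-cells."""

    sequence: str
    start: int
    end: int
    supporting_matches: tuple[DonorMatch, ...]
    associated_alleles: frozenset[str]

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def match_donors(
    mapps_genotypes: Sequence[DonorGenotype],
    tcell_genotypes: Sequence[DonorGenotype],
) -> list[DonorMatch]:
    """All cross-cohort donor pairs sharing at least one DRB1 allele."""
    matches = []
    for m in mapps_genotypes:
        for t in tcell_genotypes:
            shared = m.carried_alleles & t.carried_alleles
            if shared:
                matches.append(DonorMatch(m.donor_id, t.donor_id, frozenset(shared)))
    return matches


def matched_residues(
    mapps_peptides: Sequence[MappsPeptide],
    positive_pools: Sequence[PeptidePool],
) -> set[int]:
    """Residues where MAPPs identifications intersect positive pool spans.

    Union over every (identification, positive pool) pair of the residue
    overlap of the identification's span with the pool's span; partial
    overlaps are kept.
    """
    residues: set[int] = set()
    for p in mapps_peptides:
        if not p.mapped:
            raise IntegrationError(f"unmapped MAPPs peptide {p.sequence!r}")
        for q in positive_pools:
            lo = max(p.start, q.span_start)
            hi = min(p.end, q.span_end)
            if lo <= hi:
                residues.update(range(lo, hi + 1))
    return residues


def combine_and_filter(
    residue_sets: Iterable[set[int]],
    min_length: int = DEFAULT_MIN_EPITOPE_LENGTH,
) -> list[tuple[int, int]]:
    """Union residue sets across matches, keep maximal runs >= ``min_length``.

    The union is decomposed into maximal runs of consecutive positions; runs
    shorter than ``min_length`` are discarded (boundary inclusive: a run of
    exactly ``min_length`` is kept).
    """
    combined: set[int] = set()
    for s in residue_sets:
        combined |= s
    runs: list[tuple[int, int]] = []
    for pos in sorted(combined):
        if runs and pos == runs[-1][1] + 1:
            runs[-1] = (runs[-1][0], pos)
        else:
            runs.append((pos, pos))
    return [(a, b) for a, b in runs if b - a + 1 >= min_length]


def distinct_peptide_spans(mapped_peptides: Sequence[MappsPeptide]) -> list[PeptideRegion]:
    """Distinct-sequence MAPPs spans as degenerate regions (alternative to merging)."""
    seen: dict[tuple[int, int, str], list[MappsPeptide]] = {}
    for p in mapped_peptides:
        seen.setdefault((p.start, p.end, p.sequence), []).append(p)
    return [
        PeptideRegion(s, e, tuple(ps), frozenset(p.donor_id for p in ps))
        for (s, e, _), ps in sorted(seen.items())
    ]


def cross_reference(
    intervals: Sequence[tuple[int, int]],
    regions: Sequence[PeptideRegion],
    protein: ProteinRecord,
    min_overlap: int = DEFAULT_MIN_EPITOPE_LENGTH,
    match_residues: Mapping[DonorMatch, set[int]] | None = None,
) -> list[EpitopeCandidate]:
    """Cross-reference surviving intervals with distinct MAPPs regions.

    For every (region, interval) pair overlapping by >= ``min_overlap``
    residues, the overlap becomes a candidate whose sequence is read off the
    protein.  ``match_residues`` (match -> matched residue set) provides the
    provenance: supporting matches are those whose residues intersect the
    candidate span, and the associated alleles are the union of their shared
    alleles.
    """
    candidates: dict[tuple[int, int], EpitopeCandidate] = {}
    for region in regions:
        for a, b in intervals:
            lo, hi = max(region.start, a), min(region.end, b)
            if hi - lo + 1 < min_overlap:
                continue
            span = (lo, hi)
            if span in candidates:
                continue
            supporting: tuple[DonorMatch, ...] = ()
            alleles: frozenset[str] = frozenset()
            if match_residues is not None:
                supporting = tuple(
                    m for m, res in match_residues.items()
                    if res & set(range(lo, hi + 1))
                )
                alleles = frozenset().union(*(m.shared_alleles for m in supporting)) \
                    if supporting else frozenset()
            candidates[span] = EpitopeCandidate(
                sequence=protein.subsequence(lo, hi),
                start=lo,
                end=hi,
                supporting_matches=supporting,
                associated_alleles=alleles,
            )
    return [candidates[k] for k in sorted(candidates)]


def integrate_epitopes(
    calls: Sequence[ResponderCall],
    mapped_peptides: Sequence[MappsPeptide],
    tcell_genotypes: Sequence[DonorGenotype],
    mapps_genotypes: Sequence[DonorGenotype],
    pools: Sequence[PeptidePool],
    protein: ProteinRecord,
    min_length: int = DEFAULT_MIN_EPITOPE_LENGTH,
    distinct: str = "regions",
) -> list[EpitopeCandidate]:
    """Run the full four-step merge of the two assays.

    1. match donors across cohorts by shared DRB1 allele; 2. per match,
    intersect the MAPPs donor's identifications with the T-cell donor's
    positive pool spans; 3. union the matched residues over all matches and
    keep maximal runs of >= ``min_length``; 4. cross-reference survivors with
    distinct MAPPs peptides (``distinct="regions"`` for cohort-merged
    continuous regions, ``"sequences"`` for distinct raw sequences).
    """
    pool_by_stimulus = {pool_stimulus(q.pool_id): q for q in pools}
    matches = match_donors(mapps_genotypes, tcell_genotypes)
    positive = positive_stimuli(calls, pools_only=True)
    peptides_by_donor: dict[str, list[MappsPeptide]] = {}
    for p in mapped_peptides:
        peptides_by_donor.setdefault(p.donor_id, []).append(p)

    match_residues: dict[DonorMatch, set[int]] = {}
    for m in matches:
        peps = peptides_by_donor.get(m.mapps_donor_id, [])
        pos_pools = [
            pool_by_stimulus[s]
            for s in sorted(positive.get(m.tcell_donor_id, set()))
            if s in pool_by_stimulus
        ]
        res = matched_residues(peps, pos_pools)
        if res:
            match_residues[m] = res

    intervals = combine_and_filter(match_residues.values(), min_length)
    if distinct == "regions":
        regions = merge_regions(mapped_peptides, scope="cohort")
    elif distinct == "sequences":
        regions = distinct_peptide_spans(mapped_peptides)
    else:
        raise IntegrationError(f"distinct must be 'regions' or 'sequences', got {distinct!r}")
    return cross_reference(
        intervals, regions, protein, min_overlap=min_length,
        match_residues=match_residues,
    )


def epitope_population_coverage(
    candidates: Sequence[EpitopeCandidate], freqs: Mapping[str, float]
) -> float:
    """Cumulative reference-population frequency (%) of all candidate alleles."""
    alleles: set[str] = set()
    for c in candidates:
        alleles |= c.associated_alleles
    return cumulative_allele_frequency(alleles, freqs)
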