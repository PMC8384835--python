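"""Processing of MHC-II immunopeptidomics (MAPPs) identifications.

MAPPs identifications are peptides eluted from MHC-II molecules on
dendritic cells and identified by LC-MS/MS; each carries an Expect Value
(EV), the search engine's statistical confidence score (lower = better).
This module filters identifications by EV, maps them exactly onto the
antigen's sequence, merges overlapping identifications into maximal
continuous presented regions (MHC-II peptides come as nested length
variants sharing a core), and summarizes the dataset.
"""

from __future__ import annotations

import dataclasses
import logging
import statistics
from collections import defaultdict
from dataclasses import dataclass
from typing import NamedTuple, Sequence

from .library import LibraryError, ProteinRecord, locate_peptide

logger = logging.getLogger(__name__)

DEFAULT_EV_THRESHOLD = 0.05


class MappsError(ValueError):
    pass


@dataclass(frozen=True)
class MappsPeptide:
    """One MS identification: donor, peptide sequence and its Expect Value.

    ``start``/``end`` (1-based inclusive) are filled by mapping onto the
    antigen and are ``None`` until then.
    """

    donor_id: str
    sequence: str
    expect_value: float
    start: int | None = None
    end: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not self.sequence:
            raise MappsError(f"donor {self.donor_id!r}: empty peptide sequence")
        if self.expect_value <= 0:
            raise MappsError(
                f"donor {self.donor_id!r}: expect value must be positive, "
                f"got {self.expect_value}"
            )
        if (self.start is None) != (self.end is None):
            raise MappsError("start and end must be set together")
        if self.start is not None and self.end - self.start + 1 != len(self.sequence):
            raise MappsError(
                f"span {self.start}-{self.end} does not match length {len(self.sequence)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def mapped(self) -> bool:
        return self.start is not None


@dataclass(frozen=True)
class PeptideRegion:
    """A maximal continuous protein region covered by overlapping identifications."""

    start: int
    end: int
    supporting_peptides: tuple[MappsPeptide, ...]
    supporting_donors: frozenset[str]

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class MappsSummary:
    """Dataset-level summary statistics of a MAPPs experiment."""

    n_donors: int
    n_identifications: int
    n_unique_regions: int
    n_distinct_sequences: int
    min_length: int
    max_length: int
    median_length: float
    mean_per_donor: float


class MappingResult(NamedTuple):
    mapped: list[MappsPeptide]
    unmapped: list[MappsPeptide]


def filter_by_expect_value(
    peptides: Sequence[MappsPeptide], threshold: float = DEFAULT_EV_THRESHOLD
) -> list[MappsPeptide]:
    """Keep identifications with EV <= ``threshold`` (boundary inclusive)."""
    return [p for p in peptides if p.expect_value <= threshold]


def map_mapps_peptides(
    peptides: Sequence[MappsPeptide], protein: ProteinRecord
) -> MappingResult:
    """Place each identification on the antigen by exact substring match.

    Unmappable peptides (no exact occurrence) are dropped with a logged
    warning and returned separately so callers can count them.  Multiply
    occurring peptides keep the first occurrence (flagged via a warning by
    the underlying locator).
    """
    mapped: list[MappsPeptide] = []
    unmapped: list[MappsPeptide] = []
    for p in peptides:
        try:
            loc = locate_peptide(protein, p.sequence)
        except LibraryError:
            unmapped.append(p)
            continue
        mapped.append(dataclasses.replace(p, start=loc.start, end=loc.end))
    if unmapped:
        logger.warning(
            "%d of %d MAPPs identifications could not be mapped onto %r and were dropped",
            len(unmapped), len(peptides), protein.id,
        )
    return MappingResult(mapped, unmapped)


def _merge_sorted(peptides: list[MappsPeptide], min_overlap: int) -> list[PeptideRegion]:
    regions: list[PeptideRegion] = []
    cur: list[MappsPeptide] = []
    cur_start = cur_end = 0
    for p in sorted(peptides, key=lambda q: (q.start, q.end, q.donor_id, q.sequence)):
        # overlap with the open region is cur_end - p.start + 1 residues
        if cur and p.start <= cur_end - min_overlap + 1:
            cur.append(p)
            cur_end = max(cur_end, p.end)
        else:
            if cur:
                regions.append(
                    PeptideRegion(cur_start, cur_end, tuple(cur),
                                  frozenset(q.donor_id for q in cur))
                )
            cur = [p]
            cur_start, cur_end = p.start, p.end
    if cur:
        regions.append(
            PeptideRegion(cur_start, cur_end, tuple(cur),
                          frozenset(q.donor_id for q in cur))
        )
    return regions


def merge_regions(
    peptides: Sequence[MappsPeptide],
    scope: str = "cohort",
    min_overlap: int = 1,
) -> list[PeptideRegion] | dict[str, list[PeptideRegion]]:
    """Merge mapped identifications into maximal continuous regions.

    Two identifications join a region iff their spans share >= ``min_overlap``
    residues; regions are maximal, sorted and non-overlapping.  With
    ``scope="cohort"`` all donors' peptides are merged together (returns a
    list); with ``scope="per_donor"`` each donor is merged separately
    (returns a donor -> regions dict).
    """
    unmapped = [p for p in peptides if not p.mapped]
    if unmapped:
        raise MappsError(
            f"{len(unmapped)} identifications lack coordinates; map them first"
        )
    if scope == "cohort":
        return _merge_sorted(list(peptides), min_overlap)
    if scope == "per_donor":
        by_donor: dict[str, list[MappsPeptide]] = defaultdict(list)
        for p in peptides:
            by_donor[p.donor_id].append(p)
        return {d: _merge_sorted(ps, min_overlap) for d, ps in sorted(by_donor.items())}
    raise MappsError(f"scope must be 'cohort' or 'per_donor', got {scope!r}")


def per_donor_unique_counts(peptides: Sequence[MappsPeptide]) -> dict[str, int]:
    """Number of unique continuous presented regions per donor."""
    per_donor = merge_regions(peptides, scope="per_donor")
    return {d: len(rs) for d, rs in per_donor.items()}


def summarize_mapps(
    peptides: Sequence[MappsPeptide], regions: Sequence[PeptideRegion]
) -> MappsSummary:
    """Summary statistics: donors, identifications, unique regions, lengths.

    Lengths are computed on individual identifications; the unique count is
    the number of cohort-scope merged regions.  Distinct raw sequences are
    reported alongside so either notion of "unique peptide" is available.
    """
    if not peptides:
        raise MappsError("cannot summarize an empty identification list")
    lengths = [p.length for p in peptides]
    donors = {p.donor_id for p in peptides}
    return MappsSummary(
        n_donors=len(donors),
        n_identifications=len(peptides),
        n_unique_regions=len(regions),
        n_distinct_sequences=len({p.sequence for p in peptides}),
        min_length=min(lengths),
        max_length=max(lengths),
        median_length=float(statistics.median(lengths)),
        mean_per_donor=len(peptides) / len(donors),
    )
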