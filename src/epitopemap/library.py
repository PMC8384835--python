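"""Overlapping peptide library design for T-cell epitope mapping.

A protein antigen is screened ex vivo by tiling its sequence into short
overlapping peptides (e.g. 15-mers staggered by 5 residues) that are
organized into consecutive pools for stimulation assays.  This module
builds the tiling and pool structure and maps peptide sequences back onto
the protein.  All coordinates are 1-based and inclusive on both ends, the
convention used when reporting epitope positions (e.g. "301-314").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

logger = logging.getLogger(__name__)

#: The 20 canonical amino-acid one-letter codes.
CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


class LibraryError(ValueError):
    """Raised when a protein or tiling request is unusable."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with an identifier.

    The sequence is normalized to uppercase on construction and must be
    non-empty and restricted to the 20 canonical residues.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not self.sequence:
            raise LibraryError(f"protein {self.id!r} has an empty sequence")
        bad = set(self.sequence) - CANONICAL_RESIDUES
        if bad:
            raise LibraryError(
                f"protein {self.id!r} contains non-canonical residues: "
                f"{''.join(sorted(bad))}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def subsequence(self, start: int, end: int) -> str:
        """Residues ``start..end`` (1-based, inclusive)."""
        if not (1 <= start <= end <= len(self.sequence)):
            raise LibraryError(f"span {start}-{end} outside 1-{len(self.sequence)}")
        return self.sequence[start - 1 : end]


@dataclass(frozen=True)
class TiledPeptide:
    """One member of the overlapping library.

    ``index`` is the 1-based ordinal in the library; ``start``/``end`` are
    1-based inclusive positions on the parent protein.
    """

    index: int
    sequence: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise LibraryError(
                f"peptide {self.index}: span {self.start}-{self.end} does not "
                f"match sequence length {len(self.sequence)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PeptidePool:
    """A pool of consecutive library peptides.

    ``span_start``/``span_end`` give the residue range covered by the pool's
    members; spans of consecutive pools overlap because the peptides do.
    """

    pool_id: int
    peptide_indices: tuple[int, ...]
    span_start: int
    span_end: int

    @property
    def size(self) -> int:
        return len(self.peptide_indices)


class PeptideLocation(NamedTuple):
    start: int
    end: int
    multiple: bool  # True if the peptide occurs more than once in the protein


def tile_protein(
    protein: ProteinRecord,
    window: int = 15,
    stagger: int = 5,
    min_terminal_length: int = 7,
) -> list[TiledPeptide]:
    """Tile ``protein`` into overlapping ``window``-mers staggered by ``stagger``.

    Full windows start at 1, 1+stagger, 1+2*stagger, ... while they fit on the
    protein.  If the last full window does not reach the C-terminus, one
    terminal peptide is appended: it starts one stagger after the last full
    window and ends at the final residue, hence is shorter than ``window``
    (e.g. a terminal 13-mer on a 1053-residue protein at 15/5).  Should that
    natural terminal fragment fall below ``min_terminal_length``, its start is
    pulled back so the fragment has exactly that length.
    """
    if not (window >= stagger >= 1):
        raise LibraryError(f"require window >= stagger >= 1, got {window}/{stagger}")
    length = len(protein)
    if length < window:
        raise LibraryError(
            f"protein {protein.id!r} (length {length}) is shorter than the "
            f"window ({window}); no library can be designed"
        )
    peptides: list[TiledPeptide] = []
    start = 1
    while start + window - 1 <= length:
        end = start + window - 1
        peptides.append(
            TiledPeptide(len(peptides) + 1, protein.subsequence(start, end), start, end)
        )
        start += stagger
    last_end = peptides[-1].end
    if last_end < length:
        term_start = peptides[-1].start + stagger
        if length - term_start + 1 < min_terminal_length:
            term_start = max(1, length - min_terminal_length + 1)
        peptides.append(
            TiledPeptide(
                len(peptides) + 1,
                protein.subsequence(term_start, length),
                term_start,
                length,
            )
        )
    return peptides


def assign_pools(peptides: Sequence[TiledPeptide], pool_size: int = 10) -> list[PeptidePool]:
    """Group library peptides into consecutive pools of ``pool_size``.

    The final pool holds the remainder (possibly fewer peptides).  Each
    pool's residue span is the (min start, max end) over its members.
    """
    if not peptides:
        raise LibraryError("cannot pool an empty peptide library")
    if pool_size < 1:
        raise LibraryError(f"pool_size must be >= 1, got {pool_size}")
    pools: list[PeptidePool] = []
    for i in range(0, len(peptides), pool_size):
        chunk = peptides[i : i + pool_size]
        pools.append(
            PeptidePool(
                pool_id=len(pools) + 1,
                peptide_indices=tuple(p.index for p in chunk),
                span_start=min(p.start for p in chunk),
                span_end=max(p.end for p in chunk),
            )
        )
    return pools


def locate_peptide(protein: ProteinRecord, peptide_sequence: str) -> PeptideLocation:
    """Locate the first exact occurrence of ``peptide_sequence`` in ``protein``.

    Returns 1-based inclusive coordinates plus a flag telling whether the
    peptide occurs more than once (first occurrence is reported; ambiguity is
    surfaced rather than resolved).  Raises :class:`LibraryError` when the
    peptide does not occur at all.
    """
    if not peptide_sequence:
        raise LibraryError("cannot locate an empty peptide")
    query = peptide_sequence.upper()
    pos = protein.sequence.find(query)
    if pos < 0:
        raise LibraryError(
            f"peptide {peptide_sequence!r} does not occur in protein {protein.id!r}"
        )
    multiple = protein.sequence.find(query, pos + 1) >= 0
    if multiple:
        logger.warning(
            "peptide %r occurs more than once in protein %r; reporting the first match",
            peptide_sequence, protein.id,
        )
    return PeptideLocation(pos + 1, pos + len(query), multiple)
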