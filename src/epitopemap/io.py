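"""Readers and writers for the pipeline's plain-text file contracts.

All tables are tab-separated with a header row; the protein is FASTA.
Column layouts:

* allele frequencies: ``allele``, ``frequency``
* genotypes: ``donor_id``, ``drb1_1``, ``drb1_2`` (extra non-DRB1 columns
  are ignored with a logged note)
* stimulation counts (long format): ``donor_id``, ``stimulus``, ``marker``,
  ``positive_count``, ``total_count``
* MAPPs identifications: ``donor_id``, ``sequence``, ``expect_value``
  (optional ``start``/``end`` once mapped)
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .association import AssociationMap, PromiscuityProfile
from .cohort import DonorGenotype
from .integrate import EpitopeCandidate
from .library import PeptidePool, ProteinRecord, TiledPeptide
from .mapps import MappsPeptide, MappsSummary, PeptideRegion
from .responders import ResponderCall, StimulationRecord

logger = logging.getLogger(__name__)

_GENOTYPE_COLUMNS = ("donor_id", "drb1_1", "drb1_2")


def read_protein_fasta(path: str | Path) -> ProteinRecord:
    """Read the first record of a FASTA file as the antigen."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if len(records) > 1:
        logger.warning("%s holds %d records; using the first", path, len(records))
    rec = records[0]
    return ProteinRecord(rec.id, str(rec.seq))


def write_protein_fasta(protein: ProteinRecord, path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(protein.sequence), id=protein.id, description="")],
        str(path),
        "fasta",
    )


def read_allele_frequencies(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return dict(zip(df["allele"].astype(str), df["frequency"].astype(float)))


def write_allele_frequencies(freqs: Mapping[str, float], path: str | Path) -> None:
    pd.DataFrame(
        {"allele": sorted(freqs), "frequency": [freqs[a] for a in sorted(freqs)]}
    ).to_csv(path, sep="\t", index=False)


def read_genotypes(path: str | Path) -> list[DonorGenotype]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    extra = [c for c in df.columns if c not in _GENOTYPE_COLUMNS]
    if extra:
        logger.info("ignoring non-DRB1 genotype columns in %s: %s", path, extra)
    return [
        DonorGenotype(str(r.donor_id), (str(r.drb1_1), str(r.drb1_2)))
        for r in df.itertuples()
    ]


def write_genotypes(genotypes: Sequence[DonorGenotype], path: str | Path) -> None:
    pd.DataFrame(
        {
            "donor_id": [g.donor_id for g in genotypes],
            "drb1_1": [g.drb1_alleles[0] for g in genotypes],
            "drb1_2": [g.drb1_alleles[1] for g in genotypes],
        }
    ).to_csv(path, sep="\t", index=False)


def read_stimulation_counts(path: str | Path) -> list[StimulationRecord]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [
        StimulationRecord(
            str(r.donor_id), str(r.stimulus), str(r.marker),
            int(r.positive_count), int(r.total_count),
        )
        for r in df.itertuples()
    ]


def write_stimulation_counts(records: Sequence[StimulationRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "donor_id": r.donor_id,
                "stimulus": r.stimulus,
                "marker": r.marker,
                "positive_count": r.positive_count,
                "total_count": r.total_count,
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


def read_mapps_peptides(path: str | Path) -> list[MappsPeptide]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    has_coords = "start" in df.columns and "end" in df.columns
    out = []
    for r in df.itertuples():
        kwargs = {}
        if has_coords and not pd.isna(r.start):
            kwargs = {"start": int(r.start), "end": int(r.end)}
        out.append(
            MappsPeptide(str(r.donor_id), str(r.sequence), float(r.expect_value), **kwargs)
        )
    return out


def write_mapps_peptides(peptides: Sequence[MappsPeptide], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "donor_id": p.donor_id,
                "sequence": p.sequence,
                "expect_value": p.expect_value,
                "start": p.start,
                "end": p.end,
            }
            for p in peptides
        ]
    ).to_csv(path, sep="\t", index=False)


def write_library(
    peptides: Sequence[TiledPeptide],
    pools: Sequence[PeptidePool],
    path: str | Path,
) -> None:
    """The designed library: index, sequence, span and pool membership."""
    pool_of = {}
    for q in pools:
        for i in q.peptide_indices:
            pool_of[i] = q.pool_id
    pd.DataFrame(
        [
            {
                "index": p.index,
                "sequence": p.sequence,
                "start": p.start,
                "end": p.end,
                "pool_id": pool_of.get(p.index),
            }
            for p in peptides
        ]
    ).to_csv(path, sep="\t", index=False)


def write_calls(calls: Sequence[ResponderCall], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "donor_id": c.donor_id,
                "stimulus": c.stimulus,
                "marker": c.marker,
                "raw_p": c.raw_p,
                "adjusted_p": c.adjusted_p,
                "positive": c.positive,
            }
            for c in calls
        ]
    ).to_csv(path, sep="\t", index=False)


def read_calls(path: str | Path) -> list[ResponderCall]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [
        ResponderCall(
            str(r.donor_id), str(r.stimulus), str(r.marker),
            float(r.raw_p), float(r.adjusted_p), bool(r.positive),
        )
        for r in df.itertuples()
    ]


def write_association_matrix(amap: AssociationMap, path: str | Path) -> None:
    amap.matrix.astype(int).rename_axis("allele").to_csv(path, sep="\t")


def write_promiscuity(profile: PromiscuityProfile, path: str | Path) -> None:
    stimuli = sorted(profile.scores)
    pd.DataFrame(
        {
            "stimulus": stimuli,
            "promiscuity_score": [profile.scores[s] for s in stimuli],
            "n_associated_alleles": [profile.allele_counts[s] for s in stimuli],
        }
    ).to_csv(path, sep="\t", index=False)


def write_regions(regions: Sequence[PeptideRegion], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "start": r.start,
                "end": r.end,
                "length": r.length,
                "n_peptides": len(r.supporting_peptides),
                "donors": ",".join(sorted(r.supporting_donors)),
            }
            for r in regions
        ]
    ).to_csv(path, sep="\t", index=False)


def write_mapps_summary(summary: MappsSummary, path: str | Path) -> None:
    pd.DataFrame(
        {
            "statistic": [
                "n_donors", "n_identifications", "n_unique_regions",
                "n_distinct_sequences", "min_length", "max_length",
                "median_length", "mean_per_donor",
            ],
            "value": [
                summary.n_donors, summary.n_identifications,
                summary.n_unique_regions, summary.n_distinct_sequences,
                summary.min_length, summary.max_length,
                summary.median_length, round(summary.mean_per_donor, 3),
            ],
        }
    ).to_csv(path, sep="\t", index=False)


def write_candidates(candidates: Sequence[EpitopeCandidate], path: str | Path) -> None:
    """The final epitope table: sequence, span, supporting donors and alleles."""
    pd.DataFrame(
        [
            {
                "sequence": c.sequence,
                "start": c.start,
                "end": c.end,
                "length": c.length,
                "mapps_donors": ",".join(
                    sorted({m.mapps_donor_id for m in c.supporting_matches})
                ),
                "tcell_donors": ",".join(
                    sorted({m.tcell_donor_id for m in c.supporting_matches})
                ),
                "alleles": ",".join(sorted(c.associated_alleles)),
            }
            for c in candidates
        ]
    ).to_csv(path, sep="\t", index=False)
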