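"""End-to-end orchestration of the three-part epitope-identification analysis.

``run_pipeline`` executes library design, responder calling, allele
association, MAPPs processing and the final integration in order, reading
the five input tables plus the antigen FASTA and writing every result table
(and a run log echoing the parameters) into the output directory.  Stage
outputs are pure functions of the inputs and configuration; a failure
aborts with the stage name and the offending record's error.
"""

from __future__ import annotations

import json
from contextlib import contextmanager
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, association, integrate, io, mapps, responders
from .library import assign_pools, tile_protein


@dataclass
class PipelineConfig:
    """Paths and parameters of one analysis run (loadable from YAML)."""

    fasta: str
    allele_frequencies: str
    genotypes_tcell: str
    genotypes_mapps: str
    counts: str
    mapps_peptides: str
    out_dir: str
    window: int = 15
    stagger: int = 5
    pool_size: int = 10
    alpha: float = 0.05
    ev_threshold: float = 0.05
    min_epitope_length: int = 9
    association_rules: tuple[str, ...] = ("any", "all")

    def __post_init__(self) -> None:
        for attr in (
            "fasta", "allele_frequencies", "genotypes_tcell",
            "genotypes_mapps", "counts", "mapps_peptides",
        ):
            p = Path(getattr(self, attr))
            if not p.exists():
                raise FileNotFoundError(f"{attr}: {p} does not exist")
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.ev_threshold <= 0:
            raise ValueError("ev_threshold must be positive")
        if self.min_epitope_length < 1:
            raise ValueError("min_epitope_length must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "association_rules" in raw:
            raw["association_rules"] = tuple(raw["association_rules"])
        return cls(**raw)


class PipelineStageError(RuntimeError):
    """A stage failed; ``stage`` names it and the cause is chained."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@contextmanager
def _stage(name: str):
    try:
        yield
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError(name, exc) from exc


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run the full analysis; returns a manifest of the written artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}

    def emit(key: str, filename: str) -> Path:
        manifest[key] = out / filename
        return manifest[key]

    with _stage("peptide_library"):
        protein = io.read_protein_fasta(config.fasta)
        peptides = tile_protein(protein, config.window, config.stagger)
        pools = assign_pools(peptides, config.pool_size)
        io.write_library(peptides, pools, emit("library", "library.tsv"))

    with _stage("responder_calling"):
        records = io.read_stimulation_counts(config.counts)
        calls = responders.call_responders(records, alpha=config.alpha)
        io.write_calls(calls, emit("calls", "calls.tsv"))
        responders.percent_responders_table(calls).to_csv(
            emit("percent_responders", "percent_responders.tsv"), sep="\t", index=False
        )
        ppd = responders.pools_per_donor(calls)
        pd.DataFrame(
            {"donor_id": list(ppd), "positive_pools": list(ppd.values())}
        ).to_csv(emit("pools_per_donor", "pools_per_donor.tsv"), sep="\t", index=False)
        responders.lfc_table(records).to_csv(
            emit("lfc", "log_fold_change.tsv"), sep="\t", index=False
        )
        responders.seb_quality_control(calls)

    with _stage("hla_association"):
        freqs = io.read_allele_frequencies(config.allele_frequencies)
        tcell_genotypes = io.read_genotypes(config.genotypes_tcell)
        for rule in config.association_rules:
            amap = association.build_association_map(calls, tcell_genotypes, rule)
            io.write_association_matrix(
                amap, emit(f"association_{rule}", f"association_{rule}.tsv")
            )
            io.write_promiscuity(
                association.promiscuity_scores(amap, freqs),
                emit(f"promiscuity_{rule}", f"promiscuity_{rule}.tsv"),
            )

    with _stage("mapps_processing"):
        raw_mapps = io.read_mapps_peptides(config.mapps_peptides)
        kept = mapps.filter_by_expect_value(raw_mapps, config.ev_threshold)
        mapped, _unmapped = mapps.map_mapps_peptides(kept, protein)
        io.write_mapps_peptides(mapped, emit("mapps_mapped", "mapps_mapped.tsv"))
        regions = mapps.merge_regions(mapped, scope="cohort")
        io.write_regions(regions, emit("mapps_regions", "mapps_regions.tsv"))
        io.write_mapps_summary(
            mapps.summarize_mapps(mapped, regions),
            emit("mapps_summary", "mapps_summary.tsv"),
        )
        counts_per_donor = mapps.per_donor_unique_counts(mapped)
        pd.DataFrame(
            {
                "donor_id": list(counts_per_donor),
                "unique_regions": list(counts_per_donor.values()),
            }
        ).to_csv(emit("mapps_per_donor", "mapps_per_donor.tsv"), sep="\t", index=False)

    with _stage("integration"):
        mapps_genotypes = io.read_genotypes(config.genotypes_mapps)
        candidates = integrate.integrate_epitopes(
            calls, mapped, tcell_genotypes, mapps_genotypes, pools, protein,
            min_length=config.min_epitope_length,
        )
        io.write_candidates(candidates, emit("candidates", "candidates.tsv"))
        coverage = integrate.epitope_population_coverage(candidates, freqs)
        with open(emit("coverage", "coverage.json"), "w") as fh:
            json.dump(
                {
                    "n_candidates": len(candidates),
                    "cumulative_allele_frequency_percent": coverage,
                },
                fh, indent=2, sort_keys=True,
            )
            fh.write("\n")

    with _stage("run_log"):
        with open(emit("run_log", "run_log.json"), "w") as fh:
            json.dump(
                {"version": __version__, "parameters": asdict(config)},
                fh, indent=2, sort_keys=True, default=str,
            )
            fh.write("\n")
    return manifest
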