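"""Figure helpers: association heatmaps, LFC heatmaps, MAPPs coverage tracks."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")  # headless; callers save to file
import matplotlib.pyplot as plt
import pandas as pd

from .association import AssociationMap
from .mapps import MappsPeptide


def plot_association_map(amap: AssociationMap, ax=None):
    """Binary allele x stimulus association heatmap."""
    if ax is None:
        _, ax = plt.subplots(
            figsize=(0.4 * len(amap.matrix.columns) + 2, 0.3 * len(amap.matrix) + 2)
        )
    ax.imshow(amap.matrix.to_numpy(dtype=int), aspect="auto", cmap="Greys")
    ax.set_xticks(range(len(amap.matrix.columns)), amap.matrix.columns, rotation=90)
    ax.set_yticks(range(len(amap.matrix)), amap.matrix.index)
    ax.set_title(f"Allele-stimulus associations ({amap.rule} rule)")
    return ax


def plot_lfc_heatmap(lfc: pd.DataFrame, marker: str, ax=None):
    """Donor x stimulus heatmap of log fold changes for one cytokine marker."""
    sub = lfc[lfc["marker"] == marker].pivot(
        index="donor_id", columns="stimulus", values="log_fold_change"
    )
    if ax is None:
        _, ax = plt.subplots(figsize=(0.35 * sub.shape[1] + 2, 0.3 * sub.shape[0] + 2))
    im = ax.imshow(sub.to_numpy(), aspect="auto", cmap="RdBu_r")
    ax.figure.colorbar(im, ax=ax, label=f"log fold change ({marker})")
    ax.set_xticks(range(sub.shape[1]), sub.columns, rotation=90)
    ax.set_yticks(range(sub.shape[0]), sub.index)
    return ax


def plot_mapps_tracks(peptides: Sequence[MappsPeptide], protein_length: int, ax=None):
    """Stacked per-donor tracks of mapped MAPPs identifications."""
    donors = sorted({p.donor_id for p in peptides})
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 0.4 * len(donors) + 2))
    offsets = {d: i for i, d in enumerate(donors)}
    lane_count: dict[str, int] = {}
    for p in sorted(peptides, key=lambda q: (q.donor_id, q.start)):
        lane = lane_count.get(p.donor_id, 0)
        lane_count[p.donor_id] = lane + 1
        y = offsets[p.donor_id] + 0.08 * (lane % 5)
        ax.hlines(y, p.start, p.end, lw=2)
    ax.set_xlim(1, protein_length)
    ax.set_yticks(range(len(donors)), donors)
    ax.set_xlabel("protein residue")
    return ax
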