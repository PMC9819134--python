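"""Figure helpers (SVG/PNG via matplotlib, Agg backend)."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .chromatogram import Chromatogram
from .clustering import InertiaCurve
from .peak_detection import PeakTable
from .profiling import FEATURE_NAMES, ProfileMatrix

__all__ = [
    "plot_chromatogram",
    "plot_elbow",
    "plot_parallel_coordinates",
    "plot_cluster_map",
]


def plot_chromatogram(
    chromatogram: Chromatogram,
    peak_table: PeakTable | None,
    path: str | Path,
) -> None:
    """One sample's trace with detected peaks marked as red crosses."""
    fig, ax = plt.subplots(figsize=(9, 3))
    ax.plot(chromatogram.rt, chromatogram.intensity, lw=0.5, color="C0")
    if peak_table is not None and len(peak_table):
        ax.plot(
            peak_table.rts,
            [p.height for p in peak_table],
            "rx",
            ms=5,
            label=f"{len(peak_table)} peaks",
        )
        ax.legend(loc="upper right", frameon=False)
    ax.set_xlabel("retention time [min]")
    ax.set_ylabel("intensity [a.u.]")
    ax.set_title(chromatogram.sample_id)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_elbow(curve: InertiaCurve, selected_k: int, path: str | Path) -> None:
    """Inertia vs. k with the elbow-selected k highlighted."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(curve.k_values, curve.inertias, "o-", color="C0")
    ax.axvline(selected_k, color="C3", ls="--", label=f"elbow k = {selected_k}")
    ax.set_xlabel("number of clusters k")
    ax.set_ylabel("within-cluster inertia")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_parallel_coordinates(
    matrix: ProfileMatrix, labels: np.ndarray, path: str | Path
) -> None:
    """Parallel-coordinates view of the 10 features coloured by cluster."""
    labels = np.asarray(labels)
    fig, ax = plt.subplots(figsize=(8, 4))
    xs = np.arange(matrix.values.shape[1])
    for row, label in zip(matrix.values, labels):
        ax.plot(xs, row, color=f"C{int(label) % 10}", alpha=0.5, lw=0.8)
    ax.set_xticks(xs, FEATURE_NAMES)
    ax.set_ylabel("standardized feature value" if matrix.standardized else "feature value")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_cluster_map(
    sample_ids: list[str], labels: np.ndarray, path: str | Path
) -> None:
    """Sample-to-cluster mapping: samples on the left, clusters right."""
    labels = np.asarray(labels)
    clusters = sorted(set(labels.tolist()))
    fig, ax = plt.subplots(figsize=(5, 0.18 * len(sample_ids) + 1))
    cluster_y = {
        c: (i + 0.5) * len(sample_ids) / len(clusters)
        for i, c in enumerate(clusters)
    }
    for i, (sid, label) in enumerate(zip(sample_ids, labels)):
        color = f"C{int(label) % 10}"
        ax.plot([0, 1], [i, cluster_y[label]], color=color, lw=0.8)
        ax.text(-0.02, i, sid, ha="right", va="center", fontsize=6)
    for c, y in cluster_y.items():
        name = f"cluster {c}" if c >= 0 else "noise"
        ax.text(1.02, y, name, ha="left", va="center", fontsize=9)
    ax.set_xlim(-0.3, 1.3)
    ax.axis("off")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
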