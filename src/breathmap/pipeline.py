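"""Convenience drivers chaining the pipeline stages over a cohort."""
from __future__ import annotations

import numpy as np

from .chromatogram import Chromatogram
from .clustering import InertiaCurve, inertia_curve, select_k_elbow, spectral
from .peak_detection import PeakParams, PeakTable, confirm_peaks, detect_peaks
from .profiling import ProfileMatrix, assemble_matrix, build_profile, standardize

__all__ = ["detect_cohort", "profile_cohort", "cluster_cohort"]


def detect_cohort(
    chromatograms: list[Chromatogram],
    params: PeakParams | None = None,
    confirm: bool = True,
    drop_unconfirmed: bool = False,
) -> list[PeakTable]:
    """Detect (and optionally DWT-confirm) peaks in every sample."""
    params = params or PeakParams()
    tables = []
    for chrom in chromatograms:
        table = detect_peaks(chrom, params)
        if confirm:
            table = confirm_peaks(table, chrom, params)
            if drop_unconfirmed:
                table = table.drop_unconfirmed()
        tables.append(table)
    return tables


def profile_cohort(
    peak_tables: list[PeakTable],
    rt_axis_range: tuple[float, float],
    standardized: bool = True,
) -> ProfileMatrix:
    """Build the (by default z-scored) 10-feature matrix of a cohort."""
    matrix = assemble_matrix(
        [build_profile(t, rt_axis_range) for t in peak_tables]
    )
    return standardize(matrix) if standardized else matrix


def cluster_cohort(
    matrix: ProfileMatrix,
    seed: int,
    k_max: int = 10,
) -> tuple[InertiaCurve, int, np.ndarray]:
    """Elbow-select k from the inertia curve, then spectral-cluster at k.

    Returns the inertia curve, the selected k and the spectral labels.
    """
    curve = inertia_curve(matrix, k_max=k_max, seed=seed)
    k = select_k_elbow(curve)
    result = spectral(matrix, k=k, seed=seed)
    return curve, k, result.labels
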