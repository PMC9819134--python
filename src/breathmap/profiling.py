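"""Per-signal 10-feature profiles and the cohort feature matrix.

Each sample's detected-peak table is condensed into a fixed-length
profile of ten features spanning count, magnitude, shape, area and
positional statistics of the peaks:

====  =======================================================
f0    number of detected peaks
f1    mean peak height (detector units)
f2    maximum peak height (detector units)
f3    mean prominence (detector units)
f4    mean width (minutes)
f5    total integrated area (detector units x minutes)
f6    mean area/intensity ratio (minutes)
f7    retention time of the tallest peak (minutes)
f8    SD of peak retention times (minutes, population SD)
f9    fraction of peaks in the first half of the rt axis
====  =======================================================

A sample with no detected peaks maps to the all-zero profile so that
degenerate samples remain clusterable.  Profiles are assembled row-wise
into a matrix and z-scored per column before distance-based clustering,
since raw features differ by orders of magnitude.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .peak_detection import PeakTable

__all__ = [
    "N_FEATURES",
    "FEATURE_NAMES",
    "FeatureProfile",
    "ProfileMatrix",
    "build_profile",
    "assemble_matrix",
    "standardize",
]

N_FEATURES = 10
FEATURE_NAMES = tuple(f"f{i}" for i in range(N_FEATURES))


@dataclass(frozen=True)
class FeatureProfile:
    """The 10-feature characteristic of one signal."""

    sample_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        if values.shape != (N_FEATURES,):
            raise ValueError(f"profile must have exactly {N_FEATURES} features")
        if not np.all(np.isfinite(values)):
            raise ValueError("profile features must be finite")
        if values[0] < 0 or not 0.0 <= values[9] <= 1.0:
            raise ValueError("peak count must be >= 0 and f9 in [0, 1]")


@dataclass
class ProfileMatrix:
    """Samples-by-features matrix; row order follows ``sample_ids``."""

    sample_ids: list[str]
    values: np.ndarray
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != N_FEATURES:
            raise ValueError(f"matrix must be n x {N_FEATURES}")
        if self.values.shape[0] != len(self.sample_ids):
            raise ValueError("row count must match sample_ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("matrix must have no missing values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


def build_profile(
    peak_table: PeakTable, rt_axis_range: tuple[float, float]
) -> FeatureProfile:
    """Condense one peak table into its 10-feature profile."""
    lo, hi = float(rt_axis_range[0]), float(rt_axis_range[1])
    if hi <= lo:
        raise ValueError("rt_axis_range must be increasing")
    if not peak_table.peaks:
        return FeatureProfile(peak_table.sample_id, np.zeros(N_FEATURES))
    rts = peak_table.rts
    if rts.min() < lo or rts.max() > hi:
        raise ValueError("peak rt outside the stated axis range")
    heights = np.array([p.height for p in peak_table])
    proms = np.array([p.prominence for p in peak_table])
    widths = np.array([p.width for p in peak_table])
    areas = np.array([p.area for p in peak_table])
    ratios = np.array([p.ratio for p in peak_table])
    mid = 0.5 * (lo + hi)
    values = np.array(
        [
            float(len(peak_table)),
            heights.mean(),
            heights.max(),
            proms.mean(),
            widths.mean(),
            areas.sum(),
            ratios.mean(),
            float(rts[np.argmax(heights)]),
            rts.std(),
            float(np.mean(rts <= mid)),
        ]
    )
    return FeatureProfile(peak_table.sample_id, values)


def assemble_matrix(profiles: list[FeatureProfile]) -> ProfileMatrix:
    """Stack profiles row-wise, preserving input order."""
    if not profiles:
        raise ValueError("need at least one profile")
    ids = [p.sample_id for p in profiles]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sample ids: {dupes}")
    return ProfileMatrix(ids, np.vstack([p.values for p in profiles]))


def standardize(matrix: ProfileMatrix) -> ProfileMatrix:
    """Z-score each column (population SD); constant columns map to zeros."""
    if matrix.standardized:
        raise ValueError("matrix is already standardized")
    x = matrix.values
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    z = np.zeros_like(x)
    nz = sd > 0
    z[:, nz] = (x[:, nz] - mean[nz]) / sd[nz]
    return ProfileMatrix(list(matrix.sample_ids), z, standardized=True)
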