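"""The :class:`Chromatogram` container — one sample's GC trace.

A chromatogram is the raw object every stage-1 operator consumes: a
strictly increasing, (near-)uniformly spaced retention-time axis in
minutes and a same-length vector of detector intensities.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Chromatogram"]

#: minimum number of points a chromatogram must have
MIN_POINTS = 8

# relative tolerance on grid-spacing uniformity; downstream width/area
# conversions assume a uniform grid
_UNIFORMITY_RTOL = 1e-6


@dataclass
class Chromatogram:
    """A single sample's retention-time / intensity trace.

    Parameters
    ----------
    sample_id
        Identifier of the sample (typically the file stem).
    rt
        Retention times in minutes, strictly increasing, uniform spacing.
    intensity
        Detector response in arbitrary units; same length as ``rt``.
    """

    sample_id: str
    rt: np.ndarray = field(repr=False)
    intensity: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.rt.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("rt and intensity must be one-dimensional")
        if self.rt.shape != self.intensity.shape:
            raise ValueError(
                f"rt has {self.rt.size} points but intensity has "
                f"{self.intensity.size}"
            )
        if self.rt.size < MIN_POINTS:
            raise ValueError(
                f"chromatogram needs at least {MIN_POINTS} points, "
                f"got {self.rt.size}"
            )
        if not np.all(np.isfinite(self.rt)) or not np.all(
            np.isfinite(self.intensity)
        ):
            raise ValueError("rt and intensity must be finite")
        diffs = np.diff(self.rt)
        if np.any(diffs <= 0):
            bad = int(np.argmax(diffs <= 0))
            raise ValueError(
                f"rt must be strictly increasing (violated between points "
                f"{bad} and {bad + 1})"
            )
        if np.ptp(diffs) > _UNIFORMITY_RTOL * max(abs(diffs.mean()), 1e-300):
            raise ValueError("rt grid must be uniformly spaced")

    @property
    def n_points(self) -> int:
        return int(self.rt.size)

    @property
    def dt(self) -> float:
        """Grid spacing in minutes."""
        return float((self.rt[-1] - self.rt[0]) / (self.rt.size - 1))

    @property
    def rt_range(self) -> tuple[float, float]:
        return float(self.rt[0]), float(self.rt[-1])

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n_points
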