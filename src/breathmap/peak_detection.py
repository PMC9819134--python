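"""Stage 1: significant-peak detection in GC/MS chromatograms.

The detector finds local maxima of the trace, measures topographic
prominence, keeps peaks whose intensity (prominence by default, see
:class:`PeakParams`) reaches a significance threshold of 10,000 detector
units, integrates each peak between its two neighbouring local minima,
and records the area / intensity ratio.  Detected peaks can then be
confirmed against the lowpass (approximation) component of a discrete
wavelet transform of the trace at decomposition levels 1 and 2, using a
reverse-biorthogonal mother wavelet: a genuine chromatographic peak
survives the lowpass, whereas a sub-filter-width spike does not.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pywt
from scipy import signal

from .chromatogram import Chromatogram

__all__ = [
    "PeakParams",
    "Peak",
    "PeakTable",
    "find_local_maxima",
    "prominence_of",
    "integration_bounds",
    "peak_area",
    "detect_peaks",
    "dwt_approximation",
    "dwt_layers",
    "confirm_peaks",
    "peak_density",
]


@dataclass(frozen=True)
class PeakParams:
    """Detection and confirmation parameters.

    ``min_intensity`` is the significance threshold in detector units.
    ``intensity_basis`` selects which per-peak quantity is thresholded
    (and used as the ratio denominator): topographic ``prominence``
    (default — invariant to baseline offsets) or raw ``height``.
    ``width_rel_height`` is the fraction of prominence below the apex at
    which width is measured.  ``confirm_levels`` are the DWT
    decomposition levels whose approximations must co-locate a maximum
    within ``confirm_rt_tol`` minutes of a peak for it to be confirmed.
    """

    min_intensity: float = 10_000.0
    intensity_basis: str = "prominence"
    width_rel_height: float = 0.5
    wavelet_member: str = "rbio2.2"
    confirm_levels: tuple[int, ...] = (1, 2)
    confirm_rt_tol: float = 0.1
    confirm_min_retention: float = 0.5

    def __post_init__(self) -> None:
        if self.min_intensity <= 0:
            raise ValueError("min_intensity must be > 0")
        if self.intensity_basis not in ("prominence", "height"):
            raise ValueError("intensity_basis must be 'prominence' or 'height'")
        if not 0.0 < self.width_rel_height < 1.0:
            raise ValueError("width_rel_height must be in (0, 1)")
        if self.confirm_rt_tol <= 0:
            raise ValueError("confirm_rt_tol must be > 0")
        if not 0.0 <= self.confirm_min_retention <= 1.0:
            raise ValueError("confirm_min_retention must be in [0, 1]")
        object.__setattr__(self, "confirm_levels", tuple(self.confirm_levels))
        if not set(self.confirm_levels) <= {1, 2}:
            raise ValueError("confirm_levels must be a subset of {1, 2}")


@dataclass
class Peak:
    """One detected peak and its measured properties.

    Grid indices (``index``, ``left_index``, ``right_index``) are present
    when the peak was measured from a trace and ``None`` when it was read
    back from a peak-table file, which stores retention times only.
    """

    rt: float
    height: float
    prominence: float
    width: float
    left_rt: float
    right_rt: float
    area: float
    ratio: float
    confirmed: bool = False
    index: int | None = None
    left_index: int | None = None
    right_index: int | None = None

    def __post_init__(self) -> None:
        if self.index is not None:
            if not self.left_index < self.index < self.right_index:
                raise ValueError(
                    "integration bounds must bracket the peak index"
                )
        if self.area < 0:
            raise ValueError("area must be >= 0")

    def basis_value(self, intensity_basis: str) -> float:
        return self.prominence if intensity_basis == "prominence" else self.height


@dataclass
class PeakTable:
    """All detected peaks of one sample, sorted by retention time."""

    sample_id: str
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        rts = [p.rt for p in self.peaks]
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValueError("peaks must have strictly increasing rt")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    @property
    def rts(self) -> np.ndarray:
        return np.array([p.rt for p in self.peaks], dtype=np.float64)

    def drop_unconfirmed(self) -> "PeakTable":
        return PeakTable(self.sample_id, [p for p in self.peaks if p.confirmed])


# ---------------------------------------------------------------------------
# Elementary operators
# ---------------------------------------------------------------------------


def find_local_maxima(intensity: np.ndarray) -> np.ndarray:
    """Indices of interior local maxima (plateaus report their left edge).

    An index qualifies when its value strictly exceeds both neighbouring
    values; a plateau of equal values flanked by strictly lower values
    counts once, at its leftmost index.  Endpoints are never maxima.
    """
    x = np.asarray(intensity, dtype=np.float64)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("need a 1-D trace of at least 3 points")
    _, props = signal.find_peaks(x, plateau_size=1)
    return props["left_edges"].astype(np.intp)


def prominence_of(intensity: np.ndarray, peak_index: int) -> float:
    """Topographic prominence of the local maximum at ``peak_index``.

    Height minus the higher of the two minimal valleys that separate the
    peak from nearer higher terrain (or from the signal edge, whichever
    comes first).
    """
    x = np.asarray(intensity, dtype=np.float64)
    maxima = find_local_maxima(x)
    if peak_index not in maxima:
        raise ValueError(f"index {peak_index} is not a local maximum")
    prom = signal.peak_prominences(x, np.array([peak_index]))[0]
    return float(prom[0])


def _min_runs(x: np.ndarray) -> list[tuple[int, int]]:
    """Maximal equal-value runs that are interior local minima.

    A run ``[a, b]`` qualifies when both flanking values exist and are
    strictly greater than the run value; runs touching an endpoint never
    qualify (the endpoint fallback of :func:`integration_bounds` covers
    monotone edges).
    """
    n = x.size
    runs: list[tuple[int, int]] = []
    a = 0
    while a < n:
        b = a
        while b + 1 < n and x[b + 1] == x[a]:
            b += 1
        if a > 0 and b < n - 1 and x[a - 1] > x[a] and x[b + 1] > x[a]:
            runs.append((a, b))
        a = b + 1
    return runs


def integration_bounds(
    intensity: np.ndarray, peak_index: int
) -> tuple[int, int]:
    """Indices of the two neighbouring local minima around a peak.

    The left bound is the nearest local-minimum run left of the peak
    (reported at its leftmost index), falling back to 0 when the trace
    rises monotonically from the start; symmetrically on the right.
    """
    x = np.asarray(intensity, dtype=np.float64)
    maxima = find_local_maxima(x)
    if peak_index not in maxima:
        raise ValueError(f"index {peak_index} is not a local maximum")
    return _bounds_from_runs(_min_runs(x), peak_index, x.size)


def _bounds_from_runs(
    runs: list[tuple[int, int]], peak_index: int, n: int
) -> tuple[int, int]:
    left = 0
    for a, b in runs:
        if b < peak_index:
            left = a
        else:
            break
    right = n - 1
    for a, b in runs:
        if a > peak_index:
            right = b
            break
    return left, right


def peak_area(
    chromatogram: Chromatogram, left_index: int, right_index: int
) -> float:
    """Trapezoidal area under the trace between the two bounds.

    No baseline subtraction is applied; units are detector units x minutes.
    """
    if not 0 <= left_index < right_index < chromatogram.n_points:
        raise ValueError(
            f"invalid integration bounds ({left_index}, {right_index})"
        )
    sl = slice(left_index, right_index + 1)
    return float(np.trapezoid(chromatogram.intensity[sl], chromatogram.rt[sl]))


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------


def detect_peaks(
    chromatogram: Chromatogram, params: PeakParams | None = None
) -> PeakTable:
    """Detect and measure all significant peaks of one chromatogram.

    Composes maxima detection, prominence measurement, the intensity
    filter, integration-bound search, trapezoidal area and the
    area/intensity ratio; width is measured at ``width_rel_height`` of
    prominence by linear interpolation on both flanks.  ``confirmed``
    flags are initialised to False (see :func:`confirm_peaks`).
    """
    params = params or PeakParams()
    x = chromatogram.intensity
    maxima = find_local_maxima(x)
    if maxima.size == 0:
        return PeakTable(chromatogram.sample_id, [])
    proms, left_bases, right_bases = signal.peak_prominences(x, maxima)
    heights = x[maxima]
    basis = proms if params.intensity_basis == "prominence" else heights
    keep = basis >= params.min_intensity
    maxima = maxima[keep]
    if maxima.size == 0:
        return PeakTable(chromatogram.sample_id, [])
    proms = proms[keep]
    heights = heights[keep]
    basis = basis[keep]
    widths_samples = signal.peak_widths(
        x,
        maxima,
        rel_height=params.width_rel_height,
        prominence_data=(proms, left_bases[keep], right_bases[keep]),
    )[0]
    widths = widths_samples * chromatogram.dt
    runs = _min_runs(x)
    peaks = []
    for i, idx in enumerate(maxima):
        left, right = _bounds_from_runs(runs, int(idx), x.size)
        area = peak_area(chromatogram, left, right)
        peaks.append(
            Peak(
                rt=float(chromatogram.rt[idx]),
                height=float(heights[i]),
                prominence=float(proms[i]),
                width=float(widths[i]),
                left_rt=float(chromatogram.rt[left]),
                right_rt=float(chromatogram.rt[right]),
                area=area,
                ratio=area / float(basis[i]),
                confirmed=False,
                index=int(idx),
                left_index=left,
                right_index=right,
            )
        )
    return PeakTable(chromatogram.sample_id, peaks)


# ---------------------------------------------------------------------------
# DWT confirmation
# ---------------------------------------------------------------------------


def _check_dwt_length(n: int, level: int, wavelet: pywt.Wavelet) -> None:
    need = wavelet.dec_len * 2**level
    if n < need:
        raise ValueError(
            f"signal of length {n} too short for level {level} with "
            f"{wavelet.name} (need >= {need} points)"
        )


def dwt_approximation(
    intensity: np.ndarray, level: int, wavelet_member: str = "rbio2.2"
) -> np.ndarray:
    """Lowpass (approximation) component at ``level``, on the original grid.

    Multilevel DWT with symmetric boundary extension; all detail bands
    are zeroed and the signal reconstructed back to the input length.
    """
    x = np.asarray(intensity, dtype=np.float64)
    if level < 1:
        raise ValueError("level must be >= 1")
    wavelet = pywt.Wavelet(wavelet_member)
    _check_dwt_length(x.size, level, wavelet)
    coeffs = pywt.wavedec(x, wavelet, mode="symmetric", level=level)
    coeffs = [coeffs[0]] + [np.zeros_like(c) for c in coeffs[1:]]
    return pywt.waverec(coeffs, wavelet, mode="symmetric")[: x.size]


def dwt_layers(
    intensity: np.ndarray, level: int, wavelet_member: str = "rbio2.2"
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Approximation plus per-level detail layers, each on the original grid.

    The layers sum to the input up to floating-point error (perfect
    reconstruction of the biorthogonal filter bank).
    """
    x = np.asarray(intensity, dtype=np.float64)
    wavelet = pywt.Wavelet(wavelet_member)
    _check_dwt_length(x.size, level, wavelet)
    coeffs = pywt.wavedec(x, wavelet, mode="symmetric", level=level)
    approx = pywt.waverec(
        [coeffs[0]] + [np.zeros_like(c) for c in coeffs[1:]],
        wavelet,
        mode="symmetric",
    )[: x.size]
    details = []
    for j in range(1, len(coeffs)):
        sel = [np.zeros_like(c) for c in coeffs]
        sel[j] = coeffs[j]
        details.append(pywt.waverec(sel, wavelet, mode="symmetric")[: x.size])
    return approx, details


def confirm_peaks(
    peak_table: PeakTable,
    chromatogram: Chromatogram,
    params: PeakParams | None = None,
) -> PeakTable:
    """Set each peak's ``confirmed`` flag from the DWT approximations.

    A peak is confirmed iff, for every level in ``confirm_levels``, the
    approximation signal at that level has a local maximum within
    ``confirm_rt_tol`` minutes of the peak's retention time whose own
    prominence retains at least ``confirm_min_retention`` of the peak's
    prominence.  The retention requirement is what actually
    distinguishes a genuine chromatographic peak from a sub-filter-width
    spike: the lowpass reconstruction of an impulse still shows small
    ringing maxima at its location, but carries only a fraction of its
    amplitude, whereas a peak wider than the filter support passes
    through the approximation almost unattenuated.
    """
    params = params or PeakParams()
    if peak_table.sample_id != chromatogram.sample_id:
        raise ValueError(
            f"peak table is for {peak_table.sample_id!r} but chromatogram "
            f"is {chromatogram.sample_id!r}"
        )
    if not peak_table.peaks:
        return PeakTable(peak_table.sample_id, [])
    levels = []
    for level in params.confirm_levels:
        approx = dwt_approximation(
            chromatogram.intensity, level, params.wavelet_member
        )
        maxima = find_local_maxima(approx)
        proms = (
            signal.peak_prominences(approx, maxima)[0]
            if maxima.size
            else np.empty(0)
        )
        levels.append((chromatogram.rt[maxima], proms))
    confirmed_peaks = []
    for peak in peak_table:
        ok = True
        for rts, proms in levels:
            near = np.abs(rts - peak.rt) <= params.confirm_rt_tol
            retained = proms[near] >= params.confirm_min_retention * peak.prominence
            if not np.any(retained):
                ok = False
                break
        confirmed_peaks.append(replace(peak, confirmed=ok))
    return PeakTable(peak_table.sample_id, confirmed_peaks)


# ---------------------------------------------------------------------------
# Cohort-level summary
# ---------------------------------------------------------------------------


def peak_density(
    peak_tables: list[PeakTable],
    n_bins: int,
    rt_range: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of all peaks from all samples over equal-width rt bins.

    Returns ``(counts, bin_edges)``; the counts sum to the total number
    of peaks.  ``rt_range`` defaults to the span of the observed peaks.
    """
    if not peak_tables:
        raise ValueError("need at least one peak table")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    rts = np.concatenate([t.rts for t in peak_tables]) if any(
        len(t) for t in peak_tables
    ) else np.empty(0)
    if rt_range is None:
        if rts.size == 0:
            raise ValueError("no peaks and no explicit rt_range")
        rt_range = (float(rts.min()), float(rts.max()))
    counts, edges = np.histogram(rts, bins=n_bins, range=rt_range)
    return counts, edges
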