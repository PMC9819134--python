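"""Stage-1 operators against brute-force oracles and closed forms."""
import numpy as np
import pytest

import breathmap as bm
from breathmap import Chromatogram, PeakParams
from breathmap.peak_detection import dwt_layers

# ---------------------------------------------------------------------------
# Brute-force oracles (independent of the implementation under test)
# ---------------------------------------------------------------------------


def brute_maxima(x):
    """Strict interior triple scan (valid for plateau-free traces)."""
    return [
        i for i in range(1, len(x) - 1) if x[i] > x[i - 1] and x[i] > x[i + 1]
    ]


def brute_prominence(x, peak):
    """Definition-level prominence: walk to nearer higher terrain each side,
    take the minimal valley, keep the higher of the two valleys."""
    h = x[peak]

    def valley(indices):
        vals = []
        for j in indices:
            if x[j] > h:
                break
            vals.append(x[j])
        return min(vals) if vals else h

    left = valley(range(peak - 1, -1, -1))
    right = valley(range(peak + 1, len(x)))
    return h - max(left, right)


def brute_bounds(x, peak):
    """Nearest interior local minimum on each side (plateau-free traces)."""
    left = 0
    for j in range(peak - 1, 0, -1):
        if x[j] <= x[j - 1] and x[j] <= x[j + 1]:
            left = j
            break
    right = len(x) - 1
    for j in range(peak + 1, len(x) - 1):
        if x[j] <= x[j - 1] and x[j] <= x[j + 1]:
            right = j
            break
    return left, right


def _random_traces(n_traces=100, length=200, seed=7734):
    rng = np.random.default_rng(seed)
    for _ in range(n_traces):
        yield rng.uniform(0.0, 1e5, size=length)


# ---------------------------------------------------------------------------
# Local maxima
# ---------------------------------------------------------------------------


class TestFindLocalMaxima:
    def test_two_isolated_peaks(self):
        assert bm.find_local_maxima([0, 1, 0, 5, 0]).tolist() == [1, 3]

    def test_constant_trace_has_no_maxima(self):
        assert bm.find_local_maxima([5, 5, 5, 5, 5]).size == 0

    def test_plateau_reports_leftmost_index(self):
        assert bm.find_local_maxima([0, 3, 3, 3, 1, 0]).tolist() == [1]

    def test_plateau_touching_endpoint_is_not_a_maximum(self):
        assert bm.find_local_maxima([3, 3, 1, 0, 0]).size == 0

    def test_matches_brute_force_on_random_traces(self):
        for x in _random_traces():
            assert bm.find_local_maxima(x).tolist() == brute_maxima(x)

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            bm.find_local_maxima([1.0, 2.0])


# ---------------------------------------------------------------------------
# Prominence
# ---------------------------------------------------------------------------


class TestProminence:
    def test_single_peak_prominence_is_height_minus_min(self):
        assert bm.prominence_of(np.array([0.0, 10.0, 0.0]), 1) == 10.0

    def test_valley_separates_from_higher_peak(self):
        # peak of height 6 separated from the higher peak by a valley at 2
        assert bm.prominence_of(np.array([0.0, 6.0, 2.0, 10.0, 0.0]), 1) == 4.0

    def test_matches_definition_on_random_traces(self):
        for x in _random_traces(n_traces=30):
            for peak in bm.find_local_maxima(x):
                assert bm.prominence_of(x, int(peak)) == pytest.approx(
                    brute_prominence(x, int(peak))
                )

    def test_never_exceeds_height_minus_global_min(self):
        for x in _random_traces(n_traces=10):
            for peak in bm.find_local_maxima(x):
                assert (
                    bm.prominence_of(x, int(peak)) <= x[peak] - x.min() + 1e-9
                )

    def test_non_maximum_index_rejected(self):
        with pytest.raises(ValueError, match="not a local maximum"):
            bm.prominence_of(np.array([0.0, 1.0, 2.0, 3.0, 2.0]), 1)


# ---------------------------------------------------------------------------
# Integration bounds and area
# ---------------------------------------------------------------------------


class TestIntegrationBounds:
    def test_neighbouring_minima(self):
        x = np.array([0.0, 1.0, 0.0, 3.0, 0.0, 2.0, 0.0])
        assert bm.integration_bounds(x, 3) == (2, 4)

    def test_monotone_edges_fall_back_to_endpoints(self):
        x = np.array([0.0, 1.0, 2.0, 5.0, 4.0])
        assert bm.integration_bounds(x, 3) == (0, 4)

    def test_plateau_minimum_spans_whole_run(self):
        # left bound at the leftmost, right bound at the rightmost plateau index
        x = np.array([5.0, 1.0, 1.0, 2.0, 6.0, 3.0, 3.0, 7.0, 9.0])
        assert bm.integration_bounds(x, 4) == (1, 6)

    def test_brackets_and_no_interior_minimum_on_random_traces(self):
        for x in _random_traces():
            for peak in bm.find_local_maxima(x):
                left, right = bm.integration_bounds(x, int(peak))
                assert left < peak < right
                assert (left, right) == brute_bounds(x, int(peak))


class TestPeakArea:
    def _chrom(self, y, dt=1.0):
        y = np.asarray(y, dtype=float)
        return Chromatogram("a", np.arange(y.size) * dt, y)

    def test_triangle_closed_form(self):
        chrom = self._chrom([0, 2, 0, 0, 0, 0, 0, 0])
        assert bm.peak_area(chrom, 0, 2) == 2.0

    def test_constant_over_one_minute(self):
        chrom = self._chrom([100.0] * 9, dt=1 / 8)
        assert bm.peak_area(chrom, 0, 8) == pytest.approx(100.0)

    def test_matches_dense_riemann_sum(self, rng):
        y = rng.uniform(0, 1e4, 50)
        chrom = self._chrom(y, dt=0.01)
        area = bm.peak_area(chrom, 3, 46)
        # dense midpoint Riemann sum over the piecewise-linear interpolant
        t = np.linspace(chrom.rt[3], chrom.rt[46], 200_001)
        dense = np.interp(t, chrom.rt, y)
        oracle = float(np.sum(0.5 * (dense[1:] + dense[:-1]) * np.diff(t)))
        assert area == pytest.approx(oracle, rel=1e-9)

    def test_reversed_bounds_rejected(self):
        chrom = self._chrom([0, 1, 0, 1, 0, 1, 0, 1])
        with pytest.raises(ValueError):
            bm.peak_area(chrom, 5, 2)


# ---------------------------------------------------------------------------
# detect_peaks
# ---------------------------------------------------------------------------


def _gaussian_chrom(height, center=10.0, width=0.05, baseline=0.0, n=2401):
    rt = np.linspace(0.0, 20.0, n)
    y = baseline + height * np.exp(-((rt - center) ** 2) / (2 * width**2))
    return Chromatogram("g", rt, y)


class TestDetectPeaks:
    def test_sub_threshold_prominence_is_filtered(self):
        table = bm.detect_peaks(_gaussian_chrom(9_999.0))
        assert len(table) == 0

    def test_single_significant_gaussian(self):
        table = bm.detect_peaks(_gaussian_chrom(20_000.0))
        assert len(table) == 1
        (peak,) = table
        assert peak.ratio > 0
        assert peak.rt == pytest.approx(10.0, abs=0.01)
        assert peak.prominence == pytest.approx(20_000.0, rel=1e-3)
        # width at half prominence ~ FWHM of the Gaussian
        assert peak.width == pytest.approx(2.3548 * 0.05, rel=0.05)

    def test_threshold_monotonicity(self, bnp37_cohort):
        _, chromatograms, _, _ = bnp37_cohort
        chrom = chromatograms[0]
        counts = [
            len(bm.detect_peaks(chrom, PeakParams(min_intensity=thr)))
            for thr in (1_000, 5_000, 10_000, 20_000, 50_000)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_shift_equivariance_in_rt(self):
        chrom = _gaussian_chrom(25_000.0)
        shifted = Chromatogram("g", chrom.rt + 7.0, chrom.intensity)
        a = bm.detect_peaks(chrom)
        b = bm.detect_peaks(shifted)
        assert len(a) == len(b) == 1
        assert b.peaks[0].rt == pytest.approx(a.peaks[0].rt + 7.0)
        for attr in ("height", "prominence", "width"):
            assert getattr(b.peaks[0], attr) == getattr(a.peaks[0], attr)

    def test_baseline_offset_moves_height_not_prominence(self):
        chrom = _gaussian_chrom(25_000.0)
        offset = Chromatogram("g", chrom.rt, chrom.intensity + 500.0)
        a = bm.detect_peaks(chrom).peaks[0]
        b = bm.detect_peaks(offset).peaks[0]
        assert b.prominence == pytest.approx(a.prominence, rel=1e-9)
        assert b.height == pytest.approx(a.height + 500.0)

    def test_cohort_counts_match_generator_ground_truth(self, bnp37_cohort):
        # every detected peak should sit within jitter range of a template
        # rt center, and every template peak far above threshold must be found
        scenario, chromatograms, labels, _ = bnp37_cohort
        for chrom, label in zip(chromatograms[::5], labels[::5]):
            template = scenario.class_templates[label]
            specs = template.shared_peaks + template.unique_peaks
            centers = np.array([p.rt_center for p in specs])
            strong = centers[
                np.array([p.height_mean for p in specs]) >= 15_000
            ]
            table = bm.detect_peaks(chrom)
            for center in strong:
                assert np.min(np.abs(table.rts - center)) < 0.15
            for peak in table:
                assert np.min(np.abs(centers - peak.rt)) < 0.15


# ---------------------------------------------------------------------------
# DWT approximation and confirmation
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("wavelet", ["rbio2.2", "rbio1.3"])
class TestDWT:
    def test_constant_signal_preserved(self, wavelet):
        x = np.full(512, 100.0)
        for level in (1, 2):
            approx = bm.dwt_approximation(x, level, wavelet)
            assert approx.shape == x.shape
            np.testing.assert_allclose(approx, 100.0, atol=1e-8)

    def test_lowpass_reduces_white_noise_variance(self, wavelet, rng):
        x = rng.normal(0.0, 1.0, 4096)
        approx = bm.dwt_approximation(x, 2, wavelet)
        assert approx.var() < x.var()

    def test_perfect_reconstruction_of_layers(self, wavelet, rng):
        x = rng.uniform(0, 1e5, 777)
        approx, details = dwt_layers(x, 2, wavelet)
        np.testing.assert_allclose(
            approx + sum(details), x, atol=1e-8 * max(1.0, np.abs(x).max())
        )

    def test_signal_too_short_for_level(self, wavelet):
        with pytest.raises(ValueError, match="too short"):
            bm.dwt_approximation(np.ones(8), 2, wavelet)


class TestConfirmPeaks:
    def test_broad_gaussian_confirmed_at_both_levels(self):
        chrom = _gaussian_chrom(20_000.0, baseline=100.0)
        table = bm.confirm_peaks(bm.detect_peaks(chrom), chrom)
        assert [p.confirmed for p in table] == [True]

    def test_impulse_unconfirmed_at_level_two(self):
        rt = np.linspace(0.0, 10.0, 1200)
        y = np.full(rt.size, 100.0)
        y[600] = 30_000.0
        chrom = Chromatogram("imp", rt, y)
        level2 = bm.confirm_peaks(bm.detect_peaks(chrom), chrom)
        assert [p.confirmed for p in level2] == [False]
        level1_only = bm.confirm_peaks(
            bm.detect_peaks(chrom), chrom, PeakParams(confirm_levels=(1,))
        )
        assert [p.confirmed for p in level1_only] == [True]

    def test_empty_table_passes_through(self):
        chrom = _gaussian_chrom(5_000.0)
        table = bm.confirm_peaks(bm.detect_peaks(chrom), chrom)
        assert len(table) == 0

    def test_mismatched_sample_id_rejected(self):
        chrom = _gaussian_chrom(20_000.0)
        table = bm.detect_peaks(chrom)
        other = Chromatogram("other", chrom.rt, chrom.intensity)
        with pytest.raises(ValueError, match="other"):
            bm.confirm_peaks(table, other)

    def test_shrinking_tolerance_never_confirms_more(self, bnp37_cohort):
        _, chromatograms, _, _ = bnp37_cohort
        chrom = chromatograms[0]
        table = bm.detect_peaks(chrom)
        confirmed = [
            sum(
                p.confirmed
                for p in bm.confirm_peaks(
                    table, chrom, PeakParams(confirm_rt_tol=tol)
                )
            )
            for tol in (0.2, 0.1, 0.05, 0.02)
        ]
        assert confirmed == sorted(confirmed, reverse=True)


# ---------------------------------------------------------------------------
# Peak density
# ---------------------------------------------------------------------------


class TestPeakDensity:
    def test_single_bin_counts_all_peaks(self):
        chrom = _gaussian_chrom(20_000.0)
        table = bm.detect_peaks(chrom)
        counts, edges = bm.peak_density([table, table], 1)
        assert counts.tolist() == [2]

    def test_counts_are_conserved_across_bins(self, bnp37_tables, bnp37_cohort):
        scenario = bnp37_cohort[0]
        counts, _ = bm.peak_density(
            bnp37_tables, 10, rt_range=(scenario.rt_start, scenario.rt_end)
        )
        assert counts.sum() == sum(len(t) for t in bnp37_tables)

    def test_modes_sit_on_template_centers(self, bnp37_tables, bnp37_cohort):
        scenario = bnp37_cohort[0]
        counts, edges = bm.peak_density(
            bnp37_tables, 105, rt_range=(scenario.rt_start, scenario.rt_end)
        )
        centers = 0.5 * (edges[:-1] + edges[1:])
        bin_width = edges[1] - edges[0]
        template_rts = np.array(
            [
                p.rt_center
                for t in scenario.class_templates
                for p in t.shared_peaks + t.unique_peaks
            ]
        )
        top_bins = centers[np.argsort(counts)[-10:]]
        for center in top_bins:
            assert np.min(np.abs(template_rts - center)) <= bin_width

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            bm.peak_density([], 10)
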