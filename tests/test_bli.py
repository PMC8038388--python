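"""Bioluminescence quantification: peaks, normalizations, t-tests.

The t-test oracle recomputes the statistic and two-sided p-value directly
from the closed-form definitions via the t distribution CDF, independent of
the implementation path.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from oxypd.bli import (DegenerateTestError, FluxTimecourse, TumorMeasurement,
                       ellipsoid_volume, flux_per_volume, fold_change,
                       normalize_to_baseline, paired_test, peak_flux,
                       significance_mark, unpaired_test)
from oxypd.phantom import FluxPhantomSpec, make_flux_timecourses


def _tc(times, flux, animal="a", session="baseline"):
    return FluxTimecourse(animal, session, np.asarray(times, float),
                          np.asarray(flux, float))


class TestPeakFlux:
    def test_maximum_and_time(self):
        assert peak_flux(_tc([0, 2, 4, 6, 8], [2, 5, 9, 7, 4])) == (9.0, 4.0)

    def test_tie_resolves_to_earliest_time(self):
        assert peak_flux(_tc([0, 2, 4], [3, 3, 3])) == (3.0, 0.0)

    def test_matches_generator_analytic_maximum(self):
        spec = FluxPhantomSpec(noise_cv=0.0)
        tcs = make_flux_timecourses(spec)
        expected = spec.analytic_flux(spec.baseline_peak).max()
        for courses in tcs.values():
            peak, t_peak = peak_flux(courses["baseline"])
            assert peak == pytest.approx(expected, rel=1e-12)
            assert t_peak == spec.time_to_peak_min

    def test_adding_a_timepoint_never_lowers_peak(self):
        base = _tc([0, 2, 4], [1, 5, 2])
        extended = _tc([0, 2, 4, 6], [1, 5, 2, 4])
        assert peak_flux(extended)[0] >= peak_flux(base)[0]

    def test_empty_timecourse_rejected(self):
        with pytest.raises(ValueError):
            _tc([], [])


class TestNormalization:
    def test_ratio_and_group_stats(self):
        ratios, g = normalize_to_baseline({"m1": (1e6, 5.5e5), "m2": (2e6, 2e6)})
        assert ratios["m1"] == pytest.approx(0.55)
        assert ratios["m2"] == 1.0
        assert g["n"] == 2
        assert g["sem"] == pytest.approx(g["sd"] / np.sqrt(2))

    def test_zero_baseline_excluded_with_log(self, caplog):
        ratios, g = normalize_to_baseline({"m1": (0.0, 1e5), "m2": (1e6, 5e5)})
        assert "m1" not in ratios and g["excluded"] == ["m1"]
        assert g["n"] == 1

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(c=st.floats(1e-6, 1e6))
    def test_common_scaling_leaves_ratio_unchanged(self, c):
        r1, _ = normalize_to_baseline({"m": (2e6, 1e6)})
        r2, _ = normalize_to_baseline({"m": (2e6 * c, 1e6 * c)})
        assert r2["m"] == pytest.approx(r1["m"], rel=1e-9)

    def test_phantom_cohort_recovers_fold_within_3_sem(self):
        spec = FluxPhantomSpec(treatment_fold=0.55, noise_cv=0.1, n_animals=6,
                               seed=21)
        tcs = make_flux_timecourses(spec)
        peaks = {a: (peak_flux(c["baseline"])[0], peak_flux(c["treatment"])[0])
                 for a, c in tcs.items()}
        _, g = normalize_to_baseline(peaks)
        assert abs(g["mean"] - 0.55) <= 3 * g["sem"]


class TestVolumes:
    def test_modified_ellipsoid_formula(self):
        assert ellipsoid_volume(10, 5) == 125.0
        assert ellipsoid_volume(8, 8) == 256.0

    def test_swapped_axes_corrected_with_warning(self):
        with pytest.warns(UserWarning):
            assert ellipsoid_volume(5, 10) == 125.0
        with pytest.warns(UserWarning):
            m = TumorMeasurement(5, 10)
        assert (m.length_mm, m.width_mm) == (10, 5)
        assert m.volume_mm3 == 125.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(l=st.floats(0.1, 50), w=st.floats(0.1, 50), c=st.floats(0.1, 10))
    def test_cubic_scaling_property(self, l, w, c):
        L, W = max(l, w), min(l, w)
        assert ellipsoid_volume(c * L, c * W) == pytest.approx(
            c ** 3 * ellipsoid_volume(L, W), rel=1e-9)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            ellipsoid_volume(0, 5)
        with pytest.raises(ValueError):
            flux_per_volume(1e6, 0.0)

    def test_flux_per_volume(self):
        assert flux_per_volume(1e6, 100.0) == 1e4
        assert flux_per_volume(1e6, 200.0) == 0.5 * flux_per_volume(1e6, 100.0)


class TestFoldChange:
    def test_direct_ratio(self):
        assert fold_change(18, 2) == 9.0
        assert fold_change(3.3, 3.3) == 1.0
        with pytest.raises(ValueError):
            fold_change(1.0, 0.0)


class TestSignificance:
    def test_mark_bands(self):
        assert significance_mark(0.2) == "ns"
        assert significance_mark(0.05) == "*"
        assert significance_mark(0.01) == "**"
        assert significance_mark(0.001) == "***"
        assert significance_mark(0.0499) == "*"

    def test_paired_identical_is_exact_null(self):
        r = paired_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t_statistic == 0.0 and r.p_value == 1.0
        assert r.significance_mark == "ns"

    def test_paired_constant_shift_is_degenerate(self):
        with pytest.raises(DegenerateTestError):
            paired_test([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])

    def test_unpaired_degenerate_and_null(self):
        r = unpaired_test([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert r.p_value == 1.0
        with pytest.raises(DegenerateTestError):
            unpaired_test([0.0, 0.0, 0.0], [1.0, 1.0, 1.0])

    def test_paired_matches_closed_form_oracle(self, rng):
        for _ in range(20):
            a = rng.normal(size=6)
            b = rng.normal(size=6)
            r = paired_test(a, b)
            d = b - a
            t = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
            p = 2 * sps.t.sf(abs(t), d.size - 1)
            assert r.t_statistic == pytest.approx(t, abs=1e-10)
            assert r.p_value == pytest.approx(p, abs=1e-10)

    def test_unpaired_matches_closed_form_oracle(self, rng):
        for _ in range(20):
            a, b = rng.normal(size=5), rng.normal(size=7)
            r = unpaired_test(a, b)
            sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) \
                / (a.size + b.size - 2)
            t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / a.size + 1 / b.size))
            p = 2 * sps.t.sf(abs(t), a.size + b.size - 2)
            assert r.t_statistic == pytest.approx(t, abs=1e-10)
            assert r.p_value == pytest.approx(p, abs=1e-10)

    def test_group_result_dispersion_conventions(self, rng):
        a, b = rng.normal(size=6), rng.normal(size=6)
        r = paired_test(a, b)
        assert r.sem_a == pytest.approx(r.sd_a / np.sqrt(6))
        assert r.mean_a == pytest.approx(a.mean())

    def test_too_small_samples_rejected(self):
        with pytest.raises(ValueError):
            paired_test([1.0], [2.0])
        with pytest.raises(ValueError):
            unpaired_test([1.0], [1.0, 2.0])


def test_timecourse_validation():
    with pytest.raises(ValueError):
        _tc([0, 2, 2], [1, 2, 3])
    with pytest.raises(ValueError):
        _tc([0, 2], [1, -1])
    with pytest.raises(ValueError):
        _tc([0, 2], [1, 2, 3])
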