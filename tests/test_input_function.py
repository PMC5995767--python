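"""The four-stage parent-plasma input-function chain."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from petquant import (DiscreteSampleTable, SampledCurve, ValidationError,
                      apply_plasma_over_blood, build_ppif, cross_calibrate,
                      fit_parent_fraction, merge_continuous_discrete)
from petquant.input_function import ParentFractionFit


def _table(time, wb=None, plasma=None, pf=None):
    time = np.asarray(time, float)
    nan = np.full(time.size, np.nan)
    return DiscreteSampleTable(time,
                               nan if wb is None else wb,
                               nan if plasma is None else plasma,
                               nan if pf is None else pf)


# --------------------------------------------------------------------------
# cross-calibration
# --------------------------------------------------------------------------

class TestCrossCalibrate:
    def test_exact_scalar_recovered(self):
        t = np.arange(0.0, 901.0)
        truth = 1e4 * np.exp(-t / 600.0)
        cont = SampledCurve(t, 0.5 * truth)
        disc = _table([200.0, 400.0, 800.0], wb=np.interp([200, 400, 800], t, truth))
        calibrated, scalar = cross_calibrate(cont, disc)
        assert scalar == pytest.approx(2.0, abs=1e-9)
        np.testing.assert_allclose(calibrated.value, truth, rtol=1e-9)

    def test_identity_when_already_matched(self):
        t = np.arange(0.0, 901.0)
        v = 1e4 * np.exp(-t / 600.0)
        disc = _table([300.0, 600.0], wb=np.interp([300, 600], t, v))
        _, scalar = cross_calibrate(SampledCurve(t, v), disc)
        assert scalar == pytest.approx(1.0, abs=1e-12)

    def test_noisy_ratios_bracketed_by_least_squares(self):
        """With per-sample ratios {1.9, 2.0, 2.1}, the single fitted scalar
        must match the closed-form weighted least-squares value."""
        t = np.arange(0.0, 901.0)
        v = np.full(t.size, 1000.0) + t  # mildly varying
        times = np.array([200.0, 400.0, 800.0])
        c_at = np.interp(times, t, v)
        d = c_at * np.array([1.9, 2.0, 2.1])
        _, scalar = cross_calibrate(SampledCurve(t, v), _table(times, wb=d))
        oracle = np.dot(d, c_at) / np.dot(c_at, c_at)
        assert scalar == pytest.approx(oracle, rel=1e-12)
        assert 1.9 <= scalar <= 2.1

    def test_no_overlapping_samples_is_an_error(self):
        cont = SampledCurve(np.arange(0.0, 901.0), np.ones(901))
        with pytest.raises(ValidationError):
            cross_calibrate(cont, _table([2000.0, 3000.0], wb=[1.0, 1.0]))

    def test_zero_continuous_at_matches_is_an_error(self):
        cont = SampledCurve(np.arange(0.0, 901.0), np.zeros(901))
        with pytest.raises(ValidationError):
            cross_calibrate(cont, _table([300.0], wb=[5.0]))


# --------------------------------------------------------------------------
# plasma-over-blood
# --------------------------------------------------------------------------

class TestPlasmaOverBlood:
    def _curve(self):
        t = np.arange(0.0, 901.0)
        return SampledCurve(t, 1e3 + t)

    def test_unit_ratio_is_identity(self):
        c = self._curve()
        disc = _table([100.0, 800.0], wb=[2.0, 3.0], plasma=[2.0, 3.0])
        out = apply_plasma_over_blood(c, disc)
        np.testing.assert_allclose(out.value, c.value)

    def test_constant_ratio_scales_everywhere(self):
        c = self._curve()
        disc = _table([100.0, 800.0], wb=[2.0, 4.0], plasma=[2.6, 5.2])
        out = apply_plasma_over_blood(c, disc)
        np.testing.assert_allclose(out.value, 1.3 * c.value, rtol=1e-12)

    def test_linear_ratio_interpolated_at_midpoint(self):
        c = self._curve()
        disc = _table([0.0, 900.0], wb=[1.0, 1.0], plasma=[1.0, 1.2])
        out = apply_plasma_over_blood(c, disc)
        mid = 450
        assert out.value[mid] == pytest.approx(1.1 * c.value[mid], rel=1e-12)

    def test_zero_blood_with_positive_plasma_rejected(self):
        c = self._curve()
        disc = _table([100.0, 800.0], wb=[0.0, 1.0], plasma=[1.0, 1.0])
        with pytest.raises(ValidationError):
            apply_plasma_over_blood(c, disc)


# --------------------------------------------------------------------------
# tail merge
# --------------------------------------------------------------------------

class TestMerge:
    def test_exponential_tail_reconstructed(self):
        t_cont = np.arange(0.0, 901.0)
        decay = lambda t: 5e3 * np.exp(-np.asarray(t) / 2500.0)
        cont = SampledCurve(t_cont, decay(t_cont))
        tail_t = np.array([1200.0, 1800.0, 2700.0, 3600.0, 4500.0, 5430.0])
        disc = _table(tail_t, plasma=decay(tail_t))
        merged = merge_continuous_discrete(cont, disc)
        tt = np.arange(901.0, 5430.0)
        rel = np.abs(merged.interp(tt) / decay(tt) - 1.0)
        assert rel.max() < 0.02

    def test_single_tail_sample_flat_continuation(self):
        t_cont = np.arange(0.0, 901.0)
        cont = SampledCurve(t_cont, np.full(901, 100.0))
        merged = merge_continuous_discrete(cont, _table([5000.0], plasma=[100.0]))
        np.testing.assert_allclose(merged.interp([2000.0, 4000.0]), 100.0)

    def test_continuous_window_kept_verbatim(self):
        t_cont = np.arange(0.0, 901.0)
        v = 1e3 * np.exp(-t_cont / 500.0)
        cont = SampledCurve(t_cont, v)
        merged = merge_continuous_discrete(cont, _table([2000.0], plasma=[50.0]))
        np.testing.assert_array_equal(merged.value[:901], v)

    def test_no_tail_sample_is_an_error(self):
        cont = SampledCurve(np.arange(0.0, 901.0), np.ones(901))
        with pytest.raises(ValidationError):
            merge_continuous_discrete(cont, _table([500.0], plasma=[1.0]))


# --------------------------------------------------------------------------
# parent fraction
# --------------------------------------------------------------------------

class TestParentFraction:
    def test_recovers_generating_sigmoid(self):
        truth = ParentFractionFit(A=0.8, T50=1200.0, h=1.5)
        t = np.array([300.0, 600.0, 900.0, 1200.0, 1800.0, 2700.0, 3600.0,
                      4500.0, 5430.0])
        fit = fit_parent_fraction(_table(t, pf=truth(t)))
        assert fit.A == pytest.approx(0.8, rel=0.01)
        assert fit.T50 == pytest.approx(1200.0, rel=0.01)
        assert fit.h == pytest.approx(1.5, rel=0.01)

    def test_no_metabolism_gives_flat_unity(self):
        t = np.array([300.0, 900.0, 2700.0, 5430.0])
        fit = fit_parent_fraction(_table(t, pf=np.ones(4)))
        assert fit.A == pytest.approx(0.0, abs=1e-3)
        np.testing.assert_allclose(fit(np.array([0.0, 1000.0, 5000.0])), 1.0,
                                   atol=1e-3)

    def test_fitted_curve_is_unity_at_zero(self):
        t = np.array([300.0, 900.0, 2700.0, 5430.0])
        fit = fit_parent_fraction(_table(t, pf=[0.95, 0.8, 0.5, 0.3]))
        assert fit(0.0) == 1.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            fit_parent_fraction(_table([300.0, 900.0], pf=[0.9, 0.7]))


# --------------------------------------------------------------------------
# composition
# --------------------------------------------------------------------------

class TestBuildPpif:
    def test_zero_noise_end_to_end_recovery(self, metas, noisefree_spec):
        from petquant import simulate_blood
        cont, disc, true_if = simulate_blood(metas[0], noisefree_spec, seed=42)
        ppif, report = build_ppif(cont, disc, 5400.0, metas[0].id)
        assert abs(ppif.auc() / true_if.auc(5400.0) - 1.0) < 0.01
        tt = np.arange(60.0, 5401.0)
        pointwise = np.abs(ppif.value_at(tt) / true_if.value_at(tt) - 1.0)
        assert pointwise.max() < 0.03
        assert report["n_clamped"] == 0

    def test_ppif_below_plasma_curve(self, metas, cohort_spec):
        from petquant import simulate_blood
        from petquant.input_function import (apply_plasma_over_blood,
                                             cross_calibrate,
                                             merge_continuous_discrete)
        cont, disc, _ = simulate_blood(metas[1], cohort_spec, seed=43)
        calibrated, _ = cross_calibrate(cont, disc)
        merged = merge_continuous_discrete(
            apply_plasma_over_blood(calibrated, disc), disc)
        ppif, _ = build_ppif(cont, disc, 5400.0)
        plasma = np.interp(ppif.time, merged.time, merged.value)
        assert np.all(ppif.values <= plasma + 1e-9)

    def test_nonnegative_output(self, metas, cohort_spec):
        from petquant import simulate_blood
        cont, disc, _ = simulate_blood(metas[2], cohort_spec, seed=44)
        ppif, _ = build_ppif(cont, disc, 5400.0)
        assert np.all(ppif.values >= 0)

    @given(c=st.floats(min_value=0.1, max_value=10.0))
    def test_scale_equivariance(self, c, metas, noisefree_spec):
        """Scaling every measured activity by c scales the ppIF by c
        (the parent fraction is a ratio and is unaffected)."""
        from petquant import simulate_blood
        cont, disc, _ = simulate_blood(metas[3], noisefree_spec, seed=45)
        base, _ = build_ppif(cont, disc, 5400.0)
        scaled_disc = DiscreteSampleTable(disc.time, disc.wholeblood * c,
                                          disc.plasma * c, disc.parent_fraction)
        scaled, _ = build_ppif(cont.scaled(c), scaled_disc, 5400.0)
        np.testing.assert_allclose(scaled.values, c * base.values, rtol=1e-7,
                                   atol=1e-9)
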