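"""Population-based input functions: standardisation, anchoring, fixed points."""
import numpy as np
import pytest

from petquant import (BasisGrid, InputFunction, ParticipantMeta,
                      ValidationError, align_peaks, build_pbif_model,
                      fit_auc_regression, make_basis, median_curve,
                      normalise_magnitude, scale_pbif, spectral_fit)
from petquant.pbif import anchor_value


def _bolus(peak_s=60.0, amp=1e4, n=5401):
    t = np.arange(float(n))
    v = amp * (np.clip(t, 0, None) / peak_s) ** 2.5 \
        * np.exp(2.5 * (1.0 - t / peak_s)) + amp * 0.05 * np.exp(-t / 4000.0) \
        * (1.0 - np.exp(-((t / peak_s) ** 2)))
    return InputFunction(v, 1.0)


def _meta(pid="p01", w=70.0, d=187.0, a=40.0):
    return ParticipantMeta(pid, w, d, a)


class TestNormaliseMagnitude:
    def test_identical_covariates_unchanged(self):
        curves = [_bolus(amp=a) for a in (1e4, 2e4, 3e4)]
        metas = [_meta(f"p{i}") for i in range(3)]
        out = normalise_magnitude(curves, metas)
        for a, b in zip(out, curves):
            np.testing.assert_array_equal(a.values, b.values)

    def test_single_weight_factor(self):
        curves = [_bolus(), _bolus(), _bolus()]
        metas = [_meta("p0", w=80.0), _meta("p1", w=70.0), _meta("p2", w=70.0)]
        out = normalise_magnitude(curves, metas)
        np.testing.assert_allclose(out[0].values, curves[0].values * 70.0 / 80.0)
        np.testing.assert_allclose(out[1].values, curves[1].values)

    def test_factor_products_match_brute_force(self, rng):
        n = 8
        curves = [_bolus(amp=1e4 * (1 + 0.1 * i)) for i in range(n)]
        metas = [_meta(f"p{i}", w=float(rng.uniform(55, 95)),
                       d=float(rng.uniform(180, 195)),
                       a=float(rng.uniform(20, 62))) for i in range(n)]
        out = normalise_magnitude(curves, metas)
        med_w = np.median([m.weight_kg for m in metas])
        med_d = np.median([m.injected_dose_mbq for m in metas])
        med_a = np.median([m.age_years for m in metas])
        for i in range(n):
            factor = (med_w / metas[i].weight_kg) * (med_d / metas[i].injected_dose_mbq) \
                * (med_a / metas[i].age_years)
            np.testing.assert_allclose(out[i].values, curves[i].values * factor,
                                       rtol=1e-12)


class TestAlignPeaks:
    def test_peak_moved_to_80s(self):
        curve = _bolus(peak_s=60.0)
        aligned = align_peaks([curve])[0]
        assert abs(aligned.peak_time(5.0) - 80.0) <= 1.0

    def test_already_at_target_unchanged(self):
        # symmetric peak at exactly 80 s: smoothing cannot move the argmax
        t = np.arange(5401.0)
        curve = InputFunction(np.exp(-((t - 80.0) / 30.0) ** 2) * 1e4
                              + 100.0 * np.exp(-t / 4000.0), 1.0)
        aligned = align_peaks([curve])[0]
        assert abs(aligned.peak_time(5.0) - 80.0) <= 1.0
        np.testing.assert_allclose(aligned.values[:1000], curve.values[:1000],
                                   rtol=1e-9)

    def test_monotone_curve_rejected(self):
        t = np.arange(1000.0)
        with pytest.raises(ValidationError):
            align_peaks([InputFunction(t, 1.0)])

    def test_left_shift_truncates_common_support(self):
        early = _bolus(peak_s=60.0)   # shifted right by ~20 s
        late = _bolus(peak_s=100.0)   # shifted left by ~20 s
        aligned = align_peaks([early, late])
        assert aligned[0].values.size == aligned[1].values.size
        assert aligned[0].values.size < early.values.size


class TestMedianCurve:
    def test_constant_curves(self):
        curves = [InputFunction(np.full(100, v), 1.0) for v in (1.0, 2.0, 10.0)]
        med = median_curve(curves)
        np.testing.assert_array_equal(med.values, np.full(100, 2.0))

    def test_identity_for_identical_curves(self):
        c = _bolus()
        med = median_curve([c, c, c])
        np.testing.assert_array_equal(med.values, c.values)

    def test_bounded_by_order_statistics(self, rng):
        curves = [InputFunction(rng.random(50) + 0.1, 1.0) for _ in range(5)]
        med = median_curve(curves)
        stack = np.stack([c.values for c in curves])
        assert np.all(med.values <= stack.max(axis=0))
        assert np.all(med.values >= stack.min(axis=0))

    def test_fewer_than_three_rejected(self):
        c = _bolus()
        with pytest.raises(ValidationError):
            median_curve([c, c])


class TestAucRegression:
    def test_exact_linear_family(self):
        curves = [_bolus(amp=1e4 * c) for c in (0.5, 1.0, 1.5, 2.0)]
        anchors = np.array([anchor_value(c, 5000.0) for c in curves])
        slope, intercept = fit_auc_regression(curves, anchors)
        # AUC is exactly proportional to the anchor for a scaled family
        assert intercept == pytest.approx(0.0, abs=abs(slope) * 1e-9)
        assert slope == pytest.approx(curves[0].auc() / anchors[0], rel=1e-9)

    def test_two_points_rejected(self):
        curves = [_bolus(), _bolus(amp=2e4)]
        with pytest.raises(ValidationError):
            fit_auc_regression(curves, np.array([1.0, 2.0]))

    def test_matches_normal_equations_oracle(self, rng):
        curves = [_bolus(amp=1e4 * (1 + 0.2 * i)) for i in range(6)]
        anchors = np.array([anchor_value(c, 5000.0) * (1 + rng.normal(0, 0.05))
                            for c in curves])
        slope, intercept = fit_auc_regression(curves, anchors)
        aucs = np.array([c.auc() for c in curves])
        X = np.column_stack([anchors, np.ones_like(anchors)])
        beta = np.linalg.solve(X.T @ X, X.T @ aucs)
        assert slope == pytest.approx(beta[0], rel=1e-9)
        assert intercept == pytest.approx(beta[1], rel=1e-6)

    def test_zero_anchor_variance_rejected(self):
        curves = [_bolus(), _bolus(), _bolus()]
        with pytest.raises(ValidationError):
            fit_auc_regression(curves, np.array([2.0, 2.0, 2.0]))


class TestScalePbif:
    def _model(self):
        curves = [_bolus(amp=1e4 * c, peak_s=60.0) for c in (0.8, 1.0, 1.25, 1.5)]
        metas = [_meta(f"p{i}") for i in range(4)]
        return build_pbif_model(curves, metas)

    def test_fixed_point_when_predicted_equals_median_auc(self):
        model = self._model()
        anchor = (model.standardised_curve.auc() - model.intercept) / model.slope
        out = scale_pbif(model, anchor)
        np.testing.assert_allclose(out.values, model.standardised_curve.values,
                                   rtol=1e-9)

    def test_linear_in_predicted_auc(self):
        model = self._model()
        a1 = (model.standardised_curve.auc() - model.intercept) / model.slope
        a2 = (2.0 * model.standardised_curve.auc() - model.intercept) / model.slope
        out1, out2 = scale_pbif(model, a1), scale_pbif(model, a2)
        np.testing.assert_allclose(out2.values, 2.0 * out1.values, rtol=1e-9)

    def test_nonpositive_anchor_rejected(self):
        with pytest.raises(ValidationError):
            scale_pbif(self._model(), 0.0)


class TestEndToEndIdentity:
    def test_scaled_family_cohort_recovers_member_curve(self):
        """A cohort whose ppIFs share one shape (scaled copies, identical
        covariates): the leave-one-out PBIF of any member equals their own
        ppIF (< 1% AUC error)."""
        scales = [0.7, 0.85, 1.0, 1.2, 1.4]
        curves = [_bolus(amp=1e4 * c, peak_s=60.0) for c in scales]
        for i, c in enumerate(curves):
            c.participant_id = f"p{i}"
        metas = [_meta(f"p{i}") for i in range(5)]
        for i in range(5):
            model = build_pbif_model(curves, metas, exclude_id=f"p{i}")
            pbif = scale_pbif(model, anchor_value(curves[i], 5400.0))
            assert abs(pbif.auc() / curves[i].auc() - 1.0) < 0.01

    def test_pbif_vt_equals_ppif_vt_for_identity_cohort(self, true_if,
                                                        fit_schedule):
        """The PBIF fixed point propagates through spectral analysis: for an
        identity cohort the PBIF-derived V_T matches the ppIF-derived V_T
        within the SA oracle tolerance."""
        from petquant.spectral import frame_weights, simulate_tissue_tac
        from petquant.synthetic import params_for_vt
        from petquant.timing import frame_average

        ppif = InputFunction(true_if.values[:5401].copy(), 1.0, "p0", "ppif")
        curves = [ppif.scaled(c) for c in (0.8, 0.9, 1.0, 1.1, 1.25)]
        for i, c in enumerate(curves):
            c.participant_id = f"p{i}"
        metas = [_meta(f"p{i}") for i in range(5)]
        model = build_pbif_model(curves, metas, exclude_id="p2")
        pbif = scale_pbif(model, anchor_value(curves[2]))

        params = params_for_vt(10.0, vb=0.0)
        tac = frame_average(simulate_tissue_tac(params, curves[2]), 1.0, fit_schedule)
        grid = BasisGrid()
        w = frame_weights(fit_schedule)
        vt_ppif = spectral_fit(tac, make_basis(curves[2], grid, fit_schedule),
                               grid, w).vt
        vt_pbif = spectral_fit(tac, make_basis(pbif, grid, fit_schedule),
                               grid, w).vt
        assert vt_pbif == pytest.approx(vt_ppif, rel=0.02)

    def test_pipeline_invariant_to_participant_order(self):
        scales = [0.7, 1.0, 1.3, 0.9, 1.1]
        curves = [_bolus(amp=1e4 * c, peak_s=55.0 + 5 * i)
                  for i, c in enumerate(scales)]
        metas = [_meta(f"p{i}", w=60.0 + 5 * i, a=25.0 + 8 * i) for i in range(5)]
        model_fwd = build_pbif_model(curves, metas, exclude_id="p0")
        order = [3, 1, 4, 2, 0]
        model_rev = build_pbif_model([curves[i] for i in order],
                                     [metas[i] for i in order], exclude_id="p0")
        np.testing.assert_allclose(model_fwd.standardised_curve.values,
                                   model_rev.standardised_curve.values, rtol=1e-9)
        assert model_fwd.slope == pytest.approx(model_rev.slope, rel=1e-9)
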