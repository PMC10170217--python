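"""Forward model: bivariate Gaussian response, HRF prediction,
preprocessing."""

import numpy as np
import pytest
from hypothesis import given, strategies as hst

import magmap.model as md
from magmap.model import (
    HRFSpec,
    TuningParams,
    dct_highpass,
    neural_response,
    percent_signal_change,
    predict_bold,
)
from magmap.stimulus import build_run


def _contour_aspect(params: TuningParams) -> float:
    """Numeric oracle: half-height iso-response contour radii along many
    rays; the aspect ratio is the extreme-radius ratio."""
    from scipy.optimize import brentq

    angles = np.linspace(0, np.pi, 721)
    radii = []
    for a in angles:
        def f(r):
            return neural_response(
                params, params.mu_d + r * np.cos(a), params.mu_n + r * np.sin(a)
            ) - np.exp(-0.5)
        radii.append(brentq(f, 1e-6, 1000.0))
    radii = np.asarray(radii)
    return radii.max() / radii.min()


class TestNeuralResponse:
    def test_peak_is_one_at_preferred_magnitudes(self):
        p = TuningParams(37.0, 61.0, 9.0, 22.0, 48.0)
        assert neural_response(p, 37.0, 61.0) == pytest.approx(1.0)

    def test_isotropic_offset(self):
        p = TuningParams(50, 50, 10, 10, 0)
        assert neural_response(p, 60, 50) == pytest.approx(np.exp(-0.5))

    @pytest.mark.parametrize("theta", [0.0, 90.0])
    def test_separability_at_axis_aligned_orientations(self, theta):
        p = TuningParams(40, 60, 8, 20, theta)
        d, n = 55.0, 48.0
        sd, sn = (8, 20) if theta == 0 else (20, 8)
        expected = np.exp(-0.5 * ((d - 40) / sd) ** 2) * np.exp(-0.5 * ((n - 60) / sn) ** 2)
        assert neural_response(p, d, n) == pytest.approx(expected)

    def test_width_swap_rotation_symmetry(self):
        # swapping the two widths while rotating by 90 deg describes the
        # identical Gaussian (the axes merely trade labels)
        p = TuningParams(40, 60, 8, 20, 25.0)
        q = TuningParams(40, 60, 20, 8, 25.0 + 90.0)
        for dx, dy in [(7.0, -12.0), (-3.0, 5.0), (15.0, 15.0)]:
            assert neural_response(p, 40 + dx, 60 + dy) == pytest.approx(
                neural_response(q, 40 + dx, 60 + dy)
            )

    def test_transpose_symmetry(self):
        # exchanging the duration and numerosity roles mirrors the
        # orientation: swap widths and send theta to 180 - theta
        p = TuningParams(40, 60, 8, 20, 25.0)
        q = TuningParams(60, 40, 20, 8, 180.0 - 25.0)
        for dx, dy in [(7.0, -12.0), (-3.0, 5.0)]:
            assert neural_response(p, 40 + dx, 60 + dy) == pytest.approx(
                neural_response(q, 60 + dy, 40 + dx)
            )

    @given(
        hst.floats(3.0, 40.0), hst.floats(3.0, 40.0), hst.floats(0.0, 179.9)
    )
    def test_contour_aspect_matches_sigma_ratio(self, sd, sn, theta):
        p = TuningParams(50, 50, sd, sn, theta)
        expected = max(sd, sn) / min(sd, sn)
        assert _contour_aspect(p) == pytest.approx(expected, rel=1e-3)

    def test_theta_wrapped_axially(self):
        assert TuningParams(50, 50, 5, 9, 190.0).theta == pytest.approx(10.0)
        p = TuningParams(50, 50, 5, 9, 30.0)
        q = TuningParams(50, 50, 5, 9, 210.0)
        assert neural_response(p, 60, 45) == pytest.approx(neural_response(q, 60, 45))

    def test_singular_width_rejected(self):
        with pytest.raises(ValueError):
            TuningParams(50, 50, 0.0, 9.0, 0.0)


class TestHRF:
    def test_kernel_contract(self):
        t, h = HRFSpec().kernel()
        assert t[-1] >= 20.0
        assert np.trapezoid(h, t) > 0
        assert t[np.argmax(h)] == pytest.approx(5.0, abs=1.5)  # peak near 5-6 s

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            HRFSpec(dt=0.5)
        with pytest.raises(ValueError):
            HRFSpec(duration=10.0)


class TestPredictBold:
    def test_far_off_params_give_flat_prediction(self, run_C):
        # centre > 6 sigma from every presented (duration, numerosity)
        far = TuningParams(99.0, 1.0, 2.0, 2.0, 0.0)
        pred = predict_bold(far, run_C)
        assert np.max(np.abs(pred)) < 1e-6

    def test_single_impulse_equals_shifted_hrf(self, run_T):
        # a one-event sequence: prediction proportional to the sampled HRF
        from dataclasses import replace

        seq = replace(run_T, events=run_T.events[:1])
        ev = seq.events[0]
        mu_d, mu_n = md.stimulus_units(seq)[0]
        pred = predict_bold(TuningParams(mu_d, mu_n, 5.0, 5.0, 0.0), seq)
        hrf = HRFSpec()
        tk, hk = hrf.kernel()
        expected = np.interp(seq.frame_times - (ev.onset + ev.duration), tk, hk,
                             left=0.0, right=0.0)
        assert np.allclose(pred, expected, atol=1e-12)

    def test_linearity_in_impulse_height(self, run_C):
        design, dn = md.unique_stimulus_design(run_C)
        nr = np.random.default_rng(0).random(len(dn))
        assert np.allclose(design @ (2 * nr), 2 * (design @ nr))

    def test_commutes_with_event_reordering(self, run_C):
        from dataclasses import replace

        rng = np.random.default_rng(3)
        perm = rng.permutation(len(run_C.events))
        shuffled = replace(run_C, events=tuple(run_C.events[i] for i in perm))
        p = TuningParams(50, 50, 20, 20, 45)
        assert np.allclose(predict_bold(p, run_C), predict_bold(p, shuffled))


class TestPreprocessing:
    def test_constant_series_unfiltered(self):
        y = np.full(300, 7.0)
        assert np.allclose(dct_highpass(y), y)

    def test_basis_vector_annihilated(self):
        basis = md.dct_basis(304, 6)
        out = dct_highpass(basis[:, 0])
        assert np.allclose(out, 0.0, atol=1e-12)

    def test_idempotent_and_variance_reducing(self, rng):
        y = rng.standard_normal(304)
        f = dct_highpass(y)
        assert np.allclose(dct_highpass(f), f, atol=1e-12)
        assert f.var() < y.var()
        assert f.mean() == pytest.approx(y.mean())

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            dct_highpass(np.arange(5.0))

    def test_psc_arithmetic(self):
        assert np.allclose(percent_signal_change(np.array([100.0, 101, 99])), [0, 1, -1])
        assert np.allclose(percent_signal_change(np.full(10, 3.0)), 0.0)

    def test_psc_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            percent_signal_change(np.array([-1.0, 1.0]))

    def test_drift_removal_recovers_prediction_shape(self, run_C):
        # prediction + 2% linear drift, preprocessed, matches the
        # filtered drift-free shape with cosine similarity > 0.99
        p = TuningParams(60, 60, 20, 20, 45)
        pred = predict_bold(p, run_C)  # percent-signal units (amp 1)
        drift = np.linspace(-2.0, 2.0, run_C.n_volumes)
        raw = 1000.0 * (1.0 + (pred + drift) / 100.0)
        out = md.preprocess(raw)
        ref = dct_highpass(pred)
        a = out - out.mean()
        b = ref - ref.mean()
        cos = (a @ b) / np.sqrt((a @ a) * (b @ b))
        assert cos > 0.99
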