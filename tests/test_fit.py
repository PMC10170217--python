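"""Grid + iterative pRF estimation and inclusion thresholds."""

import numpy as np
import pandas as pd
import pytest

import magmap.fit as ft
import magmap.model as md
from magmap.fit import FitGrid, apply_threshold, glm_scale
from magmap.model import TuningParams


class TestGlmScale:
    def test_exact_linear_relation(self, rng):
        pred = rng.standard_normal(304)
        glm, r2 = glm_scale(pred, 3.0 * pred + 5.0)
        assert glm.amplitude == pytest.approx(3.0)
        assert glm.baseline == pytest.approx(5.0)
        assert r2 == pytest.approx(1.0)

    def test_orthogonal_data(self):
        t = np.arange(100.0)
        pred = np.sin(2 * np.pi * t / 10)
        data = np.cos(2 * np.pi * t / 10)  # orthogonal over full periods
        glm, r2 = glm_scale(pred, data)
        assert abs(glm.amplitude) < 1e-10
        assert r2 <= 1e-10

    def test_constant_prediction_rejected_with_sentinel(self):
        glm, r2 = glm_scale(np.full(50, 2.0), np.arange(50.0))
        assert r2 == -np.inf

    def test_noisy_r2_matches_variance_ratio(self, rng):
        pred = rng.standard_normal(304) * 2.0
        noise = rng.standard_normal(304)
        data = pred + noise
        _, r2 = glm_scale(pred, data)
        expected = 1.0 - noise.var() / data.var()
        assert r2 == pytest.approx(expected, abs=0.05)


@pytest.fixture(scope="module")
def small_grid():
    return FitGrid(mu=np.arange(0.0, 101.0, 10.0),
                   sigma=np.geomspace(2, 80, 6),
                   theta=np.arange(0.0, 180.0, 45.0))


class TestGridFit:
    def test_recovers_exact_grid_point(self, probe_seqs, small_grid):
        cache = ft.combined_design(probe_seqs)
        design, dn = cache
        true = TuningParams(40.0, 60.0, small_grid.sigma[2], small_grid.sigma[3], 45.0)
        data = 2.0 * (design @ md.neural_response(true, dn[:, 0], dn[:, 1])) + 1.0
        out = ft.grid_fit(data, probe_seqs, small_grid, design_cache=cache)
        row = out.iloc[0]
        assert (row.mu_d, row.mu_n, row.theta) == (40.0, 60.0, 45.0)
        assert row.sigma_d == pytest.approx(small_grid.sigma[2])
        assert row.sigma_n == pytest.approx(small_grid.sigma[3])
        assert row.amplitude == pytest.approx(2.0)
        assert row.r2 == pytest.approx(1.0)

    def test_tie_break_prefers_smaller_width_product(self, run_C, small_grid):
        # an isotropic response is identical at every theta; among the
        # duplicated winners the smallest-sigma, lowest-index one wins
        cache = ft.combined_design(run_C)
        design, dn = cache
        true = TuningParams(50.0, 50.0, small_grid.sigma[1], small_grid.sigma[1], 0.0)
        data = design @ md.neural_response(true, dn[:, 0], dn[:, 1])
        out = ft.grid_fit(data, run_C, small_grid, design_cache=cache)
        assert out.iloc[0].theta == 0.0  # lowest grid index among ties

    def test_determinism(self, run_C, small_grid, rng):
        data = rng.standard_normal((5, run_C.n_volumes))
        a = ft.grid_fit(data, run_C, small_grid)
        b = ft.grid_fit(data, run_C, small_grid)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            FitGrid(mu=np.array([]))

    def test_pure_noise_rarely_passes_threshold(self, run_C, rng):
        data = rng.standard_normal((200, run_C.n_volumes))
        out = ft.grid_fit(data, run_C)
        passed = apply_threshold(out)
        assert passed.mean() <= 0.05


class TestIterativeFit:
    def test_off_grid_noiseless_recovery(self, probe_seqs):
        cache = ft.combined_design(probe_seqs)
        design, dn = cache
        true = TuningParams(47.3, 58.1, 14.0, 26.0, 30.0)
        data = design @ md.neural_response(true, dn[:, 0], dn[:, 1])
        grid = ft.grid_fit(data, probe_seqs, design_cache=cache)
        out = ft.iterative_fit(grid, data, probe_seqs, design_cache=cache)
        assert abs(out.iloc[0].mu_d - 47.3) < 1.0
        assert abs(out.iloc[0].mu_n - 58.1) < 1.0
        assert out.iloc[0].r2 > 0.999

    def test_refinement_never_decreases_r2(self, probe_seqs, rng):
        from magmap.evaluation import _simulate_probe_data
        import magmap.simulate as sim

        patch, _ = sim.make_patch(5)
        spec = sim.GroundTruthSpec(n_side=5, seed=0)
        truth = sim.make_truth(patch, spec, "I", rng).iloc[:20]
        data = _simulate_probe_data(truth, probe_seqs, 1.0, 7)
        cache = ft.combined_design(probe_seqs)
        grid = ft.grid_fit(data, probe_seqs, design_cache=cache)
        ref = ft.iterative_fit(grid, data, probe_seqs, design_cache=cache)
        assert (ref.r2 >= grid.r2 - 1e-9).all()

    def test_fixed_point_when_start_optimal(self, probe_seqs):
        cache = ft.combined_design(probe_seqs)
        design, dn = cache
        true = TuningParams(50.0, 50.0, 20.0, 30.0, 45.0)
        data = design @ md.neural_response(true, dn[:, 0], dn[:, 1])
        start = pd.DataFrame([{"mu_d": 50.0, "mu_n": 50.0, "sigma_d": 20.0,
                               "sigma_n": 30.0, "theta": 45.0,
                               "amplitude": 1.0, "baseline": 0.0, "r2": 1.0 - 1e-12}])
        out = ft.iterative_fit(start, data, probe_seqs, design_cache=cache)
        assert abs(out.iloc[0].mu_d - 50.0) < 0.1
        assert abs(out.iloc[0].mu_n - 50.0) < 0.1
        assert out.iloc[0].r2 >= start.iloc[0].r2 - 1e-9


class TestThreshold:
    def _frame(self, **overrides):
        base = dict(mu_d=50.0, mu_n=50.0, sigma_d=10.0, sigma_n=10.0,
                    theta=0.0, amplitude=1.0, baseline=0.0, r2=0.5)
        base.update(overrides)
        return pd.DataFrame([base])

    def test_boundary_r2_included(self):
        assert apply_threshold(self._frame(r2=0.25)).iloc[0]
        assert not apply_threshold(self._frame(r2=0.2499)).iloc[0]

    def test_out_of_range_mu_excluded(self):
        assert not apply_threshold(self._frame(mu_d=101.0, r2=0.99)).iloc[0]

    def test_negative_amplitude_excluded(self):
        assert not apply_threshold(self._frame(amplitude=-1.0, r2=0.99)).iloc[0]
        assert apply_threshold(self._frame(amplitude=-1.0, r2=0.99),
                               require_positive_amplitude=False).iloc[0]


class TestReducedModelFit:
    def test_noiseless_1d_recovery_off_grid(self, run_T):
        cache = ft.combined_design(run_T)
        design, dn = cache
        pred = design @ np.exp(-0.5 * ((dn[:, 0] - 43.7) / 12.3) ** 2)
        out = ft.fit_vertices_1d(4.0 * pred, run_T, axis=0)
        assert abs(out.iloc[0].mu - 43.7) < 0.5
        assert abs(out.iloc[0].sigma - 12.3) < 0.5
        assert out.iloc[0].r2 > 0.9999
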