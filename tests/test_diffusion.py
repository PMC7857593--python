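"""Short-time diffusion estimator: closed form, CI, conditioning."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from memlens.diffusion import (
    DegenerateSampleError, DisplacementSample, collect_displacements,
    displacement_loglik, estimate_D, state_conditioned_D,
)
from memlens.synthetic import sample_displacements

from conftest import make_trajectory


class TestEstimator:
    def test_single_displacement_closed_form(self):
        est = estimate_D(DisplacementSample(lag=1.0, values=[2.0]))
        assert est.D == pytest.approx(1.0)  # 4 / (4 * 1 * 1)

    def test_recovers_true_D_from_theoretical_sample(self):
        sample = sample_displacements(D=0.5, lag=1.0, n=100_000, seed=3)
        est = estimate_D(sample)
        assert abs(est.D - 0.5) / 0.5 < 0.01
        assert est.ci95[0] < 0.5 < est.ci95[1]
        assert est.fit_ks < 0.01

    def test_deterministic(self):
        s = DisplacementSample(lag=2.0, values=np.linspace(0.1, 1.0, 50))
        e1, e2 = estimate_D(s), estimate_D(s)
        assert e1.D == e2.D and e1.ci95 == e2.ci95 and e1.fit_ks == e2.fit_ks

    def test_scale_equivariance(self, rng):
        values = rng.rayleigh(1.0, size=500)
        d1 = estimate_D(DisplacementSample(lag=1.0, values=values)).D
        d2 = estimate_D(DisplacementSample(lag=1.0, values=3.0 * values)).D
        assert d2 == pytest.approx(9.0 * d1)

    def test_all_zero_sample_rejected(self):
        with pytest.raises(DegenerateSampleError):
            estimate_D(DisplacementSample(lag=1.0, values=np.zeros(10)))

    def test_matches_numerical_likelihood_maximization(self, rng):
        """Closed form equals numerically maximized likelihood to 1e-8.

        The likelihood is maximized by root-finding its stationarity
        condition (analytic score of the stated P(dr); a generic float64
        line search cannot resolve the flat optimum below sqrt(eps)), with
        a Brent line search as a coarse sanity check.
        """
        from scipy.optimize import brentq
        for _ in range(100):
            n = rng.integers(50, 2000)
            d_true = 10 ** rng.uniform(-2, 1)
            lag = rng.choice([0.5, 1.0, 2.0])
            values = rng.rayleigh(np.sqrt(2 * d_true * lag), size=n)
            sample = DisplacementSample(lag=lag, values=values)
            d_hat = estimate_D(sample).D

            def score(d):  # d/dD of the log-likelihood
                return np.sum(-1.0 / d + values ** 2 / (4 * lag * d ** 2))

            lo, hi = d_hat / 16, d_hat * 16
            assert score(lo) > 0 > score(hi)
            d_numeric = brentq(score, lo, hi, xtol=1e-300, rtol=1e-15)
            assert abs(d_numeric - d_hat) / d_hat < 1e-8

        opt = minimize_scalar(
            lambda logd: -displacement_loglik(sample, np.exp(logd)),
            bounds=(np.log(d_hat) - 2, np.log(d_hat) + 2),
            method="bounded", options={"xatol": 1e-12})
        assert abs(np.exp(opt.x) - d_hat) / d_hat < 1e-6

    def test_ci_contains_estimate(self, rng):
        values = rng.rayleigh(1.0, size=100)
        est = estimate_D(DisplacementSample(lag=1.0, values=values))
        assert est.ci95[0] < est.D < est.ci95[1]

    def test_ci_coverage_spot_check(self, rng):
        """Exact gamma CI covers the truth at close to nominal rate."""
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            values = rng.rayleigh(np.sqrt(2 * 0.1), size=1000)
            est = estimate_D(DisplacementSample(lag=1.0, values=values))
            hits += est.ci95[0] <= 0.1 <= est.ci95[1]
        assert 0.90 <= hits / n_rep <= 0.99


class TestCollectDisplacements:
    def test_stationary_particle_gives_zeros(self):
        traj = make_trajectory([[[1, 1, 0]]] * 10)
        s = collect_displacements(traj, [0], lag=1.0)
        assert np.all(s.values == 0.0) and s.n == 9

    def test_ballistic_fixture(self):
        coords = [[[0.5 + 0.3 * t, 1.0, 0.0]] for t in range(10)]
        traj = make_trajectory(coords, box=(100.0, 100.0, 10.0))
        s = collect_displacements(traj, [0], lag=1.0)
        np.testing.assert_allclose(s.values, 0.3, atol=1e-12)

    def test_incommensurate_lag_rejected(self):
        traj = make_trajectory([[[1, 1, 0]]] * 10)
        with pytest.raises(ValueError, match="multiple"):
            collect_displacements(traj, [0], lag=0.7)

    def test_nonoverlapping_interval_count(self):
        traj = make_trajectory([[[1, 1, 0]]] * 11)
        assert collect_displacements(traj, [0], lag=2.0).n == 5
        assert collect_displacements(traj, [0], lag=2.0, overlapping=True).n == 9

    def test_mask_excludes_boundary_spanning_intervals(self):
        coords = [[[0.5 + 0.1 * t, 1.0, 0.0]] for t in range(10)]
        traj = make_trajectory(coords, box=(100.0, 100.0, 10.0))
        mask = np.zeros((10, 1), dtype=bool)
        mask[:5, 0] = True  # only frames 0..4 -> 4 one-frame intervals
        s = collect_displacements(traj, [0], lag=1.0, mask=mask)
        assert s.n == 4

    def test_mean_square_displacement_law(self, rng):
        """Free Brownian paths reproduce <dr^2> = 4 D lag within 2%."""
        d_true, dt = 0.05, 1.0
        steps = rng.normal(0, np.sqrt(2 * d_true * dt), size=(1000, 100, 2))
        paths = np.cumsum(steps, axis=0)
        box = np.array([200.0, 200.0, 10.0])
        coords = np.zeros((1000, 100, 3))
        coords[:, :, :2] = np.mod(paths, box[:2])
        traj = make_trajectory(list(coords), box=box)
        s = collect_displacements(traj, np.arange(100), lag=1.0)
        assert s.n > 9e4
        assert np.mean(s.values ** 2) == pytest.approx(4 * d_true * dt, rel=0.02)


class TestStateConditioning:
    def _two_state_traj(self, rng, d_bound, d_free, n_frames=400, n_part=40):
        """Particles bound in the first half, free in the second."""
        half = n_frames // 2
        steps = np.concatenate([
            rng.normal(0, np.sqrt(2 * d_bound), size=(half, n_part, 2)),
            rng.normal(0, np.sqrt(2 * d_free), size=(n_frames - half, n_part, 2)),
        ])
        paths = np.cumsum(steps, axis=0)
        box = np.array([500.0, 500.0, 10.0])
        coords = np.zeros((n_frames, n_part, 3))
        coords[:, :, :2] = np.mod(paths, box[:2])
        traj = make_trajectory(list(coords), box=box)
        intervals = {p: [(0.0, float(half))] for p in range(n_part)}
        return traj, intervals

    def test_recovers_unity_ratio_for_equal_D(self, rng):
        traj, intervals = self._two_state_traj(rng, 0.02, 0.02)
        res = state_conditioned_D(traj, np.arange(40), intervals, lag=1.0)
        assert res.ratio == pytest.approx(1.0, abs=0.05)

    def test_recovers_threefold_ratio(self, rng):
        traj, intervals = self._two_state_traj(rng, 0.01, 0.03,
                                               n_frames=1000, n_part=50)
        res = state_conditioned_D(traj, np.arange(50), intervals, lag=1.0)
        assert res.ratio == pytest.approx(3.0, rel=0.15)

    def test_empty_bound_set_returns_free_only(self, rng):
        traj, _ = self._two_state_traj(rng, 0.02, 0.02, n_frames=50)
        res = state_conditioned_D(traj, np.arange(40), {}, lag=1.0)
        assert res.bound is None and res.free is not None and res.ratio is None
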