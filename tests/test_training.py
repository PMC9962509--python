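"""Ridge and kernel-weighted readout training against independent oracles."""

import numpy as np
import pytest

from gaitesn.training import (
    KernelBank,
    NormalEquations,
    RidgeReadout,
    accumulate_normal_equations,
    default_centers,
    kernel_importance,
    select_kernel,
    solve_ridge,
    train_kernel,
    train_standard,
)


def _random_records(rng, n_records=3, n_states=6, n_out=2, t=40):
    xs = [rng.normal(size=(n_states, t + 5 * i)) for i in range(n_records)]
    ys = [rng.normal(size=(n_out, x.shape[1])) for x in xs]
    return xs, ys


class TestNormalEquations:
    def test_single_record_equals_direct_products(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(5, 30))
        y = rng.normal(size=(2, 30))
        ne = accumulate_normal_equations([x], [y])
        assert np.allclose(ne.xxt, x @ x.T, atol=1e-12)
        assert np.allclose(ne.yxt, y @ x.T, atol=1e-12)

    def test_two_records_equal_their_concatenation(self):
        rng = np.random.default_rng(1)
        xs, ys = _random_records(rng, 2)
        ne = accumulate_normal_equations(xs, ys)
        xcat, ycat = np.hstack(xs), np.hstack(ys)
        assert np.allclose(ne.xxt, xcat @ xcat.T, atol=1e-10)
        assert np.allclose(ne.yxt, ycat @ xcat.T, atol=1e-10)

    def test_weighted_against_dense_oracle(self):
        rng = np.random.default_rng(2)
        xs, ys = _random_records(rng)
        ws = [rng.uniform(0, 2, x.shape[1]) for x in xs]
        ne = accumulate_normal_equations(xs, ys, ws)
        xxt = sum(x @ np.diag(w) @ x.T for x, w in zip(xs, ws))
        yxt = sum(y @ np.diag(w) @ x.T for x, y, w in zip(xs, ys, ws))
        assert np.abs(ne.xxt - xxt).max() < 1e-10
        assert np.abs(ne.yxt - yxt).max() < 1e-10

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        xs, ys = _random_records(rng, 4)
        a = accumulate_normal_equations(xs, ys)
        b = accumulate_normal_equations(xs[::-1], ys[::-1])
        assert np.allclose(a.xxt, b.xxt, atol=1e-10)
        assert np.allclose(a.yxt, b.yxt, atol=1e-10)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="!="):
            accumulate_normal_equations([np.ones((3, 5))], [np.ones((2, 6))])

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            accumulate_normal_equations(
                [np.ones((3, 5))], [np.ones((2, 5))], [np.array([1, 1, -1, 1, 1.0])]
            )


class TestSolveRidge:
    def test_recovers_exact_linear_map(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(2, 6))
        x = rng.normal(size=(6, 80))
        ne = accumulate_normal_equations([x], [a @ x])
        w = solve_ridge(ne, 1e-12)
        assert np.abs(w - a).max() < 1e-6

    def test_large_gamma_shrinks_to_zero(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(4, 50))
        y = rng.normal(size=(2, 50))
        ne = accumulate_normal_equations([x], [y])
        assert np.abs(solve_ridge(ne, 1e12)).max() < 1e-8

    def test_against_pseudo_inverse_oracle(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(4, 30))
        y = rng.normal(size=(2, 30))
        gamma = 1e-6
        ne = accumulate_normal_equations([x], [y])
        got = solve_ridge(ne, gamma)
        want = (y @ x.T) @ np.linalg.pinv(x @ x.T + gamma * np.eye(4))
        assert np.abs(got - want).max() < 1e-8

    def test_singular_system_names_remedy(self):
        x = np.zeros((3, 10))
        ne = accumulate_normal_equations([x], [np.zeros((1, 10))])
        with pytest.raises(np.linalg.LinAlgError, match="gamma > 0"):
            solve_ridge(ne, 0.0)


class TestKernelImportance:
    def test_gaussian_closed_form(self):
        assert kernel_importance([1.0], 1.0, 0.2)[0] == pytest.approx(1.0)
        up, down = kernel_importance([1.3, 0.7], 1.0, 0.2)
        assert up == pytest.approx(down)  # symmetric around the centre
        assert kernel_importance([1.2], 1.0, 0.2)[0] == pytest.approx(np.exp(-0.5))

    def test_invalid_width(self):
        with pytest.raises(ValueError, match="width"):
            kernel_importance([1.0], 1.0, 0.0)


class TestTrainStandard:
    def test_output_shapes_per_task(self):
        rng = np.random.default_rng(7)
        xs = [rng.normal(size=(10, 60))]
        ged = [rng.integers(0, 2, size=(5, 60)).astype(float)]
        grf = [rng.normal(size=(3, 60))]
        assert train_standard(xs, ged).w_out.shape == (5, 10)
        assert train_standard(xs, grf).w_out.shape == (3, 10)

    def test_beats_zero_readout_on_training_split(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=(3, 8))
        xs = [rng.normal(size=(8, 100)) for _ in range(2)]
        ys = [a @ x + 0.01 * rng.normal(size=(3, x.shape[1])) for x in xs]
        w = train_standard(xs, ys, 1e-6).w_out
        mae = np.mean([np.abs(w @ x - y).mean() for x, y in zip(xs, ys)])
        mae_zero = np.mean([np.abs(y).mean() for y in ys])
        assert mae < mae_zero


class TestTrainKernel:
    def test_huge_width_degenerates_to_standard(self):
        rng = np.random.default_rng(9)
        xs, ys = _random_records(rng)
        params = [1.0, 1.2, 1.4]
        standard = train_standard(xs, ys, 1e-6).w_out
        trained = train_kernel(xs, ys, params, "cycle_duration",
                               centers=[1.0, 1.4], width=1e9, gamma=1e-6)
        for w in trained.bank.readouts:
            assert np.abs(w - standard).max() < 1e-8

    def test_narrow_width_specializes_per_cluster(self):
        """Tight kernels reproduce per-cluster standard training."""
        rng = np.random.default_rng(10)
        slow_x = [rng.normal(size=(5, 50)) for _ in range(2)]
        slow_y = [rng.normal(size=(2, 50)) for _ in range(2)]
        fast_x = [rng.normal(size=(5, 50)) for _ in range(2)]
        fast_y = [rng.normal(size=(2, 50)) for _ in range(2)]
        params = [1.4, 1.4, 0.8, 0.8]
        trained = train_kernel(slow_x + fast_x, slow_y + fast_y, params,
                               "cycle_duration", centers=[0.8, 1.4],
                               width=0.01, gamma=1e-6)
        w_fast = train_standard(fast_x, fast_y, 1e-6).w_out
        w_slow = train_standard(slow_x, slow_y, 1e-6).w_out
        assert np.abs(trained.bank.readouts[0] - w_fast).max() < 1e-6
        assert np.abs(trained.bank.readouts[1] - w_slow).max() < 1e-6

    def test_record_weight_constant_across_samples(self):
        """Kernel training equals manual accumulation with per-record scalars."""
        rng = np.random.default_rng(11)
        xs, ys = _random_records(rng, 2)
        params = [1.0, 1.3]
        center, width = 1.1, 0.15
        trained = train_kernel(xs, ys, params, "cycle_duration",
                               centers=[center, 2.0], width=width, gamma=1e-6)
        scalars = kernel_importance(params, center, width)
        ws = [np.full(x.shape[1], s) for x, s in zip(xs, scalars)]
        manual = solve_ridge(accumulate_normal_equations(xs, ys, ws), 1e-6)
        assert np.abs(trained.bank.readouts[0] - manual).max() < 1e-12

    def test_degenerate_centre_flagged(self):
        rng = np.random.default_rng(12)
        xs, ys = _random_records(rng, 2)
        with pytest.warns(UserWarning, match="unusable"):
            trained = train_kernel(xs, ys, [1.0, 1.01], "cycle_duration",
                                   centers=[1.0, 500.0], width=0.05)
        assert not trained.bank.usable[1]

    def test_default_centers_span_percentiles(self):
        v = np.linspace(0.8, 1.6, 200)
        c = default_centers(v, 5)
        assert c.size == 5
        assert c[0] == pytest.approx(np.percentile(v, 5))
        assert c[-1] == pytest.approx(np.percentile(v, 95))


class TestSelectKernel:
    def _bank(self, usable=(True, True, True)):
        readouts = [np.full((1, 2), float(i)) for i in range(3)]
        return KernelBank("cycle_duration", [1.0, 1.5, 2.0], 0.1, readouts,
                          np.array(usable))

    def test_exact_centre(self):
        assert select_kernel(self._bank(), 1.5)[0, 0] == 1.0

    def test_midway_ties_to_lower_centre(self):
        # 1.25 is exactly representable: a true tie between 1.0 and 1.5
        assert select_kernel(self._bank(), 1.25)[0, 0] == 0.0

    def test_outside_range_takes_nearest_extreme(self):
        assert select_kernel(self._bank(), 99.0)[0, 0] == 2.0
        assert select_kernel(self._bank(), -5.0)[0, 0] == 0.0

    def test_skips_unusable(self):
        bank = self._bank((True, False, True))
        assert select_kernel(bank, 1.5)[0, 0] != 1.0

    def test_all_unusable_raises(self):
        bank = self._bank((False, False, False))
        with pytest.raises(RuntimeError, match="usable"):
            select_kernel(bank, 1.5)

    def test_non_finite_parameter(self):
        with pytest.raises(ValueError, match="finite"):
            select_kernel(self._bank(), np.nan)


class TestRidgeReadoutEstimator:
    def test_fit_predict_matches_solver(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(50, 6))
        y = rng.normal(size=(50, 2))
        est = RidgeReadout(gamma=1e-6).fit(X, y)
        ne = accumulate_normal_equations([X.T], [y.T])
        assert np.allclose(est.coef_, solve_ridge(ne, 1e-6), atol=1e-12)
        assert est.predict(X).shape == (50, 2)

    def test_sample_weight_flows_through(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(40, 4))
        y = rng.normal(size=(40,))
        w = rng.uniform(0, 1, 40)
        est = RidgeReadout(gamma=1e-6).fit(X, y, sample_weight=w)
        ne = accumulate_normal_equations([X.T], [y[None, :]], [w])
        assert np.allclose(est.coef_, solve_ridge(ne, 1e-6), atol=1e-12)

    def test_sklearn_clone(self):
        from sklearn.base import clone

        est = RidgeReadout(gamma=0.5)
        assert clone(est).gamma == 0.5
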