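"""One-cycle schedule, LR range test, bound selection and training loop."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leukoscope import onecycle_training as oc
from leukoscope import synthetic_smear as ss
from leukoscope.dense_model import DenseNetConfig, build_model


class TestBuildSchedule:
    def test_partition_arithmetic(self):
        s = oc.build_schedule(0.01, 0.1, 100, 0.1)
        assert s.step_size == 45
        assert s.tail == 10

    def test_zero_final_fraction_boundary(self):
        s = oc.build_schedule(0.01, 0.1, 100, 0.0)
        assert s.step_size == 50
        assert s.tail == 0

    def test_equal_bounds_rejected(self):
        with pytest.raises(ValueError):
            oc.build_schedule(0.1, 0.1, 100, 0.1)

    def test_too_few_iterations_rejected(self):
        with pytest.raises(ValueError):
            oc.build_schedule(0.01, 0.1, 3, 0.1)

    def test_final_lr_below_min(self):
        s = oc.build_schedule(0.01, 0.1, 100, 0.1)
        assert s.final_lr < s.min_lr
        assert s.final_lr == pytest.approx(0.01 / 100)


class TestLrAt:
    SCHED = oc.build_schedule(0.01, 0.1, 100, 0.1)

    def test_starts_at_min(self):
        assert oc.lr_at(self.SCHED, 0) == pytest.approx(0.01)

    def test_peak_at_step_size(self):
        assert oc.lr_at(self.SCHED, self.SCHED.step_size) == pytest.approx(0.1)

    def test_end_below_min(self):
        assert oc.lr_at(self.SCHED, 99) < self.SCHED.min_lr

    def test_midpoint_linearity(self):
        # step_size is odd (45); check linear interpolation directly
        lr = oc.lr_at(self.SCHED, 9)
        assert lr == pytest.approx(0.01 + (0.1 - 0.01) * 9 / 45, abs=1e-12)

    def test_out_of_range(self):
        with pytest.raises(IndexError):
            oc.lr_at(self.SCHED, 100)
        with pytest.raises(IndexError):
            oc.lr_at(self.SCHED, -1)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(total=st.integers(10, 400), ff=st.floats(0.0, 0.5))
    def test_continuity_no_jumps(self, total, ff):
        s = oc.build_schedule(0.01, 0.1, total, ff)
        trace = oc.lr_trace(s)
        # tail spans iterations 2*step_size .. total-1, hence tail-1 steps
        max_slope = max((s.max_lr - s.min_lr) / max(s.step_size, 1),
                        (s.min_lr - s.final_lr) / max(s.tail - 1, 1))
        assert np.all(np.abs(np.diff(trace)) <= max_slope + 1e-12)

    def test_ascent_descent_symmetry(self):
        s = self.SCHED
        for j in range(s.step_size + 1):
            up = oc.lr_at(s, s.step_size - j)
            down = oc.lr_at(s, s.step_size + j)
            assert up == pytest.approx(down, abs=1e-12)


class TestRangeTest:
    def test_exponential_loss_stops_early(self):
        """loss = exp(lr) with factor 4 must trigger the stopping rule."""
        res = oc.lr_range_test(lambda lr: math.exp(3 * lr), 0.01, 5.0, 50,
                               smoothing=0.5, divergence_factor=4.0)
        assert res.diverged_at is not None
        assert res.lrs[-1] < 5.0

    def test_constant_loss_never_diverges(self):
        res = oc.lr_range_test(lambda lr: 1.0, 0.01, 1.0, 30)
        assert res.diverged_at is None
        assert len(res.lrs) == 30

    def test_non_finite_first_step_is_divergence_not_exception(self):
        res = oc.lr_range_test(lambda lr: float("nan"), 0.01, 1.0, 20)
        assert res.diverged_at == 0

    def test_quadratic_descent_suggests_near_critical_rate(self):
        """Steepest descent on f(w) = a/2 w^2 contracts the iterate by a
        factor |1 - a*lr| per step, so a fixed-length probe from w0 returns
        loss (a/2) * (w0 * |1 - a*lr|^m)^2 — minimal at the analytic optimum
        lr* = 1/a and divergent past 2/a. The suggested max must land within
        one grid step of lr*."""
        a, w0, m = 2.0, 1.0, 3

        def step_fn(lr):
            w = w0
            for _ in range(m):
                w = w * (1.0 - a * lr)
            return 0.5 * a * w * w

        n = 40
        lrs = np.linspace(0.05, 1.2, n)
        res = oc.lr_range_test(step_fn, 0.05, 1.2, n, smoothing=0.0,
                               divergence_factor=4.0)
        grid_step = lrs[1] - lrs[0]
        assert res.suggested_max == pytest.approx(1.0 / a, abs=grid_step)

    def test_replay_reproduces_stopping_point(self):
        rng = np.random.default_rng(0)
        losses = list(1.0 + 0.1 * rng.standard_normal(30)) + [50.0, 60.0]
        stop = oc.replay_stopping_rule(losses, smoothing=0.9, divergence_factor=4.0)
        assert stop is not None
        assert oc.replay_stopping_rule(losses, smoothing=0.9,
                                       divergence_factor=4.0) == stop


class TestSuggestBounds:
    def test_factor_3_4(self):
        res = oc.RangeTestResult(np.array([0.35]), np.array([1.0]),
                                 np.array([1.0]), None, 0.35)
        lo, hi = oc.suggest_bounds(res, "factor3_4")
        assert hi == 0.35
        assert lo == pytest.approx(0.1)

    def test_factor_10_20_one_cycle(self):
        res = oc.RangeTestResult(np.array([1.5]), np.array([1.0]),
                                 np.array([1.0]), None, 1.5)
        lo, hi = oc.suggest_bounds(res, "factor10_20_one_cycle")
        assert lo == pytest.approx(0.1)

    @pytest.mark.parametrize("policy", oc.BOUND_POLICIES)
    def test_min_below_max(self, policy):
        res = oc.RangeTestResult(np.array([0.7]), np.array([1.0]),
                                 np.array([1.0]), None, 0.7)
        lo, hi = oc.suggest_bounds(res, policy)
        assert 0 < lo < hi

    def test_missing_suggestion_rejected(self):
        res = oc.RangeTestResult(np.array([]), np.array([]), np.array([]), 0, None)
        with pytest.raises(ValueError):
            oc.suggest_bounds(res, "factor3_4")


class TestTrainLoop:
    def _tiny_setup(self, n_train=3, n_val=2, epochs=2, batch=4):
        train_s = ss.generate_dataset(n_train, 64, seed=1)
        val_s = ss.generate_dataset(n_val, 64, seed=2)
        ipe = oc.iterations_per_epoch(len(train_s), batch)
        sched = oc.build_schedule(0.005, 0.08, epochs * ipe, 0.1)
        model = build_model(DenseNetConfig(seed=0))
        return model, train_s, val_s, sched, epochs, batch

    def test_zero_epochs_noop(self):
        model, train_s, val_s, sched, _, batch = self._tiny_setup()
        before = {p.name: p.value.copy() for p in model.parameters()}
        model, hist = oc.train(model, train_s, val_s, sched, 0, batch, seed=0)
        assert hist.iteration_lr == []
        for p in model.parameters():
            assert np.array_equal(p.value, before[p.name])

    def test_lr_trace_equals_schedule(self):
        model, train_s, val_s, sched, epochs, batch = self._tiny_setup()
        _, hist = oc.train(model, train_s, val_s, sched, epochs, batch, seed=0)
        expected = [oc.lr_at(sched, i) for i in range(sched.total_iterations)]
        assert hist.iteration_lr == expected

    def test_schedule_mismatch_reports_both_counts(self):
        model, train_s, val_s, _, _, batch = self._tiny_setup()
        bad = oc.build_schedule(0.005, 0.08, 999, 0.1)
        with pytest.raises(oc.ConfigurationError, match="999"):
            oc.train(model, train_s, val_s, bad, 2, batch, seed=0)

    def test_deterministic_given_seed(self):
        m1, train_s, val_s, sched, epochs, batch = self._tiny_setup()
        m1, h1 = oc.train(m1, train_s, val_s, sched, epochs, batch, seed=5)
        m2 = build_model(DenseNetConfig(seed=0))
        m2, h2 = oc.train(m2, train_s, val_s, sched, epochs, batch, seed=5)
        assert h1.iteration_loss == h2.iteration_loss
        for p1, p2 in zip(m1.parameters(), m2.parameters()):
            assert np.array_equal(p1.value, p2.value)

    def test_history_frames_export(self, tmp_path):
        model, train_s, val_s, sched, epochs, batch = self._tiny_setup()
        _, hist = oc.train(model, train_s, val_s, sched, epochs, batch, seed=0)
        it = hist.iterations_frame()
        ep = hist.epochs_frame()
        assert list(it.columns) == ["iteration", "lr", "loss"]
        assert list(ep.columns) == ["epoch", "train_acc", "val_acc",
                                    "train_loss", "val_loss"]
        assert len(ep) == epochs
        it.to_csv(tmp_path / "it.csv", index=False)
        ep.to_csv(tmp_path / "ep.csv", index=False)
        assert (tmp_path / "it.csv").exists()
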