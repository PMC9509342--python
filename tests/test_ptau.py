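"""Oracle and property tests for the p-tau selection statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from evomode import (
    InsufficientDataError,
    ModeThresholds,
    PTauConfig,
    PTauResult,
    SelectionMode,
    TimeGrid,
    classify_mode,
    compute_p_tau,
    first_passage_time,
    fit_propagator_decay,
    frequency_propagator,
    logistic_sojourn_ratio,
    origination_time,
    sojourn_time_curve,
)
from evomode.ptau import PropagatorCurve

from conftest import logistic, make_record, make_set

GRID1 = TimeGrid((0.0, 100.0, 200.0, 300.0), generations_per_day=1.0)
LIN = dict(interpolation="linear", origination="segment")


class TestOrigination:
    def test_linear_crossing_of_first_segment(self):
        rec = make_record([0.0, 100.0], [0.0, 0.20])
        grid = TimeGrid((0.0, 100.0), 1.0)
        assert origination_time(rec, grid, 0.01, **LIN) == pytest.approx(5.0)

    def test_first_sample_already_high_clips_to_zero(self):
        rec = make_record([0.0, 100.0], [0.30, 0.60])
        grid = TimeGrid((0.0, 100.0), 1.0)
        assert origination_time(rec, grid, 0.01, **LIN) == 0.0

    def test_never_established_returns_none(self):
        rec = make_record([0.0, 100.0], [0.005, 0.005])
        grid = TimeGrid((0.0, 100.0), 1.0)
        assert origination_time(rec, grid, 0.01, **LIN) is None

    def test_generations_scale_with_grid(self):
        rec = make_record([0.0, 10.0], [0.0, 0.20])
        grid = TimeGrid((0.0, 10.0), generations_per_day=15.0)
        # same crossing, expressed in generations (150 gens per segment)
        assert origination_time(rec, grid, 0.01, **LIN) == pytest.approx(7.5)


class TestFirstPassage:
    # hand-computed on (0,0.0) (100,0.2) (200,0.5) (300,0.96), linear chords
    rec = make_record([0.0, 100.0, 200.0, 300.0], [0.0, 0.2, 0.5, 0.96])

    def test_intermediate_level(self):
        t = first_passage_time(self.rec, GRID1, 0.3, 0.01, **LIN)
        assert t == pytest.approx(133.0 + 1 / 3 - 5.0, abs=0.01)

    def test_near_fixation_level(self):
        t = first_passage_time(self.rec, GRID1, 0.95, 0.01, **LIN)
        assert t == pytest.approx(200.0 + 100 * 0.45 / 0.46 - 5.0, abs=0.01)

    def test_level_never_reached(self):
        assert first_passage_time(self.rec, GRID1, 0.99, 0.01, **LIN) is None

    def test_level_below_origination_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            first_passage_time(self.rec, GRID1, 0.005, 0.01)

    def test_exact_sample_hit_uses_sample_time(self):
        rec = make_record([0.0, 100.0, 200.0], [0.0, 0.5, 0.9])
        t = first_passage_time(rec, GRID1, 0.5, 0.01, **LIN)
        assert t == pytest.approx(100.0 - 2.0)  # origination at 2.0


class TestPropagator:
    def test_enumeration_five_trajectories(self, five_trajectories):
        cfg = PTauConfig()
        curve = frequency_propagator(five_trajectories, cfg)
        G = dict(zip(curve.x, curve.G))
        assert curve.n_established == 5
        assert G[0.3] == pytest.approx(0.6)
        assert G[0.95] == pytest.approx(0.4)

    def test_all_fixing_gives_unity(self):
        ts = make_set({"a": [0.0, 1.0], "b": [0.1, 1.0]}, [0.0, 100.0])
        curve = frequency_propagator(ts, PTauConfig())
        assert all(g == 1.0 for g in curve.G)

    def test_single_trajectory_step_function(self):
        ts = make_set({"a": [0.0, 0.5, 0.4]}, [0.0, 100.0, 200.0])
        curve = frequency_propagator(ts, PTauConfig())
        for x, g in zip(curve.x, curve.G):
            assert g == (1.0 if x <= 0.5 else 0.0)

    def test_monotone_nonincreasing_always(self, five_trajectories):
        curve = frequency_propagator(five_trajectories, PTauConfig())
        assert all(b <= a for a, b in zip(curve.G, curve.G[1:]))

    def test_no_established_trajectories_signalled(self):
        ts = make_set({"a": [0.0, 0.005]}, [0.0, 100.0])
        with pytest.raises(InsufficientDataError):
            frequency_propagator(ts, PTauConfig())


class TestSojournCurve:
    def test_mean_of_two_first_passages(self):
        # both reach 0.3; by hand their passage times are 100-5=95 and 200-10=190
        ts = make_set(
            {"a": [0.0, 0.3, 0.3], "b": [0.0, 0.15, 0.3]},
            [0.0, 100.0, 200.0],
        )
        cfg = PTauConfig(interpolation="linear")
        curve = sojourn_time_curve(ts, cfg)
        T = dict(zip(curve.x, curve.T))
        n = dict(zip(curve.x, curve.n_reaching))
        assert n[0.3] == 2
        t_a = first_passage_time(ts.record("a"), ts.grid, 0.3, 0.01, **LIN)
        t_b = first_passage_time(ts.record("b"), ts.grid, 0.3, 0.01, **LIN)
        assert T[0.3] == pytest.approx((t_a + t_b) / 2)

    def test_unreached_levels_are_nan_with_zero_count(self, five_trajectories):
        cfg = PTauConfig(grid=(0.01, 0.3, 0.95, 0.995))
        curve = sojourn_time_curve(five_trajectories, cfg)
        assert math.isnan(curve.T[-1])
        assert curve.n_reaching[-1] == 0

    def test_nondecreasing_over_equal_reacher_sets(self, five_trajectories):
        # the mean first-passage time is guaranteed monotone only between
        # grid levels reached by the same set of trajectories (the mean over
        # a shrinking subset can drop when the survivors are the fast ones)
        curve = sojourn_time_curve(five_trajectories, PTauConfig())
        triples = list(zip(curve.x, curve.T, curve.n_reaching))
        for (x1, t1, n1), (x2, t2, n2) in zip(triples, triples[1:]):
            if n1 == n2 and not (math.isnan(t1) or math.isnan(t2)):
                assert t2 >= t1 - 1e-9

    def test_dense_logistic_matches_closed_form(self):
        s = 0.05
        days = np.arange(0.0, 301.0, 1.0)
        ts = make_set({"m": logistic(days, s)}, list(days))
        cfg = PTauConfig(grid=(0.01, 0.3, 0.5, 0.9, 0.95), interpolation="linear")
        curve = sojourn_time_curve(ts, cfg)
        for x, t in zip(curve.x, curve.T):
            if x <= 0.01:
                continue
            expected = math.log(x * 0.99 / ((1 - x) * 0.01)) / s
            assert t == pytest.approx(expected, rel=0.02)

    def test_coarse_logistic_exact_under_logit_interpolation(self):
        # at 100-generation sampling the linear chord overestimates tau by
        # ~90% on a pure logistic; logit interpolation is exact
        s = 0.05
        days = np.arange(0.0, 401.0, 100.0)
        ts = make_set({"m": logistic(days, s)}, list(days))
        res_logit = compute_p_tau(ts, PTauConfig(saturation=1e-12))
        assert res_logit.tau == pytest.approx(logistic_sojourn_ratio(), rel=1e-6)
        res_lin = compute_p_tau(ts, PTauConfig(interpolation="linear"))
        assert res_lin.tau > 3.0  # documented failure mode of the chord


class TestComputePTau:
    def test_ratio_example(self, five_trajectories):
        res = compute_p_tau(five_trajectories, PTauConfig(interpolation="linear"))
        assert res.p == pytest.approx(2 / 3)
        assert res.n_established == 5
        assert res.n_reached_xm == 3
        assert res.n_reached_xf == 2
        # tau equals the ratio of hand-averaged first-passage times
        fp = lambda mid, x: first_passage_time(
            five_trajectories.record(mid), five_trajectories.grid, x, 0.01, **LIN
        )
        t_m = np.mean([fp(m, 0.3) for m in ("c", "d", "e")])
        t_f = np.mean([fp(m, 0.95) for m in ("d", "e")])
        assert res.tau == pytest.approx(t_f / t_m)
        assert not res.tau_is_lower_bound

    def test_all_fix_gives_p_one(self):
        days = np.arange(0.0, 301.0, 10.0)
        ts = make_set(
            {"a": logistic(days, 0.05), "b": logistic(days, 0.04)}, list(days)
        )
        res = compute_p_tau(ts)
        assert res.p == 1.0

    def test_no_fixation_reports_lower_bound(self):
        # plateau at 0.5 for the whole observation: tau is a lower bound
        days = [0.0, 500.0, 1000.0, 2000.0, 3000.0]
        ts = make_set({"a": [0.0, 0.45, 0.5, 0.5, 0.5]}, days)
        res = compute_p_tau(ts, PTauConfig(interpolation="linear"))
        assert res.p == 0.0
        assert res.tau_is_lower_bound
        orig = origination_time(ts.record("a"), ts.grid, 0.01, **LIN)
        t_m = first_passage_time(ts.record("a"), ts.grid, 0.3, 0.01, **LIN)
        assert res.tau == pytest.approx((3000.0 - orig) / t_m)

    def test_short_observation_not_confident(self):
        days = [0.0, 50.0, 100.0]
        ts = make_set({"a": [0.0, 0.5, 0.96]}, days)
        res = compute_p_tau(ts)
        assert not res.confident
        assert res.mode is SelectionMode.UNDETERMINED

    def test_nothing_reaching_xm_signalled(self):
        ts = make_set({"a": [0.0, 0.1, 0.1]}, [0.0, 100.0, 200.0])
        with pytest.raises(InsufficientDataError, match="xm"):
            compute_p_tau(ts)


def _result(p, tau, lower=False, confident=True):
    return PTauResult(
        p=p, tau=tau, tau_is_lower_bound=lower, n_established=10,
        n_reached_xm=10, n_reached_xf=int(10 * p), mode=SelectionMode.UNDETERMINED,
        confident=confident, T_xm=100.0, T_xf=100.0 * tau,
    )


class TestClassifyMode:
    @pytest.mark.parametrize(
        "p,tau,lower,expected",
        [
            (1.0, 2.25, False, SelectionMode.PERIODIC_SWEEPS),
            (0.3, 4.0, True, SelectionMode.DIVERSIFYING),
            (0.5, 1.8, False, SelectionMode.CLONAL_INTERFERENCE),
            (0.95, 3.5, False, SelectionMode.UNDETERMINED),  # fast p, slow tau
            (0.1, 2.0, False, SelectionMode.UNDETERMINED),  # low p, fast tau
            (0.0, 12.0, True, SelectionMode.DIVERSIFYING),
        ],
    )
    def test_decision_rule(self, p, tau, lower, expected):
        assert classify_mode(_result(p, tau, lower)) is expected

    def test_boundaries_resolve_to_undetermined(self):
        # p exactly at the diversifying cut with slow tau: not diversifying,
        # not periodic, tau too slow for interference
        assert classify_mode(_result(0.5, 4.0)) is SelectionMode.UNDETERMINED

    def test_unconfident_is_always_undetermined(self):
        assert (
            classify_mode(_result(1.0, 2.0, confident=False))
            is SelectionMode.UNDETERMINED
        )

    def test_thresholds_overridable(self):
        th = ModeThresholds(p_periodic_min=0.7)
        assert classify_mode(_result(0.75, 2.0), th) is SelectionMode.PERIODIC_SWEEPS


class TestLogisticSojournRatio:
    def test_standard_thresholds_print_two(self):
        assert round(logistic_sojourn_ratio(0.01, 0.3, 0.95), 1) == 2.0
        # exact closed form: ln(1881)/ln(42.428...)
        expected = math.log(0.95 * 0.99 / (0.05 * 0.01)) / math.log(
            0.3 * 0.99 / (0.7 * 0.01)
        )
        assert logistic_sojourn_ratio(0.01, 0.3, 0.95) == pytest.approx(expected)

    def test_equal_thresholds_give_unity(self):
        assert logistic_sojourn_ratio(0.01, 0.3, 0.3 + 1e-12) == pytest.approx(1.0)

    def test_order_violation_rejected(self):
        with pytest.raises(ValueError):
            logistic_sojourn_ratio(0.3, 0.01, 0.95)


class TestPropagatorDecayFit:
    def test_exact_exponential(self):
        x = tuple(np.linspace(0.05, 0.95, 10))
        curve = PropagatorCurve(x=x, G=tuple(np.exp(-3.0 * np.array(x))), n_established=50)
        assert fit_propagator_decay(curve).lam == pytest.approx(3.0)

    def test_flat_propagator_has_zero_decay(self):
        x = (0.1, 0.5, 0.9)
        curve = PropagatorCurve(x=x, G=(1.0, 1.0, 1.0), n_established=5)
        assert fit_propagator_decay(curve).lam == 0.0

    def test_noisy_exponential_within_ten_percent(self, rng):
        x = np.linspace(0.05, 0.95, 19)
        G = np.exp(-2.0 * x) * (1 + 0.05 * rng.standard_normal(len(x)))
        curve = PropagatorCurve(x=tuple(x), G=tuple(G), n_established=100)
        assert fit_propagator_decay(curve).lam == pytest.approx(2.0, rel=0.1)

    def test_too_few_points_signalled(self):
        curve = PropagatorCurve(x=(0.1, 0.5, 0.9), G=(1.0, 0.5, 0.0), n_established=3)
        with pytest.raises(InsufficientDataError):
            fit_propagator_decay(curve)


@st.composite
def trajectory_sets(draw):
    n_days = draw(st.integers(3, 6))
    days = sorted(draw(st.lists(
        st.floats(0.0, 400.0, allow_nan=False).map(lambda v: round(v, 1)),
        min_size=n_days, max_size=n_days, unique=True,
    )))
    n_traj = draw(st.integers(1, 5))
    trajs = {
        f"m{i}": [
            round(draw(st.floats(0.0, 1.0, allow_nan=False)), 4)
            for _ in range(n_days)
        ]
        for i in range(n_traj)
    }
    return make_set(trajs, days)


class TestInvariants:
    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(ts=trajectory_sets())
    def test_curves_monotone_and_p_bounded(self, ts):
        cfg = PTauConfig()
        try:
            G = frequency_propagator(ts, cfg)
        except InsufficientDataError:
            return
        assert all(b <= a + 1e-12 for a, b in zip(G.G, G.G[1:]))
        T = sojourn_time_curve(ts, cfg)
        assert all(
            b <= a for a, b in zip(T.n_reaching, T.n_reaching[1:])
        )
        try:
            res = compute_p_tau(ts, cfg)
        except InsufficientDataError:
            return
        assert 0.0 <= res.p <= 1.0

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(ts=trajectory_sets())
    def test_per_trajectory_passage_ordering(self, ts):
        # on any single interpolated path, the first occurrence at xf cannot
        # precede the first occurrence at xm
        for rec in ts.records:
            tm = first_passage_time(rec, ts.grid, 0.3, 0.01)
            tf = first_passage_time(rec, ts.grid, 0.95, 0.01)
            if tm is not None and tf is not None:
                assert tf >= tm - 1e-9
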