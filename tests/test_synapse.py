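"""Synapse event mechanics, transfer, STDP curve, fit, weight dependence."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fgstdp.synapse import (
    SynapseParams,
    TimeOrderingError,
    decay_to,
    fit_stdp,
    make_state,
    on_post_spike,
    on_pre_spike,
    set_weight,
    stdp_curve,
    transfer,
    weight_dependence,
)


class TestEventMechanics:
    def test_first_pre_spike_sets_180mv(self, params):
        state = make_state(params)
        on_pre_spike(state, params, 1.0)
        assert state.v_fg_pre == pytest.approx(0.180)

    def test_first_post_spike_sets_135mv(self, params):
        state = make_state(params)
        on_post_spike(state, params, 1.0)
        assert state.v_fg_post == pytest.approx(0.135)

    def test_subthreshold_sample_leaves_storage(self, params):
        # a pre spike long after the last post samples s_post ~ 0: no LTD
        state = make_state(params)
        on_post_spike(state, params, 1.0)
        m0 = state.m
        on_pre_spike(state, params, 10.0)
        assert state.m == m0

    def test_causal_pair_potentiates(self, params):
        state = make_state(params)
        w0 = state.w
        on_pre_spike(state, params, 1.0)
        on_post_spike(state, params, 1.001)
        assert state.w > w0

    def test_anticausal_pair_depresses(self, params):
        state = make_state(params)
        w0 = state.w
        on_post_spike(state, params, 1.0)
        on_pre_spike(state, params, 1.001)
        assert state.w < w0

    def test_decay_identity_at_state_time(self, params):
        state = make_state(params)
        on_pre_spike(state, params, 1.0)
        v = state.v_fg_pre
        decay_to(state, params, 1.0)
        assert state.v_fg_pre == v

    def test_decay_one_time_constant(self, params):
        state = make_state(params)
        on_pre_spike(state, params, 1.0)
        decay_to(state, params, 1.0 + params.tau_pre_s)
        assert state.v_fg_pre == pytest.approx(0.180 / math.e)

    def test_long_silence_drains_integrators(self, params):
        state = make_state(params)
        on_pre_spike(state, params, 1.0)
        on_post_spike(state, params, 1.001)
        decay_to(state, params, 100.0)
        assert state.v_fg_pre < 1e-6 and state.v_fg_post < 1e-6

    def test_time_ordering_enforced(self, params):
        state = make_state(params)
        on_pre_spike(state, params, 1.0)
        with pytest.raises(TimeOrderingError):
            on_post_spike(state, params, 0.5)

    def test_storage_unchanged_by_decay(self, params):
        state = make_state(params)
        on_pre_spike(state, params, 1.0)
        on_post_spike(state, params, 1.002)
        m = state.m
        decay_to(state, params, 50.0)
        assert state.m == m  # storage leak off by default

    def test_simultaneous_tie_no_plasticity(self, params):
        state = make_state(params)
        on_pre_spike(state, params, 1.0)
        m0 = state.m
        on_post_spike(state, params, 1.0)  # identical timestamp: Delta-t = 0
        assert state.m == m0

    def test_causal_flag_overrides_tie(self, params):
        state = make_state(params)
        on_pre_spike(state, params, 1.0)
        m0 = state.m
        on_post_spike(state, params, 1.0, causal=True)
        assert state.m < m0  # LTP injection (m falls, weight rises)


class TestTransfer:
    def test_resting_weight_is_151mv(self, params):
        assert transfer(params.m_rest, params) == pytest.approx(0.151, abs=1e-9)

    def test_saturates_at_poles(self, params):
        assert transfer(-10.0, params) == pytest.approx(0.5, abs=1e-12)
        assert transfer(10.0, params) == pytest.approx(0.0, abs=1e-12)
        assert transfer(-10.0, params) <= 0.5

    def test_monotone_decreasing(self, params):
        ms = np.linspace(-1.0, 1.0, 101)
        ws = [transfer(m, params) for m in ms]
        assert all(a > b for a, b in zip(ws, ws[1:]))


class TestSetWeight:
    def test_anchor_inverse(self, params):
        state = make_state(params)
        set_weight(state, params, 0.151)
        assert state.m == pytest.approx(params.m_rest, abs=1e-9)

    @pytest.mark.parametrize("target", [0.01, 0.151, 0.3, 0.45])
    def test_round_trip(self, params, target):
        state = make_state(params)
        set_weight(state, params, target)
        assert transfer(state.m, params) == pytest.approx(target, abs=1e-9)

    @pytest.mark.parametrize("target", [0.0, 0.5, -0.1, 0.6])
    def test_saturation_unreachable(self, params, target):
        state = make_state(params)
        with pytest.raises(ValueError):
            set_weight(state, params, target)


class TestStdpCurve:
    def test_zero_dt_zero_change(self, params):
        assert stdp_curve(params, [0.0])[0][1] == 0.0

    def test_sign_structure(self, params):
        curve = dict(stdp_curve(params, [1.0, -1.0]))
        assert curve[1.0] > 0 and curve[-1.0] < 0

    @pytest.mark.parametrize("dt_ms", list(range(1, 46, 4)))
    def test_sign_follows_timing_within_windows(self, params, dt_ms):
        curve = dict(stdp_curve(params, [float(dt_ms), float(-dt_ms)]))
        assert curve[dt_ms] > 0
        assert curve[-dt_ms] < 0

    def test_far_tail_negligible(self, params, default_curve):
        peak = max(abs(dw) for _, dw in default_curve)
        tail = dict(stdp_curve(params, [500.0, -500.0]))
        assert abs(tail[500.0]) < 0.01 * peak
        assert abs(tail[-500.0]) < 0.01 * peak

    def test_magnitude_nonincreasing_along_branches(self, default_curve):
        dts = np.array([p[0] for p in default_curve])
        dws = np.array([p[1] for p in default_curve])
        pos = dws[dts > 0][np.argsort(dts[dts > 0])]
        neg = dws[dts < 0][np.argsort(-dts[dts < 0])]  # increasing |dt|
        assert all(a >= b - 1e-12 for a, b in zip(pos, pos[1:]))
        assert all(abs(a) >= abs(b) - 1e-12 for a, b in zip(neg, neg[1:]))

    def test_empty_grid_rejected(self, params):
        with pytest.raises(ValueError):
            stdp_curve(params, [])


class TestFit:
    def test_recovers_exact_exponentials(self):
        dts = np.concatenate([-np.arange(1, 200, 2)[::-1], np.arange(1, 200, 2)])
        curve = [
            (dt, 0.02 * math.exp(-dt / 20.0) if dt > 0 else -0.01 * math.exp(dt / 80.0))
            for dt in dts
        ]
        fit = fit_stdp(curve)
        assert fit.a_plus == pytest.approx(0.02, rel=1e-6)
        assert fit.tau_plus_ms == pytest.approx(20.0, rel=1e-6)
        assert fit.a_minus == pytest.approx(0.01, rel=1e-6)
        assert fit.tau_minus_ms == pytest.approx(80.0, rel=1e-6)
        assert fit.residual < 1e-9

    def test_default_calibration_window_constants(self, default_fit):
        assert default_fit.tau_plus_ms == pytest.approx(16.8, rel=0.10)
        assert default_fit.tau_minus_ms == pytest.approx(76.5, rel=0.10)

    def test_single_branch_rejected(self, params):
        curve = stdp_curve(params, [1.0, 5.0, 10.0])
        with pytest.raises(ValueError):
            fit_stdp(curve)


class TestWeightDependence:
    def test_no_depression_below_zero_pole(self, params):
        (w, dw), = weight_dependence(params, -1.0, [0.0])
        assert dw == pytest.approx(0.0, abs=1e-6)

    def test_potentiation_vanishes_at_upper_pole(self, params):
        pairs = weight_dependence(params, 1.0, [0.499, 0.4999])
        assert abs(pairs[1][1]) < abs(pairs[0][1])
        assert abs(pairs[1][1]) < 1e-4

    def test_ltp_branch_interior_maximum(self, params):
        grid = np.linspace(0.01, 0.49, 49)
        dws = np.array([dw for _, dw in weight_dependence(params, 1.0, grid)])
        k = int(np.argmax(dws))
        assert 0 < k < len(grid) - 1
        assert dws[k] > dws[0] and dws[k] > dws[-1]

    def test_out_of_range_weight_rejected(self, params):
        with pytest.raises(ValueError):
            weight_dependence(params, 1.0, [0.6])


class TestDetailedBalance:
    def test_successive_causal_ltp_injections_shrink(self, params):
        # the storage-level injection is self-limiting; the weight-level
        # increment additionally carries the VTC slope and may transiently
        # grow near mid-range, so the invariant is asserted on |dm|
        state = make_state(params)
        injections = []
        t = 1.0
        for _ in range(30):
            m0 = state.m
            on_pre_spike(state, params, t)
            on_post_spike(state, params, t + 0.001)
            injections.append(abs(state.m - m0))
            decay_to(state, params, t + 5.0)  # drain integrators between pairs
            t += 10.0
        assert all(a >= b - 1e-15 for a, b in zip(injections, injections[1:]))
        assert injections[-1] < injections[0]


class TestNearestPairingOracle:
    """Event-driven plasticity equals a brute-force nearest-spike replay."""

    @staticmethod
    def _replay(params, events):
        # independent re-derivation: at each spike, the counter trace is
        # recomputed from only the most recent counter spike
        m = params.m_rest
        last_pre = last_post = None
        for t, kind in events:
            if kind == "pre":
                if last_post is not None and t != last_post:
                    s_post = (
                        params.gain_post
                        * params.dv_post
                        * math.exp(-(t - last_post) / params.tau_post_s)
                    )
                    if s_post > params.theta_post:
                        m += (
                            params.c_minus
                            * (s_post - params.theta_post)
                            * math.exp(-(m - params.m_rest) / params.lambda_minus)
                        )
                last_pre = t
            else:
                if last_pre is not None and t != last_pre:
                    s_pre = (
                        params.gain_pre
                        * params.dv_pre
                        * math.exp(-(t - last_pre) / params.tau_pre_s)
                    )
                    if s_pre > params.theta_pre:
                        m -= (
                            params.c_plus
                            * (s_pre - params.theta_pre)
                            * math.exp((m - params.m_rest) / params.lambda_plus)
                        )
                last_post = t
        return m

    @pytest.mark.parametrize("seed", range(10))
    def test_random_sequences_match(self, params, seed):
        rng = np.random.default_rng(seed)
        times = np.sort(rng.uniform(0.0, 20.0, size=100))
        kinds = rng.choice(["pre", "post"], size=100)
        events = list(zip(times, kinds))
        state = make_state(params)
        for t, kind in events:
            if kind == "pre":
                on_pre_spike(state, params, t)
            else:
                on_post_spike(state, params, t)
        assert state.m == pytest.approx(self._replay(params, events), abs=1e-12)


class TestWeightBoundsProperty:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_weight_stays_in_bounds_random_events(self, seed):
        params = SynapseParams()
        rng = np.random.default_rng(seed)
        n = 400
        times = np.sort(rng.uniform(0.0, 60.0, size=n))
        kinds = rng.integers(0, 2, size=n)
        state = make_state(params)
        for t, k in zip(times, kinds):
            if k:
                on_pre_spike(state, params, t)
            else:
                on_post_spike(state, params, t)
            assert 0.0 <= state.w <= params.vtc_vmax
            assert state.v_fg_pre >= 0.0 and state.v_fg_post >= 0.0

    def test_long_hammering_sequence_bounded(self, params):
        rng = np.random.default_rng(12345)
        n = 100_000
        times = np.cumsum(rng.exponential(0.01, size=n))
        kinds = rng.integers(0, 2, size=n)
        state = make_state(params)
        for t, k in zip(times, kinds):
            if k:
                on_pre_spike(state, params, t)
            else:
                on_post_spike(state, params, t)
        assert 0.0 <= state.w <= params.vtc_vmax


class TestParamValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(pairing_mode="weird"),
            dict(vtc_slope=0.0),
            dict(theta_pre=-0.1),
            dict(c_plus=-1.0),
            dict(m_rest=100.0),  # transfer(m_rest) = 0, outside (0, vmax)
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SynapseParams(**kwargs)

    def test_accumulate_mode_piles_up(self):
        params = SynapseParams(pairing_mode="accumulate")
        state = make_state(params)
        on_pre_spike(state, params, 1.0)
        on_pre_spike(state, params, 1.0005)
        assert state.v_fg_pre > 0.30  # two nearly-unrelaxed jumps
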