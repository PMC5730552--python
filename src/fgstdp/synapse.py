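"""Behavioral floating-gate synapse with weight-dependent, pair-based STDP.

The synapse keeps three floating-gate state variables:

* ``v_fg_pre`` / ``v_fg_post`` — leaky integrators charged by pre- and
  postsynaptic spikes (jumps of ~180 / 135 mV) and relaxing through their
  tunnel junctions.  A counter-spike samples the opposite integrator through
  an amplifying readout stage (``gain_pre`` / ``gain_post``); only sampled
  values beyond the junction injection thresholds (0.35 V / 0.33 V in
  magnitude) move charge onto the storage gate.
* ``m`` — the storage-gate voltage.  Charge injection is self-limiting
  (detailed balance): the further ``m`` has moved from its resting level,
  the smaller further injection in that direction,

      LTP (post spike):  dm = -c_plus  * (|s_pre| - theta_pre) * exp(+(m - m_rest) / lambda_plus)
      LTD (pre spike):   dm = +c_minus * (s_post - theta_post) * exp(-(m - m_rest) / lambda_minus)

The stored level maps to the transmitted weight through a saturating
voltage-transfer characteristic (VTC), a decreasing logistic bounded in
(0, 0.5 V); LTP injects electrons so ``m`` falls and the weight rises.

Pairing is nearest-spike by default: each spike resets its own integrator,
so only the most recent counter-spike matters.  All default constants below
are calibrated against the printed behavioral anchors (STDP window time
constants 16.8 / 76.5 ms, resting weight 151 mV, 20 Hz pairing saturation
near 0.27 V); the procedure is documented in docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, curve_fit

from .device import LeakModel

__all__ = [
    "SynapseParams",
    "SynapseState",
    "StdpFit",
    "TimeOrderingError",
    "FitError",
    "transfer",
    "make_state",
    "set_weight",
    "decay_to",
    "on_pre_spike",
    "on_post_spike",
    "stdp_curve",
    "fit_stdp",
    "weight_dependence",
    "default_params",
]


class TimeOrderingError(ValueError):
    """An event was delivered earlier than the synapse's current time."""


class FitError(RuntimeError):
    """STDP-curve fit failed; carries the last iterate if available."""

    def __init__(self, msg, last_iterate=None):
        super().__init__(msg)
        self.last_iterate = last_iterate


@dataclass(frozen=True)
class SynapseParams:
    """Behavioral constants of the FG synapse (SI units: V, s).

    Defaults are the calibrated nominal circuit; see module docstring.
    """

    dv_pre: float = 0.180        # FG jump per presynaptic spike (V)
    dv_post: float = 0.135       # FG jump per postsynaptic spike (V)
    tau_pre_s: float = 0.028677836845661556  # presynaptic integrator relaxation (s), calibrated
    tau_post_s: float = 0.2576104989808312   # postsynaptic integrator relaxation (s), calibrated
    gain_pre: float = 9.166666666666668      # sampling-stage gain, FG voltage -> |s_pre|
    gain_post: float = 5.185185185185184     # sampling-stage gain, FG voltage -> s_post
    theta_post: float = 0.35     # LTD injection threshold on s_post (V)
    theta_pre: float = 0.33      # LTP injection threshold on |s_pre| (V)
    c_plus: float = 0.0132       # LTP injection gain (V per unit excess)
    c_minus: float = 0.042777604886657015    # LTD injection gain, calibrated
    lambda_plus: float = 0.35    # LTP detailed-balance scale (V)
    lambda_minus: float = 0.35   # LTD detailed-balance scale (V)
    vtc_vmax: float = 0.5        # VTC output ceiling (V)
    vtc_slope: float = 0.1       # VTC logistic width (V)
    vtc_mid: float = 0.0         # storage level at half-maximal weight (V)
    m_rest: float = 0.08377920853875029      # resting level, transfer(m_rest) = 151 mV
    pairing_mode: str = "nearest"
    storage_leak: LeakModel | None = None  # retention leak; off for plasticity runs
    storage_c_f: float = 30e-15  # storage node capacitance (F)
    leak_pre: LeakModel | None = None   # optional physical leak overriding tau_pre_s
    leak_post: LeakModel | None = None
    c_pre_f: float = 25e-15
    c_post_f: float = 25e-15

    def __post_init__(self):
        if self.pairing_mode not in ("nearest", "accumulate"):
            raise ValueError("pairing_mode must be 'nearest' or 'accumulate'")
        if not (self.vtc_vmax > 0 and self.vtc_slope > 0):
            raise ValueError("VTC ceiling and slope must be positive")
        if not (self.theta_pre > 0 and self.theta_post > 0):
            raise ValueError("injection thresholds must be positive")
        if min(self.c_plus, self.c_minus, self.gain_pre, self.gain_post) < 0:
            raise ValueError("gains must be non-negative")
        w0 = transfer(self.m_rest, self)
        if not (0 < w0 < self.vtc_vmax):
            raise ValueError("transfer(m_rest) must lie strictly inside (0, vmax)")

    @property
    def eff_tau_pre(self) -> float:
        if self.leak_pre is not None:
            return self.leak_pre.tau_for(self.c_pre_f)
        return self.tau_pre_s

    @property
    def eff_tau_post(self) -> float:
        if self.leak_post is not None:
            return self.leak_post.tau_for(self.c_post_f)
        return self.tau_post_s


def default_params(**overrides) -> SynapseParams:
    """The calibrated nominal synapse, with optional field overrides."""
    return SynapseParams(**overrides)


@dataclass
class SynapseState:
    """Live state of one synapse.

    Integrator voltages are stored as magnitudes; the presynaptic one is
    sampled with negative sign (s_pre <= 0 in circuit polarity).
    """

    v_fg_pre: float = 0.0
    v_fg_post: float = 0.0
    m: float = 0.0
    w: float = 0.0
    t: float = 0.0
    last_pre_t: float = -math.inf
    last_post_t: float = -math.inf


def transfer(m: float, params: SynapseParams) -> float:
    """Saturating VTC: storage level ``m`` -> weight in (0, vmax), decreasing."""
    x = (m - params.vtc_mid) / params.vtc_slope
    # guard exp overflow at extreme storage levels
    if x > 700.0:
        return 0.0
    return params.vtc_vmax / (1.0 + math.exp(x))


def make_state(params: SynapseParams, t: float = 0.0) -> SynapseState:
    """Fresh synapse at the resting storage level."""
    m = params.m_rest
    return SynapseState(m=m, w=transfer(m, params), t=t)


def set_weight(state: SynapseState, params: SynapseParams, target_w: float) -> SynapseState:
    """Program the storage node so the weight equals ``target_w`` (interior only).

    The storage level is found by bisection on the VTC; integrators are
    zeroed (the node is programmed at rest).
    """
    if not (0.0 < target_w < params.vtc_vmax):
        raise ValueError(
            f"target weight {target_w} outside the open interval (0, {params.vtc_vmax})"
        )
    # bracket: logistic is monotone decreasing in m
    lo, hi = params.vtc_mid - 60 * params.vtc_slope, params.vtc_mid + 60 * params.vtc_slope
    m = brentq(lambda mm: transfer(mm, params) - target_w, lo, hi, xtol=1e-12)
    state.m = m
    state.w = transfer(m, params)
    state.v_fg_pre = 0.0
    state.v_fg_post = 0.0
    return state


def decay_to(state: SynapseState, params: SynapseParams, t: float) -> SynapseState:
    """Relax the spike integrators (and optionally the storage node) to time ``t``."""
    if t < state.t:
        raise TimeOrderingError(f"event at t={t} precedes state time {state.t}")
    dt = t - state.t
    if dt > 0.0:
        state.v_fg_pre *= math.exp(-dt / params.eff_tau_pre)
        state.v_fg_post *= math.exp(-dt / params.eff_tau_post)
        if params.storage_leak is not None:
            tau_m = params.storage_leak.tau_for(params.storage_c_f)
            state.m = params.m_rest + (state.m - params.m_rest) * math.exp(-dt / tau_m)
            state.w = transfer(state.m, params)
        state.t = t
    return state


def on_pre_spike(
    state: SynapseState, params: SynapseParams, t: float
) -> tuple[SynapseState, float]:
    """Process a presynaptic spike: sample s_post (possible LTD), then transmit.

    Returns the state and the transmitted weight (after any update).  A post
    spike at the identical timestamp yields no plasticity (the Delta-t = 0
    branch of the pair rule).
    """
    decay_to(state, params, t)
    s_post = params.gain_post * state.v_fg_post
    if params.pairing_mode == "nearest":
        state.v_fg_pre = params.dv_pre
    else:
        state.v_fg_pre += params.dv_pre
    if s_post > params.theta_post and t != state.last_post_t:
        dm = (
            params.c_minus
            * (s_post - params.theta_post)
            * math.exp(-(state.m - params.m_rest) / params.lambda_minus)
        )
        state.m += dm
        state.w = transfer(state.m, params)
    state.last_pre_t = t
    return state, state.w


def on_post_spike(
    state: SynapseState, params: SynapseParams, t: float, causal: bool = False
) -> SynapseState:
    """Process a postsynaptic spike: sample s_pre (possible LTP).

    A post spike at the identical timestamp as the last pre spike is a
    Delta-t = 0 tie and injects nothing — unless ``causal`` is set, which
    marks a spike emitted in response to that pre event and is treated as
    the Delta-t -> 0+ limit (full potentiation).
    """
    decay_to(state, params, t)
    s_pre_mag = params.gain_pre * state.v_fg_pre
    if params.pairing_mode == "nearest":
        state.v_fg_post = params.dv_post
    else:
        state.v_fg_post += params.dv_post
    if s_pre_mag > params.theta_pre and (causal or t != state.last_pre_t):
        dm = (
            -params.c_plus
            * (s_pre_mag - params.theta_pre)
            * math.exp((state.m - params.m_rest) / params.lambda_plus)
        )
        state.m += dm
        state.w = transfer(state.m, params)
    state.last_post_t = t
    return state


def _single_pair_dw(params: SynapseParams, dt_s: float, w0: float) -> float:
    """Weight change from one pre/post pair separated by ``dt_s`` at weight ``w0``."""
    state = make_state(params)
    set_weight(state, params, w0)
    t0 = 1.0
    if dt_s == 0.0:
        return 0.0
    if dt_s > 0.0:
        on_pre_spike(state, params, t0)
        on_post_spike(state, params, t0 + dt_s)
    else:
        on_post_spike(state, params, t0)
        on_pre_spike(state, params, t0 - dt_s)
    return state.w - w0


def stdp_curve(
    params: SynapseParams, dt_values_ms, v_w0: float = 0.151
) -> list[tuple[float, float]]:
    """Single-pair STDP curve: (Delta-t in ms, Delta-V_w in V) per timing.

    Each timing uses a fresh synapse programmed to ``v_w0``; Delta-t = 0
    yields zero by the pair-rule convention.
    """
    dt_values_ms = list(dt_values_ms)
    if not dt_values_ms:
        raise ValueError("dt_values must be non-empty")
    out = []
    for dt_ms in dt_values_ms:
        if abs(dt_ms) >= 1000.0:
            raise ValueError("|Delta-t| must be below 1 s")
        out.append((dt_ms, _single_pair_dw(params, dt_ms * 1e-3, v_w0)))
    return out


@dataclass(frozen=True)
class StdpFit:
    """Exponential-window fit of an STDP curve."""

    a_plus: float      # V
    a_minus: float     # V
    tau_plus_ms: float
    tau_minus_ms: float
    residual: float    # rms over all fitted points (V)


def fit_stdp(curve) -> StdpFit:
    """Least-squares fit of A+ e^(-dt/tau+) / -A- e^(dt/tau-) to the two branches."""
    dts = np.array([p[0] for p in curve], dtype=float)
    dws = np.array([p[1] for p in curve], dtype=float)
    pos = dts > 0
    neg = dts < 0
    if not pos.any() or not neg.any():
        raise ValueError("curve must contain both positive and negative Delta-t samples")

    def expo(t, a, tau):
        return a * np.exp(-t / tau)

    try:
        (a_p, tau_p), _ = curve_fit(
            expo, dts[pos], dws[pos],
            p0=(max(dws[pos].max(), 1e-4), 20.0),
            maxfev=20000,
        )
        (a_m, tau_m), _ = curve_fit(
            expo, -dts[neg], -dws[neg],
            p0=(max((-dws[neg]).max(), 1e-4), 80.0),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError(f"STDP fit did not converge: {exc}") from exc
    pred = np.where(pos, expo(dts, a_p, tau_p), 0.0) + np.where(
        neg, -expo(-dts, a_m, tau_m), 0.0
    )
    mask = pos | neg
    residual = float(np.sqrt(np.mean((dws[mask] - pred[mask]) ** 2)))
    if tau_p <= 0 or tau_m <= 0:
        raise FitError(
            "fit converged to non-positive time constant",
            last_iterate=(a_p, tau_p, a_m, tau_m),
        )
    return StdpFit(
        a_plus=float(a_p),
        a_minus=float(a_m),
        tau_plus_ms=float(tau_p),
        tau_minus_ms=float(tau_m),
        residual=residual,
    )


def weight_dependence(params: SynapseParams, dt_ms: float, w_grid) -> list[tuple[float, float]]:
    """Single-pair Delta-V_w as a function of the starting weight."""
    out = []
    for w0 in w_grid:
        if not (0.0 <= w0 <= params.vtc_vmax):
            raise ValueError("w_grid values must lie in [0, vmax]")
        # poles are unreachable by set_weight; evaluate the limit there
        if w0 <= 0.0 or w0 >= params.vtc_vmax:
            out.append((float(w0), 0.0))
            continue
        out.append((float(w0), _single_pair_dw(params, dt_ms * 1e-3, float(w0))))
    return out
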