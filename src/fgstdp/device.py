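"""Floating-gate charge-relaxation physics.

A floating gate (FG) loses its stored charge through a thin tunnel junction.
This module models that leak either phenomenologically (a single exponential
time constant) or physically, with a low-bias direct-tunneling law of
Simmons/WKB form,

    I(V) = area * g0 * V * exp(-2 * kappa * t_tun),
    kappa = sqrt(2 * m* * m_e * q * phi) / hbar,

where ``t_tun`` is the barrier thickness, ``phi`` the barrier height and
``m*`` the effective tunneling mass ratio.  Barrier lowering under bias is
ignored, so the law is linear in V and free relaxation of an FG node of
capacitance C is exactly exponential with tau = C / G(barrier).

The only free prefactor ``g0`` is fixed by :func:`calibrate_leak` against a
relaxation-time anchor; the exponential thickness sensitivity (two orders of
magnitude in tau per ~30% thickness change around 1.2 nm) is carried entirely
by kappa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.constants import electron_mass, elementary_charge, hbar

__all__ = [
    "TunnelBarrier",
    "FgNode",
    "LeakModel",
    "CalibrationError",
    "NonConvergenceError",
    "tunnel_current",
    "relax_fg",
    "relaxation_time",
    "retention_time",
    "calibrate_leak",
    "DEFAULT_BARRIER_EV",
    "DEFAULT_MASS_RATIO",
    "INTEGRATOR_G0",
    "STORAGE_G0",
    "default_integrator_leak",
    "default_storage_leak",
]

# SiO2 barrier defaults used when calibration is under-determined.
DEFAULT_BARRIER_EV = 3.1
DEFAULT_MASS_RATIO = 0.4

# Prefactors (S/m^2) frozen from calibrate_leak against the printed anchors:
#  - integrator junction: tau_relax = 0.5 s at t_tun = 1.3 nm, C_FG = 2 fF,
#    60 x 120 nm^2 junction area;
#  - storage stack (TJ2 60x120 + TJ3 120x240 nm^2 in parallel, 1.75 nm,
#    30 fF): retention time 85 s, the midpoint of the 70-100 s band.
INTEGRATOR_G0 = 1.0650008095696636e+06
STORAGE_G0 = 4.8498409829467995e+05

_RELAX_T_MIN = 1e-6   # s, search floor for threshold-crossing times
_RELAX_T_MAX = 1e4    # s, search horizon
_RELAX_RTOL = 1e-3


class CalibrationError(RuntimeError):
    """No parameter set within bounds reproduces the anchors."""

    def __init__(self, msg: str, residuals=None):
        super().__init__(msg)
        self.residuals = residuals


class NonConvergenceError(RuntimeError):
    """A threshold-crossing search exhausted its horizon."""


@dataclass(frozen=True)
class TunnelBarrier:
    """Tunnel-junction geometry and barrier parameters.

    thickness_nm : barrier thickness t_tun (nm)
    area_nm2     : junction area (nm^2)
    barrier_ev   : barrier height phi (eV)
    mass_ratio   : effective tunneling mass m*/m_e, in (0, 1]
    g0           : conductance prefactor (S/m^2), calibrated
    """

    thickness_nm: float
    area_nm2: float
    barrier_ev: float = DEFAULT_BARRIER_EV
    mass_ratio: float = DEFAULT_MASS_RATIO
    g0: float = INTEGRATOR_G0

    def __post_init__(self):
        if not (self.thickness_nm > 0):
            raise ValueError("barrier thickness must be positive")
        if not (self.area_nm2 > 0):
            raise ValueError("junction area must be positive")
        if not (self.barrier_ev > 0):
            raise ValueError("barrier height must be positive")
        if not (0 < self.mass_ratio <= 1):
            raise ValueError("effective mass ratio must lie in (0, 1]")
        if not (self.g0 > 0):
            raise ValueError("conductance prefactor must be positive")

    @property
    def kappa(self) -> float:
        """WKB decay constant (1/m)."""
        return math.sqrt(
            2.0 * self.mass_ratio * electron_mass
            * elementary_charge * self.barrier_ev
        ) / hbar

    @property
    def conductance(self) -> float:
        """Small-signal junction conductance G = area * g0 * exp(-2 kappa t) (S)."""
        area_m2 = self.area_nm2 * 1e-18
        t_m = self.thickness_nm * 1e-9
        return area_m2 * self.g0 * math.exp(-2.0 * self.kappa * t_m)


@dataclass(frozen=True)
class LeakModel:
    """Charge-relaxation law of an FG node.

    Exactly one mode is active: ``exponential`` (phenomenological time
    constant ``tau_s``) or ``tunneling`` (physical, via ``barrier``).
    """

    mode: str
    tau_s: float | None = None
    barrier: TunnelBarrier | None = None

    def __post_init__(self):
        if self.mode == "exponential":
            if self.tau_s is None or not (self.tau_s > 0):
                raise ValueError("exponential mode requires tau_s > 0")
            if self.barrier is not None:
                raise ValueError("exponential mode takes no barrier")
        elif self.mode == "tunneling":
            if self.barrier is None:
                raise ValueError("tunneling mode requires a barrier")
            if self.tau_s is not None:
                raise ValueError("tunneling mode takes no tau_s")
        else:
            raise ValueError(f"unknown leak mode {self.mode!r}")

    def tau_for(self, c_fg_f: float) -> float:
        """Effective relaxation time constant (s) for capacitance ``c_fg_f`` (F)."""
        if self.mode == "exponential":
            return self.tau_s
        return c_fg_f / self.barrier.conductance


@dataclass
class FgNode:
    """A floating-gate node: capacitance, stored voltage and its leak."""

    c_fg_f: float
    leak: LeakModel
    v_fg: float = 0.0

    def __post_init__(self):
        if not (self.c_fg_f > 0):
            raise ValueError("C_FG must be positive")
        if not math.isfinite(self.v_fg):
            raise ValueError("V_FG must be finite")


def tunnel_current(voltage: float, barrier: TunnelBarrier) -> float:
    """Net tunneling current (A) across ``barrier`` at ``voltage`` (V).

    Linear in voltage and area; exponentially suppressed by thickness.
    """
    if not math.isfinite(voltage):
        raise ValueError("voltage must be finite")
    return barrier.conductance * voltage


def relax_fg(node: FgNode, v0: float, duration: float) -> float:
    """FG voltage after free relaxation from ``v0`` for ``duration`` seconds.

    The leak law is linear in voltage in both modes, so the decay is a pure
    exponential with the node's effective time constant.
    """
    if duration < 0:
        raise ValueError("duration must be non-negative")
    if duration == 0:
        return v0
    tau = node.leak.tau_for(node.c_fg_f)
    return v0 * math.exp(-duration / tau)


def _crossing_time(node: FgNode, v0: float, level: float) -> float:
    """Smallest t with |V(t)| <= level, by bisection on a log-time grid."""
    tau = node.leak.tau_for(node.c_fg_f)
    if not math.isfinite(tau) or tau <= 0:
        raise NonConvergenceError(
            f"leak produces no decay (effective tau = {tau}); "
            f"searched up to {_RELAX_T_MAX} s"
        )
    if abs(relax_fg(node, v0, _RELAX_T_MAX)) > level:
        raise NonConvergenceError(
            f"|V| did not fall below {level} V within the {_RELAX_T_MAX} s horizon"
        )
    lo, hi = _RELAX_T_MIN, _RELAX_T_MAX
    if abs(relax_fg(node, v0, lo)) <= level:
        return lo
    while (hi - lo) / hi > _RELAX_RTOL:
        mid = math.sqrt(lo * hi)
        if abs(relax_fg(node, v0, mid)) <= level:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def relaxation_time(node: FgNode, v_peak: float) -> float:
    """Half-peak relaxation time: smallest t with |V(t)| < |v_peak| / 2."""
    if v_peak == 0:
        raise ValueError("v_peak must be nonzero")
    if node.leak.mode == "exponential":
        return node.leak.tau_s * math.log(2.0)
    return _crossing_time(node, v_peak, abs(v_peak) / 2.0)


def retention_time(storage_node: FgNode, v_m0: float) -> float:
    """Retention time: smallest t at which |V_m| has declined by 10%."""
    if v_m0 == 0:
        raise ValueError("v_m0 must be nonzero")
    if storage_node.leak.mode == "exponential":
        return storage_node.leak.tau_s * math.log(10.0 / 9.0)
    return _crossing_time(storage_node, v_m0, 0.9 * abs(v_m0))


def calibrate_leak(
    anchors: list[tuple[float, float, float]],
    mode: str = "tunneling",
    area_nm2: float = 60.0 * 120.0,
    barrier_ev: float = DEFAULT_BARRIER_EV,
    mass_ratio: float = DEFAULT_MASS_RATIO,
    rtol: float = 0.05,
) -> LeakModel:
    """Fit the free leak parameter to ``(c_fg_fF, t_tun_nm, tau_relax_s)`` anchors.

    In tunneling mode the single free parameter is the prefactor ``g0``
    (barrier height and mass ratio stay at their SiO2 defaults when
    under-determined); each anchor fixes it in closed form and the geometric
    mean is taken, with every anchor required to be reproduced within
    ``rtol`` relative error.  In exponential mode tau_s = tau_target / ln 2
    (single effective anchor).
    """
    if not anchors:
        raise ValueError("at least one anchor is required")
    ln2 = math.log(2.0)
    if mode == "exponential":
        taus = [tau_target / ln2 for (_, _, tau_target) in anchors]
        tau = math.exp(sum(math.log(t) for t in taus) / len(taus))
        resid = [abs(t * ln2 - tgt) / tgt for t, (_, _, tgt) in zip(taus, anchors)]
        if max(abs(tau * ln2 - tgt) / tgt for (_, _, tgt) in anchors) > rtol:
            raise CalibrationError(
                "mutually inconsistent anchors for a one-parameter model",
                residuals=resid,
            )
        return LeakModel(mode="exponential", tau_s=tau)
    if mode != "tunneling":
        raise ValueError(f"unknown leak mode {mode!r}")

    ref = TunnelBarrier(1.0, area_nm2, barrier_ev, mass_ratio, g0=1.0)
    g0s = []
    for c_fg_ff, t_tun_nm, tau_target in anchors:
        if not (c_fg_ff > 0 and t_tun_nm > 0 and tau_target > 0):
            raise ValueError("anchors must have positive C_FG, t_tun and tau")
        # tau_relax = ln2 * C / (area * g0 * exp(-2 kappa t))
        atten = math.exp(-2.0 * ref.kappa * t_tun_nm * 1e-9)
        g0s.append(ln2 * c_fg_ff * 1e-15 / (tau_target * area_nm2 * 1e-18 * atten))
    g0 = math.exp(sum(math.log(g) for g in g0s) / len(g0s))

    residuals = []
    for (c_fg_ff, t_tun_nm, tau_target), _ in zip(anchors, g0s):
        barrier = TunnelBarrier(t_tun_nm, area_nm2, barrier_ev, mass_ratio, g0=g0)
        node = FgNode(c_fg_f=c_fg_ff * 1e-15, leak=LeakModel("tunneling", barrier=barrier))
        residuals.append(abs(relaxation_time(node, 1.0) - tau_target) / tau_target)
    if max(residuals) > rtol:
        raise CalibrationError(
            f"anchors not reproducible within {rtol:.0%} by a single prefactor",
            residuals=residuals,
        )
    return LeakModel(
        mode="tunneling",
        barrier=TunnelBarrier(
            anchors[0][1], area_nm2, barrier_ev, mass_ratio, g0=g0
        ),
    )


def default_integrator_leak(t_tun_nm: float = 1.3) -> LeakModel:
    """Anchor-calibrated leak of the state-variable integrator junction."""
    return LeakModel(
        mode="tunneling",
        barrier=TunnelBarrier(t_tun_nm, 60.0 * 120.0, g0=INTEGRATOR_G0),
    )


def default_storage_leak(t_tun_nm: float = 1.75) -> LeakModel:
    """Band-calibrated leak of the weight-storage stack (TJ2 + TJ3 in parallel)."""
    return LeakModel(
        mode="tunneling",
        barrier=TunnelBarrier(
            t_tun_nm, 60.0 * 120.0 + 120.0 * 240.0, g0=STORAGE_G0
        ),
    )
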