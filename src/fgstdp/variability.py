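"""MOSFET mismatch models and Monte-Carlo propagation to synapse behavior.

Random dopant fluctuation (RDF) shifts each transistor's threshold voltage
with the Pelgrom area law, sigma_Vt = A_RDF / sqrt(L * W); line-edge
roughness (LER) perturbs the drawn channel length with sigma_L =
A_LER / sqrt(W).  Device-level deviations are mapped onto the behavioral
synapse parameters by a transparent first-order sensitivity rule:

* a state-variable device's Vt deviation scales its per-spike FG jump and
  its sampling threshold proportionally (1% per mV by default);
* its length deviation scales the corresponding leak time constant by the
  relative channel-length change;
* storage-stack Vt deviations shift the resting storage level m_rest
  directly (volt for volt), spreading the initial weight.

``run_mc`` draws an ensemble of perturbed circuits and reruns the STDP
curve (and optionally the supervised-competition experiment) per circuit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .network import protocol_supervised
from .synapse import SynapseParams, stdp_curve, transfer

__all__ = [
    "MosfetGeometry",
    "VariabilityParams",
    "DEVICE_GEOMETRY",
    "sigma_vth",
    "sigma_length",
    "sample_circuit",
    "run_mc",
]

A_RDF_DEFAULT = 1.27e-9   # V*m
A_LER_DEFAULT = 1.04e-12  # m^(3/2)


@dataclass(frozen=True)
class MosfetGeometry:
    """Drawn channel dimensions in nm."""

    l_nm: float
    w_nm: float

    def __post_init__(self):
        if not (self.l_nm > 0 and self.w_nm > 0):
            raise ValueError("channel dimensions must be positive")


# Geometries of the devices whose mismatch matters behaviorally:
# state-variable integrator junctions (pre and post) and the storage stack.
DEVICE_GEOMETRY: dict[str, MosfetGeometry] = {
    "integrator_pre": MosfetGeometry(60.0, 120.0),    # TJ4 + M11 group
    "integrator_post": MosfetGeometry(60.0, 120.0),   # TJ1 + M2 group
    "storage_tj2": MosfetGeometry(60.0, 120.0),
    "storage_tj3": MosfetGeometry(120.0, 240.0),
    "storage_readout": MosfetGeometry(90.0, 1400.0),  # M10
}


@dataclass(frozen=True)
class VariabilityParams:
    """Mismatch amplitudes and device-to-behavior sensitivities."""

    a_rdf: float = A_RDF_DEFAULT
    a_ler: float = A_LER_DEFAULT
    vth_sensitivity_per_mv: float = 0.01   # relative jitter of jump/threshold per mV
    m_rest_sensitivity: float = 1.0        # V of m_rest shift per V of storage Vt dev

    def __post_init__(self):
        if self.a_rdf < 0 or self.a_ler < 0:
            raise ValueError("mismatch amplitudes must be non-negative")


def sigma_vth(geom: MosfetGeometry, a_rdf: float = A_RDF_DEFAULT) -> float:
    """Pelgrom threshold-voltage mismatch (V) for the given geometry."""
    if a_rdf < 0:
        raise ValueError("a_rdf must be non-negative")
    area_m2 = geom.l_nm * 1e-9 * geom.w_nm * 1e-9
    return a_rdf / math.sqrt(area_m2)


def sigma_length(w_nm: float, a_ler: float = A_LER_DEFAULT) -> float:
    """LER channel-length standard deviation (nm) for channel width ``w_nm``."""
    if not (w_nm > 0):
        raise ValueError("channel width must be positive")
    if a_ler < 0:
        raise ValueError("a_ler must be non-negative")
    return a_ler / math.sqrt(w_nm * 1e-9) * 1e9


def sample_circuit(
    params: SynapseParams,
    var: VariabilityParams,
    geometry: dict[str, MosfetGeometry] | None = None,
    rng: np.random.Generator | None = None,
    max_tries: int = 100,
) -> SynapseParams:
    """One mismatch realization of the behavioral synapse.

    Invalid draws (violating the parameter invariants) are rejected and
    resampled.
    """
    geometry = geometry or DEVICE_GEOMETRY
    rng = rng if rng is not None else np.random.default_rng()
    for _ in range(max_tries):
        try:
            return _draw(params, var, geometry, rng)
        except ValueError:
            continue
    raise RuntimeError("could not draw a valid circuit realization")


def _draw(params, var, geometry, rng) -> SynapseParams:
    def vth_dev(role):
        return rng.normal(0.0, sigma_vth(geometry[role], var.a_rdf))

    def rel_len_dev(role):
        g = geometry[role]
        return rng.normal(0.0, sigma_length(g.w_nm, var.a_ler)) / g.l_nm

    s = var.vth_sensitivity_per_mv * 1e3  # per volt of Vt deviation
    pre_vt = vth_dev("integrator_pre")
    post_vt = vth_dev("integrator_post")
    m_shift = var.m_rest_sensitivity * (
        vth_dev("storage_tj2") + vth_dev("storage_tj3") + vth_dev("storage_readout")
    )
    return replace(
        params,
        dv_pre=params.dv_pre * (1.0 + s * pre_vt),
        dv_post=params.dv_post * (1.0 + s * post_vt),
        theta_pre=params.theta_pre * (1.0 + s * pre_vt),
        theta_post=params.theta_post * (1.0 + s * post_vt),
        tau_pre_s=params.tau_pre_s * (1.0 + rel_len_dev("integrator_pre")),
        tau_post_s=params.tau_post_s * (1.0 + rel_len_dev("integrator_post")),
        m_rest=params.m_rest + m_shift,
    )


def run_mc(
    n_circuits: int = 200,
    experiment: str = "stdp",
    seed: int | np.random.SeedSequence = 0,
    params: SynapseParams | None = None,
    var: VariabilityParams | None = None,
    dt_values_ms=None,
    duration: float = 100.0,
) -> dict:
    """Monte-Carlo ensemble over mismatched circuits.

    ``experiment="stdp"``: per-circuit single-pair STDP curves from each
    circuit's own resting weight, plus the resting-weight distribution and
    its normal fit.  ``experiment="supervised"``: per-circuit supervised
    competition (bias synced to N2) reporting terminal (w1, w2).
    """
    if n_circuits < 2:
        raise ValueError("need at least two circuits")
    if experiment not in ("stdp", "supervised"):
        raise ValueError(f"unknown experiment {experiment!r}")
    params = params or SynapseParams()
    var = var or VariabilityParams()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    circuit_seeds = ss.spawn(n_circuits)
    if dt_values_ms is None:
        dt_values_ms = [float(d) for d in range(-100, 0, 4)] + [
            float(d) for d in range(1, 101, 4)
        ]

    circuits = []
    w0s = np.empty(n_circuits)
    for i in range(n_circuits):
        rng = np.random.default_rng(circuit_seeds[i])
        p_i = sample_circuit(params, var, rng=rng)
        circuits.append((p_i, circuit_seeds[i]))
        w0s[i] = transfer(p_i.m_rest, p_i)

    out: dict = {
        "experiment": experiment,
        "n_circuits": n_circuits,
        "weights0": w0s,
        "normal_fit": {"mean": float(w0s.mean()), "std": float(w0s.std(ddof=1))},
        "shapiro_p": float(stats.shapiro(w0s).pvalue),
    }
    if experiment == "stdp":
        rows = []
        sign_ok = 0
        for i, (p_i, _) in enumerate(circuits):
            curve = stdp_curve(p_i, dt_values_ms, v_w0=float(np.clip(w0s[i], 1e-4, 0.4999)))
            for dt, dw in curve:
                rows.append({"circuit": i, "dt_ms": dt, "dvw": dw})
            dts = np.array([c[0] for c in curve]); dws = np.array([c[1] for c in curve])
            pos_ok = dws[(dts > 0) & (dts <= 20)].mean() > 0
            neg_ok = dws[(dts < 0) & (dts >= -20)].mean() < 0
            sign_ok += pos_ok and neg_ok
        out["curves"] = pd.DataFrame(rows)
        out["sign_correct_fraction"] = sign_ok / n_circuits
    else:
        term = np.empty((n_circuits, 2))
        for i, (p_i, c_ss) in enumerate(circuits):
            tr = protocol_supervised(
                synced_source="N2", duration=duration,
                seed=c_ss.spawn(1)[0], params=p_i,
            )
            term[i] = (tr.weights["w1"][-1], tr.weights["w2"][-1])
        out["terminal_weights"] = pd.DataFrame(term, columns=["w1", "w2"])
        wins2 = int((term[:, 1] > term[:, 0]).sum())
        out["p_w2_wins"] = wins2 / n_circuits
        out["binom_p_vs_half"] = float(
            stats.binomtest(wins2, n_circuits, 0.5, alternative="greater").pvalue
        )
    return out
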