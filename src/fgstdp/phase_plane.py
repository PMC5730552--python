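"""Statistical phase-plane analysis of the two-afferent weight dynamics.

The expected drift (dVw1/dt, dVw2/dt) is estimated on a grid over the
(w1, w2) plane: at each node the network is initialized with those weights,
the competition protocol is run for a short horizon, and the mean weight
displacement per unit time is averaged over replicate runs with independent
seed substreams.  Trajectories from full-length runs can then be overlaid
and compared against the interpolated field direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .network import (
    protocol_alternating,
    protocol_supervised,
    protocol_unsupervised,
)

__all__ = ["VectorField", "vector_field", "overlay_trajectories", "protocol_runner"]


@dataclass
class VectorField:
    """Mean weight drift over a (w1, w2) grid, with Monte-Carlo errors."""

    w1_nodes: np.ndarray        # (n1,)
    w2_nodes: np.ndarray        # (n2,)
    dw1: np.ndarray             # (n1, n2) V/s
    dw2: np.ndarray             # (n1, n2)
    se1: np.ndarray             # standard errors
    se2: np.ndarray
    replicates: int


def protocol_runner(kind: str, **kwargs) -> Callable:
    """A runner(w1, w2, horizon, seed) -> Trace for one competition protocol."""
    table = {
        "compete": protocol_unsupervised,
        "alternate": protocol_alternating,
        "supervise": protocol_supervised,
    }
    if kind not in table:
        raise ValueError(f"unknown protocol {kind!r}")
    proto = table[kind]

    def runner(w1: float, w2: float, horizon: float, seed):
        return proto(
            duration=horizon, seed=seed, w_init=(w1, w2),
            sample_dt=horizon, **kwargs
        )

    return runner


def vector_field(
    runner: Callable,
    w1_nodes,
    w2_nodes,
    horizon_s: float = 2.0,
    replicates: int = 10,
    seed: int | np.random.SeedSequence = 0,
) -> VectorField:
    """Estimate the weight-drift field at every interior grid node.

    Node weights must lie strictly inside (0, 0.5 V): the saturating
    transfer cannot be programmed exactly to its poles.
    """
    if not (horizon_s > 0):
        raise ValueError("horizon must be positive")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    w1_nodes = np.asarray(w1_nodes, dtype=float)
    w2_nodes = np.asarray(w2_nodes, dtype=float)
    for nodes in (w1_nodes, w2_nodes):
        if nodes.min() <= 0.0 or nodes.max() >= 0.5:
            raise ValueError("grid nodes must lie strictly inside (0, 0.5 V)")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    n1, n2 = w1_nodes.size, w2_nodes.size
    dw1 = np.empty((n1, n2)); dw2 = np.empty((n1, n2))
    se1 = np.empty((n1, n2)); se2 = np.empty((n1, n2))
    node_seeds = ss.spawn(n1 * n2)
    for i, w1 in enumerate(w1_nodes):
        for j, w2 in enumerate(w2_nodes):
            rep_seeds = node_seeds[i * n2 + j].spawn(replicates)
            d1 = np.empty(replicates); d2 = np.empty(replicates)
            for r in range(replicates):
                tr = runner(w1, w2, horizon_s, rep_seeds[r])
                d1[r] = (tr.weights["w1"][-1] - w1) / horizon_s
                d2[r] = (tr.weights["w2"][-1] - w2) / horizon_s
            dw1[i, j] = d1.mean(); dw2[i, j] = d2.mean()
            denom = math.sqrt(replicates) if replicates > 1 else 1.0
            se1[i, j] = d1.std(ddof=1) / denom if replicates > 1 else 0.0
            se2[i, j] = d2.std(ddof=1) / denom if replicates > 1 else 0.0
    return VectorField(w1_nodes, w2_nodes, dw1, dw2, se1, se2, replicates)


def overlay_trajectories(
    field: VectorField, traces, se_factor: float = 3.0
) -> list[dict]:
    """Compare trajectory displacement directions with the local field.

    For each trace, every displacement segment whose start lies inside the
    grid hull and where the interpolated field magnitude exceeds
    ``se_factor`` times its standard error contributes the angle between
    the empirical displacement and the field vector.  Returns per-trace
    statistics (mean angle in degrees, counted and excluded segments).
    """
    interp = {
        name: RegularGridInterpolator(
            (field.w1_nodes, field.w2_nodes), getattr(field, name),
            bounds_error=False, fill_value=np.nan,
        )
        for name in ("dw1", "dw2", "se1", "se2")
    }
    lo1, hi1 = field.w1_nodes[0], field.w1_nodes[-1]
    lo2, hi2 = field.w2_nodes[0], field.w2_nodes[-1]
    reports = []
    for tr in traces:
        w1 = tr.weights["w1"]; w2 = tr.weights["w2"]
        angles = []
        excluded = 0
        for k in range(len(w1) - 1):
            p = (w1[k], w2[k])
            disp = np.array([w1[k + 1] - w1[k], w2[k + 1] - w2[k]])
            if not (lo1 <= p[0] <= hi1 and lo2 <= p[1] <= hi2):
                excluded += 1
                continue
            v = np.array([float(interp["dw1"](p)), float(interp["dw2"](p))])
            se = np.array([float(interp["se1"](p)), float(interp["se2"](p))])
            vmag = np.linalg.norm(v)
            if not np.isfinite(vmag) or vmag <= se_factor * np.linalg.norm(se):
                excluded += 1
                continue
            dmag = np.linalg.norm(disp)
            if dmag == 0.0:
                excluded += 1
                continue
            cosang = float(np.clip(np.dot(disp, v) / (dmag * vmag), -1.0, 1.0))
            angles.append(math.degrees(math.acos(cosang)))
        reports.append(
            {
                "mean_angle_deg": float(np.mean(angles)) if angles else float("nan"),
                "n_segments": len(angles),
                "n_excluded": excluded,
            }
        )
    return reports
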