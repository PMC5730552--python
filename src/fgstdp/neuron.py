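"""Stein point neuron and Poisson spike sources.

The postsynaptic neuron follows the Stein model: the subthreshold membrane
potential decays exponentially with time constant tau_m and jumps by
alpha * V_w (the transmitted weight) at each input spike; on reaching
threshold it fires and resets.  Between events the decay is applied in
closed form, so simulation is exactly event-driven — postsynaptic spikes can
only occur at input-event instants.  There is no refractory period.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SteinParams",
    "SteinState",
    "SpikeTrain",
    "integrate",
    "poisson_train",
    "binned_alternating_trains",
    "alternating_trains_with_bins",
    "spawn_seeds",
]


@dataclass(frozen=True)
class SteinParams:
    """Membrane constants (mV, ms as printed; stored as mV and s)."""

    tau_m_s: float = 0.010
    threshold_mv: float = 90.0
    alpha: float = 0.3
    reset_mv: float = 0.0

    def __post_init__(self):
        if not (self.tau_m_s > 0):
            raise ValueError("tau_m must be positive")
        if not (self.threshold_mv > self.reset_mv):
            raise ValueError("threshold must exceed reset")


@dataclass
class SteinState:
    u_m_mv: float = 0.0
    t: float = 0.0


@dataclass(frozen=True)
class SpikeTrain:
    """Strictly increasing spike times of one source."""

    times: np.ndarray
    source_id: str = ""

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.size:
            if (np.diff(times) <= 0).any():
                raise ValueError("spike times must be strictly increasing")
            if times[0] < 0:
                raise ValueError("spike times must be non-negative")

    def __len__(self):
        return int(self.times.size)


def integrate(
    state: SteinState, params: SteinParams, events
) -> tuple[SteinState, SpikeTrain]:
    """Drive the membrane with ``(time_s, weight_V)`` events; return emitted spikes.

    Decay between events is exact; each event adds alpha * weight (V -> mV).
    Threshold is checked after each increment and the membrane resets
    immediately on firing.
    """
    emitted = []
    last_t = state.t
    for t, w in events:
        if t < last_t:
            raise ValueError("events must be time-sorted and not precede the state")
        state.u_m_mv = params.reset_mv + (state.u_m_mv - params.reset_mv) * math.exp(
            -(t - last_t) / params.tau_m_s
        )
        state.u_m_mv += params.alpha * w * 1000.0
        if state.u_m_mv >= params.threshold_mv:
            emitted.append(t)
            state.u_m_mv = params.reset_mv
        state.t = t
        last_t = t
    # strictly-increasing guard: simultaneous double crossings collapse to one spike
    times = np.array(emitted, dtype=float)
    if times.size:
        times = np.unique(times)
    return state, SpikeTrain(times=times, source_id="emitted")


def spawn_seeds(master_seed: int, n: int) -> list[np.random.SeedSequence]:
    """Deterministic per-source substreams from one master seed."""
    return np.random.SeedSequence(master_seed).spawn(n)


def poisson_train(
    rate_hz: float, duration_s: float, rng_seed, source_id: str = ""
) -> SpikeTrain:
    """Homogeneous Poisson train via i.i.d. exponential inter-spike intervals."""
    if rate_hz < 0 or duration_s < 0:
        raise ValueError("rate and duration must be non-negative")
    if rate_hz == 0 or duration_s == 0:
        return SpikeTrain(times=np.empty(0), source_id=source_id)
    rng = np.random.default_rng(rng_seed)
    # draw in blocks until the horizon is passed
    times = []
    t = 0.0
    expected = max(16, int(rate_hz * duration_s * 1.5))
    while True:
        isis = rng.exponential(1.0 / rate_hz, size=expected)
        cum = t + np.cumsum(isis)
        take = cum[cum < duration_s]
        times.append(take)
        if cum[-1] >= duration_s:
            break
        t = cum[-1]
    return SpikeTrain(times=np.concatenate(times), source_id=source_id)


def alternating_trains_with_bins(
    rate_hz: float,
    bin_width_s: float,
    duration_s: float,
    n_sources: int,
    rng_seed,
) -> tuple[list[SpikeTrain], np.ndarray]:
    """Binned alternating Poisson input plus the per-bin active-source index.

    In every bin of width ``bin_width_s`` a uniformly chosen source fires a
    Poisson train at ``rate_hz``; all others stay silent.
    """
    if not (bin_width_s > 0):
        raise ValueError("bin width must be positive")
    if n_sources < 2:
        raise ValueError("need at least two sources")
    if rate_hz < 0 or duration_s < 0:
        raise ValueError("rate and duration must be non-negative")
    rng = np.random.default_rng(rng_seed)
    n_bins = int(math.ceil(duration_s / bin_width_s)) if duration_s > 0 else 0
    active = rng.integers(0, n_sources, size=n_bins)
    per_source = [[] for _ in range(n_sources)]
    for b in range(n_bins):
        t0 = b * bin_width_s
        t1 = min(t0 + bin_width_s, duration_s)
        n = rng.poisson(rate_hz * (t1 - t0))
        if n:
            ts = np.sort(rng.uniform(t0, t1, size=n))
            # enforce strict monotonicity against measure-zero duplicates
            ts = np.unique(ts)
            per_source[active[b]].append(ts)
    trains = []
    for i, chunks in enumerate(per_source):
        times = np.concatenate(chunks) if chunks else np.empty(0)
        trains.append(SpikeTrain(times=times, source_id=f"N{i + 1}"))
    return trains, active


def binned_alternating_trains(
    rate_hz: float,
    bin_width_s: float,
    duration_s: float,
    n_sources: int,
    rng_seed,
) -> list[SpikeTrain]:
    """Binned alternating Poisson input (active-bin bookkeeping discarded)."""
    trains, _ = alternating_trains_with_bins(
        rate_hz, bin_width_s, duration_s, n_sources, rng_seed
    )
    return trains
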