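"""Event-driven network engine and the four experiment protocols.

A network wires spike sources (Poisson, binned-alternating, or scheduled
trains) through plastic FG synapses onto Stein neurons.  Processing is
strictly event-driven: a presynaptic spike first drives synaptic
transmission and the membrane update; an emitted postsynaptic spike then
triggers postsynaptic plasticity on all afferent synapses at the same
instant (where the pair rule assigns no plasticity to exact timestamp
ties).  Scheduled sources can also act as "neurons" whose firing is imposed
— their spikes are presynaptic on efferent synapses and postsynaptic on
afferent ones, transmission first.

Simultaneous presynaptic events are processed in ascending source order and
the membrane threshold is checked after each increment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .neuron import (
    SpikeTrain,
    SteinParams,
    SteinState,
    alternating_trains_with_bins,
    poisson_train,
)
from .synapse import (
    SynapseParams,
    SynapseState,
    make_state,
    on_post_spike,
    on_pre_spike,
    set_weight,
)

__all__ = [
    "Synapse",
    "Network",
    "Trace",
    "run",
    "protocol_bidirectional_pairing",
    "protocol_unsupervised",
    "protocol_alternating",
    "protocol_supervised",
]


@dataclass
class Synapse:
    """A directed connection with its own parameters and live state."""

    name: str
    pre: str
    post: str
    params: SynapseParams
    state: SynapseState
    plastic: bool = True


@dataclass
class Network:
    """Sources, synapses and neurons of one experiment.

    ``sources`` maps a name to its full spike train (pre-generated);
    ``neurons`` maps a name to (params, state).  A source name may coincide
    with nothing in ``neurons``: scheduled sources need no membrane.
    """

    sources: dict[str, SpikeTrain]
    synapses: list[Synapse]
    neurons: dict[str, tuple[SteinParams, SteinState]] = field(default_factory=dict)

    def __post_init__(self):
        endpoints = set(self.sources) | set(self.neurons)
        for syn in self.synapses:
            if syn.pre not in endpoints or syn.post not in endpoints:
                raise ValueError(f"synapse {syn.name} references unknown endpoints")


@dataclass
class Trace:
    """Sampled weight series and emitted/scheduled spikes of a run."""

    times: np.ndarray
    weights: dict[str, np.ndarray]
    spikes: dict[str, np.ndarray]


def run(network: Network, duration: float, sample_dt: float = 0.5) -> Trace:
    """Process all source spikes in time order; sample weights every ``sample_dt``."""
    if not (duration > 0):
        raise ValueError("duration must be positive")
    if not (sample_dt > 0):
        raise ValueError("sample_dt must be positive")

    src_names = sorted(network.sources)
    all_t, all_src = [], []
    for i, name in enumerate(src_names):
        times = network.sources[name].times
        keep = times[times <= duration]
        all_t.append(keep)
        all_src.append(np.full(keep.size, i, dtype=int))
    if all_t:
        t_arr = np.concatenate(all_t)
        s_arr = np.concatenate(all_src)
        order = np.lexsort((s_arr, t_arr))  # time-major, then source id
        t_arr, s_arr = t_arr[order], s_arr[order]
        if t_arr.size > 1 and (np.diff(t_arr) < 0).any():
            raise RuntimeError("internal event queue lost time order")
    else:
        t_arr = np.empty(0)
        s_arr = np.empty(0, dtype=int)

    efferent = {name: [] for name in src_names}
    afferent: dict[str, list[Synapse]] = {}
    for syn in sorted(network.synapses, key=lambda s: s.name):
        if syn.pre in efferent:
            efferent[syn.pre].append(syn)
        afferent.setdefault(syn.post, []).append(syn)

    sample_times = np.arange(0.0, duration + 0.5 * sample_dt, sample_dt)
    weights = {syn.name: np.empty(sample_times.size) for syn in network.synapses}
    emitted: dict[str, list[float]] = {name: [] for name in network.neurons}
    next_sample = 0

    def record_until(t: float):
        nonlocal next_sample
        while next_sample < sample_times.size and sample_times[next_sample] <= t:
            for syn in network.synapses:
                weights[syn.name][next_sample] = syn.state.w
            next_sample += 1

    def fire(neuron_name: str, t: float, trigger: Synapse | None):
        # a spike emitted in response to a pre event is causal (Delta-t -> 0+)
        # for the synapse that delivered that event
        emitted[neuron_name].append(t)
        for syn in afferent.get(neuron_name, []):
            if syn.plastic:
                on_post_spike(syn.state, syn.params, t, causal=syn is trigger)

    for t, si in zip(t_arr, s_arr):
        record_until(t - 1e-15)
        src = src_names[si]
        # presynaptic role: transmission, then membrane update per synapse
        for syn in efferent[src]:
            if syn.plastic:
                _, w = on_pre_spike(syn.state, syn.params, t)
            else:
                w = syn.state.w
            tgt = network.neurons.get(syn.post)
            if tgt is not None:
                n_params, n_state = tgt
                n_state.u_m_mv = n_params.reset_mv + (
                    n_state.u_m_mv - n_params.reset_mv
                ) * math.exp(-(t - n_state.t) / n_params.tau_m_s)
                n_state.t = t
                n_state.u_m_mv += n_params.alpha * w * 1000.0
                if n_state.u_m_mv >= n_params.threshold_mv:
                    n_state.u_m_mv = n_params.reset_mv
                    fire(syn.post, t, syn)
        # postsynaptic role of a scheduled source: afferent plasticity
        if src not in network.neurons:
            for syn in afferent.get(src, []):
                if syn.plastic:
                    on_post_spike(syn.state, syn.params, t)

    record_until(duration)
    spikes = {name: np.array(ts) for name, ts in emitted.items()}
    for name in src_names:
        spikes[name] = network.sources[name].times
    return Trace(times=sample_times, weights=weights, spikes=spikes)


def _plastic_synapse(name, pre, post, params, w0=None) -> Synapse:
    state = make_state(params)
    if w0 is not None:
        set_weight(state, params, w0)
    return Synapse(name=name, pre=pre, post=post, params=params, state=state)


def protocol_bidirectional_pairing(
    dt_pair_s: float = 0.001,
    period_s: float = 0.050,
    duration: float = 100.0,
    params: SynapseParams | None = None,
    sample_dt: float = 0.5,
) -> Trace:
    """Two bidirectionally coupled neurons firing correlated pairs.

    N1 leads N2 by ``dt_pair_s`` every ``period_s``; both synapses are
    plastic from the resting weight.  Firing is imposed (scheduled), as in
    the deterministic pairing experiment.
    """
    if not (0 < dt_pair_s < period_s):
        raise ValueError("need 0 < dt_pair < period")
    params = params or SynapseParams()
    t1 = np.arange(0.0, duration, period_s)
    t2 = t1 + dt_pair_s
    net = Network(
        sources={
            "N1": SpikeTrain(times=t1, source_id="N1"),
            "N2": SpikeTrain(times=t2[t2 < duration], source_id="N2"),
        },
        synapses=[
            _plastic_synapse("w12", "N1", "N2", params),
            _plastic_synapse("w21", "N2", "N1", params),
        ],
    )
    return run(net, duration, sample_dt)


def _two_afferent_network(
    trains: list[SpikeTrain],
    params: SynapseParams,
    stein: SteinParams,
    w_init: tuple[float, float] | None,
    extra_sources: dict[str, SpikeTrain] | None = None,
    extra_synapses: list[Synapse] | None = None,
) -> Network:
    sources = {"N1": trains[0], "N2": trains[1]}
    if extra_sources:
        sources.update(extra_sources)
    synapses = [
        _plastic_synapse("w1", "N1", "N3", params, w_init and w_init[0]),
        _plastic_synapse("w2", "N2", "N3", params, w_init and w_init[1]),
    ]
    if extra_synapses:
        synapses.extend(extra_synapses)
    return Network(
        sources=sources,
        synapses=synapses,
        neurons={"N3": (stein, SteinState())},
    )


def protocol_unsupervised(
    rates_hz: tuple[float, float] = (5.0, 5.0),
    duration: float = 150.0,
    seed: int | np.random.SeedSequence = 0,
    params: SynapseParams | None = None,
    stein: SteinParams | None = None,
    w_init: tuple[float, float] | None = None,
    sample_dt: float = 0.5,
) -> Trace:
    """Two independent Poisson afferents competing on one Stein neuron."""
    if min(rates_hz) <= 0:
        raise ValueError("rates must be positive")
    params = params or SynapseParams()
    stein = stein or SteinParams()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seeds = ss.spawn(2)
    trains = [
        poisson_train(rates_hz[i], duration, seeds[i], source_id=f"N{i + 1}")
        for i in range(2)
    ]
    net = _two_afferent_network(trains, params, stein, w_init)
    return run(net, duration, sample_dt)


def protocol_alternating(
    rate_hz: float = 20.0,
    bin_width_s: float = 0.2,
    duration: float = 150.0,
    seed: int | np.random.SeedSequence = 0,
    params: SynapseParams | None = None,
    stein: SteinParams | None = None,
    w_init: tuple[float, float] | None = None,
    sample_dt: float = 0.5,
) -> Trace:
    """Bin-alternating drive: one afferent active at 20 Hz per 200 ms bin."""
    params = params or SynapseParams()
    stein = stein or SteinParams()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    trains, _ = alternating_trains_with_bins(rate_hz, bin_width_s, duration, 2, ss)
    net = _two_afferent_network(trains, params, stein, w_init)
    return run(net, duration, sample_dt)


def protocol_supervised(
    rate_hz: float = 20.0,
    bin_width_s: float = 0.2,
    sup_rate_hz: float = 80.0,
    sup_weight: float = 0.050,
    synced_source: str = "N1",
    duration: float = 150.0,
    seed: int | np.random.SeedSequence = 0,
    params: SynapseParams | None = None,
    stein: SteinParams | None = None,
    w_init: tuple[float, float] | None = None,
    sample_dt: float = 0.5,
    sync_mode: str = "spike",
    sup_lag_s: float = 0.001,
) -> Trace:
    """Alternating drive plus a fixed-weight bias (teacher) neuron synced to
    one afferent.

    The bias neuron N_sup holds a non-plastic synapse of ``sup_weight`` onto
    N3.  Two readings of "in sync" are available:

    * ``sync_mode="spike"`` (default): N_sup echoes every spike of the
      synced afferent with a short teacher lag (``sup_lag_s``) and adds an
      independent Poisson train during the synced bins so its in-bin rate
      reaches ``sup_rate_hz``.  The paired arrival boosts the membrane
      exactly when the synced input fires, steering causal credit to it.
    * ``sync_mode="bin"``: N_sup fires a plain Poisson train at
      ``sup_rate_hz`` during the synced afferent's active bins only.
    """
    if synced_source not in ("N1", "N2"):
        raise ValueError("synced_source must be 'N1' or 'N2'")
    if sync_mode not in ("spike", "bin"):
        raise ValueError("sync_mode must be 'spike' or 'bin'")
    params = params or SynapseParams()
    stein = stein or SteinParams()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    bins_ss, sup_ss = ss.spawn(2)
    trains, active = alternating_trains_with_bins(
        rate_hz, bin_width_s, duration, 2, bins_ss
    )
    synced_idx = 0 if synced_source == "N1" else 1
    extra_rate = sup_rate_hz - rate_hz if sync_mode == "spike" else sup_rate_hz
    full_sup = poisson_train(max(0.0, extra_rate), duration, sup_ss, source_id="Nsup")
    keep = full_sup.times
    if keep.size:
        bin_of = np.minimum((keep / bin_width_s).astype(int), active.size - 1)
        keep = keep[active[bin_of] == synced_idx]
    if sync_mode == "spike":
        echoed = trains[synced_idx].times + sup_lag_s
        keep = np.unique(np.concatenate([echoed, keep]))
        keep = keep[keep < duration]
    sup_train = SpikeTrain(times=keep, source_id="Nsup")

    sup_state = SynapseState(w=sup_weight, m=0.0)
    sup_syn = Synapse(
        name="wsup", pre="Nsup", post="N3", params=params, state=sup_state,
        plastic=False,
    )
    net = _two_afferent_network(
        trains, params, stein, w_init,
        extra_sources={"Nsup": sup_train},
        extra_synapses=[sup_syn],
    )
    return run(net, duration, sample_dt)
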