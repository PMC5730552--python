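# fgstdp — behavioral simulator of a floating-gate STDP synaptic circuit

`fgstdp` models an analog CMOS synapse in which both the spike traces and
the synaptic weight live as charge on floating gates (FGs) that leak
through thin tunnel junctions. It is written for neuromorphic-circuit and
computational-neuroscience researchers who want to study the *behavior* of
such a synapse — plasticity windows, weight dependence, synaptic
competition, device scaling and mismatch — without transistor-level (SPICE)
simulation.

## The model

**Pair-based, weight-dependent STDP.** The weight change for one pre/post
spike pair at timing difference Δt = t_post − t_pre follows

    Δw(Δt) =  A₊ exp(−Δt/τ₊)   if Δt > 0   (LTP)
             −A₋ exp(+Δt/τ₋)   if Δt < 0   (LTD)
              0                 if Δt = 0

with τ₊ ≈ 16.8 ms and τ₋ ≈ 76.5 ms emerging from the circuit dynamics
rather than being imposed: each spike kicks its FG integrator by ~180 mV
(pre) / ~135 mV (post); the counter-spike samples the decayed trace through
an amplifying readout, and only samples beyond the junction injection
thresholds (0.35 V / 0.33 V) move charge onto the storage gate. Injection
is self-limiting (detailed balance) and the storage voltage maps to the
weight through a saturating transfer characteristic bounded in (0, 0.5 V),
which together produce soft-bounded, weight-dependent STDP.

**Stein point neuron.** The postsynaptic membrane obeys
τ_m du_m/dt = −u_m + α Σᵢⱼ V_wⁱ δ(t − tⱼⁱ) with τ_m = 10 ms, α = 0.3 and a
90 mV firing threshold; simulation is exactly event-driven (closed-form
decay between events).

**Device physics.** FG leakage follows a Simmons/WKB direct-tunneling law
I = A·g₀·V·exp(−2κ t_tun), calibrated so a 1.3 nm barrier with 2 fF gives a
0.5 s half-peak relaxation time; the storage stack is calibrated into the
70–100 s retention band. Mismatch uses the Pelgrom relation
σ_Vt = A_RDF/√(LW) and the line-edge-roughness law σ_L = A_LER/√W.

## Worked example

```python
import numpy as np
from fgstdp import SynapseParams, stdp_curve, fit_stdp, protocol_unsupervised

params = SynapseParams()                      # calibrated nominal circuit
dts = np.concatenate([-np.arange(1, 401, 3)[::-1], np.arange(1, 401, 3)])
fit = fit_stdp(stdp_curve(params, dts.tolist(), v_w0=0.151))
print(f"tau+ = {fit.tau_plus_ms:.1f} ms, tau- = {fit.tau_minus_ms:.1f} ms")

trace = protocol_unsupervised(rates_hz=(5.0, 5.0), duration=150.0, seed=0)
print(f"w1 = {trace.weights['w1'][-1]:.3f} V, w2 = {trace.weights['w2'][-1]:.3f} V")
```

prints

```
tau+ = 16.8 ms, tau- = 76.5 ms
w1 = 0.387 V, w2 = 0.044 V
```

The fitted windows are the LTP/LTD time constants of the synapse's pair
rule. The competition run shows the two 5 Hz Poisson afferents
bifurcating: one synapse wins (≈0.39 V, enough for its spikes to fire the
neuron single-handedly) while the other is depressed toward zero — which
of the two wins is a fair coin flip across seeds.

The same experiments are available from the shell:

```sh
fgstdp stdp-curve --out curve.csv && fgstdp fit --curve curve.csv
fgstdp compete --duration 150 --seed 0 --out trace.csv
fgstdp dev sweep --t-tun 1.0:1.6:7 --c-fg 1,2,5,10 --out sweep.csv
fgstdp mc --n 200 --experiment stdp --out mc/
```

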