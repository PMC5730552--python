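# Methods

## Scope and level of abstraction

`fgstdp` is a *behavioral* simulator: it reproduces the input/output
behavior of a floating-gate (FG) synaptic circuit — spike-triggered state
variables, thresholded charge injection onto a storage gate, a saturating
voltage-transfer characteristic (VTC), and FG leakage — without solving
transistor equations. Spikes are instantaneous events; the physical pulse
(0.5 V, 30 µs) is absorbed into the per-spike FG jumps and the injection
gains, which is safe because the pulse width is orders of magnitude below
every plasticity time scale. Bias voltages internal to the circuit do not
appear; the control voltage that sets the resting weight is collapsed into
the resting storage level `m_rest`.

## Synapse model

State per synapse: two integrator voltages `v_fg_pre`, `v_fg_post`
(magnitudes, exponentially relaxing with `tau_pre_s`, `tau_post_s`), a
storage level `m`, and the cached weight `w = transfer(m)`.

Event rules (nearest-spike pairing by default — each spike resets its own
integrator, so only the most recent counter-spike matters):

* presynaptic spike at t: relax both integrators to t; sample
  `s_post = gain_post * v_fg_post`; set `v_fg_pre = dv_pre`; if
  `s_post > theta_post`, inject
  `dm = +c_minus (s_post − theta_post) exp(−(m − m_rest)/lambda_minus)`
  (LTD: m rises, w falls); transmit the post-update weight.
* postsynaptic spike at t: mirror image with `gain_pre`, `theta_pre` and
  `dm = −c_plus (|s_pre| − theta_pre) exp(+(m − m_rest)/lambda_plus)`
  (LTP: electron injection, m falls, w rises).
* `transfer(m) = vmax / (1 + exp((m − vtc_mid)/vtc_slope))`, a decreasing
  logistic bounded in (0, 0.5 V). LTP injects electrons so the storage
  node goes more negative as the weight grows; the polarity is an internal
  convention invisible at the weight level.

The sampling gains deserve a note: the raw FG jumps (180/135 mV) lie below
the injection thresholds (0.33/0.35 V), so without the amplifying readout
stage that the physical sampling subcircuits implement, no plasticity could
ever occur. The gains are therefore explicit behavioral parameters,
calibrated jointly with the leak time constants (below).

**Timestamp ties.** A pre and post spike at the identical timestamp is the
Δt = 0 branch of the pair rule: no plasticity (`stdp_curve` returns 0
there by convention). One exception is load-bearing: a postsynaptic spike
*emitted in response to* a presynaptic event occurs at that event's
timestamp in an event-driven scheme, yet it is causally *after* the input.
Such spikes are processed as the Δt → 0⁺ limit (full LTP for the driving
synapse). Without this, the reinforcement loop that underlies synaptic
competition — "my spike made the neuron fire, so strengthen me" — is
structurally absent and no protocol bifurcates.

## Neuron model and network engine

The Stein neuron decays in closed form between events and jumps by
`alpha * V_w` per input spike (alpha = 0.3, threshold 90 mV, reset 0, no
refractory period). Postsynaptic spikes can only occur at input-event
instants, so the whole network is simulated exactly, event by event, with
no time-stepping error. Simultaneous presynaptic events are processed in
ascending source order with the threshold checked after each increment.
Sampling for traces is passive and cannot perturb the dynamics.

A consequence worth keeping in mind: with a 151 mV resting weight an EPSP
is 45.3 mV, so the neuron initially fires only on near-coincident spike
clusters (sub-millisecond pairs, or 2–3 spikes within a few ms). Early
network activity is therefore sparse and fluctuation-driven, and the
competition protocols progress through rare discrete reinforcement events
until a weight passes 0.3 V (300 mV × α = 90 mV), after which that
afferent drives the neuron on every spike.

## Device model

Leakage through a tunnel junction uses a one-carrier Simmons/WKB form,

    I(V) = area * g0 * V * exp(−2 κ t_tun),   κ = sqrt(2 m* m_e q φ)/ħ,

with φ = 3.1 eV (SiO₂) and m* = 0.4 when under-determined, and barrier
lowering ignored. The law is linear in V, so FG relaxation is a pure
exponential with τ = C_FG/G and the retention time is independent of the
programmed level (a mild level dependence seen in circuit-level studies is
deliberately not reproduced). The free prefactor g₀ is set by
`calibrate_leak`:

* integrator junction: anchored at τ_relax(1.3 nm, 2 fF) = 0.5 s
  (half-peak definition), giving g₀ ≈ 1.065 × 10⁶ S/m² for the
  60 × 120 nm junction;
* storage stack (TJ2 ∥ TJ3, 1.75 nm, 30 fF): anchored at an 85 s retention
  time (10%-decline definition), the midpoint of the 70–100 s band.
  Propagating the integrator prefactor to the storage geometry would give
  ≈39 s, outside the band, so the storage junction carries its own
  calibrated prefactor — physically, the two stacks need not share a
  barrier quality factor.

Threshold-crossing times are found by bisection on a log-time grid between
1 µs and 10⁴ s at 10⁻³ relative tolerance (closed form in exponential
mode). The exponential thickness sensitivity reproduces the headline
scaling: +30% t_tun around 1.2 nm raises τ_relax ≈ 60×, while tenfold
C_FG raises it exactly 10×.

## Calibration of the default synapse

Anchors (all printed circuit-level quantities): fitted STDP windows
τ₊ = 16.8 ms and τ₋ = 76.5 ms; resting weight 151 mV; VTC output range
0–0.5 V; pairing saturation ≈0.27 V under 20 Hz bidirectional pairing at
Δt = 1 ms; injection thresholds 0.35/−0.33 V; FG jumps 180/135 mV.

Procedure, in order:

1. Structure: `vtc_slope = 0.1 V`, `vtc_mid = 0`; `m_rest` follows in
   closed form from the 151 mV resting weight. Sampling-gain prominences
   were set to `gain_pre·dv_pre = 5·theta_pre` and
   `gain_post·dv_post = 2·theta_post`; these fix the LTP/LTD window
   *cutoffs* (a thresholded exponential vanishes beyond τ·ln(G/θ)).
2. `tau_pre_s` and `tau_post_s` are root-found so that least-squares fits
   of the exponential pair rule to the simulated single-pair curve return
   exactly 16.8 and 76.5 ms.
3. `c_minus/c_plus` is root-found so the potentiated synapse in the
   bidirectional 20 Hz pairing protocol plateaus at 0.270 V — the plateau
   is the balance between LTP at +1 ms and the cross-pair LTD at −49 ms
   that the wide LTD window makes significant.
4. The remaining two degrees of freedom — the detailed-balance scales
   (λ± = 0.35 V) and the absolute injection scale (c₊ = 0.0132 V) — set
   how strongly the soft bounds pinch the dynamics and how large each
   discrete weight kick is. They were selected, before freezing, so that
   the unsupervised 5 Hz competition both escapes the joint-growth
   equilibrium within 150 s and drains the losing synapse below 50 mV
   (≈94% of seeded runs), while the pairing plateau and window fits above
   are unaffected (they are re-converged after every choice). Only the
   ratio slope·(1/λ₊ + 1/λ₋) matters here; the m-axis scale is otherwise
   arbitrary.

Steps 2–3 form a fixed point that converges in two iterations; the
resulting constants are frozen as the `SynapseParams` defaults and are
recoverable by rerunning the procedure.

One knock-on effect of the chosen prominence: the LTP window terminates at
τ_pre·ln 5 ≈ 46 ms, so a single pair at Δt = +50 ms produces exactly zero
change (the LTD side, with its 170 ms cutoff, is still active there). The
sign structure Δw·Δt > 0 holds for 1–45 ms.

## Competition protocols

* **Bidirectional pairing** (deterministic): two scheduled neurons fire
  1 ms-offset pairs every 50 ms; the causal synapse saturates at 0.27 V,
  the anti-causal one is driven to zero.
* **Unsupervised** (5 Hz Poisson × 2 → Stein neuron, 150 s): joint growth
  by shared near-coincidence reinforcement, then winner-take-all once one
  weight can fire the neuron alone. The winner is a fair coin flip; the
  loser is depressed by the (LTD-window-dominated) uncorrelated pre/post
  statistics.
* **Alternating** (20 Hz in 200 ms bins, one source per bin): both weights
  drift up early; separation develops but more slowly than in the
  unsupervised case — full bifurcation within 150 s occurs in only a
  minority of runs, a known gap relative to the crisper circuit-level
  behavior.
* **Supervised**: a bias (teacher) neuron with a fixed 50 mV synapse fires
  in sync with one afferent. Default synchrony is spike-locked: N_sup
  echoes each synced spike 1 ms later and adds independent Poisson spikes
  (up to 80 Hz) during the synced bins. The paired arrival lifts the
  membrane exactly when the synced afferent transmits, multiplying that
  afferent's chance of driving the neuron; the synced synapse wins in
  ≈97–98% of seeded 150 s runs, mirrored for either choice. A bin-level
  Poisson reading of "in sync" (`sync_mode="bin"`) is also provided; it
  biases the outcome in the same direction but saturates near 88–92%
  because a rate-only bias shifts the sparse escape race much more weakly.

## Phase plane

The drift field (dVw1/dt, dVw2/dt) is estimated per grid node by
programming the weights (`set_weight`, bisection on the VTC), running the
protocol for a 2 s horizon, and averaging over replicates with independent
seed substreams (default 15 × 15 interior nodes over [0.02, 0.48 V]²,
10 replicates — replicates are added on top of the single-evaluation
original to obtain standard errors). Trajectory overlay interpolates the
field bilinearly and reports the mean angle between trajectory
displacements and the local field, excluding segments outside the hull or
where the field is within 3 standard errors of zero.

## Variability

Pelgrom RDF (σ_Vt = A_RDF/√(LW), A_RDF = 1.27 × 10⁻⁹ V·m) and LER
(σ_L = A_LER/√W, A_LER = 1.04 × 10⁻¹² m^{3/2}) act on a per-device
geometry table (integrator junctions 60 × 120 nm, storage TJs 60 × 120 and
120 × 240 nm, readout 90 × 1400 nm). The device→behavior map is first
order and transparent: an integrator device's Vt deviation scales its FG
jump and sampling threshold by 1%/mV; its length deviation scales the leak
time constant proportionally; storage-stack Vt deviations shift `m_rest`
volt-for-volt, spreading the initial weight (≈15 mV s.d., normal by
construction and confirmed by Shapiro–Wilk at α = 0.01, n = 200).
Realizations violating parameter invariants are rejected and resampled.
The 200-circuit STDP ensemble preserves the LTP/LTD sign structure in
well over 90% of circuits; the supervised ensemble (bias synced to N2)
shifts the terminal weight distribution significantly toward V_w2.

## What the synthetic stimuli do and do not emulate

All stimuli are generated internally: deterministic pair schedules,
homogeneous Poisson trains (i.i.d. exponential inter-spike intervals), and
binned alternating drives. Real presynaptic populations have refractory
structure, rate nonstationarity and cross-correlations that these renewal
processes lack, so passing competition statistics here demonstrates the
circuit-level mechanism, not robustness to naturalistic input. Problem
sizes used throughout (150 s competition runs, 100-seed ensembles,
200-circuit Monte Carlo) were chosen as the smallest that give stable
statistics for the reported fractions.

## Numerical choices and degenerate inputs

Times are in seconds, voltages in volts, capacitances in farads
internally; configs accept ms/mV/fF. Exponential decays are evaluated in
closed form everywhere (no integration error); `set_weight` inverts the
VTC by bisection to 10⁻¹² V; the VTC underflows to exactly 0 beyond
m − vtc_mid > 700·slope to avoid overflow. Degenerate inputs raise typed
errors: negative durations, unsorted events, out-of-range weights
(0 and 0.5 V are unreachable poles), leak models with no decay
(non-convergence carries the search horizon), inconsistent calibration
anchors (the error lists residuals).

## Known limitations

* Power consumption, temperature dependence, dielectric-breakdown margins
  and exact transient voltage shapes are circuit-level quantities outside
  the model.
* The linear tunneling law makes retention independent of the programmed
  level; only the band, not the level dependence, is reproduced.
* Alternating-drive bifurcation is slower than its circuit-level
  counterpart (see above).
* Behavioral mismatch propagation is first-order; correlated
  (layout-dependent) mismatch is not modeled.
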