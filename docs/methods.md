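# Methods

## The model

`hbih` implements a conductance-based model of a bursting neuron of the
Huber–Braun family, extended with a hyperpolarization-activated cation
current (HCN-like, "I_h").  The membrane equation balances six current
densities (µA/cm²):

    C_m dV/dt = −I_d − I_r − I_sd − I_sr − I_h − I_l

* **I_d, I_r** — fast depolarizing (Na_V-like) and repolarizing
  (K_dr-like) spike currents.  The fast activation a_d is instantaneous
  (algebraic, no time constant exists for it in the model), evaluated from
  its Boltzmann curve inside the right-hand side; a_r relaxes with
  τ_r = 2 ms.
* **I_sd** — slow persistent depolarizing current (Na_P/Ca_T-like),
  gate a_sd, τ_sd = 10 ms.
* **I_sr** — slow repolarizing, calcium-activated potassium-like current.
  Its "gate" a_sr tracks intracellular calcium: it integrates the inward
  I_sd (coupling η = 0.014 cm²/µA) against first-order removal
  (κ = 0.18), with τ_sr = 35 ms.  The conductance depends on a_sr through
  a saturable binding term a_sr²/(a_sr² + K_sr) with K_sr = 0.4² = 0.16,
  which keeps g_sr a true maximal conductance when a_sr is driven high.
* **I_h** — hyperpolarization-activated current, gate a_h with negative
  activation slope (s_h = −0.14 mV⁻¹, half-activation −85 mV),
  τ_h = 125 ms, reversal −30 mV.
* **I_l** — ohmic leak (E_l = −80 mV), temperature-scaled like every
  other current.

Temperature enters through ρ(T) = 1.3^((T−25)/10) on all conductances and
φ(T) = 3^((T−25)/10) on all gating kinetics.  All defaults live in
`ModelParameters`; they serialize to/from JSON with exactly the field
names above and unknown keys rejected.

The **slow subsystem** sets g_d = g_r = 0 and clamps a_r ≡ 0, leaving the
4-dimensional (V, a_sd, a_sr, a_h) oscillator that carries the model's
slow subthreshold rhythm — and, for some parameters, its chaos.

## Integration protocol

Classic fixed-step RK4.  The default step is **dt = 0.025 ms**, chosen to
resolve the fastest gate (τ_r = 2 ms, shortened ~3.3× by φ at 36 °C); an
order-4 convergence test against the leak-current closed form and a
step-halving check on the firing rate (< 1 % change at 36 °C) back the
choice.  Slow-subsystem analyses use dt = 0.05 ms (the stiffest remaining
time constant is τ_sd = 10 ms).  No adaptive stepping: fixed steps keep
Lyapunov renormalization and sweep results exactly reproducible.

Long runs discard a 30 s equilibration segment, then record the
production segment.  States are stored on a strided grid (0.1 ms by
default) to bound memory, but **threshold crossings are detected on the
full-resolution stream inside the compiled loop**, with linear
interpolation between steps, so spike/return-interval statistics are
independent of the recording stride.

Initial conditions (never stated for this model family) are
deterministic: V = −60 mV, gates on their steady-state curves, a_sr on
its nullcline −η·I_sd/κ.  In periodic regimes the 30 s equilibration
erases this choice (tested); in chaotic regimes only distributional
quantities (spike counts, exponents) are meaningful, and they are
ergodic averages over ≥ 150 s.

## Spike detection and firing patterns

A spike is an upward crossing of −15 mV.  Patterns are summarized by an
integer code (0 no oscillation, 1 subthreshold oscillation, 2
skipping/polymodal, 3 regular tonic, 4 bursting, 5 tonic 20–50 spikes/s,
6 > 50 spikes/s).  The published definitions are visual; the decision
tree here is:

1. fewer than 5 spikes → code 0 if the last 10 s of V are flat
   (peak-to-peak < 2 mV), else code 1;
2. rate > 50 → 6; rate ∈ (20, 50] → 5;
3. ISI coefficient of variation < 0.05 → 3 (tonic);
4. otherwise split ISIs at the geometric mean of the extreme ISIs; call
   runs of short intervals "bursts".  Code 4 requires ≥ 2 bursts, median
   intra-burst ISI < 100 ms, a modal spikes-per-burst ≥ 2, and ≥ 90 % of
   bursts within ±1 spike of the mode; anything else irregular → 2.

The < 100 ms intra-burst bound is what separates true bursts (few-ms to
tens-of-ms doublets/triplets riding one slow-wave crest) from skipping,
whose shortest interval is a full slow-wave period (≳ 150 ms at 36 °C).

## Chaos measures

**Trajectory MLE** (`mle_ode`): two-trajectory Benettin/Sprott
renormalization.  A companion trajectory starts offset by d0 = 10⁻⁶ in a
scaled metric (voltage measured in units of 100 mV, gates in units of 1)
along a seeded random unit direction; every 1 ms the log distance ratio
is accumulated and the companion is rescaled to d0.  The exponent is the
mean log ratio per ms after discarding the first 10 % of intervals
(alignment with the most expanding direction).  Default accumulation
200 s.  Validation: exact on linear systems (|error| < 10⁻³ for
λ ∈ {−1, −0.1, 0.1}/ms) and agreement within ±0.02 with an independent
tangent-linear (Jacobian-propagation) oracle on the Lorenz system, whose
exponent ≈ 0.906 is reproduced.  A `saturated` flag marks runs whose
separation persistently reaches attractor size (renormalization too
infrequent for the expansion rate).

**Interval-series Lyapunov exponent** (`isi_lyapunov`): delay-1 Takens
reconstruction of the ISI (or return-interval) series at dimensions
m = 7, 9, 11.  For each reference point the k nearest neighbors
(k = max(1, ⌊0.0005 · n⌋), Theiler window of m samples) are followed
r = 6 steps forward; the slope of log⟨d_i⟩ vs. i (OLS over the 7 points)
is kept when its two-sided p-value < 0.05; the exponent is the mean of
the significant slopes, and 0 with `significant=False` otherwise.  Units:
per interval step.

Two numerical choices matter here:

* *Noise floor.*  A periodic orbit sampled at finite precision yields a
  degenerate point cloud whose spread is round-off (measured ~10⁻⁹ of
  the interval scale, versus ~10⁻² for chaotic series).  OLS on that
  noise returns "significant" slopes of ±10⁻⁴.  A reconstruction whose
  mean neighbor distance is below 10⁻⁶ of the median interval is
  therefore declared degenerate (non-significant) — the k-NN analogue of
  a radius-based vicinity cap being unsatisfiable on a degenerate cloud.
* *Validation dimensions.*  The logistic-map surrogate (exponent ln 2 per
  step) is validated at m = 3, 4, 5: with m = 7–11 and r = 6 a map this
  expansive saturates the reconstruction's dynamic range within the
  advance window (the neighbor distance already carries the 2^(m−1)
  amplification of the trailing coordinate), biasing the slope low.  The
  model's interval series (exponents ~0.1–0.3 per step) are well inside
  the regime where the production dimensions are appropriate.

**Lempel-Ziv complexity** (`lempel_ziv`): Kaspar–Schuster production-step
count c(n) of the binarized spike train (bin width = half the minimum
ISI, so no bin holds two spikes), normalized by n/log₂n.  Identities
c = 2 for a constant word and c = 3 for an alternating word are tested by
hand-trace; seeded random words normalize to 1.0 ± 0.1.

## Slow-subsystem analysis

At an equilibrium every gate sits on its Boltzmann curve and a_sr on its
nullcline, so equilibria reduce to a scalar current balance in V, scanned
at 0.01 mV over [−90, 20] mV and polished by Brent's method (residual
norm < 10⁻⁹).  Stability comes from the eigenvalues of a central-
finite-difference Jacobian (relative step 10⁻⁶) of the 4-dimensional
field — numeric, so the model definition stays single-sourced.

`equilibrium_branch` recomputes all equilibria across a parameter grid
and marks a Hopf bifurcation where a complex pair's real part changes
sign and a limit point where the number of equilibria changes, each
refined by bisection to 10⁻⁵ in the parameter.  Continuation of periodic
orbits (Floquet analysis) is deliberately out of scope; the
period-doubling route is localized *empirically* instead, through return
intervals.

Return intervals are the times between successive upward crossings of
V_eq, the voltage of the unstable-focus equilibrium at the same
parameter point.  `count_distinct_intervals` clusters the values by 1-D
single linkage (split where the sorted gap exceeds 2 % of the median);
counts above 32 are reported as a "many" sentinel.  A period-doubling
cascade appears as the count going 1 → 2 → 4 …; note that a *single*
orbit can legitimately contribute 2 or 3 distinct values when its
waveform crosses V_eq more than once per cycle (this happens for
g_sd ≳ 0.25 at g_h = 0.4), so counts index doublings only relative to
the current crossing multiplicity.

Parameter points whose attractor equilibrium is *stable* are reported as
non-oscillating without simulation: near the Hopf point transients decay
on the 1/|Re λ| scale (thousands of seconds), no practical equilibration
removes them, and a decaying spiral would otherwise masquerade as an
oscillation with a drifting (spuriously "chaotic") interval series.
Return intervals are a property of the attractor, which for a stable
focus is the equilibrium itself.

## Sweeps

Every grid point is simulated independently from the deterministic
default initial state — no state carry-over, so diagrams cannot depend on
sweep direction.  Per-point seeds (used only by the MLE perturbation
direction) derive from the grid seed and the point's integer coordinates,
making tables bit-identical across worker counts and orderings.  Failed
points are recorded with a status string, never fatal.

## Reference protocol sizes

The headline quantities (`hbih.reproduce`, also run by
`scripts/acceptance.py`) use:

* spike count: full model, T = 36.3 °C, 1000 s after 30 s equilibration;
* τ_h cutoff: 100→300 ms in 10 ms steps, 300 s per point, largest τ_h
  with a significant positive interval-series exponent;
* slow-subsystem doubling extent: g_sd 0.15→0.40 in 0.0025 steps at
  g_h = 0.4, 200 s per oscillating point, largest g_sd with > 1 distinct
  return interval;
* first ISI doubling: full model at g_h = 0.2, g_sd 0.216→0.220 in 10⁻⁴
  steps, 150 s per point, smallest g_sd past the single-ISI region with
  2 distinct ISI values.

These spans are the package's reference study conditions: long enough
that counts and exponents are stable ergodic summaries (doubling the
spans moves the headline numbers well under their quoted tolerances),
small enough to run on a laptop core in minutes.

## What the surrogates do and do not show

The surrogate generators (`hbih.surrogates`) exercise the estimators on
series with *known* exponents: constant/periodic series (degenerate,
must come back non-significant), logistic-map series (ln 2 per step),
and linear/Lorenz flows.  Passing these validates the estimators'
numerics, not their behavior on experimental data: real spike trains add
measurement jitter, nonstationarity and finite length, none of which the
surrogates model.  The noise floor above addresses round-off
degeneracy only; genuinely noisy periodic data may still require
surrogate-data testing, which is out of scope here.

## Known limitations

* Pattern classification near regime boundaries is inherently
  discontinuous; codes at transition points can flip with simulation
  length.
* The empirical doubling detector cannot see cascade rungs narrower than
  the parameter grid; the published cascades were resolved down to 10⁻⁵
  conductance steps, and the acceptance protocols use local fine scans
  only where a rung's location is asserted.
* The two-trajectory MLE reports only the *maximal* exponent; no
  spectrum, no Kaplan–Yorke dimension.
* Two-parameter bifurcation-curve continuation (PD/HB/LP curves in the
  (g_sd, g_h) plane) is out of scope; the eigenvalue-based HB/LP markers
  cover one-parameter branches only.
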