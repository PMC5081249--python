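# Methods

## The gating models

Both schemes treat the channel as four identical, independent S4 voltage
sensors coupled to one pore gate.

**10-state KV7.1 scheme.** States form a 5×2 grid: C0–C4 (closed) and O0–O4
(open), the column index counting activated sensors. Horizontal transitions
are single-sensor activation steps with binomial statistical factors (4, 3,
2, 1 forward; 1, 2, 3, 4 backward). Vertical transitions open the gate from
*any* column; an allosteric coupling factor `f ≥ 1` multiplies the opening
equilibrium once per activated sensor, and equivalently biases sensor
activation in the open row. Detailed balance around every elementary square
of the grid holds by construction: the open-row sensor equilibrium exceeds
the closed-row one by exactly `f`, matching the factor `f` gained by the
opening equilibrium per column. Because opening is possible with few sensors
active, the fluorescence and conductance curves of this scheme track each
other closely.

**6-state IKs (KV7.1+KCNE1) scheme.** A linear chain C0–C4 with one
concerted opening step C4 ↔ O. Opening requires all four sensors, which
separates the fluorescence (sensor-driven, far left) from the conductance
(opening-driven, far right) along the voltage axis — the defining phenotype
of the KCNE1-containing channel.

**Rate laws.** Every transition direction follows
`k(V) = multiplicity · k0 · exp(z·(V − dV)·F/RT)` with a signed partial
charge `z` and an offset `dV`. This single-exponential (Eyring) form is the
standard parameterization for this channel family. Temperature enters
through RT/F (25.4 mV at the 295 K default); an optional Q10 factor rescales
all `k0` for warm-bath protocols (IKs gating Q10 is high, reported around
5–7.5, but no kinetic rescaling is applied unless requested).

**Fluorescence observable.** Each state emits
`n_activated · f1 (+ f2 if open)`. `f1` is the per-sensor increment behind
the main fluorescence component (F1); `f2` is the smaller increment that
accompanies opening (F2), with `f2 < 4·f1`. Current is
`I = Gmax · Po · (V − E_rev)` with equal unitary conductance for all open
states (no subconductance levels are modeled).

**Perturbations.** A mutation or drug effect is a transition-class-targeted
modification: adding `ΔV` to the `dV` of both directions of a class
translates that step's equilibrium along the voltage axis (the equilibrium
constant at `V` equals the unperturbed one at `V − ΔV`); separate forward /
backward rate scale factors express purely kinetic effects. Shifting *all*
classes translates every steady-state observable exactly, which the test
suite exploits as an equivariance invariant.

## Wild-type parameter values

The packaged parameter files are **synthetic calibrated stand-ins**, not
transcriptions of a published rate table. They were fitted once so that the
wild-type models reproduce the published behavior of this channel pair:

* 10-state: G(V) and F(V) midpoints near −25 mV and close together;
  activation completing within a 3 s test pulse;
* 6-state: main F(V) component near −100 mV with a shallow (~45 mV) apparent
  slope, G(V) near +25 mV with slope factor ~15–20 mV, ~1 s activation at
  +40 mV and ~1 s deactivation at −20 mV;
* the documented responses to transition-class shifts (+50 mV on the S4
  class: both 10-state curves +35–40 mV, 6-state G(V) ≈ +10 mV with the
  F1/F2 components merging; +140 mV on the opening class: G(V) ≈ +100 mV in
  both schemes, 10-state F(V) shifted less and shallower, 6-state F1/F2
  separation increasing).

Anyone with the original rate constants can drop them in through the same
JSON schema (`schema_version: 1`) and the whole toolbox applies unchanged.

## Numerics

The generator matrix uses the column convention `dp/dt = Q p` (columns sum
to zero), states ordered C0…C4 then O0…O4 / O. Within a constant-voltage
segment, occupancies propagate exactly by `expm(Q·Δt)` applied per sample
step; a stiff BDF ODE solve (rtol 1e−8) is an independent cross-check path,
and the two agree to better than 1e−6 on the full IKs VCF protocol. Sweep
families restart from the holding-voltage steady state except the 1 Hz
train, which chains sweeps (the accumulation is the point). Steady states
are computed as Boltzmann weights accumulated in log space along a spanning
tree of the (reversible) scheme graph — stable at voltages where the
generator is numerically singular — and validated against the generator's
null space and long-time propagation.

## Analysis conventions

* **Tail G(V):** current read 5 ms after tail onset (configurable;
  interpolation stays strictly inside the tail segment), one point per
  sweep, no leak subtraction. An optional averaging window (off by default)
  averages samples over `[delay, delay+window]`; its decay bias is uniform
  across sweeps of one curve and cancels after normalization.
* **Boltzmann fits:** `G = Gmax/(1 + exp((V50 − V)/s))` by least squares
  (lmfit); fits whose `V50 + 2s` exceeds the sampled range are flagged
  `approximation` (lower estimates). A shared-slope variant ties `s` across
  paired curves from one cell. The double-Boltzmann fit (baseline + two
  ordered components) seeds midpoints at the 25th/75th percentile crossing
  voltages of the normalized rise and retries from a fixed set of quantile
  seeds — deterministic, seed-free; collapsed components are flagged.
* **Energetics:** `z = 25/s` with the 25 mV constant fixed by convention
  (not recomputed from temperature); `ΔΔG0 = z·ΔV50·F` in kJ/mol. This
  two-state estimate systematically underestimates `z`; results carry that
  caveat.
* **Kinetics:** T50 metrics interpolate the half-amplitude crossing
  linearly; end-of-pulse / steady-state levels average the final 5 samples;
  an optional 5-sample median filter handles noisy traces (off for clean
  synthetic data). Exponential fits (1 or 2 components plus offset) order
  `τ_fast ≤ τ_slow` and flag vanishing components.
* **Statistics:** Dunnett via `scipy.stats.dunnett` with two-sided adjusted
  p-values against the control; Bonferroni pairs as two-sample t-tests with
  p×(number of pairs) capped at 1; paired time-constant ratios tested with a
  two-tailed one-sample t against 1. Two-sided p < 0.05 is the significance
  threshold; degenerate zero-variance inputs are flagged, not reported as
  significant.

## Synthetic recordings

The surrogate generator emulates two-electrode voltage-clamp and VCF
recordings: Gaussian current noise (default 0.05 µA, the order of a
500 Hz-filtered TEVC baseline), optional ohmic leak `g_leak·(V − E_leak)`,
Gaussian fluorescence noise with optional exponential photobleaching of the
baseline (default rate 0 — bleaching is only switched on to probe
robustness), lognormal cell-to-cell Gmax spread (σ = 0.25), and optional
per-cell global voltage jitter (2 mV SD in the population experiments).
Heterozygous expression is a two-population linear current mixture
`p·I_wt + (1−p)·I_mut`; random subunit co-assembly with intermediate
phenotypes is deliberately out of scope. One root seed spawns per-cell
child generators, so datasets are bit-stable.

What the generator does *not* emulate: capacitive transients and series
resistance, endogenous background conductances, fluorophore quenching
chemistry, inactivation, oocyte batch effects. Passing recovery tests
therefore demonstrate correctness of the analysis chain under the stated
noise structure, not robustness to every artifact of real recordings.

## Validation experiments and problem sizes

* The model-shift experiment simulates full sweep families (2 ms sampling)
  and fits curves exactly as recorded data would be.
* The recovery grid programs global shifts of −50…+50 mV, generates n = 8
  noisy cells per group (noise 0.1 µA ≈ 5% of the maximal tail amplitude,
  2 mV V50 jitter) against one shared wild-type reference batch, and uses an
  activation family extended to +140 mV so every shifted curve saturates
  inside the measured window; mean absolute recovery error across the grid
  is ~1 mV.
* Fit calibration uses 200 noisy Boltzmann repeats (σ = 2% of Gmax);
  statistical calibration uses 1000 simulated null batches each for the
  Dunnett family-wise error and the one-sample t-test.

## Known limitations

* The stand-in parameters reproduce the documented curve-level behavior,
  not any specific published current traces; fitted slope factors for the
  10-state scheme come out steeper than typical experimental G(V) slopes.
* Tail-current read-outs at a fixed tail voltage re-equilibrate slightly
  during the delay; for strongly left-shifted variants this produces the
  "hooked tail" artifact familiar from experiments. The short default delay
  keeps the effect small but nonzero.
* Fits to non-saturating curves are lower estimates and are flagged, never
  silently corrected.
* No inactivation states: the triple-pulse protocol is provided for its
  voltage-program definition only.
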