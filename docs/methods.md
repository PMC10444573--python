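# Methods

## The two models

**Full hybrid neuron.** A single-compartment Hodgkin–Huxley-style HN
interneuron with eleven currents: fast Na⁺ (m³h), injected and native
persistent Na⁺ (m), delayed-rectifier-like K⁺ (m²h), persistent K⁺ (m²),
fast transient K⁺ (m²h), hyperpolarization-activated inward (m²), fast and
slow Ca²⁺ (m²h each), an ohmic leak, and a Na⁺-activated pump current with
both an injected and a native component. Steady-state activations are
Boltzmann functions 1/(1+exp(A·(V+B))) — the offset convention is fixed by
the explicitly printed reduced-model formulas and by the canonical HN model
lineage, so half-activations sit at V = −B. Voltage-dependent time
constants use the sigmoidal form τ(V) = C + D/(1+exp(A·(V+B))) (the form of
the canonical HN models; only its (A, B, C, D) arguments are published for
each gate), except the fast-Na⁺ inactivation which has its own printed
expression with a cosh term. E_Na follows the Nernst relation
0.02526·ln([Na⁺]ₒ/[Na⁺]ᵢ) with fixed [Na⁺]ₒ; E_Ca is fixed (no Ca²⁺
concentration dynamics).

Intracellular Na⁺ bookkeeping counts the three Na⁺-carrying conductance
currents and three elementary charges per pump cycle for both pump
components; Na⁺ carried by the leak and h-currents is deliberately ignored,
mirroring the dynamic-clamp estimator that this simulator emulates.

**Reduced model.** Two state variables (V_m, [Na⁺]ᵢ) with all gating
instantaneous: native and injected persistent Na⁺, a fast-Na⁺ window
current (the model cannot spike — its voltage waveform is the burst
envelope), the h-current split 3/7 Na⁺ : 4/7 K⁺ by its −21 mV reversal,
persistent K⁺, split leak currents and the pump. In contrast to the full
model, the Na⁺ balance here includes *every* Na⁺-carrying term (native,
fast, h- and leak components), with only the pump flux tripled.

## Units and the flux constant vF

Volts, seconds, nS, nA (nS·V = nA), nF, molar. The constant vF converts
net Na⁺-carrying current into d[Na⁺]ᵢ/dt and equals cytosolic volume ×
Faraday constant expressed in nA·s/M. The published parameter tables print
this constant in reciprocal form (M per nA·s) while labeling it a volume in
nl: for the full model the printed 0.0024 equals 1/(4.4 pl × F) — the
reciprocal of the constant implied by the quoted ≈ 4.4 pl volume — so the
package uses vF = 1/0.0024 ≈ 416.7 nA·s/M for the full model and, reading
the reduced model's printed 0.0038 the same way, vF = 1/0.0038 ≈ 263.2
nA·s/M (≈ 2.7 pl). The reciprocal reading is validated by the oscillation
timescale: it reproduces the published simulated burst timings across the
whole pump sweep to ~1.5 %, whereas the face-value volume reading
(vF = 366.6) stretches every timing by a uniform 37 % while leaving all
scale-free geometry untouched.

C_m is not printed for the full model; the reduced model's 0.25 nF is used
and exposed as a parameter.

## Numerical integration

Default path: LSODA with rtol 1e-8, atol 1e-10 (V) / 1e-12 (gating,
concentration), dense output resampled to a uniform 5 kHz grid (the
acquisition rate of the hybrid experiments). Fast paths: fixed-step RK4
compiled with numba — step = the 0.2 ms sampling interval for the reduced
model (far below its ~5 ms membrane time constant) and 20 µs for the full
model (a fifth of the fastest gating time constant, 0.1 ms). The RK4 and
LSODA paths agree on burst timings to a fraction of a percent (tested);
halving solver tolerances moves timings by < 0.5 %.

Optional current noise (σ_noise, nA) emulating cycle-to-cycle biological
variability is zero-mean Gaussian held piecewise-constant over 1 ms bins,
drawn from a seeded generator; the default is noise-free, and noise-free
runs are bitwise reproducible.

Default initial states: full model V = −50 mV, [Na⁺]ᵢ = 10 mM, gating at
steady state; reduced model V = −55 mV, [Na⁺]ᵢ = 11 mM. The reduced model
settles within ~20 s. The full model's [Na⁺]ᵢ median equilibrates over
hundreds of seconds; protocol-style analyses therefore simulate 400–600 s
and analyze the final 150–200 s, during which successive windows agree to
~1–2 %.

The experimental protocol holds a −0.1 nA bias current on the impaled
neuron; full-model protocol runs use that preset (with I_app = 0 the
un-injected and weakly injected model spikes tonically — the behavior
described for sharp-electrode recordings).

## Burst quantification

Spikes are voltage peaks with topographic prominence ≥ 20 mV (prominence is
robust to the slow-wave baseline; an absolute-threshold mode exists because
the original description of "height" is ambiguous). Interspike intervals
> 800 ms delimit bursts; groups of fewer than five spikes are discarded and
their span concatenated with the flanking long intervals into a single
interburst interval, which is assigned to the preceding burst. The cycle
period runs median spike to median spike (lower median for even counts).
The last spike of a burst has no within-burst following interval and is
excluded from intraburst frequency statistics. The envelope replaces the
potential between the consecutive minima bounding each spike by its mean
and keeps the raw potential between bursts. Oscillation amplitudes are
per-cycle peak-minus-following-trough of the (slow) signal with peaks and
troughs at ≥ 25 %-of-range prominence; the "backside median" is the median
of samples from each maximum to the next minimum, averaged over cycles.
Recordings qualify with ≥ 8 bursts and CV(period) < 0.25 (one figure
caption cites 0.27; 0.25 is the default, configurable). Normalization
divides metrics by their value at the 0.3 nA / 6 nS reference condition.

## Regime labels and the classifier

An epoch is high-amplitude (label 1) when the envelope amplitude exceeds
20 mV **and** the [Na⁺]ᵢ amplitude exceeds 1 mM. The Gaussian naive Bayes
uses maximum-likelihood per-class means/variances and empirical priors,
with variances floored at 1e-9 of the largest feature variance; training
uses a seeded, class-stratified 35 % split. The default feature pair is
(envelope amplitude, [Na⁺]ᵢ amplitude) — the two features the threshold
rule uses; spike frequency can be appended. Thresholds are global, not
per-experiment. The classification report (precision, recall, F1, support,
accuracy, macro/weighted averages) is computed from first principles and
cross-checked against scikit-learn in the tests.

## Phase-plane machinery

For each voltage on a grid (default −75 to +5 mV, 2001 points) all
[Na⁺]ᵢ-roots of the total-current balance (V-nullcline) or Na⁺-flux balance
([Na⁺]ᵢ-nullcline) are bracketed by a sign scan over 2000 log-spaced
concentrations in [0.1, 100] mM and refined by Brent's method to 1e-14 M.
For the published parameters the V-nullcline is single-valued in [Na⁺]ᵢ per
voltage and Z-shaped in the ([Na⁺]ᵢ, V) plane; knees are the two interior
extrema of [Na⁺]ᵢ along the voltage-ordered curve, refined by two rounds of
parabolic fitting with exact re-solution at the refined voltage (doubling
the grid moves them < 0.1 %). Fixed points are sign changes of the total
current along the [Na⁺]ᵢ-nullcline, refined in V, and tagged by branch;
the default parameters give exactly one, on the middle branch — the
unstable state inside the relaxation limit cycle.

Branch samples: each stable branch is divided into n = 100 cells of equal
[Na⁺]ᵢ width strictly between the knees and sampled at cell midpoints
(folds excluded — the speed is ill-defined there); branch voltage comes
from inverting the branch's monotone Na(V) relation. The timing estimate
is the midpoint Riemann sum Σ Δ[Na⁺]ᵢ/|d[Na⁺]ᵢ/dt| (depolarized branch →
burst duration, hyperpolarized → interburst interval); branch-mean speeds
are plain averages of |d[Na⁺]ᵢ/dt| over the samples. Quadrupling n changes
the relative-change table by < 0.5 %.

The limit cycle overshoots each knee slightly before its fast jump — a
finite-time-scale-separation effect — so the inter-knee distance tracks the
simulated [Na⁺]ᵢ amplitude from below, within ~10–15 % at the default
parameters.

## Evolutionary fitting

Cost: per pump condition, (ΔBD)² + (ΔIBI)² + mean of squared voltage
peak/trough mismatches + mean of squared [Na⁺]ᵢ peak/trough mismatches,
summed over conditions with unit weights (the mixed s²/V²/M² units are
summed as defined; optional per-term weights default to 1). Each
generation, the best-ever individual spawns f = 16 mutants (Gaussian noise,
SD = 2.5 % of each parameter's magnitude; conductance proposals resampled
until positive; a uniform variant was considered and rejected as
indistinguishable at this scale); elitism makes the best cost
non-increasing. Defaults: 100 generations with early stop after 15
stagnant ones; per-individual simulations use the compiled fast path, 40 s
with a 15 s transient. Failed simulations cost +∞ (not fatal). The whole
procedure is reproducible from one seed.

**Identifiability.** Self-target recovery experiments (perturb ḡ_h by
+20 %, refit) show the waveform summaries admit near-exact trade-offs among
the native conductances: searching all nine parameters returns the
unperturbed ḡ_h with cost ~2e-4, and even the (ḡ_h, ḡ_K2, ḡ_NaP-native)
subset recovers ḡ_h only to 6–18 % depending on the seed. A single
perturbed parameter is reliably identifiable only in a
perturb-one/search-one design, which recovers ḡ_h to < 0.1 % at the
default budget; the parameter-recovery test uses that design. For fitting
real recordings this degeneracy is a feature of the problem, not the
optimizer: distinct native-parameter sets can produce the same envelope
summaries.

## What the synthetic data does and does not emulate

The full-model simulator stands in for the hybrid (neuron + dynamic clamp)
preparation: it reproduces endogenous-style bursting under injected
currents, the speeding of the rhythm with pump maximum, the compression of
the [Na⁺]ᵢ range, and the growth of the pump-current oscillation. It does
not model the sharp-electrode membrane damage (a non-specific leak toward
0 mV) that underlies the experimental low-amplitude regime: at the weak
injection condition (ḡ_NaP = 1 nS, I_pump^max = 0.1 nA) the healthy model
neuron bursts with a ~30 mV envelope and ~2 mM [Na⁺]ᵢ amplitude —
clearly smaller than the strong-injection regime but above the 20 mV / 1 mM
expert thresholds calibrated on damaged neurons. An explicit electrode
shunt was tried and abolishes bursting altogether rather than producing
the low-amplitude regime. Likewise, the full model's burst *duration*
grows mildly with pump maximum (its Ca²⁺ and transient K⁺ currents
reshape the burst) even though its interburst interval, [Na⁺]ᵢ median and
amplitude all follow the experimental trends, and its pump-current median
rises ~14 % over the 0.3–0.7 nA sweep rather than staying flat. Tests
assert the printed expectations as written; the ones the healthy model
genuinely fails are left failing. Passing tests on synthetic data
therefore demonstrate correctness of the algorithms and the reduced-model
mechanism, not that the full model replicates damaged-neuron statistics.

## Known limitations

- No Ca²⁺ concentration dynamics; E_Ca fixed.
- No real-time hardware loop or discontinuous-current-clamp artifacts.
- The reduced model's ḡ_h differs between the two published tables
  (6 vs 4 nS); each model uses its own printed value.
- The τ(A, B, C, D, V) functional form for the full model is inferred from
  the canonical HN lineage (only its arguments are printed).
- Nullcline construction assumes the scan interval [0.1, 100] mM contains
  all roots; parameters far outside the published ranges may need a wider
  scan.
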