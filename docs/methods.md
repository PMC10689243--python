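# Methods notes

This note records the scientific assumptions, parameter choices and
numerical conventions behind `homeoplast`, including every point where
the design was genuinely open and a choice had to be made.

## Plasticity simulator

**Model.** One rate neuron with somatic and dendritic compartments;
explicit Euler integration with `dt = 1` in the same arbitrary unit as
the network time constant `τ = 10`. The stimulus-on/off epochs
(`t_on = t_off = 100` steps) play the role of flicker on/off periods.
The simulated run covers the overstimulation phase only: initial
weights `wᵢ = 1 + ξ`, `ξ ~ N(0, 0.1)` serve as the baseline state, and
the regime parameters (`A₂`, `I_inh`) take their during-overstimulation
values throughout the run.

**Stimulus gating.** Presynaptic visual drive is gated: `vᵢ` enters the
presynaptic rate only during stimulus-on epochs, and the modulation is
zero in the off epochs. An `ungated_stimulus` toggle applies `vᵢ` at
every step for sensitivity analysis.

**Noise.** `ξ` is drawn once at initialization; the presynaptic noise
`ζᵢ(t) ~ N(0, 0.1)` is redrawn independently per input per step; the
somatic aggregate excitatory and inhibitory rates each carry an
independent `U(0, 0.1)` perturbation per step. All draws for a run are
pre-generated in a fixed, documented order (`draw_noise`), which makes
runs bitwise reproducible and lets an independent re-implementation
integrate the identical noise realization — the basis of the oracle
equivalence test.

**Rectifications and clipping.** The postsynaptic drive uses the nested
rectification `[I_soma + [I_dend]₊]₊` as specified; with `dt ≤ τ` this
keeps `r(t) ≥ 0` for all t. Presynaptic rates are rectified at zero
before entering the dendritic sum (`rectify_presyn` toggle): with noise
s.d. 0.1, negative rates are possible and unphysical. Weights are *not*
clipped at zero; negative excursions are retained because clipping
would distort the monotonicity of the reinstatement sweeps.

**Closed-form check.** With all noise off, `v ≡ 0` *and* the recurrent
feedback `α = 0`, presynaptic rates equal `r₀` exactly, the Hebbian
term vanishes, and each weight decrements by exactly `A₂·r(t)·dt` per
step; the test integrates this by hand and requires agreement to 1e-10
relative. (With `α > 0` the feedback term keeps presynaptic rates above
`r₀` even without visual drive, so the strict closed form requires
`α = 0`.)

**Sweeps.** Both reinstatement sweeps start from the late-adult
configuration and share matched seed substreams across levels (a master
`SeedSequence` spawns one child per seed, reused at every level). The
per-level summary is the mean weight change per visual-responsiveness
bin (10 equal-width bins on [0, 1]); normalization divides by the
late-adult reference bin value, with near-zero reference bins reported
as NaN rather than infinity. The downscaling sweep levels
`[0.6, 0.7, 0.8, 0.9]` are interpreted as `×10⁻⁴`, commensurate with
`A₂ = 0.48×10⁻⁴`. Directional claims are operationalized as: the
inhibition sweep's *absolute* suppression (reference minus top level,
per bin) peaks in the most-visual bin; the downscaling sweep's
*relative* weakening (change from reference in units of the reference
change) peaks in the least-visual bin, where Hebbian potentiation is
negligible and the uniform homeostatic decrement dominates.

## ΔF/F₀ processing

The baseline F₀ is a running 10th percentile over a 30 s window (both
configurable and logged in the output); the percentile window is
evaluated on a stride grid and linearly interpolated, which is exact at
grid points and ample for a slow baseline. The 15% threshold is an
absolute ΔF/F₀ floor; a fraction-of-max alternative sits behind
`threshold_mode`. Events are maximal suprathreshold runs with a minimum
width of 2 frames (single-frame noise rejection). Windowed AUC
integrates the piecewise-linear trace over the exact epoch interval
(interpolating at epoch endpoints), so AUC is exactly additive over any
partition of a window. All epochs are half-open `[start, end)` in
seconds; frames are 0-based. Activity classes use quartiles of the
reference (young-adult control) distribution with left-closed
boundaries: `f ≤ Q1` low, `Q1 < f ≤ Q3` middle, `f > Q3` high.

## Spine analysis

The dendrite scaling coefficient κ is a Theil–Sen slope of spine on
dendrite restricted to dendrite-active frames; the median pairwise
slope resists spine-only transients that bias ordinary least squares
upward. κ is clipped at zero; a never-active dendrite yields κ = 0.
The corrected trace `max(spine − κ·dendrite, 0)` is re-floored at the
trace threshold.

A stimulus event counts as time-locked when an event onset falls in
`[epoch start, epoch end + 0.5 s)`; the 0.5 s tail accommodates the
slow indicator. The null threshold is the 80th percentile of
false-positive fractions computed per spine on dark-period activity
against a time-matched dummy schedule, and the visual label requires
the real fraction to exceed **both** the null threshold and the fixed
0.20 floor (conjunctive reading; the floor is exposed for sensitivity
analysis). The event count always comes from the schedule, never a
constant.

Clustering matches labels at each positional offset in both directions
(each adjacent pair counted once), with branch ends contributing only
defined offsets; the null shuffles labels within the branch.

## Assemblies

Pairwise Pearson correlations are computed on thresholded continuous
ΔF/F₀ (not binarized), by default over visual-stimulation epochs.
A pair qualifies when `r > 0` and two-sided `p < 0.05`, uncorrected —
no multiple-testing procedure is applied by default, matching the
experimental convention; a Benjamini–Hochberg option exists. Neurons
with zero qualifying partners in a channel are NaN, never zero, and
NaNs propagate through the post/baseline session ratio.

## Structural quantification

Peaks are maximal runs above `1.15 ×` background; the width at the
threshold crossing (linearly interpolated between samples) is the
spine-size proxy — width at the crossing level, not at half-maximum.
The scaling-factor grid spans `seed·[0.5, 1.5]` in steps of 0.001
around the median-ratio seed (an invented but logged span); the seed
point itself is always evaluated, grid factors are snapped to 12
decimals to avoid one-ulp mismatches inflating the KS distance, and
ties resolve to the smallest factor. Only multiplicative scaling is
implemented; an additive variant is a possible extension. The
colocalization tolerance defaults to 0.25 µm. Profile integrals use
trapezoids on the background-normalized curve, so a flat background
contributes its length. c-Fos positivity is `intensity >
1.2 × background`; weak expression is `≤` the 30th percentile of the
pooled, per-group mean-normalized control distribution; the bootstrap
records percent positive per batch of 10, 500 replicates.

## Electrophysiology

Noise RMS is a robust estimate — 1.4826 × MAD of the first difference,
divided by √2 — which reflects sample-to-sample noise even on
event-rich traces (dedicated event-free segments are not assumed).
The trace is boxcar-smoothed over 0.5 ms before thresholding at
2.5 × RMS (strictly greater); runs narrower than 1 ms are rejected and
runs closer than 2 ms are merged (both invented stabilizers, exposed as
parameters). Amplitudes are peaks on the smoothed trace: the raw-sample
maximum carries an extreme-value noise bias of roughly two standard
deviations. The amp×freq product quotient is the primary E:I
estimator; an AUC-based quotient (summed event areas per second) is
provided as the alternative. Event polarity comes from the
holding-condition metadata, never from the data.

## Behavior

HR, FAR and performance follow the standard touchscreen definitions;
sessions with an undefined metric (zero denominator) are dropped from
the learning-rate fit and counted, not imputed. The learning rate is
the OLS slope of performance on the 1-based session index (session
index, not calendar day). Correction trials are assumed excluded from
the input counts.

## Synthetic data

The generators are pure functions of (spec, seed) and bitwise
reproducible. Calcium transients use a single-exponential kernel with a
1.5 s decay (GCaMP6s-like); traces are built as Poisson event trains on
a baseline with sinusoidal drift and Gaussian noise, plus a background
ROI. Spine traces are spine-only events plus κ times the dendrite trace
plus noise. Mini trains have exponential inter-event intervals and
lognormal amplitudes (mean-corrected so the planted mean amplitude is
exact). Profiles are Gaussian bumps with planted centers, widths and
levels. Behavioral sessions are binomial draws from a hit rate climbing
linearly at the planted slope with a flat false-alarm rate.

Scenario presets plant round-number effects whose *directions* follow
the overstimulation biology (young-stim: activity ↓, mEPSP amplitude ↓,
mIPSP frequency ↑, VGAT density ↑, E–I coupling ↑; old-stim: the
reverses, with E–E coupling ↑); the magnitudes are generator ground
truth for recovery tests, not claims about real data. The population
generator plants block correlations through shared latent factors;
feasibility requires `ρ_EI ≤ √(ρ_EE·ρ_II)` (positive-definiteness), so
the defaults are `ρ_EE = ρ_II = 0.5`, `ρ_EI = 0.3`, leaving headroom
for the planted post-stimulation shifts.

**What the generators do not emulate:** imaging artifacts (motion,
bleaching beyond smooth drift), indicator nonlinearity and saturation,
correlated network events in single-cell traces, axon/dendrite
crossings, 2-D/3-D image structure, and task dynamics beyond
session-level outcome counts. Tests passing on synthetic data therefore
validate the estimators under the assumed statistical structure, not
robustness to those artifacts.

## Problem sizes

The test suite and the acceptance script run the simulator at its full
scale (N = 200 inputs, T = 10 000 steps) over 20 matched seeds for the
regime and sweep contrasts, and the oracle-equivalence check at N = 20,
T = 500. Recovery suites use 200 synthetic animals (7 sessions × 100
trials), 50 population seeds (18 neurons × 1000 frames), 100 dendrites,
200 null spines (48 stimulus events each) and 60 s voltage traces at
20 kHz. The full suite completes in about a minute on one CPU.

## Known limitations

- The simulator is a single-postsynaptic-neuron rate model; no spiking,
  conductances, or recurrent network beyond the scalar feedback α.
- The running-percentile baseline assumes transients occupy a minority
  of each window; traces with near-continuous activity would bias F₀
  upward.
- The scaling-factor test assumes positive-valued measures and purely
  multiplicative rescaling.
- The mini detector is a threshold detector: overlapping events within
  the 2 ms merge window count once, and very slow-rising events can
  fall below the smoothed threshold.
- Correlation significance is per-pair and uncorrected by default,
  matching the experimental convention rather than controlling a
  family-wise error rate.
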