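# Methods

This note documents the models, parameter choices and numerical decisions
behind `wmreselect`, in the spirit of a package methods appendix. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Orientation space

Bar tilts are 180°-periodic: θ and θ+180° are the same stimulus. All
orientations live in (−90°, +90°], the maximum reproduction error is 90°,
and the chance-level mean absolute error for uniform guessing is 45°. All
circular machinery (von Mises components, resultant lengths) operates on
*doubled angles* (2θ in radians), which maps orientation space onto the
full circle where standard circular statistics apply.

## Task generator

`TaskConfig` defaults encode the reference design: 648 trials per
participant in 27 blocks of 24 — one third no-interruption blocks, one
third fixed-onset interruption blocks (three blocks at each onset), one
third variable-onset blocks — interrupter onsets at 600/1,400/2,400 ms
post-cue, probe at 3,200 ms, epochs −200…4,200 ms at 250 Hz. Within every
block the four cued-side × response-hand cells are exactly balanced
(tilt sign determines response hand: anticlockwise ↔ left), and the
interrupter's tilt sign is counterbalanced against the memory tilt, so
item-location and response-hand contrasts are orthogonal in the trial
average. Cohort defaults are 30 participants (the reference study's
retained sample); desk-scale analyses use 20.

Interrupter reaction times are truncated normal: mean 400 ms, SD 50 ms,
bounds 100–800 ms — anchored to the reported ~400-ms mean and the 800-ms
response deadline. Probe-response times are lognormal (median 1 s,
σ=0.25); interrupter accuracy is Bernoulli(0.95).

## Report mixture and attractive bias

Reports are drawn from a three-component mixture on doubled angles: a von
Mises centered on the target (probability `p_target`), a von Mises on the
interrupter orientation (*swap*, `p_nontarget`), and a uniform *guess*
component. Trials without an interrupter fold the swap mass into the
target component. `kappa_from_sd_deg` converts a report SD in orientation
degrees into the doubled-angle concentration via the wrapped-normal
approximation κ ≈ 1/σ².

The attractive bias is a derivative-of-Gaussian shift of the
target-centered mean toward the interrupter:
Δμ(d) = g · (d/w) · exp((1 − (d/w)²)/2), with d the signed
interrupter-minus-target difference, peak amplitude g (`bias_gain`,
default 1.5° in the pipeline) at d = ±w (`bias_width_deg`, 20°). Only the
*measured* bias curve is constrained by the literature; this smooth odd
generative form is a modeling choice of the package.

### Mixture fitting

`fit_mixture` runs EM with a shared concentration for the two von Mises
components, 10 restarts (one deterministic near-pure-target start plus
Dirichlet-random starts), relative log-likelihood tolerance 1e-8, and
Fisher's piecewise approximation for the inverse of A(κ)=I₁/I₀ in the
M-step. Log-densities use exponentially scaled Bessel functions so large
κ stays finite.

Identifiability: a von Mises with κ→0 *is* the uniform density, so on
guess-dominated data the mixture is degenerate and the memory components
can absorb random density fluctuations. The fitter therefore enforces
κ ≥ 1 (report SD ≲ 29° in orientation space — far looser than any
plausible memory report) and caps κ ≤ 1e4, flagging boundary fits. Even
so, purely uniform data yield p_guess ≈ 0.75–0.9 rather than exactly 1 at
finite n; the tests assert dominance of the guess component and the
κ-floor diagnostic rather than the unattainable limit.

### Exclusions and bias curve

Trial exclusion follows the reference rules: probe RT > 5,000 ms or >
2.5 SD above the participant's mean across all conditions; interruption
trials with a missing, wrong, or >800-ms interrupter response. Datasets
with >15% rejected trials, or a mean absolute error ≥45° in any
block-type × onset condition, are flagged for exclusion (never silently
dropped). The bias curve demeans *signed* errors per participant across
all interruption trials (signed demeaning is the only choice that removes
a constant response bias; whether the original analysis demeaned within
or across onset conditions is ambiguous — across is used here), then bins
by the target–interrupter difference with a 45°-wide window stepping at
5°, with circular wrapping of the (itself 180°-periodic) difference axis.
Empty bins are NaN, never 0.

## Gaze

The generator produces 1-kHz binocular traces: a common eye-position
signal (Ornstein–Uhlenbeck drift, SD 0.3°, τ=200 ms) plus per-eye
measurement noise, with a cue-locked Gaussian deflection (center 500 ms,
σ=250 ms) and an interrupter-response-locked deflection (center +250 ms,
σ=200 ms) signed by cued side with peak amplitude `towardness_amp`
(default 0.1°, the fixational-bias scale). Blinks are Poisson events
(100–300 ms) saturating both eyes.

Preprocessing: linear interpolation across blink intervals padded ±100 ms
(boundary blinks extend the nearest value), eye averaging, downsampling
to 250 Hz by a moving-average anti-alias filter followed by decimation
(the downsampling method is unspecified in the source literature; this is
the package's choice), removal of trials exceeding ±2.75° in x or y,
15-sample (60 ms) centered moving average with edge truncation, and
per-trial baselining to the −200–0 ms mean. Baselining is applied after
smoothing (the ordering is ambiguous in the literature; it is idempotent
either way). Towardness = (mean x on right-cued − mean x on left-cued)/2.

## Spectral analysis

Power comes from `mne.time_frequency.tfr_array_morlet` with
n_cycles = f × 0.3 s — the fixed 300-ms analysis window — using mne's
zero-mean (admissibility-corrected) Morlet convention; frequencies span
3–40 Hz in full analyses and 4–32 Hz at 2-Hz spacing with 4× time
decimation in desk-scale runs. Output samples within 150 ms (half a
window) of an epoch edge are flagged and excluded from cluster testing.
Power is computed per trial and averaged within condition *before* the
normalized difference (induced-power convention), on raw (not
log-transformed) power; the lateralization contrast is self-normalizing
so no baseline correction is applied.

For a pair like PO7/PO8, each electrode's contralateral and ipsilateral
trial-average power (by cued side for the visual basis, response hand for
the motor basis; hemisphere inferred from the 10-20 label's digit parity)
forms 100·(contra−ipsi)/(contra+ipsi), averaged over the pair; |L| ≤ 100
by construction and cells with zero total power propagate NaN. Band
courses are unweighted means over 8–12 Hz (alpha) or 13–30 Hz (beta).

Response-locked analysis re-epochs around interrupter-response times
(onset + trial RT), −400…+400 ms. To keep wavelet edges out of the
analysis window, the raw signal is re-epoched with a ±300-ms pad, the TFR
computed, then cropped to the stated window; trials whose padded window
leaves the source epoch are dropped and counted.

## EEG-like generator

Each channel carries 1/f (power-law) Gaussian noise, normalized per trial
to `noise_sd` (1.0 arbitrary units). Channels of an effect pair add a
band oscillation (frequency uniform in the band per trial/channel, random
phase, lognormal amplitude jitter, base amplitude 0.5 — roughly 2× the
band-integrated background in the alpha band, so single-trial SNR is low
but 20-participant group effects are clear). Inside the effect windows
the amplitude on the channel contralateral to the relevant feature is
multiplied by (1 − attenuation); windows have 100-ms raised-cosine ramps.
Between-participant variance is realistic rather than zero: attenuation
~N(0.3, 0.08) clipped to [0, 0.95] and lognormal amplitude scaling per
participant.

Default effect layout: alpha (PO7/PO8, item side) transient 200–700 ms
cue-locked and transient 0–600 ms response-locked; beta (C3/C4, response
hand) sustained from 300 ms cue-locked *until the interrupter onset*,
then sustained from the interrupter response to the epoch end (on
no-interruption trials, sustained to the epoch end). The beta pause
during interrupter handling reflects the motor plan for the interrupter
response displacing the working-memory action plan, and is what lets a
response-locked beta cluster begin at the response rather than span the
whole epoch.

What the generator does **not** emulate: volume conduction and realistic
topographies (only the four effect channels carry signal), oscillatory
asymmetries, aperiodic-exponent variation, eye-movement artifacts in EEG,
and any coupling between behavioral precision and neural attenuation.
Passing tests therefore validate the *analysis machinery* — recovery of
planted effects at realistic SNR — not neurophysiological realism.

## Cluster-based permutation inference

One-sample (vs 0) or paired (on differences): pointwise t-values are
thresholded at the two-sided critical value for cluster alpha 0.05
(strict inequality; the sidedness choice is exposed); contiguous
supra-threshold points — 4-neighborhood in time×frequency — form clusters
per sign; cluster mass is the summed t. The null records the maximum
|mass| over 1,024 random whole-participant sign flips and
p = (1 + #{null ≥ |mass|})/(1 + 1,024). With ≤10 participants the 2ⁿ sign
patterns are enumerated exhaustively instead, making p exact
(p = #{null ≥ |mass|}/2ⁿ; the identity pattern goes through the identical
arithmetic so it always counts itself). Sign flips leave per-point mean
squares invariant, so permuted t-maps need only the flipped means — this
is what makes 200-dataset calibration runs cheap. Points with zero
variance get t = 0 when the mean is 0 (all-zero data produce no clusters)
and a huge sentinel t otherwise (exact constant effects join clusters).

Trial rejection uses Rosner's generalized ESD on per-trial variance
summed over channels (α=0.05, up to 15% of trials): all candidate
counts i = 1…k are evaluated and the largest i with R_i > λ_i is flagged,
which is what makes the procedure robust to masking.

## Cross-correlation

z[k] = Σᵢ x[i]·y[i−k] over the full lag range ±(n−1) including partial
overlap. Default normalization divides by √(Σx²·Σy²) (global energy;
bounded in [−1,1] by Cauchy–Schwarz, invariant to positive rescaling);
a per-lag variant divides by the energies of the overlapping segments.
Courses are mean-centered over the analysis window by default (prevents
shared offsets from dominating). Sign convention: y[i] = x[i−d] peaks at
k = −d, so a *delayed* motor course shows a *negative* peak lag.

A systematic finding from validation: with partial-overlap lags retained,
global normalization of mean-centered signals acquires an
overlap-proportional cross term that biases peak lags toward zero by
about one sample. The pipeline's peak-lag readout therefore uses the
per-lag (overlap-normalized) variant, which removes the bias; planted
delays of ±100 and ±200 ms are recovered within one 4-ms sample.
Peak-lag ties break toward the smallest |lag|, then the negative lag.
Lags with less than 50% overlap are masked by default. The zero-lag test
is a one-sample t of per-participant peak lags; an all-zero-lag cohort
has zero variance and is reported as flagged/non-significant rather than
an error.

The course-level generator (`sample_reselection_courses`) emulates
*trial-averaged* participant band courses: negative Gaussian bumps
(peak 100 ms post-response, σ=60 ms — fully supported inside the
−400…400 ms window even at ±200 ms delays) with lognormal amplitude
variation and OU residual noise at 5% of the bump amplitude, the residual
scale appropriate for several-hundred-trial averages.

## Problem sizes and determinism

Desk-scale runs use 20 participants × 324 trials for the end-to-end EEG
analyses, 200 simulated datasets for calibration, and 1,024 permutations
throughout — sizes at which every planted effect is comfortably
recoverable on a single CPU. Every generator and every permutation test
is driven by explicit integer seeds (numpy `default_rng` with keyed
streams per participant and purpose), and a full pipeline rerun with the
same configuration is byte-identical in all numeric outputs.

## Known limitations

- The mixture degeneracy at κ→0 (above) makes guess proportions near 1
  identifiable only asymptotically.
- The cluster test on the bias curve treats overlapping moving-window
  bins as an ordered axis; bin overlap induces dependence along the axis,
  which sign-flip exchangeability at the participant level tolerates but
  which makes cluster extents on that axis conservative descriptors.
- Cluster "onset" is read out as the first supra-threshold sample of a
  significant cluster; with strong effects this tracks the threshold
  crossing of the smeared (±~150 ms wavelet) effect edge, not the true
  generative onset.
- The ESD trial score (summed channel variance) targets broadband
  artifacts; focal single-channel artifacts dilute.
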