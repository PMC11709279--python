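# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the known limitations of the package. Everything quantitative
stated here is computed by the test suite or by `scripts/acceptance.py`.

## Data model

A probe placement is a `TrialResponseTable`: per-site, per-condition,
per-repetition time-averaged rates (spikes/s) with optional single-trial
PSTHs on a common time axis (default 2 ms bins, onset at 0 ms). Stimulus
conditions are grating drift directions in degrees plus one blank (uniform
gray) condition, encoded as a reserved token and stored last. Because blank
trials are interleaved at a lower rate than each direction, per-condition
trial counts differ; arrays are NaN-padded with an explicit trial-count
vector. Two dialects are supported: HDF5 (rates + PSTHs) and a long-format
CSV (rates only). Both round-trip bit-exactly; the CSV path uses `%.17g`
on write and round-trip float parsing on read.

## Site screening

The SNR of a site is max over directions of the variance (over time bins,
ddof = 1; the choice cancels in the ratio) of the trial-averaged PSTH in
the 0–200 ms post-onset window, divided by the same variance under the
blank. Sites pass only with SNR **strictly** greater than 8. Sites whose
blank variance is zero have undefined SNR and are excluded with a reason
rather than passed through as NaN.

## Tuning curves and indices

Direction tuning uses a two-lobe von Mises curve with lobes fixed 180°
apart and a shared normalization that makes each lobe peak at its
amplitude and vanish at the opposite direction. Fitting is bounded local
least squares (`scipy.optimize.least_squares`, trf) from fixed initial
guesses: θ_pref at the measured argmax (lowest index on ties), σ₁ = σ₂ = 1,
α = β = max − min, R₀ = min. Bounds: σ ∈ (10⁻³, 50], α, β ≥ 0, θ_pref
within ±180° of the guess. If the optimizer ever returns a worse residual
than its own starting point, the starting point is kept and the fit is
flagged unconverged. Orientation tuning is the single-lobe, angle-doubled
analogue; its half-width at half-height has the closed form
Δ = ½·arccos(ln cosh σ₁ / σ₁).

DSI and OSI are computed from the **fitted** curve at the preferred and
null (orthogonal) angles; a raw-response variant (`raw_dsi`) is available.
Responses are not blank-subtracted before fitting, R₀ may be negative, and
the DSI requires R_pref + R_null > 0 (otherwise the site is excluded with
a logged reason). Angles are degrees at every interface and radians
internally.

F1/F0 is the amplitude of the Fourier component of the trial-averaged
PSTH at the stimulus temporal frequency, over the mean rate; it requires
at least two stimulus cycles.

## Layers, latency, probe QC

Relative depth runs 0 (cortical surface / L2-3 border) to 1 (L6 / white
matter). Layer boundaries sit at 0.35, 0.58, 0.76; membership is
lower-closed/upper-open, so a site exactly at 0.35 is L4. L2/3 and L5 form
the output group, L4 and L6 the input group.

Latency is the first post-onset time at which the baseline-subtracted
response reaches half of its post-onset maximum, linearly interpolated
between bins. The maximum is searched in 0–200 ms (the screening window)
to avoid rebound peaks; both windows are configurable.

Probe perpendicularity QC: RF-center dispersion is the mean Euclidean
distance of RF centers from their mean divided by twice the geometric mean
of the RF radii (the product-form population-averaged diameter); the
geometric mean is one isolated function so an arithmetic-mean reading is a
one-line swap. Preferred-orientation consistency is the modulus of the
mean unit phasor at doubled angle — 1 iff all orientations agree mod 180°,
and invariant to rotating all orientations together.

The current source density helper is the negative second spatial
difference of the LFP across uniformly spaced channels; edge channels are
dropped.

## Interlaminar gain models

Input and output layer-averaged rates are paired by repetition index
within condition; conditions with unequal counts are truncated to the
common minimum. Blank samples enter the objective with the same weight as
grating samples.

The smoothed threshold-linear transfer f(g) is the exact Gaussian
expectation A·E[max(g + ε − g₀, 0)], ε ~ N(0, σ²); it converges to
A·max(g − g₀, 0) as σ → 0. Because the gain multiplies the drive inside
f, rescaling the gains w′ = w/c while setting A′ = A·c, g₀′ = g₀/c,
σ′ = σ/c (power law: A′ = A·cⁿ) leaves predictions unchanged. Tuned-gain fits are therefore reported with the mean gain over
grating conditions normalized to 1; the gain tuning shape and its DSI are
invariant to this convention. Models III/IV ([wR − T]₊) have no such
degeneracy and are left unnormalized.

Fitting is bounded least squares with seeded multi-start (the base start
uses the per-condition output/input mean-rate ratio as the gain guess;
restarts jitter it), keeping the best objective. Bounds: A ∈ (0, 100],
g₀ within ± the maximum drive, σ ∈ (10⁻³, max drive], exponent
n ∈ [0.5, 5], gains ≥ 0. The number of free parameters counts the scale
normalization: 3 for Model I (threshold-linear), n_conditions + 2 for
Model II, n_conditions + 1 for Models III/IV.

Fit quality: the adjusted goodness of fit

    adjR² = 1 − (N−1)/(N−Nparam) · 2·Σ(R̂−R)² / (Σ(R̂−R̂̄)² + Σ(R−R̄)²)

(sums over samples; a perfect fit gives exactly 1), plus Gaussian-residual
AIC = N·ln(J/N) + 2·Nparam and BIC with ln(N)·Nparam. Population
summaries gate probes at adjR²(tuned-gain model) > 0.8.

The DSI enhancement decomposition is
contrib_nonlin = (DSI_ModelI − DSI_in)/(DSI_out − DSI_in) and
contrib_gain = (DSI_ModelII − DSI_ModelI)/(DSI_out − DSI_in); the two
always sum to (DSI_ModelII − DSI_in)/(DSI_out − DSI_in).

Response-ratio tuning divides output by input mean rates per condition
after circularly shifting the direction axis so the preferred direction
maps to 90°; ratios where the input response is not positive are masked.

## Granger causality

Layer signals are site-averaged MUA time courses per condition. VAR
coefficients are OLS on lagged regressors; trials are pooled into one
regression with no lags crossing trial boundaries, after per-trial mean
removal. Model order is selected by AIC over 1..max_order (default 20);
the reduced (source-omitting) regression reuses the full model's order.
GC(to ← from | rest) = ln(Σ_reduced[to]/Σ_full[to]); small negative
estimates are clamped to zero. Within a probe, GC values are z-scored over
all (condition, layer-pair) entries. Condition contrasts across probes use
paired Wilcoxon signed-rank tests with Bonferroni correction (p multiplied
by the number of layer-pair comparisons, capped at 1).

## Statistics battery

One value per probe placement (the median over sites within a laminar
group) feeds interlaminar comparisons: Wilcoxon signed-rank for paired
groups, Wilcoxon rank-sum for independent groups, both two-sided;
chi-square on the 2×2 table for proportions; Spearman rank correlation for
associations; an exact two-sided sign test (binomial for n ≤ 100, normal
approximation beyond) for medians against a reference. The SEM of a median
is a seeded 1000-resample bootstrap. Bonferroni correction is applied only
to declared families (the GC contrasts); other tests are uncorrected.

## Synthetic generator: what it emulates, and what it does not

The generator plants: per-input-site two-lobe von Mises tuning with a
small (sd 5°) per-site jitter of the preferred direction around a shared
columnar preference; a gain curve w(θ) = w̄(1 + m·cos(θ − θ_pref)) whose
gain DSI equals m exactly, with the blank gain w̄(1 − 1.1m) below the
null-direction gain; the smoothed threshold-linear nonlinearity; a latency
offset (defaults 51.8 ms output vs 38.6 ms input, implemented as a
logistic PSTH rise whose half-maximum sits at the configured latency); and
trial noise, by default Gaussian on rates with sd ∝ √mean (Poisson-like
variance scaling; fractional-sd and Poisson variants available).

Default study conditions: 12 equally spaced directions, 10 repetitions per
direction, blank trials ≈ 10 % of all trials, a gain DSI of 0.3, input-site
peak ≈ 30 spikes/s over a 5 spikes/s offset with input DSI 0.25, and a
mean gain (0.85) chosen so the output/input response ratio is ≈ 1 in the
preferred direction and below 1 elsewhere — i.e. the preferred response is
preserved across layers while non-preferred and spontaneous activity are
attenuated.

Output trials are, by default, **coupled** to the input: the output at
repetition i is the forward pass of the realized input-layer average at
repetition i, plus output noise. This mirrors the repetition pairing of
the transmission model and makes the per-condition gains identifiable
(with uncoupled identical repetitions, a per-condition-gain model has more
parameters than distinct constraints). Setting the output noise scale to
zero yields data exactly on the model manifold — the configuration used by
the self-consistency checks. The noise-free mean relation
output = f(w(S) · input-layer mean) holds exactly by construction.

Not emulated: within-trial spike-count statistics (rates are Gaussian
summaries), eye-specific responses, spatial direction maps, cross-site
noise correlations beyond the shared drive, and any biophysics. PSTH
trial noise is drawn independently of the time-averaged rate noise, so
integrating a trial PSTH does not reproduce that trial's rate. Passing
tests therefore demonstrate correctness of the analysis chain under the
planted model, not robustness to every property of real recordings.

The Granger-causality stage of the pipeline uses a separate VAR fixture
with condition-dependent coupling strengths (blank < null < preferred) on
the planted feedforward (L4→L2/3, L4→L5) and recurrent (L2/3→L5) edges,
since the rate-level generator has no temporal dynamics to carry directed
interactions.

## Problem sizes and determinism

Default verification sizes: 20 seeded probes for noisy parameter recovery;
400 replicates for type-I calibration (12 probe-pairs each, resampled from
a common site-DSI pool so the null holds exactly); GC fixtures at 10,000
to 50,000 samples; an 8-probe pipeline run with 3,000-sample GC series.
Every random draw flows from an explicit seed; identical (config, seed)
pairs reproduce byte-identical reports.

## Known limitations

- The tuned-gain model's per-condition gains are only identifiable through
  within-condition drive variability; probes with very low trial counts or
  noise-free uncoupled repetitions leave the gain curve underdetermined.
- The acquisition-side voltage thresholding that produces MUA (and its own
  SNR criterion) is upstream of this package; analyses start from rates.
- Conditional GC assumes linear stationary dynamics within the analyzed
  epoch; no spectral decomposition is provided.
- The gain-DSI extraction takes the preferred direction at the maximum
  fitted gain; under heavy noise the argmax can jump a grid step, which
  inflates single-probe errors (medians across probes are reported for
  this reason).
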