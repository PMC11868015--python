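# Methods

## Setting and data model

The package analyses beat-to-beat RR-interval recordings from athletes
climbing a steep hill near the end of a long endurance race, stopping
briefly at the top for manual blood-pressure and lactate measurements,
then riding on. The analysis window for heart-rate variability (HRV) is
the 5 min following (and including) the stop: directly after maximal
exertion, vagal reactivation and baroreflex engagement are pronounced, so
the low-frequency (LF) component is expected to discriminate between
subjects with and without coronary artery calcification (CAC+/CAC−).

Inputs are plain CSV: one RR file per subject (`t_ms`, `rr_ms`), an
events file (hill start, stop start, stop end in seconds), a subjects
table (metadata, BP and lactate triplets at the start and at the hill
top), and optional 1 Hz power/speed traces.

## Artifact detection and correction

Chest-strap RR series carry missed beats (two intervals fused), extra
beats (one interval split) and ectopic-like displacements (one interval
shortened, the next lengthened). Detection uses a percentage-threshold
median filter: beat *i* is flagged when its interval deviates from the
median of the surrounding window, centre beat excluded, by more than
`threshold_fraction` (default 0.05) of that median.

Choices where the procedure is genuinely open:

- **Window length** — 11 beats (5 each side), configurable. A beat-count
  window (rather than a fixed time span) is used; at exercise heart rates
  11 beats is 4–6 s, long enough for a stable local median and short
  enough to track the post-stop HR drop.
- **Centre exclusion** — the flagged beat is excluded from its own window
  median so a large artifact cannot mask itself.
- **Edges** — truncated windows; an interior minimum of one neighbour.

Correction methods: `none`, `deletion` (flagged beats removed, survivor
times recomputed from cumulative sums), `linear`/`cubic` (interpolation of
RR as a function of beat *time* over unflagged beats, respecting uneven
spacing; consecutive flagged beats are corrected as one span; flagged
beats at the extremes take the nearest unflagged value, logged), and
`arima`. The ARIMA order is (1,1,1), fitted per flagged span on the most
recent unflagged beats (at least 60, at most 120); on insufficient history
or fit failure the span falls back to linear interpolation with a log
message. All methods except deletion preserve series length and leave
unflagged interval values untouched; beat times are re-accumulated so that
time differences always equal the intervals.

## HRV metrics

RMSSD and SDNN (sample SD, n−1 denominator) are computed on the corrected
but **not** resampled beat series, standard practice for time-domain HRV.
Spectral powers come from the evenly resampled tachogram: a cubic spline
of RR(t) evaluated on a 4 Hz grid spanning the window (no extrapolation).
4 Hz puts the Nyquist frequency (2 Hz) far above the 0.4 Hz upper band
edge while keeping 300-s windows at 1200 samples.

The estimator is a single-segment boxcar periodogram after removing mean
and linear trend, scaled so the ordinate sum equals the detrended mean
square (powers in ms²). Welch averaging is deliberately not the default: a
5-min window cannot be split into enough segments to keep the 0.04 Hz
resolution the LF band needs. No taper is applied beyond detrending
(configurable). Band edges are half-open, upper-inclusive — VLF (0, 0.04],
LF (0.04, 0.15], HF (0.15, 0.4] Hz — so no bin is double-counted; the
zero-frequency bin is excluded since detrending removes it. Total power is
the sum of the three bands by construction. Windows holding less than
~90 s of beats trigger a reliability warning, reflecting the minimum
duration at which ultra-short LF estimates become stable.

## Haemodynamic indices

Instantaneous HR (60000/RR at beat times) is interpolated to a 1 Hz grid
and smoothed with a 5-s centred mean; "HR at a time point" always means
this 5-s mean, a documented choice since beat-level HR at an instant is
noisy. Summaries: maximum HR over the climb, time-weighted mean HR over
the stop and over the 5-min window, and the 30-s recovery
HR(stop) − HR(stop + 30 s). Each summary HR is also expressed as a
percentage of the laboratory maximum (from a VO2max test) and as the HR
reserve fraction (HR − HR_rest)/(HR_max,lab − HR_rest), reported ×100.

Pressure indices: pulse pressure per site, start→hill-top deltas,
RPP_max = SBP_THH × HR_max,uphill, RPP_mean = SBP_THH × HR_mean,stop (the
cuff is read during the stop, so the stop-mean HR is the matching rate; no
correction is attempted for the delay between stopping and the reading —
a known limitation). Lactate is measured in triplicate and aggregated as
the mean of the two closest replicates; equal gaps resolve toward the
lower-mean pair (logged), a documented tie-break since "the two closest"
does not define one.

## Group statistics

Continuous variables: median (25th–75th percentile) with linear-
interpolation quantiles; two-sided Mann–Whitney test. The reported U is
the first-listed (CAC−) sample's statistic — rank sum minus n1(n1+1)/2
with midranks for ties. Tie-free samples with n1+n2 ≤ 16 use the exact
null distribution; otherwise the normal approximation with tie correction
and 0.5 continuity correction. Categorical variables use the chi-square
test with Yates continuity correction. Significance is two-tailed at
α = 0.05 with no multiple-testing correction (none is applied in the
reporting convention this pipeline mirrors). Logistic models are fitted by
unpenalised maximum likelihood on untransformed predictors; odds ratios
carry Wald 95% CIs exp(β ± 1.96·SE). Completely separating predictors are
detected (non-overlapping ranges between outcome classes), flagged,
excluded from the fit and reported without odds ratios; rows with missing
predictors are dropped (complete-case analysis, no imputation).

Walker detection: a subject is classified as having dismounted when power
is ≤ 0 W for a contiguous stretch of at least 20% of the climb, or — with
no power meter — when speed stays below 1.8 m/s for the same stretch. The
speed threshold is a documented guess exposed in configuration; subjects
with neither channel are excluded from the cyclists-only subgroup with a
log message.

## Pipeline

`run_full_analysis` executes preprocess → HRV → haemodynamics → group
statistics, with ARIMA at the 5% threshold as default correction, and
emits: a baseline table, the full-cohort hill-top comparison, the
cyclists-only comparison, two logistic models — the primary model (LF,
SBP/DBP at the hill top, ΔDBP, ΔPP, mean RPP) and an expanded adjusted
model (LF plus age, sex, BMI, maximum HR, VO2max, smoking, resting
SBP/DBP, ΔDBP) — and a sensitivity grid of the LF p-value under each
correction method, full cohort and cyclists only. Outputs are CSV/JSON
plus a plain-text rendering; configuration is a flat YAML file with
unknown keys rejected, and config + seed fully determine every output
byte.

## Synthetic cohorts

The simulator generates the study conditions the analysis assumes: a
56-subject cohort (31 CAC−, 25 CAC+) by default, with group-level
distributions parameterised by median and IQR. Spectral powers (and other
strictly positive, right-skewed latents) are sampled log-normally with
μ = ln(median) and σ = ln(q75/q25)/(2·z₀.₇₅); pressures and vitals are
sampled normally with σ = IQR/1.349, truncated at physiological bounds
([30, 320] mmHg for BP). Degenerate (zero-width) IQRs reproduce the median
exactly. Hill-top SBP is redrawn until it exceeds the start value; an
optional ΔDBP specification replaces direct sampling of hill-top DBP.
Default group targets (LF 12.4 vs 6.3 ms², SBP_THH 220 vs 235 mmHg, and so
on) are the emulated study conditions; smoking prevalence, which the
baseline table does not print, is set once to 0.10 per group as realistic
for a middle-aged Scandinavian leisure-athlete cohort.

Beat generation is integral pulse frequency modulation: the target RR is
a deterministic HR skeleton (baseline riding at 78% of lab max, linear
climb to the uphill peak, mono-exponential post-stop recovery with
τ = 60 s whose amplitude is set by the configured 30-s drop, then a gentle
rise after remounting) plus one sinusoid per band with amplitude
√(2·power), so the generated tachogram carries known band powers on
genuinely unevenly spaced beats — exercising the resampling step rather
than bypassing it. Artifacts are injected at configurable rate and mix
(missed/extra/ectopic) with total time conserved to < 1 ms and positions
returned as ground truth. Walkers are the lowest-VO2max subjects of each
group (six per group by default) and show zero power and walking speed
over the middle 40% of the climb; 38/56 subjects carry power meters, the
rest get speed-only traces.

What the simulator does **not** emulate: respiration-driven HF coupling,
non-stationary band powers within the window, measurement-device error
models, GPS/altitude, or any within-subject pre-race HRV baseline (the
emulated study reports none, so only the post-stop window is calibrated).
Passing tests therefore demonstrate correctness of the computational
chain under the stated generative model, not robustness to every
pathology of real field recordings.

## Calibration experiments and problem sizes

Two pipeline-level experiments validate the statistical layer end to end,
at sizes chosen to give stable Monte-Carlo estimates at desk scale:
difference-free cohorts (both groups drawn from CAC− parameters, 20 per
group, 200 runs in the test suite) must flag ~5% of variables at α = 0.05;
and cohorts with the configured LF separation (12.4 vs 6.3 ms²) at 100 per
group must flag LF, in the correct direction, in ≥ 90% of 50 seeded runs.
Both run artifact-free with correction `none`, isolating the statistical
calibration from the correction stage, which has its own round-trip
checks (median LF error after linear/cubic/ARIMA correction ≤ 15% at
3–5% injected artifacts over 50 seeds).

## Numerical notes and limitations

- Quantiles: NumPy's linear-interpolation convention throughout.
- The IPFM integrator uses trapezoidal accumulation on a 0.05-s grid;
  beat times are found by inverse interpolation of the cumulative area.
- Detection on constant series flags nothing; a fully flagged series, or
  more than half flagged, is refused rather than corrected.
- The exponential post-stop recovery is a modelling choice: only the 30-s
  drop statistic is calibrated, not the functional form.
- The 5-s HR smoothing means recovery estimates on heavily modulated
  series scatter by a few bpm around the configured drop.
- VLF power recovered from simulated post-stop windows exceeds the latent
  target because the recovery trend itself carries very-low-frequency
  energy past the linear detrend; LF and HF are unaffected.
- Default simulator seed: 20180421, recorded in config and logs.
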