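# Methods

This note records the models, estimators, numerical choices and known
limitations behind `crossmu`, in the order data flow through the pipeline.

## Session model and units

A *session* is one subject × leg × timepoint recording. After loading,
every quantity is canonical: time in seconds (written as decimal text with
12 significant digits, so a write→read→write cycle is byte-identical),
force in newtons, voltage in microvolts; sample indices are 0-based.
Spike times may be supplied as seconds or as sample indices plus a
sampling rate and are normalised on load. Duplicate or non-increasing
spike times are rejected rather than repaired — decomposition output
should never contain them, so they indicate an upstream fault worth
surfacing.

## Force analysis

Force is filtered with a 4th-order 20 Hz Butterworth applied
forward–backward (`scipy.signal.sosfiltfilt`). Zero-phase filtering was
chosen so that force values interpolated at spike times (recruitment and
derecruitment thresholds) are not biased by filter lag; the cost is that
the effective magnitude response is the squared single-pass response
(−6 dB rather than −3 dB at the cutoff), which the filter-contract tests
pin down.

MVC is the maximum of the filtered force inside each annotated MVC window;
the highest of the (typically three) trial maxima is the session MVC.
Whether to filter before taking the maximum is genuinely open; filtering
first was chosen for symmetry with every other force readout and because a
20 Hz low-pass cannot depress a ≥ 2 s voluntary plateau.

Plateau detection returns the longest contiguous window in which the
filtered force stays within ±5 % of the target and that lasts at least
5 s. An explicit plateau annotation always overrides detection, so
operator-marked windows survive round trips. Note that on an ideal
trapezoid the ±5 % band admits the tail of the ramp (tolerance ÷ ramp
slope, 0.25 s at 20 N/s), which is why the tests assert the hold is
covered rather than an exact ramp-corner split.

Force steadiness is CoV = s/x̄ of the filtered force in the plateau
window. All SDs in the package use n−1.

## Discharge analysis

Instantaneous rate is 1/ISI assigned to the closing spike. Recruitment
and derecruitment rates are means of the first and last five instantaneous
rates; the sustained-phase rate averages rates whose ISIs lie entirely
inside the plateau window, and ISI CoV is computed over the same ISIs.
The "last five" reading for derecruitment is the only sensible
interpretation of a rule stated once for both contraction ends.

ISIs outside 0.02–0.5 s (2–50 pps) are treated as decomposition artifacts
and excluded from rate and variability estimates, with exclusions
auditable. The bounds mirror physiological discharge limits for
submaximal isometric contractions.

The quality gate keeps trains with pulse-to-noise ratio ≥ 30 dB
(inclusive). Tracking honours externally supplied pre↔post links
verbatim; otherwise spike-triggered templates are matched by maximum
normalized cross-correlation through an optimal one-to-one assignment
(`scipy.optimize.linear_sum_assignment`), discarding pairs below 0.8.

The cumulative spike train bins each tracked train at 1 ms, sums across
MUs and smooths with a unit-area 400 ms Hann window. Neither bin width
nor kernel is critical for the reported quantity — the mean over the
plateau — because with a rectangular kernel that mean is identically
(spike count)/(window duration), an equality the tests enforce to 1e−9;
the Hann default only suppresses edge ripple in the trace itself.

## MUP morphology and near-fibre metrics

Automatic cursors: peaks are the global extrema; onset and end are the
outermost samples of supra-threshold activity (threshold
max(10 µV, 3·noise SD)) sustained for ≥ 0.1 ms. Manually supplied cursors
pass through untouched.

Area is Σ|v|·Δt between onset and end (µV·ms). Turns are counted by
threshold-hysteresis turning-point detection: starting from the onset
value, a direction is established once the waveform moves > 20 µV from the
reference, and a turn is recorded at the running extreme whenever the
waveform reverses by > 20 µV. This is equivalent to "significant
direction changes > 20 µV between successive accepted turns" on clean
waveforms, and it is the only formulation we found under which
sub-threshold ripple provably never creates or destroys a turn — a
property the suite checks. The negative-peak ratio is
|v(p) − v(p−w)| / |v(p+w) − v(p)| with w = 500 µs, undefined (NaN) when
the fall is flat.

The near-fibre MUP is the discrete second temporal difference scaled by
1/Δt², followed by a zero-phase 2nd-order 10 kHz low-pass. The double
differentiator itself supplies the low-frequency emphasis (its magnitude
rises as f², crossing the useful MUP band around a few hundred hertz), so
no separate high-pass is applied; adding one at 500 Hz would visibly
distort sub-millisecond lobes and break the analytic-second-derivative
check the suite performs on a σ = 0.5 ms Gaussian (1 % RMS).

NF jiggle is the consecutive-pair mean absolute NFM difference normalized
by the mean-NFM rectified area, as a percentage, evaluated over the
cursor-delimited NFM duration. Consecutive (temporally ordered) pairs
were chosen over all-pairs to reduce sensitivity to slow drift; the
estimator lives in one function so the convention can be swapped if a
different one must be matched. Restricting to the NFM duration matters in
practice: white acquisition noise is amplified ∝ f² by the differentiator,
and integrating it over silent padding would swamp the jitter signal.
MUP trains with < 40 discharges are excluded; contamination ("contains
MUPs from multiple MUs") uses the external flag when present, otherwise a
train is flagged when > 20 % of realizations correlate with the template
below 0.8.

## Synthetic cohort

The generator is a statistical surrogate for decomposed vastus lateralis
recordings, not a volume-conductor simulation. Its defaults are the study
conditions: 13 subjects × 2 legs × 2 timepoints; 3 MVC trials; a 25 %-MVC
trapezoid (5 s ramps, 12 s hold, 1 kHz force, spike times on a 2 kHz
grid); baseline cell means of 286/296 N MVC and 7.43/7.32 pps plateau FR
(control/exercise); post-intervention multipliers 266/286 and 252/296 on
MVC, 8.66/7.32 on the exercised leg's firing rate and 1.0 on the
control's; force-steadiness targets 0.024/0.025 (pre) and 0.021/0.027
(post); MUP morphology unchanged. Between-subject SDs (99 N for MVC,
0.8 pps for FR, lognormal σ = 0.25 on steadiness) were set so the
simulated EMM confidence intervals and the R²m/R²c pattern match what a
cohort of this size and heterogeneity produces; subject effect multipliers
vary with SD 0.05 (MVC) and 0.08 (FR), with a −0.75 coupling between a
subject's MVC loss and FR rise in the exercised leg so that the ΔFR–ΔMVC
correlation is negative there and near zero in the control leg.

Pool structure: exponentially spaced recruitment thresholds
(θᵢ = R^(i/n)/R, R = 30) — the field-standard surrogate; rate law
min(peak, onset + gain·(e − θ)); Fuglevand-type twitches (exponential
amplitude range, contraction times 90→30 ms) convolved with the spike
trains, the sum rescaled so the plateau mean equals the target force.

Two calibrations make injected parameters *recoverable*, not just
approximate:

- Renewal ISIs are truncated-normal, T = µ(1 + c·Z), Z ∈ [−3, 3] (the
  lower bound tightened when c ≥ 1/3 to keep T > 0), with µ solved by
  quadrature so that E[1/T] equals the nominal rate. The mean
  instantaneous firing rate — the quantity the estimators measure — is
  therefore unbiased for the injected rate; parametrising by 1/E[T]
  instead would build in a +c² bias (≈ 2 % at c = 0.15). With c = 0 every
  discharge metric is an exact closed form.
- On the plateau, the deviation of the force from its mean is rescaled
  (cosine-tapered at the window edges, ramps untouched) so the
  post-20-Hz-filter CoV equals the steadiness target; if the twitch-sum
  fluctuation falls short, calibrated 1–3 Hz tremor is added instead.
  Wideband sensor noise (0.2 % of the mean) rides on top and is removed by
  the analysis filter.

MUP templates are sums of Gaussian-first-derivative lobes (6 fibres,
σ 0.3–0.5 ms, latencies spread over ±1.2 ms); realizations re-draw
per-fibre latencies with the jitter SD (default 25 µs, a standard adult
NMJ figure) and add 0.2 µV white noise. Jiggle rises near-linearly with
jitter (≈ 25 % at 25 µs, ≈ 40 % at 50 µs under the defaults), and the
paired-seed monotonicity of that relationship is tested.

What the generator does **not** emulate: decomposition errors (missed or
merged discharges), non-stationary recruitment during the hold,
between-MU heterogeneity of ISI CoV (it is uniform at 0.15, so the
fitted ISI-CoV model sees almost no true variance and can flag
trivially small effects), motor-unit replacement between timepoints
(tracked units are re-identified exactly), and any volume-conduction
realism in the force ramps — the twitch-summed ramp is sublinear in the
excitation, so simulated recruitment thresholds in newtons sit lower than
typical human values. Passing tests therefore validate the estimators and
the inference machinery, not the physiological realism of any particular
waveform.

For replicate-heavy statistical calibration (type-I error, power) the
package uses the metric-level samplers (`sample_subject_metric`,
`sample_mu_metric`), which draw directly from the additive-cell-means
structure the signal-level generator realises — same subject intercepts,
same multiplicative effects, i.i.d. residuals — at a tiny fraction of the
cost. Signal-level recovery is exercised separately by the
injected-parameter tests. Problem sizes in the shipped suites (20
replicates for recovery, 500/200 for calibration/power, cohorts of 2–6
subjects in end-to-end tests) were chosen as the smallest sizes at which
the quantities under test are statistically stable.

## Inference

Models are fitted with `statsmodels` `MixedLM` by REML: fixed effects of
leg, time and their interaction (sum-to-zero coding, so the single-df
Wald tests are the balanced type-III main effects), a random subject
intercept, and for MU-level responses a variance-component intercept per
MU nested within subject. Optimization tries L-BFGS then conjugate
gradients, falling back to Powell when a boundary fit (variance
component ≈ 0) makes the analytic score singular; boundary fits are
flagged `singular`, never refitted with a different structure, matching
common practice at n = 13.

Denominator degrees of freedom use a between–within (containment)
approximation: within-cluster effects get N − clusters − (p − 1), EMMs
and the intercept get subjects − 1. On the balanced 2 × 2 designs this
pipeline produces this equals the Satterthwaite df (e.g. 36 for 13
subjects × 4 cells), which is confirmed against `lme4`/`lmerTest` in the
test suite; for unbalanced MU-level data it is an approximation, chosen
because no maintained Python implementation of Satterthwaite/Kenward–Roger
exists and the df are large enough there (> 100) for the distinction to be
immaterial.

EMMs are model-based cell predictions averaged over random effects, with
t CIs on subjects − 1 df. Pairwise cell contrasts are unadjusted by
default (the reported p-values look unadjusted in this literature);
nothing in the architecture prevents adding a multiplicity adjustment at
the contrast table. Effect sizes: paired Cohen's d = mean Δ / SD Δ for
subject-level metrics (defined as 0 when post ≡ pre, undefined for a
nonzero constant shift); for nested models d = EMM contrast divided by
√(subject + MU + residual variance). Variance explained follows the
variance-partition form: R²m = var(Xβ̂)/(var(Xβ̂) + Σσ²ᵤ + σ²ₑ) and R²c
adds the random-effect variances to the numerator.

CST deltas are compared across legs with a paired t-test on per-subject
(exercise − control) deltas; ΔFR vs ΔMVC uses the product-moment
correlation with a two-sided p, requiring n ≥ 3 and non-degenerate
variance.

## Known limitations

- The turns hysteresis and the jiggle pairing convention are reasonable
  operationalizations of under-specified printed rules; both are isolated
  in single functions.
- The containment df is exact only for balanced designs (see above).
- `MixedLM` can converge to a boundary where `lme4` finds an interior
  optimum; the singular flag marks these fits.
- The CLI report renders tables only; no figures are produced.
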