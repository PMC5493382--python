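# Methods

## The model

The nine-sensor protocol defines the proximal and distal composite skin
temperatures as fixed convex combinations of site temperatures:
T_PROX = 0.324·T_A + 0.1465·(T_LIA + T_RIA) + 0.1915·(T_LMT + T_RMT) and
T_DIST = 0.25·(T_LF + T_RF + T_LH + T_RH). When a subset S of a group's
sensors is available, the composite is re-modelled as T̂ = Σ_{s∈S} w_s T_s
with the excluded sensors' weights fixed at exactly 0, and the free weights
estimated by unconstrained linear least squares against the full-set
reference: ŵ = argmin ‖T − Xŵ‖². There is **no intercept** — the model is a
pure weighted sum — and **no sum-to-one or nonnegativity constraint**: the
optimal single-sensor weights (≈ 0.98–1.04) show the unconstrained fit is
what the operative tables contain.

The design matrix X pools all subjects into per-site *macro-signals*: each
subject's retained samples are appended in ascending subject-id order, so
X is N×P with N the total number of group-complete samples in the cohort.
A row enters the design only where **every** sensor of the group — not just
the subset — is valid, so the reference T is defined at every row. The
complete-case rule is applied per group: a gap in a distal sensor never
discards proximal samples.

Numerically the solve uses SVD-based least squares (`numpy.linalg.lstsq`)
rather than inverting X′X; on full-rank designs the two coincide (asserted
in tests to 1e-8 relative), and the orthogonal route is stable when columns
are strongly correlated, as homologous sites are. A design whose smallest
singular value falls below `rank_tol = 1e-10` times the largest is rejected
as singular, naming the near-collinear columns; in a full table run such
subsets are recorded as failed rows rather than aborting the table. The
solver is packaged as a scikit-learn-style estimator
(`LinearCompositeModel`, with `fit`/`predict`/`coef_`/`get_params`) so it
composes with sklearn tooling; the module-level `fit_weights` /
`reconstruct` / `fit_all` functions are thin wrappers.

## Performance factors

For each subset: MSE = (1/N)‖T − T̂‖² (°C²), MAE = (1/N)Σ|Tᵢ − T̂ᵢ| (°C),
the 25th/75th percentiles Q1/Q3 of the **signed** error T − T̂, a day/night
MAE split, and the leave-one-subject-out cross-validation error (CVE): for
each subject, weights are re-fitted on the other subjects' pooled rows and
the held-out subject's rows reconstructed; CVE is the mean absolute
held-out error.

Choices the definitions leave open, fixed here:

- **Percentile convention**: linear interpolation between order statistics
  (`numpy.percentile` default). Any fixed convention would do; this is the
  most common and is pinned for reproducibility.
- **CVE aggregation**: all held-out absolute errors are pooled before
  averaging (default); the mean-of-per-subject-means variant is implemented
  and switchable (`aggregate="per_subject"`). With equally sized folds the
  two coincide.
- **Day/night boundary**: day is wall-clock [07:00, 19:00), night the
  complement — half-open intervals so each boundary instant belongs to
  exactly one stratum.
- **Histogram bins**: signed-error histograms use 0.0625 °C bins (one
  logger quantization step), aligned on multiples of the bin width.

Tables store weights and factors at full precision; CSV export rounds to
4 decimals. A transcription of the published protocol tables ships with the
package (`provenance="published"`) for lookup without refitting; its
day/night columns are empty because no numeric day/night values were
published.

## Preprocessing

Raw per-sensor CSVs are nearest-sample aligned onto a shared uniform grid,
tolerating clock skew up to 1.5 min (half the 3-min sampling interval);
non-overlapping sensor ranges are an error. Samples outside plausibility
bounds (default 20–42 °C, configurable) are marked invalid. Nothing is ever
interpolated: every retained sample equals a raw reading, invalid instants
propagate as gaps, and preprocessing is idempotent. The exact artifact
rules used with the original logger software are not public; the bounds and
skew tolerance here are explicit, configurable stand-ins chosen to excise
only physically impossible readings.

## Synthetic cohorts

The generator emulates the study design the analysis assumes: 13 subjects,
24 h from midday to midday, 3-min sampling (480 samples/site), values
quantized to the 0.0625 °C logger resolution. Each site follows a
single-harmonic cosinor — the simplest model with the day/night structure
the analysis probes — plus Gaussian noise with three components: a
subject-level offset (SD 0.5 °C) shared by all nine sites, a pair-level
component shared by left/right homologues, and an independent site-level
component; pair and site components are mixed as √ρ·pair + √(1−ρ)·own with
ρ = 0.85, giving homologous noise correlation ρ on top of the shared
circadian signal. Per-sample noise SD is 0.25 °C (sensor error plus
short-term vasomotor/postural fluctuation). Non-wear events (default: one
30-min event per day, e.g. showering) remove all sensors simultaneously,
carving contiguous gaps. Defaults for the per-site cosinor parameters are
physiologically plausible rather than fitted to any dataset: proximal sites
are warmer with small amplitudes (mesor 34.3–35.3 °C, amplitude
0.4–0.7 °C), distal sites cooler with large amplitudes (mesor 30.5–31.8 °C,
amplitude 1.8–2.3 °C), and all sites peak at night (acrophase 03:00–05:00).
An optional daytime noise multiplier (default 1, i.e. off) emulates
activity-driven daytime variability for studying the day/night error split.

Reproducibility: subject *i* draws from
`SeedSequence(seed, spawn_key=(i,))`, so cohorts are bit-identical across
runs and independent of generation order.

What the generator does **not** model: thermoregulatory physics, posture
and activity masking beyond non-wear gaps, skewed or multimodal noise,
sensor drift, and between-subject differences in rhythm shape. Passing
tests therefore demonstrate correctness of the estimation machinery and the
qualitative structure that follows from correlated homologues — not
calibrated accuracy values for real cohorts; the numeric MSE/MAE cells of a
fitted table are properties of whatever cohort was fitted.

## What is analytically forced vs. data-dependent

Because each reference composite is an exact linear combination of its full
sensor set, the full-set fit recovers the fixed formula weights with zero
residual on *any* full-rank cohort — this, the least-squares optimality
against a brute-force grid-search oracle, and the monotone improvement of
training MSE along nested subset chains are exact checks in the test suite.
Data-dependent quantities (per-subset MAE in °C, CVE, quartiles) are checked
qualitatively: non-homologous 3-sensor proximal placements win, hand+foot
distal pairs beat both-feet/both-hands, and CVE tracks MAE closely on
cohorts of exchangeable subjects.

## Problem sizes

Default analyses run a 13-subject × 480-sample cohort (N ≈ 6000 rows per
design, P ≤ 5), for which a full 31-subset table with cross-validation fits
in well under a second; the brute-force grid-search oracle used in tests
runs on designs with N ≤ 100, P ≤ 3.

## Known limitations

- Synthetic defaults are plausible placeholders, not calibrated to any
  recorded cohort; absolute error levels on real data will differ.
- Clock-drift correction is limited to constant-offset nearest-sample
  alignment.
- No regularized/robust regression variants and no time-lagged models; the
  estimator is intentionally the plain least-squares re-tuning the
  operative tables define.
- Confidence intervals on weights are not reported (none are defined for
  the protocol tables).
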