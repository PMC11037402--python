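# Methods

## The canonical waveform model

A pupillogram around a flash stimulus is modelled as

    D(t) = b − a1·σ((t − t1)/s1) + a2·σ((t − t2)/s2),   σ(x) = 1/(1 + e^(−x))

the sum of a falling (constriction) and a rising (re-dilation) logistic
sigmoid on a baseline `b`. Physiological constraints are imposed as hard
bounds during fitting: `s1, s2 > 0`, `t2 > t1`, `0 ≤ a2 ≤ a1` (the pupil
recovers at most back to baseline — no overshoot) and `b − a1 > 0` (the
trough asymptote stays positive). Internally the fitter parameterises
`a1 = u·b` with `u ∈ [0, 0.95]` and `a2 = r·a1` with `r ∈ [0, 1]`, which
turns all the coupled constraints into box bounds for a trust-region least
squares solve. Initial values come from the trace itself (pre-flash mean,
trough depth and timing) refined over a small fixed grid of constriction
time scales (0.05/0.1/0.2 s) and re-dilation delays (0.7/1.2 s); there is
no random restart, so a given trace always produces the bit-identical fit.
Fits that hit their bounds are flagged in the diagnostics, not rejected.

## Parameter extraction

INIT, END and CAMP follow their sample-based definitions: INIT is the mean
over the first 250 ms of the trace, END the median of a 130 ms window
centred on the post-flash minimum (searched within 1.5 s of flash onset,
window clipped to the trace), CAMP = INIT − END. A trace whose minimum
never drops below baseline is flagged non-constricting and reports
END = INIT, CAMP = 0. The remaining parameters come from the fitted model,
which is far less noise-sensitive than frame-to-frame differences:

* FIN is the model asymptote `b − a1 + a2`.
* MCV/PDV are the extrema of the analytic derivative on a dense grid,
  split at the trough: MCV is the most negative value before it, PDV the
  most positive after it. MCV is stored signed (≤ 0); magnitude accessors
  exist on the parameter type.
* LAT is the time after flash onset at which the constriction sigmoid has
  delivered 1 % of `a1`, i.e. `t1 − s1·ln 99 − onset`. The 1 % threshold is
  a configurable operationalisation of "commencement of constriction"; a
  model-based onset was chosen over a raw-trace one because the raw onset
  is undefined at realistic noise levels.
* T75 is the first time after the trough at which the model reaches
  END + 0.75·CAMP, minus the trough time, found by bisection on a dense
  bracket. The search extends 60 s past the trough (the model is analytic
  beyond the trace); if the asymptote never attains the threshold the value
  is NaN and flagged unreached. Because the asymptotic recovery fraction
  `a2/a1` can sit close to 0.75, unreached flags are an expected, not an
  exceptional, outcome on shallow re-dilations.

## Lighting correction

Each parameter except INIT is corrected with a two-step scheme. A
regression model predicts the parameter from the baseline diameter B
(the INIT measurement) and the camera exposure E, using a 12-term candidate
pool: B, E, B², E², B⁻¹, E⁻¹, log B, log E, (log B)², (log E)², B·E and
log B·log E. Model structure is ranked by Gaussian BIC
(`n·ln(RSS/n) + k·ln n`, k counting the intercept). Because the full pool
has only 2¹² = 4096 subsets, the default search enumerates all of them
exactly — the stepwise forward/backward search exists only as a fallback
for larger pools, and by construction the default ranking coincides with
brute-force enumeration. The leading 250 subsets are refit with LASSO
(α = 0.006 on internally standardised features, coefficients reported on
the original scale, zeroed terms dropped), and the winner is the candidate
with the smallest leave-one-subject-out cross-validated MSE, ties broken
toward fewer terms and then better BIC rank. The winning model stores the
training grand mean of the parameter and the correction is

    corrected = average + measured − predicted,

which replaces the lighting-explained part of a measurement by the
training-population mean while preserving the subject's deviation from the
norm exactly (the map is shift-equivariant in the measurement).
`correct_dataset_loso` repeats the whole selection per held-out subject so
no recording is ever corrected by a model that saw its own subject;
`fit_correction_models` + `apply_correction_models` cover the deployment
case where the correction is trained on one cohort and applied to another
(disjoint subjects give the same leave-subject-out guarantee).

Light dependence before/after correction is quantified by the F statistic
of a categorical illumination factor in an OLS model with per-subject
intercepts — a fixed-effect approximation of the random-intercept model
that is exact for balanced designs. (One source describes the test with a
random slope as well; we implement the stated model formula, which has
intercepts only.)

## The PuRe score

The published raw score is the linear combination

    PuRe = 0.007·INIT − 2.438·END_c + 2.773·FIN_c + 0.838·MCV_c
           + 1.239·PDV_c + 2.604·CAMP_c

with no intercept; LAT_c and T75_c are not inputs. INIT enters
uncorrected. MCV_c enters as constriction *speed* (a magnitude): the
positive coefficient only rewards brisk constriction if the input grows
with constriction velocity, and clinical pupillometers conventionally
report constriction velocity as a positive speed. Since stored MCV is
signed and non-positive, and the correction chain is equivariant under a
sign flip of the response, the corrected speed is exactly `−mcv_c`; the
scoring pipeline applies that negation.

The 0–5 scale is a piecewise-linear map calibrated on raw-score samples
from reactive ("pre") and unreactive ("post") recordings. With m = sample
median and s = sample standard deviation (n−1 denominator), the anchors are

    (m_post − 3s_post → −0.5), (m_post − s_post → 0.2), (m_post → 0.8),
    (m_post + s_post → 1.0), (0 → 3.0), (m_pre − 3s_pre → 4.0), (m_pre → 4.5)

interpolated linearly, extrapolated beyond the end anchors with the
adjacent segment's slope, and clamped to [0, 5]. The anchors must be
strictly increasing in raw score — a calibration whose post-distribution
median is non-negative is rejected with diagnostics rather than silently
producing a non-monotone scale. On the result, 0 is a non-reactive pupil,
(0, 3) an abnormal/sluggish response and [3, 5] normal; the scaled 3.0
boundary coincides with raw 0.

`train_pure_model` re-derives a score of the same family: logistic
regression with an L1 penalty (α = 0.006) on the expanded feature set
(base parameters, their squares, inverses and pairwise products), solved
by L-BFGS-B on the positive/negative split of the weights so the L1 term
is exact. The light-invariance penalty is γ times the variance of
per-illumination-level mean scores over the reactive class — a
differentiable, scale-aware choice among the many penalties consistent
with "a penalty for light dependence"; γ defaults to 0 and the published
coefficients are never mutated by training. The default feature set
mirrors the published inputs (INIT plus END/FIN/CAMP/MCV/PDV corrected):
T75_c is NaN whenever a recording is non-constricting, so including it by
default would discard exactly the unreactive class the model must learn;
it can be opted in for cohorts where it is finite.

## The synthetic cohorts

The generator's defaults are the study conditions the rest of the package
is validated under:

* Lighting study: 9 subjects × 8 illuminance levels (5, 16, 43, 112, 380,
  1343, 3900, 10000 lx — log-spaced over the studied range, including the
  commonly reported 5/112/1343 lx conditions) × 5 repeats = 360
  recordings; 5 s at 60 Hz with a 1 s flash starting at 1 s.
* Clinic cohort: 15 patients × 2 eyes × pre/post mydriatic = 60
  recordings, each under uniform 12–120 lx clinic lighting.

Per subject, a Hill-type sigmoid in illuminance sets the baseline diameter
(dark-adapted d_max ~ U(6, 8) mm, bright floor d_min ~ U(2, 3) mm,
half-constriction illuminance U(60, 200) lx, exponent U(0.6, 1.0)). The
flash response amplitude is `amp_gain·(b − d_min)` with gain U(0.6, 0.9),
`a2 = 0.8·a1`, and the re-dilation midpoint trails the constriction
midpoint by 1.3 s. Latency (offset U(0.50, 0.62) s) and both time scales
(s1 ~ U(0.060, 0.085) s, s2 ~ U(0.22, 0.35) s) drift upward with
log-illuminance (through z = log10(1 + lux)/4, slopes 0.10 s, 20 % and
25 %), so that *every* extracted parameter — not only the size-derived
ones — carries a light dependence for the correction stage to remove.
These ranges put INIT, CAMP, MCV, PDV, latency and recovery time in the
ranges adult pupillometry reports. Camera exposure is `1000/(1 + lux/50)`
firmware units with 3 % multiplicative log-normal jitter. Measurement
noise is i.i.d. Gaussian per frame, 0.05 mm by default. Mydriasis
multiplies the response amplitude by δ = 0.02 and pins the baseline at
95 % of the way from d_min to d_max, emulating a fixed dilated pupil.

Every random draw flows from the master seed through named substreams
(CRC-keyed `SeedSequence`s), so a configuration reproduces its dataset
exactly across processes; ground-truth waveform parameters are emitted per
recording for oracle tests.

What the generator does *not* emulate: blinks and tracking artefacts
(optional NaN-gap handling is out of scope), consensual coupling between
eyes, pharmacokinetic time courses, photometrically calibrated retinal
illuminance, and any real camera's exposure semantics. Passing tests
therefore demonstrate that the computation chain is correct and
light-invariant *under its own assumptions*, not that the published
coefficient values transfer to data from any particular device.

## Numerical choices and problem sizes

* BIC uses the Gaussian profile form without the additive constant
  (rank-invariant either way); RSS is floored at 1e−12 to keep perfect
  fits finite.
* LASSO inner cross-validation fits use a Gram-precomputed coordinate
  descent with tolerance 1e−4 (final refit 1e−5); subset RSS during
  enumeration comes from normal equations on the standardised Gram matrix
  with a pseudo-inverse fallback for collinear subsets.
* The noisy-recovery check is operationalised as the mean relative error
  over 20 seeded replicates per parameter (a per-replicate bound would
  test the noise draw, not the estimator).
* Time-grid densities: 2001 points for velocity extrema, 4001 points over
  60 s for the T75 bracket, refined by `brentq`.
* CSV output uses 9 significant digits; model JSON round trips are exact.
* Default problem sizes (360 + 60 recordings, 4096-subset enumeration,
  250 LASSO candidates × 9 folds) keep a full end-to-end run in the
  low minutes on one core; the leave-one-subject-out correction of the
  lighting study (63 model selections) is the single most expensive step.

## Known limitations

* The published coefficients were derived on real patient data from one
  device; this package reproduces the formulas and the pipeline, and its
  synthetic experiments mirror the qualitative findings (strong F
  reduction under correction, perfect pre/post separation), not the
  printed per-parameter F and R² values, which are functions of data not
  contained in the formulas.
* Exposure is treated as an opaque positive scalar; no firmware semantics
  are assumed and no per-device recalibration database is provided.
* The random-intercept F-test approximation is exact only for balanced
  designs; heavily unbalanced cohorts (high dropout) shift the F values
  slightly.
* T75 on shallow re-dilations is intrinsically ill-conditioned (the
  threshold sits near the asymptote), which is why the corrected T75
  carries the weakest light-invariance improvement of the seven
  parameters.
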