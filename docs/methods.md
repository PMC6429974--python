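# Methods

## The staging problem

A subject undergoing progressive central blood-volume depletion passes
through states that arterial pressure alone reports poorly: mean and
systolic pressure are defended by the baroreflex until late, while the
*shape* of the per-beat pressure wave changes continuously — pulse pressure
falls with stroke volume, the dicrotic notch fades as vasoconstriction and
reduced ejection reshape the reflected wave, and systole occupies a larger
fraction of the shortening cardiac cycle. `pulsestage` casts tracking of
this process as ordinal classification: class 0 is supine baseline
(normovolemia), classes 1–3 are the first, second and third tertile of
elapsed time under the hypovolemic stimulus, so "severity" is defined purely
chronologically and the classifier must recover it from morphology alone.
The per-beat predictions are deliberately noisy; the quantity of interest is
the smoothed, model-averaged trace in [0, 3], read as a continuous severity
estimate.

## Pipeline

**Beat segmentation.** Upstrokes are maxima of the 10-Hz low-passed first
difference of the pressure signal, with a 0.25-s refractory period and an
adaptive height threshold (20% of the 99th percentile of positive slopes).
Each beat's foot is the pressure minimum in the 0.3 s before its upstroke,
located on the smoothed signal and refined ±3 samples on the raw signal.
Beats outside 0.25–2.5 s duration or with pulse pressure < 10 mmHg are
rejected; beats whose half-open span `[onset, onset+duration)` overlaps a
calibration interval are removed. A signal with total range < 1 mmHg yields
no beats (flat-line guard).

**Normalization.** Each beat is resampled to exactly 33 points, endpoints
inclusive, with shape-preserving monotone cubic Hermite interpolation
(Fritsch–Carlson tangents, `scipy.interpolate.PchipInterpolator`): the
interpolant cannot overshoot the raw range, reproduces linear segments
exactly, and is the identity when the beat already has 33 samples.
Amplitude is *not* rescaled — absolute mmHg values are informative and enter
the model as-is. The choice of an endpoint-inclusive grid (rather than
half-open) is a dialect decision; nothing downstream depends on it beyond
reproducibility.

**PCA.** Covariance PCA (scikit-learn, full SVD) of the n×33 matrix; no
standardization, since all 33 features share units. Components are
sign-fixed so the largest-magnitude loading is positive, making the basis
deterministic across solvers. By default the basis is fitted per
leave-one-subject-out fold (no test-subject leakage, enforced by a
`fitted_on` tag checked at projection time); `pca_scope: global` switches to
a single PCA over all data for fidelity with analyses that parametrized the
full matrix once. Default k = 5 scores per beat; the
`component_addition_curve` utility reports κ/accuracy/MSE as k grows.

**SVM.** One-vs-one soft-margin linear SVM: for each of the six class
pairs a separator minimizing ½‖w‖² + C·Σξᵢ (libsvm via scikit-learn,
tolerance 1e-4 in the pipeline, tighter in oracle tests). Prediction is
majority vote over the six separators; vote ties and zero decision values
resolve to the lower class index — deterministic and conservative about
alarming. C defaults to 0.01; the canonical grid {0.001 … 100} is swept by
`c_grid_sweep` with identical subsample draws at every C so that C is the
only varying factor. No class weights, no probability calibration, no
feature rescaling (a config switch enables standardization if wanted).

**Evaluation protocol.** For each held-out subject: pool the beats of all
*other presyncope* subjects (tolerant subjects never train — their labels
presume a progression they did not complete); draw 10 independent
subsamples of ⌈10%⌉ of the pool without replacement (a draw containing
fewer than two classes is redrawn, at most 100 times; a `with_replacement`
switch restores classical bootstrap resampling); train one SVM per
subsample; predict every held-out beat with each model; smooth each
discrete trace with a *trailing* 20-beat moving average (early positions
average available history) and average the ten smoothed traces.
Smoothing and averaging are both linear, so their order is immaterial
(asserted in tests). Per-class accuracy uses the averaged trace rounded
with x.5 toward the lower class; per-class MSE uses the continuous trace
(the only reading that produces sub-unit per-class errors). Cohort tables
report median [IQR] across presyncope subjects; κ is computed once from the
pooled (summed) confusion matrix, not averaged across subjects. All
subsample draws derive from `SeedSequence(seed, spawn_key=(subject_index,))`,
so runs are bit-reproducible and sweeps over C or k reuse identical draws.

**Severity trend.** A subject is called *increase* when the averaged trace
over the final 10% of the LBNP segment exceeds **both** the baseline mean
and the mid-LBNP mean (window 40–60% of the segment) by ≥ 0.5 classes;
otherwise *stagnation*. The two-reference rule is deliberate: the tolerant
phenotype is a trace that rises early and then flattens at a sub-maximal
level, which a baseline-only comparison would misread as progression. Both
deltas, the tail fraction and the mid window are exposed in `EvalConfig`.

**Presyncope detector.** Disjunction of four criteria evaluated beat-wise:
SAP below 80 mmHg; and trailing-60-s total declines (window maximum minus
current value) of SAP ≥ 25 mmHg, DAP ≥ 15 mmHg, or HR ≥ 15 bpm. While less
than 60 s of history exists only the absolute floor is evaluated. The
windowed-decline reading of "per minute" rates is robust to beat-level
noise; the disjunctive combination follows the convention for safety-abort
criteria. Rate criteria are invariant to time translation and to common
additive offsets; the floor is intentionally not offset-invariant.

## Synthetic cohort generator

The generator produces the statistical structure the pipeline assumes, not
cardiovascular mechanics. Each beat is three additive components: a
raised-cosine-squared systolic upstroke, an exponential diastolic run-off
pinned to zero at both beat ends (consecutive beats join continuously at the
diastolic foot), and a Gaussian dicrotic wave at 38% of the reference cycle
whose amplitude is 20% of pulse pressure at severity 0. Systolic-peak and
notch times scale with the square root of the cycle length (the classical
ejection-time relation), so tachycardia shifts morphology in normalized
time. A latent severity s(t) ∈ [0, 1] is 0 at baseline, jumps by 0.2 over
the first 20 s of LBNP (the chamber pressure is established within tens of
seconds and translocates blood immediately), and ramps the remaining 0.8 as
((t−onset)/T)² toward 1 at the subject's ramp duration T ~ N(900, 180²) s.
Severity drives: pulse pressure −45% at s = 1 (DAP held), dicrotic amplitude
−90%, HR +30 bpm. Presyncope subjects then enter a terminal vasodepressor
collapse — SAP and DAP falling at 30 mmHg/min — and the recording ends at
the first beat on which the package's own presyncope detector fires on the
programmed per-beat series, which guarantees generator/detector consistency
by construction. Tolerant subjects plateau at s = 0.5 and complete the full
30-min LBNP phase. Beat-to-beat period jitter is 2% (i.i.d. Gaussian);
additive measurement noise is 2 mmHg SD; every 70 s a 2-s flat-line
calibration artifact is written into the signal and (by default) listed in
the recording's artifact intervals.

Cohort defaults — 15 subjects (12 presyncope, 3 tolerant), 5-min baseline,
200 Hz, baseline hemodynamics 120/70 mmHg and 65 bpm with between-subject
SDs of 4/3 mmHg and 5 bpm — describe a screened, homogeneous young-adult
cohort. The SDs are a deliberate design point: the evaluation protocol
trains on at most 11 subjects per fold, which cannot marginalize large
between-subject baseline offsets, and the package's recovery guarantees are
stated for a regime in which severity-driven morphology change dominates
between-subject morphology variance. Raising these SDs toward
population-level values (≈ 8/6 mmHg, 7 bpm) yields a markedly harder task
(pooled κ ≈ 0.4) and is the better emulation of an unscreened cohort.

**What passing tests do and do not show.** The generator's morphology drift
is low-dimensional (pulse-pressure scaling, notch amplitude, systolic
timing) and monotone in a scalar severity; real waveforms carry
respiration, movement artifacts, baroreflex oscillations, and
subject-specific response *shapes*, none of which are emulated. Recovery
results on this cohort therefore demonstrate that the pipeline's mechanics
are correct and leak-free — not that the method attains any particular
accuracy on human data.

## Numerical choices and degenerate inputs

Seconds everywhere; intervals half-open [start, end). Signal CSVs are
written with 12 significant digits (round-trip < 1e-9 mmHg) and sampling
uniformity is enforced at 1 ppm on read. κ returns 0 by convention when
chance agreement is 1 (single-cell confusion). PCA refuses all-identical
beats (zero variance); the SVM refuses single-class or non-finite input;
flat recordings yield zero beats with a warning, and subjects with no usable
beats are excluded from the beat matrix with a warning. The pipeline's
global seed derives the generator stream (seed) and evaluation stream
(seed + 1).

## Problem sizes

The bundled study conditions produce ≈ 25,000 usable beats across 15
subjects (≈ 1,400 per presyncope subject, ≈ 2,300 per tolerant subject);
the full leave-one-subject-out evaluation trains 150 SVMs on subsamples of
≈ 1,500 beats × 5 features and completes in well under a minute on one CPU.
The feature-saturation analysis uses a reduced cohort (8 presyncope
subjects, 2-min baseline, fixed 7-min ramp) with between-subject SDs set to
zero so that morphological variation is confined to the three
severity-driven modes plus noise.

## Known limitations

- Class tertiles are arbitrary time cuts through a continuous process;
  beats near tertile boundaries are intrinsically ambiguous, which bounds
  attainable per-beat accuracy (and κ) well below 1 regardless of model
  quality. The middle classes are always the hardest.
- The trailing moving average lags the underlying state by ~half a window
  (~10 beats), slightly penalizing accuracy just after each class boundary.
- The linear SVM sees absolute mmHg PCA scores; it compensates for
  between-subject offsets only to the extent the training pool spans them.
- The severity-trend rule is a design choice (no canonical definition
  exists); its two thresholds are configuration, not estimates.
- WFDB-format input is not supported; signals are exchanged as two-column
  CSV plus a YAML marks document.
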