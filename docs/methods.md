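# Methods

## Problem and pipeline

`vmstress` classifies stressed vs. non-stressed performers of a short
mental-arithmetic task from multichannel physiological recordings (20 EEG
channels plus one ECG lead, one 180 s baseline trial and one 60 s task
trial per subject, labels G = good/non-stressed and B = bad/stressed from
a subject-info table). The pipeline is:

1. **Variational mode decomposition (VMD).** Each channel is decomposed
   into `K` band-limited modes `u_k` with center frequencies `w_k` by
   minimizing the summed bandwidths of the analytic, baseband-demodulated
   modes subject to `sum_k u_k = f`, solved with the standard ADMM scheme
   in the frequency domain (Wiener-filter mode updates, spectral-centroid
   frequency updates, dual ascent with step `tau`).
2. **Second-order-difference Poincaré plots.** For each retained mode,
   `X(t) = x(t+1) - x(t)` is plotted against `Y(t) = x(t+2) - x(t+1)`.
3. **Descriptors.** Per plot: the dispersion-ellipse area `pi*a*b` with
   `a, b` the square roots of the eigenvalues of the raw second-moment
   matrix `[[SX^2, SXY], [SXY, SY^2]]`; the mean radial distance `m`; and
   the central tendency measure `CTM(r)`, the fraction of points strictly
   inside radius `r` (default 0.5).
4. **Balancing and screening.** Minority-class subjects are replicated
   (whole-subject, channel-wise, fresh ids) to class parity; each
   descriptor column is screened with the two-sided Wilcoxon signed-rank
   test at `alpha = 0.05`, pairing the two class samples positionally
   after deterministic sorting.
5. **Classification.** Per (brain-region, mode-group) subset the rows are
   flattened into one vector per subject-trial, standardized with
   training-set statistics only, and classified with an MLP (3 hidden
   layers x 10 ReLU units, Adam, learning rate 1e-3, L2 1e-4, 200
   iterations) or an RBF SVM (C = 0.90, gamma = 0.02, iteration cap 100,
   tolerance 1e-3), under a stratified subject-level 70/10/20 split or
   10-fold cross validation with pooled fold predictions. Reported:
   sensitivity, specificity, accuracy (percent), F1, Cohen's kappa.

## Model assumptions

The discriminative signal is assumed to live in the *variability* of the
oscillatory modes, not their mean amplitude: a mode whose amplitude
envelope fluctuates more produces larger successive differences, hence a
wider Poincaré cloud, larger ellipse area and mean distance, and lower
CTM. The classifiers only need this second-order structure; no
phase-locking, connectivity or nonstationarity model is assumed.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `K` | 10 | modes extracted per channel; features keep modes 1–8, the low-to-mid modes that carry structured energy |
| `alpha` | 2000 | VMD bandwidth penalty; conventional value giving well-separated narrowband modes |
| `tau` | 0 | dual-ascent step; 0 tolerates broadband noise instead of forcing exact reconstruction (the residual is always reported) |
| `tol` | 1e-7 | ADMM stopping tolerance on relative mode change |
| `r` | 0.5 | CTM radius, in the signal's amplitude units |
| `alpha` (screen) | 0.05 | two-sided significance threshold (95% confidence) |
| split | 70/10/20, k=10 | subject-level, stratified, seeded |

VMD hyperparameters are config-overridable everywhere; the sampling rate
is always taken from the EDF header.

## Numerical choices

* **Mirror extension** of half the signal length on each side before the
  FFT softens boundary artifacts; modes are cropped back afterwards.
* **Mode ordering** is by ascending converged center frequency regardless
  of initialization, so "mode 1" is always the lowest-frequency mode.
* **Degenerate eigenvalues**: round-off can push the ellipse's small
  eigenvalue slightly negative; it is clamped by absolute value, which
  also guarantees real radii for exactly collinear clouds (area 0).
* **Wilcoxon zeros and ties**: zero paired differences are dropped before
  testing; the exact null is enumerated for n <= 25 informative pairs, the
  normal approximation with continuity correction is used beyond. A
  feature with fewer than two nonzero differences is reported untestable
  and not retained.
* **Undefined rates** (empty denominator) are reported as `None` with a
  flag, never coerced to zero.
* **EDF quantization**: the writer maps each channel's physical range to
  the full 16-bit digital range; physical bounds are serialized in <= 8
  ASCII characters rounded *outward* so no sample leaves the stored range.

## Design choices where the design was open

* **Instance unit and leakage.** The classification instance is the
  subject-trial feature vector, and all splits are at the subject level so
  a subject (or its balancing replica's source) never appears on both
  sides of a split boundary within one fold assignment. Replicas are
  treated as new subjects, mirroring a dummy-participant protocol.
* **Validation partition.** scikit-learn's MLP cannot consume an external
  validation set, so the 10% partition is scored after fitting and
  reported as `validation_accuracy`, a monitoring diagnostic; it never
  influences training. The SVM ignores it.
* **Mean distance and r.** `m` is the mean Euclidean norm of plot points
  and does not depend on `r`; `r` is carried as metadata because the
  feature-map convention tags both `m` and `ctm` with it.
* **SVM epsilon / iteration limit.** The configured `epsilon = 0.1` is a
  regression-style parameter that is inert for classification; it is kept
  in the config for fidelity and documented as inert. The iteration limit
  maps to the solver's cap, which can stop the solver early (flagged).
* **Gender subsets** are implemented (`good_vs_bad_female/male`) but
  expected weak; balancing replicas carry no gender and are excluded from
  gender-filtered comparisons.
* **Screening is a report, not a filter**: all three descriptors are
  passed to the classifiers, matching the protocol the package implements;
  the screen documents their individual significance.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *layout* and the *statistical mechanism* the
pipeline exploits: 21 named channels (7 frontal, 4 temporal, 3 central,
3 parietal, 2 occipital, 1 behind-ear, 1 ECG), two trials of differing
duration in a 3:1 ratio, a fixed sampling rate, and two subject classes.
Each EEG channel is a sum of amplitude-modulated narrowband oscillations
at 4, 8, 12, 20 and 30 Hz (classical theta–beta rhythms) plus white
noise; stressed subjects draw their slow envelope modulation with variance
multiplied by `1 + effect_size`. The ECG channel is a ~1.1 Hz jittered
spike train with the same class-dependent modulation. Defaults are 26
non-stressed + 10 stressed subjects and 180 s / 60 s trials, mirroring
the emulated cohort; `fs` defaults to 128 Hz, a desk-scale rate that
keeps all bands below Nyquist.

Not emulated: volume conduction and channel correlation, 1/f background
spectra, artifacts (blinks, EMG), nonstationary band power, realistic ECG
morphology. Passing tests therefore demonstrate that the pipeline detects
class differences in mode-wise amplitude variability under controlled
conditions — not that comparable accuracy is attainable on any particular
real dataset.

## Reference experiment sizes

The packaged experiments (`vmstress.experiments`) fix desk-scale problem
sizes chosen so the full pipeline runs on one CPU in minutes:

* *cohort*: 10+10 subjects, full 21-channel montage, 12 s baseline / 4 s
  task at 128 Hz, K = 10 with modes 1–8 kept, MLP, 10-fold CV. Used for
  the strong-effect (accuracy >= 95% at effect size 3) and null-effect
  (accuracy within the binomial 95% interval of chance) demonstrations.
* *dose-response*: 6+6 subjects, 5-channel montage (one per region plus
  ECG), 6 s / 2 s trials, 6-fold CV, effect sizes {0, 0.5, 1, 2, 3} x 10
  seeds; checks that median pooled accuracy is nondecreasing in effect
  size.

VMD in these experiments runs with `max_iter = 200`; convergence flags
are carried through the reports.

## Known limitations

* The MLP frequently exhausts its 200 iterations on small samples; this
  is reported as a flag rather than silently extended, because the
  iteration budget is part of the protocol.
* Exact signed-rank enumeration assumes no ties among nonzero absolute
  differences; with continuous descriptors ties have probability zero,
  but discretized inputs would silently degrade exactness.
* The EDF writer supports integer sampling rates and whole-second
  recordings (one data record per second) — sufficient for the layouts
  the package targets.
* With `tau = 0` the decomposition does not reconstruct the input
  exactly; the unmodeled remainder is returned in `VMDResult.residual`
  and never dropped.
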