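# Methods

This note documents the models, the generator, the numerical choices and
the limits of what the test suite shows. Symbols: `X` sensor data
(channels × samples, µV), `w` a spatial filter (column of the unmixing
matrix `W`), `a` a spatial pattern (column of `A`), `z` the z-scored 1-Hz
arousal target, `C(e)` the covariance of epoch `e`.

## Data model and the synthetic generator

One "subject" is a 270-s, 30-channel recording at 250 Hz structured as
ride (148 s) – break (30 s) – ride (92 s), plus a 1-Hz arousal rating on
a 50-step 0–100 dial. The generator (`alphadec.synth`) emulates the
features the analyses rely on:

- **Arousal trace.** Gaussian-smoothed noise (bandwidth `smooth_s`, default
  8 s — the autocorrelation of real dial traces is not characterized, so
  this is an explicit knob, not a fixed constant) riding on per-phase
  offsets (45 / 15 / 65 rating units: first ride moderate, break low,
  second ride high), clipped to [0, 100] and quantized to the dial grid
  *after* smoothing, matching the order of operations of a physical dial.
- **Alpha sources.** `n_alpha_sources` (default 4) narrowband noise
  sources with a Gaussian amplitude spectrum (σ = 0.8 Hz) centred at the
  configured individual peak (default 10 Hz), so essentially all power
  lies within peak ± 2 Hz and the spectral argmax is well defined. The
  first source is the *arousal source*: its amplitude envelope is
  `1 − κ·z₀₁(t)` with `z₀₁` the min–max-normalised trace and
  `κ = coupling_kappa ∈ [0, 1]`; κ = 0 is the null model. Linear coupling
  is the simplest monotone inverse relation, which is all the hypothesis
  asserts. Three uncoupled alpha sources are planted alongside because
  the component-selection rule requires at least four credible alpha
  components per kept subject; with a single planted source every
  synthetic subject would be excluded by the study's own rule.
- **Background.** `1/f^b` sources (default slope 1, FFT spectral
  shaping) carry the aperiodic spectrum; sensor noise is white Gaussian
  (the aperiodic structure is already in the background sources).
- **Mixing.** Patterns are channel-index-smoothed Gaussian weights
  (neighbouring montage entries are spatially close), with a 3× weight on
  centro-parietal/occipital channels for alpha sources. No lead-field
  model is in scope; patterns are "plausibly blurred", not biophysical.
- **Amplitudes.** Alpha sources 8 µV, background 12 µV, sensor noise
  2 µV (1 µV in the recovery studies' "high SNR" condition). Chosen once
  so that a typical subject's channel spectra show a visible alpha bump
  over the 1/f background, comparable to clean adult EEG.

`GroundTruth` returns the mixing matrix, the arousal source's column and
its envelope, so recovery is measured as |cosine| between estimated and
planted patterns (sign/scale are not identified in any of these models).

What the generator does **not** emulate: ocular/muscle artifacts, head
movement, line noise, non-stationary background, volume-conduction
physics, inter-subject variability in montage or rating style. Passing
tests therefore show the *estimators* behave correctly under the assumed
data model, not that real-data performance is guaranteed.

## Preprocessing

Cropping removes 2.5 s at each ride edge and keeps the first 30 s of the
break (raw input only; generator output is born cropped, and the
operation is idempotent via a `cropped` flag). Ratings are averaged in
non-overlapping 1-s windows. The 100-µV screen flags epochs on any
channel except the frontal eye-proxy set (Fp1, Fp2, F7, F8); subjects
with > 90 flagged epochs (a third of the data) are excluded. The screen
feeds only the exclusion rule here — artifact cleaning itself (robust
referencing, ICA) is out of scope, so flagged epochs are *not* removed
from decoding input. The tertile split is rank-based with stable ties
(earlier epoch → lower tertile): it guarantees 90/90/90 at n = 270 and is
deterministic; value-based cuts would not guarantee balanced classes.

## Spectra and the aperiodic model

Welch PSD: 5-s Hann segments, 50% overlap, density scaling. The
aperiodic component is the two-parameter power law
`log p(f) = −log a − b·log f` (natural log throughout; the choice of base
only rescales thresholds consistently), fitted by least squares on
(log f, log p) over 0–40 Hz excluding ±4 Hz around the alpha peak and the
zero-frequency bin. This one model serves both peak detection (argmax of
the detrended residual in 8–13 Hz, no minimum-prominence requirement —
boundary argmax is returned and low prominence merely logged) and
component selection, rather than pulling in a separate multi-peak
parameterization for one of the two jobs. In the pipeline the peak is
located in two passes: a rough fit without exclusion window locates a
provisional peak, then the fit is repeated excluding ±4 Hz around it.

## SSD

Band filters are zero-phase Hamming-windowed sinc FIRs with 1-Hz
transition width (≈ 825 taps at 250 Hz), applied to the continuous signal
before epoching. The eigenproblem is posed as `(C_s, C_n)` — identical
eigenvectors to `(C_s, C_s + C_n)` with monotonically related
eigenvalues — after whitening by the signal covariance with rank
truncation at eigenvalue ratio 1e-10 of the largest. Patterns come from
the (pseudo-)inverse of the full rank-restricted filter matrix.
Component spectra for selection are computed from **broadband**
projections `WᵀX` (the 1/f background must be visible for detrending);
decoding uses the signal-band projections.

Selection: (A) detrended peak within α_i ± 2 Hz > 0.35, on the
natural-log residual scale — the printed units of this constant are
ambiguous in the source material (µV²/Hz vs V²/Hz, applied after log
detrending), so it is exposed as a parameter with 0.35 as default; and
(B) after z-scoring the detrended spectrum over the full 0–40 Hz fit
range (the alternative — z-scoring only a display window — is narrower
and less stable), the in-window peak exceeds the larger of the two
adjacent 2-Hz flank means by ≥ 1.45. Subjects need ≥ 4 selected
components.

## SPoC

Filters solve `C_z w = λ C̄ w` with `C_z = ⟨z(e)C(e)⟩` and are normalized
to `wᵀC̄w = 1`, which makes each λ *equal* the population covariance
between z and the component's per-epoch variance — a self-consistency
contract asserted to 1e-6 in the tests. The most negative λ is retained
(directed hypothesis: high arousal, low alpha power). Surrogate targets
randomize Fourier phases while preserving amplitudes (DC and Nyquist bins
kept, so the surrogate is exactly real with identical mean, variance and
autocorrelation); each of the `n_perm` permutations re-runs the full
decomposition — re-correlating a fixed component against shuffled targets
would understate the selection flexibility of the null. The p-value uses
the +1 permutation correction, `p = (#{r_perm < r_obs}+1)/(n_perm+1)`.
The z normalization is a z-score. A constant estimated power series
yields r = 0 by convention (it carries no comodulation). The group test
subtracts each subject's own surrogate mean from their observed r and
runs a lower-tailed one-sample t on the differences — the per-subject
null mean is the natural pairing; a pooled constant would mix subjects
with different null centres.

## CSP, LDA, cross-validation

Class-mean covariance = mean of per-epoch covariances. All CSP
quantities (filters, class means, log-variance features
`log wᵀC(e)w`) are functions of the per-epoch covariances alone, so CV
and permutation loops consume a precomputed covariance stack; features
via the tensor path use population variance (the ddof convention shifts
all features by one additive constant, to which LDA is invariant). LDA
uses the closed-form Ledoit–Wolf shrinkage intensity on class-centred
training data. Randomized 10-fold CV is stratified by class (the source
material does not say; at 90+90 epochs unstratified folds can end up
heavily unbalanced, and stratification is flagged as the package's
choice). Sub-blocked CV: 3 contiguous sub-blocks, fold f concatenates
the f-th chunk (length n/30) of each sub-block; remainders extend each
sub-block's final chunk so folds always partition the epochs. SMOTE
(k = 5 minority neighbours, convex interpolation; duplication fallback at
a single minority sample) balances training folds only; test folds stay
unbalanced and are scored by ROC-AUC with "high arousal" positive and
signed LDA decision values as scores; single-class test folds are
skipped with a warning. Block permutation shuffles 10 contiguous label
blocks with internal order intact; p-values use the +1 correction.

## LSTM

Implemented directly on numpy arrays (forward, backpropagation through
time, Adam); gradients are verified against central finite differences.
Architecture grid as in the study design: 1–2 LSTM layers then 1–2 FC
layers with sizes from {10, 15, 20, 25, 30, 40, 50, 65, 80, 100},
non-increasing (bottleneck); ReLU or ELU between layers; scalar tanh
output matched to ±1 labels with MSE loss; L1/L2 regularization with
Λ ∈ {0, 0.18, 0.36, 0.72, 1.44}; Adam with lr ∈ {1e-2, 1e-3, 5e-4};
mini-batches of 9; 20 passes. The 270 × 250 × 10 tensor is built first
(zero-padded component slots), then mid-tertile rows are dropped. Each
used component slot is scaled to unit overall standard deviation —
µV-scale inputs saturate the gate nonlinearities and stall learning. An
output of exactly 0 maps to the positive class (a measure-zero event
needing a deterministic rule). Cross-validation reuses the CSP
randomized 10-fold split object so model accuracies are comparable
within subject. The two-step random search evaluates `n_draws` sampled
configurations on a subject subset, pools each subset subject's two best
and re-evaluates the pooled candidates on everyone; selection is mean CV
accuracy with draw-order tie-breaks. Default architecture for the sanity
studies: one 25-unit LSTM + one 10-unit FC, lr 1e-3, no regularization.

## Statistics

Exact binomial tests sum the pmf directly (two-sided by default — the
chance-level null is undirected; a one-sided flag exists), verified
exhaustively against brute-force summation for n ≤ 200. Group means use
upper-tailed one-sample t vs 0.5. The 2×2 repeated-measures ANOVA uses
the per-subject contrast identity (for two-level within factors each
effect's F(1, n−1) is the squared paired t on the corresponding
contrast), cross-checked against pingouin in the tests. Cross-model
correlations are Bonferroni-corrected over the number of pairs. The
break-exclusion control reruns labelling (80/80/80 at 240 s), SPoC and
sub-blocked CSP with block permutation on the rides-only crop, refitting
SSD on the 240-s data by default (filters for "without break" should be
estimated without the break; filter reuse is available as an option),
and feeds two-sided paired t-tests.

## Study sizes and numerical choices

Simulation studies run at desk scale: null calibration uses 100 subjects
× 200 permutations (p-value granularity 1/201 is ample for checking the
α = 0.05 rejection rate against [0.01, 0.10]); recovery uses 20 coupled
subjects; LSTM checks use 3 training seeds over the shared 10-fold split.
Degenerate inputs raise rather than warn: constant rating traces
(tertiles undefined), constant targets (SPoC undefined), zero-variance
metric vectors (t undefined). Log features are floored at 1e-20 before
the logarithm; eigenproblems use `scipy.linalg.eigh` with descending
sorts and documented tie conventions. Cohort seeds fan out to
per-subject, per-stage streams via `SeedSequence` spawn keys (all derived
seeds < 2³¹), making every report reproducible from one integer.

## Known limitations

- The generator's stationarity and white sensor noise understate real
  EEG's artifact burden; selection thresholds tuned for clean synthetic
  spectra may admit noisier components on real data.
- SPoC surrogate tests re-run the decomposition but share the fixed
  epoch covariances; slow drifts in real covariances are represented in
  neither the null nor the generator.
- The LSTM studies use a fixed small architecture; the full random
  search is implemented and tested but not exercised at the study's
  original breadth (20 draws × 10 subjects) in the default suites.
- eLORETA source localization, PREP referencing, ICA cleaning and
  questionnaire analyses are outside the package's scope.
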