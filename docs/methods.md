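# Methods

## Problem and signal model

The package decodes which of three imagined shoulder movements — flexion,
extension or abduction — produced a 5 s, 14-channel EEG trial sampled at
128 Hz (Emotiv Epoc+ montage, 10-20 positions). The physiological carrier
of class information is event-related desynchronization (ERD): motor
imagery attenuates the mu (8–13 Hz) and beta (13–30 Hz) rhythms over
sensorimotor cortex, with a spatial pattern that differs between actions.
Only the four frontocentral channels FC5, F3, F4 and FC6 enter the
analysis; the rest of the montage is carried through I/O but ignored by
the decoder.

## Pipeline

1. **Preprocessing.** A second-order IIR 50 Hz notch (Q = 30, applied
   forward–backward so it is zero-phase) removes line interference, then a
   common average reference (CAR) subtracts the instantaneous mean of the
   four selected channels from each of them. `car_scope="all"` instead
   references against the full 14-channel mean before selecting the four
   channels; the 4-channel variant is the default because it is the
   unambiguous reading of the reference formula, while the full-montage
   variant matches the prose description of CAR. Notch Q is a design
   choice: at Q = 30 the −3 dB stopband is ≈ 1.7 Hz wide, far from the
   30 Hz upper edge of the beta band.

2. **EMD and the AF matrix.** Each channel's 1–4 s segment (384 samples;
   the 0–1 s cue period is excluded) is decomposed by empirical mode
   decomposition. Sifting uses cubic-spline envelopes through the extrema
   with two extrema mirrored beyond each end, the Cauchy SD criterion with
   threshold 0.2 and a cap of 10 sifts per IMF; decomposition stops when
   the residual is monotone or has fewer than three extrema. These are the
   standard sifting defaults; the mirror extension suppresses envelope end
   swings on 384-sample windows. At 128 Hz the mu and beta rhythms land
   almost entirely in IMF1 and IMF2 (a property the test suite checks on
   synthetic trials: ≥ 80 % of 8–30 Hz energy). The one-sided FFT
   amplitude spectra of IMF1 and IMF2 (rectangular window, no padding,
   scaled 2/N so a unit sinusoid at a bin centre has magnitude 1) are
   restricted to the closed interval 8–30 Hz — with 1/3 Hz bin spacing
   that is M = 67 bins — and stacked into the 8 × 67 amplitude-frequency
   (AF) matrix, rows ordered IMF1×(FC5, F3, F4, FC6) then IMF2×(same).
   The band is taken as one contiguous interval; M is frozen at the first
   trial and a later mismatch is an error.

3. **AF-CSP features.** Classical two-class CSP applied to AF matrices.
   Per-trial covariances are trace-normalised; the class covariance is
   their arithmetic mean (the per-trial normalisation is prescribed, the
   averaging convention is the standard CSP choice). A ridge
   ε·trace(R)/N with ε = 1e−8 guards against rank-deficient AF matrices.
   Whitening of R_l + R_r followed by the eigendecomposition of the
   whitened R_l yields filters W (rows ordered by descending eigenvalue,
   signs canonicalised so each row's largest coefficient is positive).
   With m = 2 filters per side the feature of a trial is the 4-vector
   f_p = log(var(Z_p)/Σ var(Z_i)) over the retained rows of Z = W X, so
   Σ exp(f) = 1 identically. One filter is fitted per one-vs-one pair:
   f1 (flexion, extension), f2 (flexion, abduction), f3 (extension,
   abduction). Filters are always fitted on the training partition of a
   fold only; anything else leaks test labels into the spatial filters.
   The stacked six-block "final eigenvector" sometimes written for the
   OVO scheme is treated as notation — classification is pairwise and
   never consumes it.

4. **OVO twin SVM.** Each pair trains a twin SVM: two nonparallel
   hyperplanes, each near its own class and at unit margin from the
   other, obtained from two box-constrained dual QPs (duals of the
   standard primal with inequality constraints; the printed kernel primal
   contains evident typos — both constraints naming the same class
   matrix, equalities where margins belong — and the standard form is
   implemented instead). The Gram-side linear systems use a ridge
   ε = 1e−7·trace(HᵀH). The duals are solved with L-BFGS-B on the
   box-constrained quadratic — the problems have one variable per
   training sample of one class (≤ 16 here), where a quasi-Newton
   bound-constrained solve is accurate and deterministic. The six
   per-subclassifier penalties are tied: c1 for every own-class plane,
   c2 for every opposite plane. The RBF kernel is
   k(u, v) = exp(−‖u−v‖²/(2λ²)) with λ the width being searched; under
   this convention the Gram matrix tends to the identity as λ → 0⁺.
   Prediction votes per pair for the class whose plane is nearer
   (perpendicular distance; in kernel space the normal's norm is
   √(wᵀK(C,C)w)); majority wins, vote ties are broken by the smallest
   summed normalised distance to the candidate's planes, remaining ties
   by class order (flexion, extension, abduction). Exact per-pair
   distance ties vote for the pair's first class, which makes the
   all-equidistant degenerate input resolve to the lowest class index.

5. **NSGA-II hyperparameter search.** Genome (c1, c2, λ) encoded in log2
   space — bounds c1, c2 ∈ [2⁻³, 2³], λ ∈ [2⁻²⁰, 2³] span up to 23
   octaves, which a linear encoding would squash against the lower bound.
   Objectives are the three per-class correct rates (CRF, CRE, CRA) from
   stratified 5-fold cross-validation, pooled across folds (sum of
   corrects over sum of totals — the count-ratio definition implies
   pooling rather than per-fold averaging), maximised jointly; the total
   rate CR is tracked for model selection but is not an objective. Folds
   are fixed per optimization run so objective differences between
   genomes reflect hyperparameters, not fold noise. Operators: binary
   tournament under the crowded comparison, simulated binary crossover
   (η_c = 20, rate 0.9), polynomial mutation (η_m = 20, per-gene rate
   0.1 — the named operators with standard distribution indices, which
   the source of the presets does not specify), (μ+λ) elitist truncation
   by (rank, crowding). Offspring are clipped to the bounds and clip
   events are counted. An archive keeps the best-CR individual ever
   evaluated, so the best-CR history is non-decreasing by construction.
   The final model is the front member with maximal CR; ties prefer the
   larger minimum per-class rate, then order. One reported Pareto row has
   c2 = 0.0100, below the stated lower bound 2⁻³ = 0.125; the bounds are
   enforced as stated and the row treated as an inconsistency of the
   source table.

   Because CSP does not depend on (c1, c2, λ), the per-fold EMD + CSP
   features are computed once per run (`CVFeatureCache`) and shared by
   every candidate — evaluating one genome then costs only three twin-SVM
   fits per fold.

## Scoring conventions

CR pools counts: CR = (CNF+CNE+CNA)/(TNF+TNE+TNA)·100, which with equal
class totals equals the mean of the per-class rates. Cohen's kappa is
computed from the confusion table as printed, marginals from its own
sums; percentage tables are treated as weights (kappa is scale
invariant). Cross-subject summaries use the **population** SD
(divisor n), the convention that reproduces the printed ±3.61 and ±5.61
spreads from the per-subject accuracies (sample SD would give 3.90 and
6.06). Where two printed values for one subject conflict (88.33 vs
86.67), the value consistent with the printed mean is used and both are
surfaced in the test suite's comments.

## Synthetic data: what it emulates and what it does not

The study's recordings are not deposited, so the generator supplies
trials with the statistical structure the method assumes: per channel,
1/f-amplitude (pink) background noise, a 50 Hz line component, and mu-
and beta-band oscillations built from two amplitude-modulated sinusoids
each (random centre frequency ≥ 1 Hz inside the band, ±0.5 Hz
trial-to-trial jitter, AM rate 0.2–0.9 Hz at depth 0.3 — slow enough
that AM sidebands stay within a ±1 Hz guard of the band edges; the
jitter and AM exist so EMD does not collapse the band to a trivial
single tone). ERD is a multiplicative attenuation 1 − d of both band
amplitudes on class-specific channels for the whole trial: flexion
attenuates FC5 (depth d) and F3 (d/2), extension mirrors on FC6/F4,
abduction attenuates F3 and F4 — a crude lateralisation surrogate making
all three pairwise contrasts informative. Defaults: d = 0.5, mu 6 μV,
beta 4 μV, pink 3 μV RMS, line 1 μV, 20 trials per class — amplitudes in
the range of scalp-recorded sensorimotor rhythms, chosen once as a
plausible moderate-SNR subject. No paper-level SNR is available to match.

Passing tests on this data show the pipeline recovers band-power spatial
structure at realistic amplitudes; they do not show performance on real
EEG, which additionally has non-stationary ERD latency, ocular/muscular
artifacts, inter-subject montage variability and volume-conducted
topographies none of which are modelled.

## Problem sizes and numerical choices

The test suite and the reproduction script use one synthetic session (60
trials), 5-fold CV, and scaled-down search budgets (population 20 for
10 generations for signal recovery; a 200-evaluation budget for the
optimizer-vs-random comparison), sizes at which the full pipeline runs
in well under a minute while leaving the per-stage algorithms identical
to a full pop-100 × 200-generation run. Tolerances asserted in tests:
EMD reconstruction ≤ 1e−8 relative, whitening and eigenvalue
complementarity to 1e−8 (1e−6 on measured EEG covariances), feature
normalisation to 1e−9, dual feasibility to 1e−6. Degenerate inputs are
first-class: equal class covariances flag the filter degenerate
(all eigenvalues 1/2), duplicate class sample sets flag the plane pair
degenerate, zero-variance components and constant signals raise labelled
errors.

## Known limitations

- EMD has no unique definition; different envelope/stopping conventions
  give slightly different IMFs. The implementation pins one standard
  convention and tests its contracts rather than bit-level agreement
  with any other implementation.
- The dual QP solver targets the small per-fold problems of this design
  (tens of samples); it is not tuned for thousands of samples.
- The generator's ERD pattern is a stand-in: real single-joint imagery
  differences are far subtler, and headline accuracies on synthetic data
  should not be read as expected real-data performance.
- Within-trial ERD latency dynamics are out of scope (whole-segment
  features only), as is any online/real-time operation.
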