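# Methods

This note documents the models and procedures implemented in `varconn`,
the defaults they run with, what the synthetic validation cohort does and
does not emulate, and the numerical choices made where the design was
genuinely open.

## MVAR estimation

Each 1-minute segment is modelled as an order-p multivariate
autoregression, `x_t = Σ_{k=1..p} A_k x_{t-k} + u_t`, `u_t ~ N(0, C)`.

- **Estimator**: ordinary least squares on the stacked one-step
  regression over t = p+1..n (equivalent to per-equation OLS), chosen
  for determinism and easy testing; Yule-Walker or lattice estimators
  would be drop-in alternatives but are not provided.
- **Mean handling**: each channel's segment mean is subtracted before
  fitting — the connectivity measures below assume zero-mean processes.
- **Noise covariance**: empirical covariance of the residuals with
  denominator `n − p`. At the 15 000-sample segments the pipeline uses,
  the difference from the degree-of-freedom-corrected denominator
  `n − p − m·p` is far below estimation noise.
- **Order**: default p = 5 (with fs = 250 Hz and 60 s windows). The
  multivariate portmanteau (Ljung-Box) statistic
  `n² Σ_{l≤h} tr(G_lᵀG_0⁻¹G_lG_0⁻¹)/(n−l)` with `m²(h−p)` degrees of
  freedom is exposed as a residual-whiteness diagnostic for choosing p
  and the window length; it reports, it does not gate.
- **Degenerate inputs**: a constant or duplicated channel makes the
  regressor matrix rank deficient and raises a linear-algebra error
  naming the condition; segments shorter than `m·p + p + 1` samples are
  rejected up front.

## Frequency-domain connectivity

From `A(f) = I − Σ_k A_k e^{−i2πfk/fs}` (the sampling rate in the
exponent keeps band edges in physical Hz), `H(f) = A(f)⁻¹` and
`S(f) = H C Hᴴ`:

- **GPDC** `= (1/√C_ii)|A_ij(f)| / √(Σ_k (1/C_kk)|A_kj(f)|²)` —
  column-normalised (`Σ_i GPDC_ij² = 1` per source column), weighting by
  innovation variances makes it scale-invariant.
- **dDTF** `= η_ij(f)·χ_ij(f)` with the full-frequency DTF
  `η_ij² = |H_ij(f)|²/Σ_{f'}Σ_k|H_ik(f')|²` (denominator over the whole
  evaluation grid) and partial coherence
  `χ_ij² = |S⁻¹_ij|²/(S⁻¹_ii S⁻¹_jj)`.

Conventions and choices:

- **Orientation**: column j is the source, row i the sink (the standard
  convention for both measures). Feature names spell the direction out
  as `metric/band/src->dst`, so nothing downstream depends on matrix
  orientation.
- **S(f)** is the model spectral matrix `H C Hᴴ`, not a periodogram —
  the self-consistent choice for a fitted MVAR, and the only one under
  which `S⁻¹` (needed by dDTF) exists by construction.
- **Grid and bands**: metrics are evaluated on the integer 1–50 Hz grid
  and averaged per band with **inclusive endpoints** (delta 1–4, theta
  4–8, alpha 8–12, beta 12–30, gamma 30–50 Hz). The shared edges 4, 8
  and 12 Hz therefore contribute to two bands each; this double counting
  is intentional and documented rather than silently resolved. The
  metric value itself (not its square) is averaged. The gamma band's
  upper edge coincides with the low-pass cutoff; the measures are
  model-based, so they remain defined there.
- **Diagonal**: self-pairs carry no directed information and are
  excluded, giving `2 × n_bands × m(m−1)` features per segment (3420 at
  m = 19).

## Random forest

Binary classification by T bagged Gini decision trees.

- **Per-tree feature subsetting**: each tree sees one fixed random
  subset of `⌊P·d⌋` columns (at least 1) for its entire growth — *not* a
  fresh subset per split. This is the less common variant but is the
  procedure implemented here by design; defaults T = 200, M = 10,
  P = 2.5% (85 of 3420 features).
- **Bootstrap**: rows resampled with replacement to the training-set
  size.
- **Splits**: exhaustive scan over candidate features with thresholds at
  midpoints between consecutive distinct sorted values; a node splits
  only while it holds ≥ 2M samples and both children keep ≥ M; the
  split minimising the child-size-weighted Gini impurity wins, with
  deterministic ties broken toward the lowest feature index, then the
  lowest threshold. Determinism makes every run exactly reproducible
  from its seed.
- **Prediction**: each leaf stores its class-1 fraction; the ensemble
  score is the plain average over trees, which supports ROC analysis.
- **Importance**: per split, the impurity decrease weighted by the
  fraction of the tree's samples reaching the node, accumulated per
  feature over all trees and normalised to sum to 1 (the CART/Breiman
  definition, which also matches mainstream library behaviour and is
  cross-checked against one in the tests). Features never used split
  have importance exactly 0.

## Cross-validation designs

- **Subject-unaware**: the K-way split happens *within* each subject
  (contiguous temporal blocks by default — conservative under temporal
  autocorrelation — with a seeded shuffled mode available); fold k tests
  on the union of every subject's k-th block. Optimistic by
  construction: the classifier has seen every test subject's other
  segments.
- **Leave-p-subjects-out**: subjects are assigned to K class-balanced
  groups by a seeded stratified shuffle ((2 controls, 2 patients) per
  fold at the 14+14 study scale); no subject ever appears on both sides
  of a fold. This is the clinically meaningful estimate.
- **ROC/AUC**: threshold sweep with trapezoidal area, equal to the
  normalised Mann-Whitney statistic; ties handled by midranks. The
  cross-fold summary is the unweighted mean of per-fold AUCs.
- **Importance summaries**: per feature, the minimum (`I_min`, "was it
  important in *every* fold?") and the mean (`I_avg`) of the per-fold
  normalised importances, with descending top-k rankings.

## Synthetic ground-truth cohorts

`varconn.synthetic` generates two-class cohorts from known MVAR models
so every stage can be validated against a known answer. Defaults (the
toy validation scale): 6 channels at 250 Hz, 6 + 6 subjects, 3 minutes
per subject, mild AR(1) self-dynamics (0.3) on every channel, and one
class effect — a lag-1 coupling ch0→ch1 of strength 0.5, band-localised
at 6 Hz — present only in class 1.

- **Band localisation**: the source channel carries a damped-oscillator
  AR(2) block (pole radius 0.9 by default) whose spectral peak has a
  closed form — `cos ω₀ = a₁(1−a₂)/(−4a₂)` — making the localisation
  testable analytically. The resonator is *shared scaffolding* present
  in both classes; only the directed cross-coefficient distinguishes
  them, so the class variants of a subject differ in exactly the stated
  entries.
- **Power calibration**: a resonant channel's innovation variance is set
  so its marginal variance is 1. Real EEG channels have comparable
  amplitudes; an uncalibrated near-unit-root oscillator would carry
  orders of magnitude more power than its neighbours and inject severe
  regressor collinearity into the fits.
- **Subject variability**: plain couplings get multiplicative
  coefficient jitter `(1 + σz)`, σ = 0.15 by default; resonators get the
  same jitter applied to their *peak frequency* instead (mirroring
  individual-peak-frequency variability, and keeping every draw
  stationary). Models failing the stability check are redrawn.
- **Toy CV shapes**: with 3 segments per subject, subject-unaware CV
  uses K = 3; leave-p-subjects-out keeps the study's fold composition of
  2 controls + 2 patients held out, i.e. K = 3 at 6 + 6 subjects.

What the generator does **not** emulate: volume conduction and common
reference (which correlate real electrodes instantaneously), artifacts
(ocular, muscular), nonstationarity across the recording, 1/f background
spectra, and genuinely nonlinear coupling. Passing the synthetic battery
therefore shows the *pipeline machinery* recovers planted linear
directed structure under subject heterogeneity — it does not certify
performance on real EEG.

## Known limitations

- **Spectral resolution at low frequencies**: an order-5 lag polynomial
  at fs = 250 Hz varies slowly below ~15 Hz, so a strong coupling
  localised in theta unavoidably produces elevated features in the
  neighbouring delta/alpha bands (and, through the partial-coherence
  factor of dDTF, a weaker echo in the reverse direction). In the
  importance rankings these sibling features compete with the planted
  one: all of them separate the classes perfectly at strong coupling,
  perfect stump splits have identical Gini decrease, and importance then
  allocates by how often each feature lands in a tree's random subset.
  The planted pair reliably dominates the ranking as a *group*, but
  which sibling occupies any single rank fluctuates seed to seed.
- **Small-sample trees**: at the toy scale (24–30 training segments)
  the M = 10 leaf rule stops every tree after its root split; the
  ensemble is a bagged-stump committee. This is the faithful consequence
  of the stated hyperparameters at that scale, not a tunable defect.
- **Window count**: at 12 minutes per subject and non-overlapping
  1-minute windows, 28 subjects yield 336 segments. Overlapping windows
  (`overlap_fraction`) are supported for protocols that window more
  densely.
- The whiteness diagnostic is advisory; the pipeline never silently
  drops segments that fail it.
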