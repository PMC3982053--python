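# Methods

## Scope and data model

`signet` analyzes signed weighted functional brain networks and their
relation to cognition and nigrostriatal dopamine integrity.  Nodes are the
90 cerebral regions of the AAL parcellation (labels shipped in
`src/signet/data/aal90_labels.txt`); edges are full-range Pearson
correlations between ROI-averaged BOLD time-series.  A 60-label subset of
the atlas (`cognitive_circuit_60.txt`) defines the "cognitive circuit" used
for the subnetwork modularity analysis.  That list is editable
configuration — a plausible prefrontal/cingulate/medial-temporal/parietal/
occipital/basal-ganglia set — not the output of any meta-analytic pipeline,
and users with their own circuit definition should supply it via
`PipelineConfig(circuit_labels=...)`.

## Time-series conditioning

The conditioning chain operates strictly in the order **discard → nuisance
regression → band-pass → correlation**; the stages do not commute, so the
order is part of the contract and `preprocess()` enforces it.

* Dummy-volume discard: default 2 volumes (212 → 210 at TR 2.4 s).
* Nuisance regression: ordinary least squares of each ROI column on an
  intercept plus the supplied regressors (white-matter/CSF signals, motion
  summaries).  Residuals are exactly orthogonal to the regressors.  A
  rank-deficient design falls back to the pseudoinverse with a warning.
* Band-pass: FFT-domain masking over the closed band [0.01, 0.08] Hz by
  default — the conventional low-frequency fluctuation range; the band is a
  parameter.  Masking was chosen over an IIR/FIR design because it is
  deterministic, exactly linear-phase, and introduces no edge-parameter
  choices; the DC bin is always removed when the low edge is positive, so
  filtered series are mean-free.
* Correlation: pairwise Pearson weights with the diagonal forced to zero.
  Weights are **not** Fisher-transformed, thresholded, or binarized; |w| = 1
  is tolerated on degenerate input (duplicated columns).  A column with
  (numerically) zero variance is an error naming the ROI.

## Signed graph measures

Positive and negative edges carry different meaning in functional networks,
so measures treat them separately.  Nodal strength is
s_i^± = Σ_j w_ij^±, with the "total" strength defaulting to the combined
magnitude s⁺ + s⁻ (the signed difference is available via
`total_mode="difference"`).

Modularity uses the asymmetric signed generalization

    Q± = (1/v±) Σ_ij (w_ij± − s_i± s_j±/v±) δ(M_i, M_j)
    Q* = Q⁺ − [v⁻/(v⁺+v⁻)] Q⁻

with sums over all ordered pairs **including i = j** (w_ii = 0, e_ii > 0).
The diagonal-inclusive convention is what makes Q* vanish identically on
the single-module partition and reduces Q* to classic Newman weighted
modularity for positive-only graphs (cross-checked against networkx in the
test suite).  A consequence worth knowing: for a graph whose only edge is
negative, the all-singletons partition scores Q* > 0, because isolating
negatively linked nodes is rewarded relative to the null.

Community detection maximizes Q* via the signed modularity matrix
B = (W⁺ − E⁺)/v⁺ − (W⁻ − E⁻)/(v⁺+v⁻): Louvain-style local moves (ties
broken toward the lowest community index, gains must exceed 1e−13) followed
by agglomeration, restarted over random node orders (default 100 restarts;
the first k restarts of a longer run coincide with a shorter run at the same
seed, so more restarts never return a lower Q*).  The single-module
partition is a fallback, so the returned Q* is never negative.  For graphs
of ≤ 10 nodes `brute_force_max_modularity` enumerates every set partition
(restricted-growth-string order; first maximum wins, which equals the
lexicographically smallest encoding on ties) and serves as the exact oracle.
Per-subject modularity is optimized independently per matrix; no group or
consensus partition is imposed.

## Behavioral composites and SBR

Raw test scores are z-scored against healthy-control norms and averaged
within fixed memberships: memory = three HVLT-R learning trials + delayed
recall; visuospatial = Benton judgment of line orientation; executive =
letter–number sequencing, symbol–digit modalities, semantic fluency,
phonemic fluency.  Missing members are an error — no silent imputation.  No
age/sex adjustment is applied to tests; those variables enter the models as
covariates.  The motor domain z-scores UPDRS-III across the sample
(population-SD convention by default, `ddof=1` available) and negates it so
all domains share the higher-is-better direction.  The specific binding
ratio is (caudate/occipital) − 1 per hemisphere, then averaged; it is
invariant to the counts scale by construction.

## PLS brain–behavior decomposition

Strength profiles (subjects × 90) and the three domain composites are
decomposed jointly by multi-response PLS (PLS2).  Columns of X and Y are
centered and scaled to unit variance (X scaling can be disabled; Y scaling
keeps the three domains commensurate).  The NIPALS core is delegated to
scikit-learn; preprocessing, component selection, score projection, and the
sign convention are own code.  Each latent variable is sign-fixed so the
largest-magnitude entry of its brain loading is positive, making loadings
reproducible across platforms.

Component count is selected by leave-one-out cross-validation: per held-out
subject the model is refit — including re-centering and re-scaling inside
the fold, to avoid leakage — and RMSEP is accumulated per response, summed
over the three domains, and minimized (ties go to fewer components).

**Identifiability.**  When successive brain–behavior covariance singular
values are of similar size, the individual PLS directions are determined
only up to rotation within their span; with ~30 subjects, chance
correlations of order 1/√30 between latent scores rotate the leading
directions appreciably even at large effect size.  Pattern recovery is
therefore assessed with `pattern_recovery_cosine`, the principal-angle
cosine between a reference pattern (in raw strength units) and the span of
the fitted raw-unit loadings — the standard subspace-aware recovery metric
for rotation-ambiguous decompositions.

## Association models

All inference is ordinary least squares with an intercept; p-values are
two-sided with dof = n − p(design), and uncorrected, matching common
reporting in this literature (a Benjamini–Hochberg column is appended to
tables for reference but never gates anything).  The LV–domain model is
`LV_score ~ executive + memory + visuospatial + motor + age + sex`; LV–SBR
and modularity–SBR models are simple regressions on the mean caudate SBR
over the SPECT subsample.  The motion screen extracts PC1 of the
standardized absolute displacements (SVD, sign-fixed like the PLS loadings)
and regresses it and the mean relative displacement on each variable of
interest separately.  Numerically perfect fits cap |t| at 1e12 with p = 0
rather than emitting non-finite statistics.

A caution that the test suite makes explicit: fitting PLS and then
regressing its LV scores on the same subjects' behavior double-dips — under
a true null the LV–domain model rejects at ≈13%, not 5%, because PLS picks
directions that covary with Y in-sample.  The correct null reference is the
permutation distribution obtained by shuffling the subject pairing between
LV scores and behavioral rows, which the acceptance checks use.

## Synthetic cohort generator

The generator emulates the study conditions: 30 subjects, 90 ROIs, 212
volumes at TR 2.4 s, three cognitive domains, an 18-subject SPECT
subsample.  Its ingredients:

* **Base connectome** — a planted-partition correlation matrix (5 contiguous
  modules; within-module r = 0.35, between-module r = 0.10), repaired to the
  nearest positive semi-definite correlation matrix by eigenvalue clipping
  at 1e−8 and rescaling to unit diagonal.
* **Latent components** — per-subject standard-normal scores s_k perturb the
  covariance by rank-one terms s_k·a_k a_kᵀ.  Component 1 is a global
  integration pattern (uniform loading 0.22): positive scores raise
  connectivity everywhere and *lower* modularity.  Components 2 and 3 are
  support patterns (0.60 over 24 posterior/striatal ROIs; 0.55 over 24
  dorsal fronto-parietal ROIs).  Behavior loadings are
  [[0,0,0], [0,−1.2,0], [0.8,0,0]] over (executive, memory, visuospatial):
  the global component is purely motor/SBR-linked (a nonzero cognitive
  loading on it would leak a motion–cognition correlation through the motor
  path, contradicting the intended motion structure), memory tracks
  component 2 negatively, executive tracks component 3.  UPDRS-III is driven
  by component 1 (weight 0.8); SBR = 2.0 + 0.8·s₁ + 0.2·s₃ + noise.  The
  SBR–component-1 coupling plus the integration effect of component 1 is
  what produces the planted negative modularity–SBR relation.
* **Time-series** — stationary AR(1) sampling (x_t = a·x_{t−1} + √(1−a²)·e_t,
  e_t ~ N(0, Σ_subject), a = 0.3) so the marginal covariance equals the
  subject covariance at every volume; AR(1) stands in for BOLD temporal
  autocorrelation.
* **Raw test scores** — per-test z-targets equal to the planted domain value
  plus N(0, 0.2) noise, mapped through plausible control norms, so the
  behavioral composites genuinely pass through the z-scoring/averaging code.
* **Demographics and motion** — age ~ N(61.7, 9.5²) clipped to [40, 80];
  motion summaries share a latent factor loading on age and UPDRS (worse
  motor → more motion) but not on cognition.
* **SPECT counts** — caudate counts constructed as (1 + SBR ± asymmetry)
  against a unit occipital reference, so the SBR formula is exercised.

Effect sizes were calibrated once, before freezing, so that the planted
structure is recoverable at the study's sample sizes (subspace recovery
cosine ≈ 0.98; modularity–SBR detection ≈ 85–90% at n = 18; LOO selects the
three-component model most often); they are test-power choices, not claims
about real effect sizes.  One seeded generator drives everything: identical
config + seed ⇒ bit-identical cohort.

### What the generator does *not* emulate

Real BOLD artifacts (scanner drift, physiological noise, spatially
correlated motion residuals), voxel-level preprocessing, site effects,
non-Gaussian score distributions, heavy-tailed connectivity noise, and any
realistic effect-size structure.  Passing tests demonstrate that the
pipeline recovers structure it is designed to detect under its own
statistical assumptions — not that those assumptions hold in real cohorts.

## Problem sizes and numerical choices

Replicate counts in the test and acceptance suites (20 cohorts for
recovery, 50 for detection, 200 permutations for the null, 100 random
8-node graphs for the oracles) were chosen as the package's own balance of
statistical resolution against desk-scale runtimes.  Degenerate inputs are
errors, not warnings: zero-variance ROIs/tests/responses, partitions
missing nodes, bands above Nyquist, non-PSD covariances, SPECT references
≤ 0.  Tolerances: oracle equivalences at 1e−12, closed-form regression
checks at 1e−8–1e−10, orthogonality at 1e−8 relative.

## Known limitations

* The Louvain optimizer is greedy; on adversarial small graphs it can miss
  the exhaustive optimum (observed ≈ 3–4% of random 8-node matrices at 100
  restarts), which is why the exact oracle exists for validation.
* PLS loadings are reported sign-fixed but remain rotation-ambiguous within
  near-degenerate singular subspaces; interpret individual LVs accordingly.
* The LV–SBR and modularity–SBR models are unadjusted simple regressions
  (a covariate-adjusted variant is available); with n = 18 their power for
  moderate couplings is limited.
* The 60-ROI circuit list is configuration, not a reproduced meta-analysis.
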