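# Methods

This note documents the models, algorithms and design choices behind
`idlescore`: a pipeline that scores progression risk in resected stage IA
non-small-cell lung cancer (NSCLC) by combining preoperative low-dose CT
(LDCT) radiomics with pathologist-reading tissue features, together with the
synthetic cohort generator used to exercise the pipeline end to end.

## 1. The problem and the estimand

After complete resection of a stage IA NSCLC, roughly 20-30% of patients
progress (local recurrence, distant metastasis, or lung-cancer death) within
about a decade, yet TNM stage and tumor grade separate these patients
poorly.  The pipeline produces, for each patient, an integrated risk score
in [0, 1] ("IDLE score") from three blocks of inputs:

* **CT block** — 173 named features per screening CT (section 3);
* **tissue block** — histologic subtype flags, highest tumor grade, largest
  invasive dimension, ROI counts, aggregated from pathologist readings;
* **clinical block** — demographics, surgery type, residual-disease status,
  lymphadenectomy, and the LDCT-to-surgery interval in days.

The primary endpoint is progression-free survival: time from surgery to
recurrence, metastasis, or lung-cancer death, right-censored otherwise,
with a 12-year administrative cap.  Scores are evaluated with
time-dependent (cumulative-case / dynamic-control) ROC analysis at 5 and 10
years, Bayes-rule time-dependent PPV/NPV, hazard-ratio risk stratification,
and multivariate Cox adjustment.

## 2. Synthetic cohorts

Real screening-trial data cannot ship with the package, so all tests run on
synthetic cohorts with a known generative truth (`idlescore.cohort`).

**Latent risk.** Each patient carries two independent standard-normal
platform signals: `z_ct` (drives lesion morphology on CT) and `z_ti`
(drives histology).  The latent log-hazard is

    eta = b_ct * z_ct + b_ti * z_ti + b_int * z_ct * z_ti + eps,
    eps ~ N(0, 0.25^2).

The product term makes cross-platform synergy a property of the data: a
model that sees only one platform cannot represent it.  Defaults
`b_ct = b_ti = 0.5`, `b_int = 1.0` give modestly informative single
platforms and a clearly better integrated predictor, the qualitative
pattern the pipeline is designed to detect.

**Event times.** Weibull proportional hazards (shape 1.1, mild risk
acceleration) on `eta`.  The baseline scale is calibrated by bisection so
that the expected observed-event fraction under censoring matches the
requested `progression_fraction` (default 0.30, matching the roughly
30%/12-year progression typical of resected stage IA cohorts).  Censoring
is independent exponential (default rate 0.05/year) plus the 12-year cap.
Observed events receive a cause label (local recurrence / distant
metastasis / lung-cancer death, default split 0.4/0.4/0.2) so
endpoint-specific decoding analyses can run.

**CT phantoms.** Each patient's volume (default 96^3 voxels at 0.5 mm; the
test suite uses 64^3 for speed) contains an air background, an ellipsoidal
soft-tissue shell (~300 HU), a lung cavity (-800 HU, Gaussian noise sd
20 HU), and one planted ellipsoidal lesion.  Three morphology knobs are
monotone functions of `z_ct`:

* *solidity* (0.30-1.0) sets mean lesion intensity (-545 to +50 HU);
* *skewness* (0-0.9) sets the skew-normal intensity asymmetry;
* *cluster count* (Poisson, 0-4) plants compact +250 HU blobs that displace
  the high-intensity weighted centers.

Lesion diameter is lognormal (median 9 mm), deliberately *independent* of
risk — in the emulated study population invasive size did not separate
progressors.  Small secondary nodules (Poisson mean 0.7) populate the
per-lung lesion table.  What the phantom does **not** emulate: airway and
vessel trees, lobar fissures (lobes are a fixed geometric partition),
scanner kernels and noise texture, respiratory motion.  Passing tests
therefore demonstrate algorithmic correctness and end-to-end signal
recovery, not clinical performance on real CT.

**Pathology readings.** 1-10 ROIs on 2-3 slides per patient (about 6 ROIs
and 2.6 slides per patient on average, the ratio seen in the emulated
cohort).  Per-ROI diagnosis mixes adenocarcinoma, AIS, large-cell,
squamous, and carcinoid with AIS probability falling and grade rising in
`z_ti` (ordered-threshold model); invasive dimension is lognormal in
`z_ti`, capped below 30 mm; 2% of graded ROIs are GX (undetermined).

**Eligibility filters.** The five-cohort selection rules (surgery received,
readings present, stage IA, largest invasive size <= 30 mm — boundary
retained, surgery within 730 days of the last LDCT — boundary retained)
are applied sequentially with a CONSORT-style exclusion report.

## 3. CT feature extraction (173 features)

Preprocessing: trilinear resampling to 0.5 mm isotropic; lung segmentation
(threshold below -300 HU, border-touching components removed, largest
component, morphological closing, hole-filling so nodules stay inside, bone
voxels >= +150 HU excluded); lesion segmentation inside a gross cube with
>= 1 cm margin (3^3 median filter, Otsu threshold computed on lung voxels
and capped at the parenchyma median + 6 robust SD — plain Otsu fails when a
small lesion occupies a tiny fraction of the cube — then opening, closing,
largest component, and a 100 HU minimum contrast check); eligibility
(equivalent diameter >= 4 mm, non-calcified: <= 10% of voxels above
+130 HU); VOI construction (peritumor = <= 5 mm distance shell within lung;
adjacent normal = 10-15 mm shell, widened inward on small fields of view;
extratumor = lung beyond the peritumoral shell clipped to the gross cube);
intensity normalisation d' = d - median(adjacent normal) + 300, applied
globally so all VOIs share one scale and energy features are meaningful.

Registry composition (fixed order, names unique):

| block | count |
|---|---|
| first-order (15) x {tumor, peritumor, extratumor} | 45 |
| GLCM (22) x 3 VOIs | 66 |
| GLRLM (11) x 3 VOIs | 33 |
| nested spatial (V, LocSd100/50/20, LocSd100V/50V/20V, d50, d20) | 9 |
| tumor/peritumor intensity ratios (mean, R50, R90) | 3 |
| lung-level (5 lobes x {count, any-solid, any-part-solid} + totals) | 17 |
| **total** | **173** |

Numerical conventions: gray levels use fixed bin width 100 (HU-like scale
of the normalised volume) anchored at the VOI minimum, so levels start at 1;
quantiles use linear (type-7) interpolation; kurtosis is non-excess;
first-order skewness/kurtosis use population moments.  GLCMs are
accumulated symmetrically at unit displacement along the 13 unique 3D
lattice directions and averaged; matrices are normalised to sum 1.  GLRLMs
use a strided-run convention: for stride d in {2,3,4,5} a run is a maximal
chain p, p+d*u, p+2d*u of in-mask voxels sharing one gray level (the
classical run-length matrix has no distance parameter, so the stride family
is defined explicitly), giving 52 matrices per VOI, averaged.  The GLCM sum
variance is taken about the sum average.  Correlation and the information
measures return 0 for degenerate (zero-variance) matrices.

The nested centers weight coordinates by intensity d, while the dispersion
LocSd weights squared distances by d^2; the asymmetry is intentional and
kept exactly as defined.  Top-p% voxel selection takes the ceil(pN/100)
highest intensities, including every voxel tied with the cutoff (so a
homogeneous lesion is symmetric and all its centers coincide).  LocSd_p is
normalised by tumor volume in mm^3; d50/d20 are Euclidean center shifts in
mm.  Lobe labels in the phantom follow a fixed geometric convention (first
axis splits left/right; the right lung divides into three axial bands, the
left into two); solidity labels use mean raw HU (> -300 solid, -600 to
-300 part-solid).

## 4. The risk model

Architecture (class `IDLEModel`): two sigmoid hidden layers (defaults
32/16 units) trained **jointly** with a sigmoid read-out head by full-batch
Adam on the binary event-by-5-year label, cross-entropy loss plus an L2
penalty on all non-bias weights (grid {0.001, 0.01, 0.1}, chosen per fit by
cross-entropy on an internal 75/25 validation split); patients censored
before the horizon without an event carry no label and are excluded from
the hidden-layer loss only.  After training, each layer's weights below the
90th percentile of |w| are set exactly to zero and the surviving weights
are re-optimised with the zeros frozen.  The pruned network is the
*feature selector*: the per-feature selection count is the number of
layer-1 units with a nonzero weight on the feature plus the number of
layer-2 units reachable through a chained nonzero path.

The final layer is a random survival forest (log-rank splitting, default
500 trees, minimum node size 5) grown on the *input variables that retain a
nonzero chained path into the second hidden layer*, standardized with
training statistics.  All features are candidates at every split when the
selected subset is small (<= 25; a sqrt-mtry fallback keeps wide inputs
tractable), because interactions between the selected platform features are
exactly what the forest must model.  The risk read-out is the ensemble
cumulative hazard at the 5-year horizon, min-max normalised to [0, 1] over
the training set and clipped for out-of-range test patients.

Two design points deserve explanation.  First, the hidden layers are
trained jointly rather than greedily layer-by-layer: a single logistic unit
trained on a label carried mostly by a cross-feature interaction has its
convex optimum near zero weights, so greedy layers collapse to constants;
joint backprop does not.  Second, the forest consumes the network-selected
input variables rather than the hidden activations: at these sample sizes
the activations bottleneck the survival information that the forest can
recover directly from the (selected) inputs, while the strong-penalty
network is a reliable selector — its first-layer weight magnitudes
concentrate on label-correlated inputs.  Both choices were made on
synthetic-data evidence and are reported as such.

**LOOCV.** The evaluation score for each patient comes from a model fitted
to the other n-1 patients; standardization statistics, the L2 choice,
pruning, selection, the forest, and the normalisation bounds are all
re-derived inside each fold, so no test-fold information enters training
(audited by a perturbation test).  Every fold starts from the same seed, so
identical training sets give identical scores.  Single-platform ablations
(`ldct_only`, `tissue_only`) drop the other platform's block but keep
demographics and the screening-to-surgery interval, and use the identical
procedure.

## 5. Evaluation statistics

* Kaplan-Meier product-limit survival (lifelines).
* Time-dependent sensitivity/specificity/AUC: cumulative cases, dynamic
  controls, IPCW case weights 1/G(T-) with G the reverse Kaplan-Meier
  censoring survival (vectorised; cross-checked against scikit-survival's
  Uno estimator).  With no censoring the AUC reduces exactly to the
  empirical event-by-t AUC.  Bootstrap SD: patient-level resampling
  (default 500), degenerate resamples skipped.
* PPV/NPV by Bayes' rule: PPV(t) = sens(t)(1 - S(t)) / P(test positive),
  NPV(t) = spec(t) S(t) / P(test negative), with S(t) the Kaplan-Meier
  estimate.  For each target sensitivity on a grid, the cutoff maximising
  specificity subject to sens >= target is used (ties toward higher
  sensitivity); unreachable targets are reported non-evaluable.
* High-risk cutoff: scan score quantiles 10-90% in 1% steps, univariate
  Cox per cutoff, >= 10 patients per group, ties to the smaller cutoff;
  the partition is rank-based, so monotone score transforms choose the
  same split.
* Cox models: partial likelihood with **Breslow** tie handling
  (statsmodels PHReg), Wald intervals.
* Cohort tables: Welch t-test for continuous variables (the safer
  unequal-variance default), two-sided Fisher exact for 2x2 categorical
  tables, chi-square otherwise.

## 6. Black-box decoding

A full-cohort refit provides the selection-count ranking (ties broken by
univariate median-split logrank p, then name).  Top variables are
dichotomised at their HR-maximising thresholds and logrank-tested against
progression, local recurrence, and distant metastasis (competing causes
censored).  Input variables and all hidden-layer activations are screened
with Welch t (continuous) or chi-square (discrete; Fisher exact when a 2x2
table has expected counts below 5, Yates correction off); the 25 smallest
p-values are standardized to z-scores with the **population** SD (rows then
have exactly mean 0, SD 1) and exported as the heatmap matrix.  The synergy
report compares integrated vs single-platform AUC(t) +/- bootstrap SD and
flags whether the integrated score beats both ablations at every horizon.

## 7. Problem sizes used by the test suite

The package's tests and the acceptance script run on deliberately
desk-scale problems chosen as the smallest sizes at which each property is
stable: 64^3 phantoms (96^3 for the registry check), cohorts of 100-200
patients, network 24/12 units with a fixed L2 of 0.01 and 50-tree forests
for the end-to-end synergy analysis (two replicate cohorts of 200
patients), 12-6 unit networks with the 3-point L2 grid for model property
tests, and 5-replicate medians for statistical calibration checks.  The
full three-platform LOOCV pipeline on a 200-patient cohort, including
phantom synthesis and feature extraction, completes in a few minutes on one
CPU core.

## 8. Known limitations

* The phantom's lung is geometric; lobe assignment and lung-level features
  exercise the code path, not anatomy.
* Grade and subtype distributions are plausible but not fitted to any real
  pathology dataset.
* The latent-risk interaction is a single product term; real cross-platform
  synergy is presumably higher-dimensional.
* LOOCV scores from different folds are min-max normalised by each fold's
  own training bounds, so pooled ROC analysis carries a small cross-fold
  incoherence, as in the emulated study design.
* With interaction-dominant signal and weak main effects, feature selection
  can miss a platform at small n; the end-to-end synergy result is tested
  at n = 200 where it is stable.
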