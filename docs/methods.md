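# Methods

This note documents the models and procedures implemented in `evmodsig`, the
choices made where the design was genuinely open, and what the synthetic
studies do and do not demonstrate.

## Candidate gene universe

Expression is z-transformed per gene across the samples of each cohort
(sample standard deviation, ddof = 1); constant genes map to all-zero rows so
matrix shape is stable and they contribute nothing to module activities.
Cohorts are always standardized separately — a signature transferred to a
validation cohort is evaluated on that cohort's own z-scores.

Differential genes between tumor and adjacent-normal samples are called with
a two-sided Wilcoxon rank-sum test per gene and Benjamini–Hochberg
adjustment at FDR ≤ 0.05. This is a deliberate stand-in for empirical-Bayes
differential callers: the pipeline's substance is downstream of the DE list,
and `select_de_genes` accepts an externally computed list verbatim (bypass
mode) when one exists. The candidate universe is the intersection of the DE
list with the EV-associated gene list, ordered by the DE list.

## Dense-module detection (MCODE)

The network is restricted to edges with confidence ≥ 0.4 (inclusive), then to
the candidate genes. Module detection follows the published MCODE procedure:

* **Vertex weighting.** Each vertex's closed neighborhood is reduced to its
  highest k-core; the weight is k<sub>max</sub> × density of that k-core,
  with density 2E/(V(V−1)). Vertices below the degree cutoff (2) are not
  scored.
* **Complex prediction.** Unused vertices seed expansions in decreasing
  weight order; a neighbor joins when its weight is at least
  (1 − node score cutoff) × seed weight, to the configured depth; each vertex
  joins at most one complex (fluff off).
* **Post-processing.** Haircut reduces a complex to its 2-core; complexes
  lacking the required k-core (2) are discarded. Module score is density ×
  size; ids `mod_1…mod_k` follow descending score.

All tie-breaks (equal weights, equal scores) are lexicographic on gene
symbol, making output deterministic. Edge confidences play no role inside
MCODE — the algorithm is defined on unweighted graphs; the score acts only as
a construction filter.

One behaviour worth stating explicitly: two equally dense complexes joined by
a single bridge edge *merge* into one complex, because the bridge endpoints'
vertex weights equal the complex-interior weights (their neighborhood's top
k-core is their own clique) and expansion therefore crosses the bridge. This
is a property of the published weighting/expansion rules, not an
implementation artifact; the unit suite pins it.

## Stage-discriminant module selection

Module activity in sample *j* is e<sub>j</sub> = Σ<sub>i∈M</sub>
Z<sub>ij</sub>, divided by √m by default (`sum` and `mean` are selectable);
the √m scaling keeps activities of differently sized modules on comparable
variance. The activity vector is discretized into k = ⌈log₂ N + 1⌉
equal-width bins over [min, max] (Sturges; k = 9 at N = 167), the maximum
landing in the top bin; a constant vector collapses to one label. The
discriminant score is the plug-in mutual information, in bits, between the
discretized activity and the dichotomized stage (I/II = low, III/IV = high;
unknown stages dropped with a log entry).

Significance: for a module of size m, 1000 gene sets of size m are drawn
without replacement from the filtered candidate network's nodes (not the
whole genome); p = (1 + #{MI<sub>rand</sub> ≥ MI<sub>obs</sub>}) / (1 + R).
The add-one estimator makes the attainable floor 1/(R+1), so the P < 0.001
gate at R = 1000 is exactly "the module beats every random draw". Selection
uses a strict inequality. No multiplicity correction is applied across
modules — the gate is a fixed threshold by design.

The companion sample-clustering view cuts average-linkage hierarchical
clustering (Euclidean distance on module-activity profiles) into two sample
clusters and tests each clinicopathological factor (stage, grade, sex, age
dichotomized at 60) against the clusters by chi-square, BH-adjusted across
the factors tested; single-level factors are excluded.

## Signature construction

The training label is death within a horizon; samples censored before the
horizon cannot be labelled and are excluded from training. The package
default is 3 years for real cohorts. For the synthetic studies the horizon
is set at the generator cohort's median overall survival (600 days):
dichotomizing far beyond the median produces ~80/20 labels whose
cross-validation error curve is nearly flat, which starves backward
elimination of signal; splitting at the median is the
classification-efficient choice.

Backward elimination: an initial forest (default 5000 trees) estimates
permutation importance (mean decrease in accuracy, 5 repeats; Gini
selectable); each iteration removes max(1, ⌈0.1 k⌉) lowest-importance
features (never crossing the stop count), refits with 3000 trees, and
records stratified 5-fold CV misclassification error, down to 2 features.
The selected signature is the smallest feature count whose CV error is
within one standard error (over folds) of the minimum — a principled reading
of "fewest features" that tolerates the flat region around the optimum. The
final forest is refit on the selected features with OOB scoring enabled.

Risk is the fraction of trees voting the poor-prognosis class — out-of-bag
votes for training samples, all-tree votes for external samples (sample ids
distinguish the two, so ids must not collide across cohorts; the synthetic
generator tags ids with its seed for this reason). Each scored cohort is
split at its **own** median risk, ties to the low group. Validation cohorts
are re-z-scored internally, the selected modules' activities recomputed, and
the survival evaluation repeated.

A comparator signature fits a multivariable Cox model directly on individual
gene z-rows (ridge 1e-6 for numerical stability), scores by linear predictor
and median-splits; duplicate gene rows are rejected as collinear.

## Survival evaluation

Kaplan–Meier curves and the two-sample log-rank test come from lifelines;
Cox models use Efron tie handling with a light ridge penalty (0.01) that
guards against separation in sparse categorical levels (its bias is
negligible at these cohort sizes; calibration tests fit with penalty 0).
Categorical covariates are one-hot encoded with the first level as
reference; the risk group's reference is "low", so reported hazard ratios
are high vs low. Time-dependent AUC is the IPCW cumulative-case /
dynamic-control estimator of scikit-survival at 365/1095/1825 days, with the
censoring distribution estimated from the same cohort; horizons with no case
or no control are reported absent.

## Microenvironment

Context scores (hypoxia, angiogenesis, inflammation) are per-sample means of
the z-scores of configurable biomarker gene sets supplied as GMT — the
published biomarker lists are not printed in any source available here, so
the sets are inputs, not constants. Cell abundances (e.g. from an external
deconvolution) enter as a cell-type × sample table. Pearson correlations of
module activities against the full context/abundance grid are BH-adjusted
across the entire grid at once (the family is recorded in the output);
zero-variance pairs are omitted. Risk-group contrasts use Welch's t-test.

## Synthetic cohorts

`SyntheticCohortConfig` defaults define one reference study:

| parameter | default | meaning |
|---|---|---|
| n_genes / n_tumor / n_normal | 900 / 200 / 50 | cohort dimensions |
| planted_module_sizes | (9,3,3,5,6,4,5,7,4,6,5,8) | 12 dense modules; the first three (9/3/3 genes) are prognostic |
| background_edge_prob / within_module_edge_prob | 0.02 / 0.95 | network densities |
| edge confidences | background U(0.05,0.95), planted U(0.4,0.999) | exercises the ≥0.4 filter |
| stage_proportions | (0.25, 0.55, 0.15, 0.05) | ~20% high stage |
| stage_effect_delta | 1.5 z-units | added to stage-module genes in stage III/IV samples |
| prognostic_log_hr | 0.8 | per unit of mean prognostic-module sum-score |
| baseline_hazard | ln2/600 per day | median OS ≈ 600 d |
| censor_time_range | (30, 2190) d | uniform administrative censoring |
| de_gene_count / de_shift | 600 / 1.5 | tumor-vs-normal shifts (planted genes included) |
| coexpression_loading | 0.3 | within-module latent-factor loading |
| hypoxia_activity_corr / hypoxia_hazard_coef | 0.5 / 0.3 | hypoxia latent ties to aggression and hazard |

Expression is unit-variance Gaussian per gene with a shared latent factor per
planted module (co-expression ρ = loading² = 0.09). Survival is exponential
with rate baseline × exp(0.8·a + 0.3·h), where a is the mean of the
prognostic modules' sum-scores and h is the hypoxia latent — standard normal
marginally but correlated 0.5 with standardized a, because a hypoxia factor
independent of all module expression could never surface in a module-based
classifier's risk groups; hypoxic tumors being more aggressive is the
intended biology. Cell abundances are softmax compositions with one cell
type linearly tied (coefficient 0.8) to the first module's activity.

Two defaults deserve justification because they deviate from the real
training cohort's make-up:

* **Stage balance.** Real resected pancreatic cohorts are ~96% stage I/II.
  At that imbalance the mutual information of any 200-sample activity vector
  is bounded by the class entropy (≈0.27 bits) while the maximum of 1000
  null draws reaches 0.16–0.21 bits, so no module — however cleanly
  separated — can reliably beat every draw and the P < 0.001 gate is
  structurally unattainable. The 80/20 default keeps the discriminant stage
  well posed; the corollary is that a published claim of twelve modules all
  passing such a gate on a 96/4 cohort should be read with caution.
* **Universe size.** The candidate universe (~340 genes after DE ∩ EV and
  network induction) keeps the 20 stage-informative genes near 6% of the
  draw pool. Random "modules" drawn from a small universe are contaminated
  with signal genes, inflating the null's tail; dilution mirrors the signal
  sparsity of a realistic reference network.

What the generator does **not** emulate: count noise and library-size
effects (values are Gaussian on the z scale), batch structure, correlated
censoring, copy-number or mutation events, and any spatial organization.
Passing synthetic tests therefore demonstrates the pipeline's statistical
machinery recovers planted structure under a favourable noise model — not
that the published gene lists are correct.

## Problem sizes in the test and acceptance runs

Replicated studies (20 seeds) run with 300/150-tree forests and 3
permutation-importance repeats; selection behaviour at n = 300 with ≤ 12
features is insensitive to tree count well below the 5000/3000 defaults,
which remain the package defaults for real cohorts. The permutation gate
always uses R = 1000 where a P < 0.001 decision is taken (the add-one floor
makes smaller R incapable of passing that gate); calibration studies use
R = 200 per module.

## Known limitations

* The MI permutation gate is a hard filter: on roughly one default synthetic
  cohort in ten, fewer than two modules survive it and the pipeline refuses
  to build a signature rather than silently relaxing the threshold.
* The RF outcome label (death within a horizon) is one defensible reading of
  "prognosis"; relapse-based labels would need recurrence annotations the
  data model does not carry.
* Plug-in MI is biased upward at small samples; the permutation null carries
  the same bias, so the p-value is calibrated, but reported MI magnitudes
  should not be compared across different sample sizes.
* The IPCW AUC estimates the censoring distribution from the evaluated
  cohort itself; with heavy censoring near a horizon the estimate is
  unstable and the horizon may be reported absent.
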