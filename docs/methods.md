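# Methods

## Problem and data model

The package scores the similarity of a colorectal tumor to the MSI-H
(microsatellite instability-high) phenotype from three feature axes:

- **Clinical/pathological categoricals** — sex, age, mucinous histology,
  differentiation, T stage, tumor site, lymphovascular and perineural
  invasion, CEA, chemo-/radiotherapy. Age and CEA are kept numeric; CEA is
  additionally dichotomized at 5 ng/ml, the standard clinical cutoff.
- **TIL measurements** — percent cellularity (positive cells / nucleated
  cells, 0–100 scale) for 16 immune cell types in three regions (tumor,
  stromal, whole). A config flag rescales 0–1 inputs.
- **Mutated-gene sets** — gene symbols detected by a targeted panel.

Missingness is structural, not numeric: an assay that was never run
(`None` / empty CSV cell) is distinct from a measured zero everywhere. In
the mutations CSV column, an empty cell means "panel not run" and the
sentinel `-` means "panel run, nothing detected". This distinction drives
model dispatch (below); within-block missing values are left as NaN and
consumed natively by the tree learners — there is no imputation.

## Mutation posterior

The mutated gene set M = {g_i} is collapsed into a naive-Bayes posterior
P(MSI-H | M) using status-conditioned per-gene mutation frequencies and
class priors (defaults 0.83 / 0.17). The computation is in log space; any
per-gene frequency below a floor ε (default 1e-4, configurable in
(0, 0.01]) is raised to ε, keeping the posterior finite and strictly
monotone in each frequency without perturbing well-supported genes. Genes
absent from the frequency table are skipped as uninformative, with a
logged warning. An empty set returns the prior; a missing profile returns
missing, never a default probability.

The default priors are deliberately configurable and worth scrutiny: a
0.83 prior for MSI-H is far above the population prevalence of MSI-H in
colorectal cancer (~15%); it is retained as the package default for
continuity with the scoring system this package implements, and any
analysis may override it.

## Ensembles, trimmed mean, dispatch

Each feature combination ("spec": an ordered tuple of blocks drawn from
clinical, mutation_posterior, gene_classes at stringency 1/2, and
`til:<cell>__<region>` columns) trains an ensemble of `n_seeds` XGBoost
classifiers (default 10) that differ only in random seed, which governs
row/column subsampling. `scale_pos_weight` is the negative/positive count
ratio of the training data — the majority/minority convention for a
positive-class weight. Base-learner defaults are conservative (depth 3,
60 rounds, learning rate 0.1, subsample and colsample 0.8, `hist`,
single-threaded) and fully overridable; none of the package's behavioral
guarantees depend on their exact values.

A score is the trimmed mean of the submodel probabilities: sort, drop
floor(0.2·n) per tail, average the rest. For n=10 this is exactly the
mean of sorted positions 3–8 (the middle 6). The decision rule is
`score >= threshold`, threshold default 0.3, boundary inclusive.
`calibrate_threshold` instead picks the observed-score cutoff whose
predicted-positive fraction is closest to a target prevalence, breaking
ties toward the lower (more inclusive) threshold.

The default lattice enumerates 44 specs: two bases (clinical alone;
clinical + all three mutation-derived blocks), each optionally augmented
with a non-empty subset of the CD8+/CD163+/PD-L1+ markers measured in one
region — 2 × (1 + 3 × 7) = 44. The deployed combination list of the
original scoring system is not public; this enumeration is the package's
own reconstruction over the named feature families and is fully
configurable (any YAML list of specs can replace it). The registry is
ordered by descending block count (ties by name), and dispatch walks that
order, scoring with the first model whose required blocks are all
available for the record. Block availability: clinical = any clinical
field present; mutation blocks = the panel was run; a TIL block = that
(cell type, region) was measured. If nothing fits, an explicit
"unscorable" error is raised.

## Evaluation

`cross_validate` mirrors deployment: per repeat, a seeded stratified
k-fold split (scikit-learn `StratifiedKFold`; per fold the positive count
deviates from proportionality by at most 1); per fold, the ensemble is
retrained on the remaining folds with the in-fold class ratio, hold-out
patients are scored by trimmed mean and called at the threshold (default
0.3 — the same as deployment, configurable), and Cohen's kappa is
computed as (p_o − p_e)/(1 − p_e). A single-class hold-out fold leaves
kappa undefined: it is recorded as missing, excluded from the repeat
mean, and warned about, preserving "mean of the fold kappas" semantics
without fabricating values. Repeat seeds and submodel seeds are
independent streams (submodel seeds are derived as repeat_seed·1000+i).
With one repeat, the SD is reported as missing.

Feature importance is dual: XGBoost's native total-gain metric averaged
across submodels, and a permutation importance — the mean absolute change
in the trimmed-mean score when one column is shuffled, averaged over
seeded shuffles. Both are normalized to sum to one. Permutation
importance is the package's attribution method of choice because it is
model-agnostic and carries its own oracle (a constant or
label-independent column must score ~0); additive-attribution packages
can be layered on externally if desired.

## TIL analytics

- **Mann-Whitney U** (two-sided, unpaired): exact null enumeration when
  both samples have ≤ 8 observations and no ties; otherwise the normal
  approximation with midrank tie correction and continuity correction
  (via `scipy.stats.mannwhitneyu`). If all values are identical the test
  is degenerate and p = 1.
- **Region contrasts**: stromal vs tumor values per cell type across
  patients, Bonferroni-adjusted over the cell types tested (one family),
  with .05/.01/.001 significance stars.
- **Four-group battery**: for each `<cell>__<region>`, the ordered
  comparisons (all MSS vs MSI-H), (other MSS vs MSI-H), (other MSS vs
  MSI-H-like MSS), (MSI-H-like MSS vs MSI-H). Benjamini-Hochberg
  adjustment runs within each comparison family across cell types by
  default (matching a per-column heat-map reading); a single family over
  the whole battery is a switch. Adjustments go through
  `statsmodels.stats.multitest`.
- **Similarity projection**: similarity(former, latter) =
  p_adj/(median_f − median_l) when the medians differ, else p_adj. The
  formula is implemented verbatim, including its discontinuity: the value
  blows up as the median difference approaches zero yet jumps to p_adj at
  exactly zero. Percentages enter on the 0–100 scale. The four
  comparisons above give each cell type a 4D latent vector.
- **Clustering**: agglomerative, Euclidean distance, complete linkage
  (scipy). Leaves are pre-sorted lexicographically by `cell__region` so
  equal-distance merges resolve deterministically; merge heights are
  non-decreasing by the monotonicity of complete linkage.

## Synthetic cohort generator

The generator emulates the study conditions every analytic module
assumes: 188 patients, exactly 24 MSI-H (a stratified draw, not
Bernoulli), clinical categoricals sampled independently per stratum from
marginals matching the published per-stratum proportions (e.g.
right-sided 67% of MSI-H vs 22% of MSS; mucinous 42% vs 16%), TIL values
from logit-normal distributions (bounded, right-skewed; σ = 0.6 on the
logit scale) with a stromal-over-tumor offset (+0.8 logits) and MSI-H
enrichment of the macrophage/Treg/CD163+/PD-L1+ compartments (+1.4
logits stromal, +0.8 tumor; +0.3 for the remaining cell types), and
gene-wise Bernoulli mutations from the packaged status-conditioned
frequency table. Whole-region values are a random convex mix of the
tumor and stromal draws, so they always respect the two-region envelope.
A `msi_like_fraction` share of MSS records (default 15%, consistent with
reports that up to ~20% of MSS tumors carry MSI-H-like profiles) draws
its TIL and mutation data from the MSI-H parameters while keeping the
MSS label; these records carry a simulation-truth `msi_like` flag used
only for validating the analytics, never as a model feature.

What the generator does **not** emulate: joint dependence among clinical
variables (only marginals are published), spatial structure, measurement
error correlated across cell types, or realistic mutation co-occurrence
(genes are independent Bernoulli). Passing tests therefore demonstrate
that the pipeline recovers structure it is pointed at — not clinical
performance on real cohorts.

Two canonical configurations are used in the tests: the **recovery**
configuration (msi_like_fraction = 0 — two clean strata, the setting for
parameter-recovery and null-calibration checks, where cross-validated
kappa is expected ≥ 0.5 on signal and ≈ 0 after label permutation) and
the **admixture** configuration (msi_like_fraction = 0.15, the setting
for the four-group analytics, where MSI-H-like-vs-MSI-H contrasts should
be non-significant while other-MSS-vs-MSI-H contrasts light up for the
shifted compartments). `simulate_null_cohort` permutes labels after a
clean-strata draw, severing all feature–label association.

Problem sizes in the default test run are the study scale itself
(n = 188, 5 × 10 cross-validation); the large-n marginal-recovery check
uses n = 10,000.

## Table-1 fixture

`data/table1_cohort.csv` reconstructs the published-style clinical
characteristics table deterministically: for each stratum and variable,
exactly the printed counts, with the unaccounted-for remainder encoded as
missing (8 missing differentiation grades, 10 missing radiotherapy
entries, 1 missing MSS tumor site — the printed strata do not sum to the
cohort size). Numeric stand-ins are used for the dichotomized variables
(age 50/70 for <65/≥65; CEA 2.0/8.0 ng/ml). Summary percentages use the
non-missing denominator per variable and stratum and round half away from
zero, which reproduces every printed integer percentage exactly.

## Numerical and degenerate-input conventions

- Posterior: log-space accumulation; logistic of the log odds with a
  branch for large |log odds|; empty table + empty gene set with
  interior priors returns the prior.
- Cohen kappa with p_e = 1 (both raters constant, same value): 1 by
  convention if agreement is perfect (it necessarily is in that case).
- Trimmed mean with n < 5: floor(0.2·n) = 0, plain mean.
- Registry persistence stores raw XGBoost boosters (JSON) plus a
  `registry.yaml` manifest; loaded ensembles predict identically to
  within float round-off.
- All randomness is explicit: simulation seeds, split seeds, submodel
  seeds, and permutation seeds are separate, logged, and reproducible;
  identical configs yield byte-identical primary outputs.

## Known limitations

- The 44-combination lattice is a documented reconstruction, not the
  original list.
- The packaged gene-frequency and gene-class tables are synthetic
  stand-ins (plausible values over 37 canonical CRC genes), suitable for
  exercising the pipeline, not for inference on real patients.
- The similarity statistic's near-zero-difference blow-up is inherited
  by design; downstream clustering drops non-finite coordinates with a
  warning rather than smoothing them.
- Survival analyses and any image- or sequencing-level processing are out
  of scope; inputs begin at tabular per-patient measurements.
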