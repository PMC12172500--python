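# Methods

This note documents the statistical machinery behind misch-kit, the
choices made where the design was genuinely open, and what the synthetic
cohort does and does not establish about real data.

## Data model

An abundance table is a samples × taxa matrix of relative abundances
with a kingdom tag (bacteria/fungi) per taxon and one taxonomic level
per table; every public operation returns rows summing to 1 (tolerance
1e−9). Cohort metadata records subject id, scalp region (T = frontal,
H = occipital), integer age in years (20–60), and clinical stage
(Healthy, AGA3, AGA5, AGA7 on the Hamilton–Norwood scale). Age bins are
closed-open 5-year intervals, with the final bin closed at 60:
[20,25), …, [55,60].

**Kingdom merging.** Bacterial and fungal tables are each row-normalized
and concatenated, then the union is renormalized, giving both kingdoms
equal mass (one half) in every sample. Rationale: 16S and ITS1 depths
are not comparable, and without renormalization the kingdom with more
taxa or deeper sequencing dominates every downstream distance. The
alternative (leave the concatenated rows at sum 2) changes JSD
magnitudes but not orderings; the equal-mass convention is the package
default and the one all reported numbers use.

**Taxonomic aggregation** sums taxa sharing a name at the target rank;
taxa unnamed at that rank pool into `unclassified_<kingdom>`. The level
grid for classifier comparisons spans phylum…species; kingdom-level
profiles are degenerate for single-kingdom tables and excluded by
default.

## Diversity

* Shannon entropy uses the natural log by default (`base` is a
  parameter); Simpson is the Gini–Simpson form 1 − Σp²; Chao1 is the
  bias-corrected estimator S + F1(F1−1)/(2(F2+1)) on integer counts
  (delegated to scikit-bio).
* Beta diversity is the Jensen–Shannon **divergence** (not its square
  root) in base 2, range [0, 1], with 0·log 0 := 0. The metric square
  root is available via a flag.
* PCoA is classical scaling (eigendecomposition of the double-centered
  −D²/2 matrix), implemented directly so negative eigenvalues are
  reported and axes restricted to positive ones; scikit-bio's
  implementation serves as an independent cross-check in the tests.
* PERMANOVA follows Anderson's one-factor decomposition:
  SS_total = Σ_{i<j} d²_{ij}/N, SS_within summed per group,
  pseudo-F = (SS_between/(a−1))/(SS_within/(N−a)), R² =
  SS_between/SS_total. The p-value uses the add-one estimator
  (1 + #{F_perm ≥ F_obs})/(1 + n_perm) so p never reaches 0; an exact
  mode enumerates all n! orderings (n ≤ 9) and reports
  #{F_perm ≥ F_obs}/n!. Permuted statistics are compared with a 1e−12
  relative tolerance to make tie counting robust to float noise.
  Single-factor tests only; age enters through its 5-year bins.
* Per-taxon group tests use the Wilcoxon rank-sum with normal
  approximation; taxon–age association uses Spearman correlation with
  Benjamini–Hochberg FDR.

## Microbial age

Training is restricted to healthy subjects (both regions per subject)
unless explicitly overridden — the clock is a healthy reference.
Feature ranking averages Gini importances over 10 forest fits on random
90% subsamples; a master seed spawns a named stream per iteration so
extending the iteration count never reshuffles earlier draws. Forward
selection evaluates ranking prefixes by cross-validated mean absolute
error with folds grouped by subject (GroupKFold), preventing the two
regions of one person from straddling a fold; the chosen panel is the
smallest prefix within one standard error of the best MAE — small,
interpretable marker panels fall out of this parsimony rule. Forests default to
500 trees; the CV metric, tie-break, and tree count are parameters.

## Stage classification

Subject-exclusive splits are stratified by stage at the subject level
with ceil(train_fraction · n) subjects per stage on the training side.
Cross-validation uses StratifiedGroupKFold (stratified by stage, grouped
by subject). The level × kingdom grid scores a default-parameter forest
per cell by pooled CV kappa. Prefix feature selection ranks taxa with a
500-tree forest (a large ensemble stabilizes the Gini ranking), scores
prefixes by grouped CV kappa (optionally averaged over fold reshuffles),
and takes the first k attaining the curve maximum. Hyperparameter tuning
is two-phase — a random broad search followed by exhaustive enumeration
of the ±1-neighbor grid around the incumbent — with grouped CV kappa as
the objective; the broad space (trees, depth, min-split, min-leaf,
max-features, class weight) is a configurable stand-in. Evaluation
repeats the 70/30 subject split, reporting per-repeat and mean Cohen's
kappa, accuracy, and macro one-vs-rest AUC; a test side missing a class
drops that class from the macro mean with a warning.

## MiSCH

Stage-distance weights: d_c is the mean JSD over all (healthy, stage-c)
sample pairs on the merged table, d_Healthy := 0 by convention, and
w_c = d_c/max_c d_c. Empirically non-monotone distances are used as-is
with a warning; an isotonic switch (pool-adjacent-violators) enforces
monotonicity. Averaged probabilities: per repeat, a forest trained on
the training side of a subject-exclusive split records probabilities for
held-out samples only; each sample's final p is the mean over repeats in
which it was held out. A sample never held out is an error by default;
`ensure_coverage=True` continues the same seed stream with extra repeats
(at most 3×) until every sample is covered — with 20 repeats at 70/30
roughly one cohort in twelve would otherwise fail by chance.

The score is `100 × (1 − Σ_c p_c w_c)`: 100 for a certainly-healthy
sample, 0 for a certain maximal-dysbiosis sample, strictly decreasing
by 100·ε·(w_j − w_i) when probability mass ε moves from stage i to a
higher-weight stage j. The combiner is a single function and can be
swapped. Categories follow the published boundaries exactly, with
upper-closed intervals: healthy (75, 100], mild (25, 75], moderate
(15, 25], severe [0, 15]. Subject-level scores take the minimum of the
two regions (the conservative reading of a paired design). A sample
whose category maps to a more severe stage than its clinical label gets
a flag `<clinical>–<mapped>` in short stage names; flagged groups are
compared to reference stages by two-group PERMANOVA, where a smaller
pseudo-F against a stage means the flagged microbiota are harder to
distinguish from it.

An important consistency constraint follows from the fixed boundaries:
with this combiner, a confidently stage-c probability vector lands in
category c only if w_AGA3 ∈ [0.25, 0.75) and w_AGA5 ∈ [0.75, 0.85).
Real cohorts that violate this band will map confident mid-stage samples
into neighboring categories; the thresholds are exposed as configuration
rather than auto-fit.

## Synthetic cohort generator

The generator emulates the study design: 89 subjects (51 Healthy, 18
AGA3, 10 AGA5, 10 AGA7) × 2 regions = 178 samples, integer ages uniform
on 20–60. Noise is Dirichlet-multinomial: subject composition
~ Dirichlet(κ · template), region profiles are the mixture
ρ·subject + (1−ρ)·fresh-draw (ρ = 0.7), counts are multinomial at depth
100,000 and renormalized.

Templates encode the qualitative dysbiosis gradient: Propionibacterium
enriched with severity (0.30 → 0.52), Corynebacterium strictly
decreasing (0.20 → 0.04), Macrococcus rising as a strong discriminator,
Malassezia depleted (0.60 → 0.15), Alternaria exploding past 50% by
AGA7, Aspergillus peaking at AGA5. The stage-to-stage spacing was
designed so the measured healthy-to-stage JSD profile lands in the
weight band that makes the published category boundaries self-consistent
(measured w ≈ (0, 0.25, 0.74, 1) on a clean cohort and
≈ (0, 0.26, 0.82, 1) in the high-risk scenario). The Dirichlet
precision κ = 500 keeps within-stage dispersion small relative to
adjacent-stage template distances — the regime matching the strong
stage discrimination the study system exhibits — while the multinomial
layer still adds depth-limited noise.

Age trends apply to healthy subjects only, as logit-scale slopes per
year on six genera (Paracoccus +0.045, Micrococcus +0.035, Rothia
−0.035, Propionibacterium −0.015, Acinetobacter +0.030, Cladosporium
+0.040) around the mid-age of 40, followed by renormalization — trends
can never produce negative abundances. Healthy subjects get a mild
fixed T/H template perturbation (alternating ±0.2 logit); AGA templates
are identical across regions, mirroring the whole-scalp dysbiosis
pattern. Background mass is spread over 24 bacterial and 7 fungal
genera by broken-stick proportions.

`inject_high_risk` appends n samples drawn from the target-stage
template but labeled with the milder stage (new subjects, both regions),
returning the ground-truth ids — the scenario used to test high-risk
discordance detection with the study's n = 10.

**Feature-selection benchmark.** `planted_feature_config` builds a
separate cohort in which exactly 22 bacterial + 5 fungal genera of 100
carry stage signal, organized in three effect tiers resolving
complementary contrasts: a severity split ({Healthy, AGA3} vs {AGA5,
AGA7}, logit effect 0.9), an onset split (Healthy vs AGA3, 0.55), and a
late-progression split (AGA5 vs AGA7, 0.38), with deterministic random
signs and precision κ = 80. The tiering makes the weakest tier gate
full four-class accuracy, so the CV-kappa curve keeps climbing until
essentially the whole panel is included — the regime where prefix
selection is a meaningful benchmark. This benchmark cohort doubles the
study design (200 subjects, same proportions): resolving the marginal
contribution of ~27 weak markers needs more statistical power than 89
subjects provide, and at the study size the plateau-onset argmax is
dominated by CV noise.

**What the simulator does not capture.** Compositions are
Dirichlet-multinomial around stage templates: no taxon–taxon
interaction structure, no zero inflation beyond sampling zeros, no
batch or subject-level covariates other than age, stage, and region,
and stage separations chosen for self-consistency with the published
score boundaries rather than estimated from data. Passing recovery
tests therefore demonstrates that the estimators and the scoring
pipeline are correct and well-calibrated under the assumed generative
model — not that real scalp cohorts are this separable.

## Numerical choices

* All randomness flows from named child streams of a master seed
  (SeedSequence with a CRC32 spawn key per name), so partial reruns
  match full runs and adding iterations never reshuffles earlier ones.
* JSD is computed via scipy's Jensen–Shannon metric (squared,
  rescaled from nats to bits) and clipped to [0, 1]; distance matrices
  must be symmetric to 1e−12 with zero diagonal.
* Forests run single-threaded with explicit integer seeds below 2³¹;
  classifier outputs always use the severity order (Healthy, AGA3,
  AGA5, AGA7) regardless of label order in the input.
* Pipeline TSV artifacts carry a `# misch-kit seed=… config=…` header
  (readers skip `#` comments) and use lexicographic taxon order, so two
  runs with the same config and master seed are byte-identical;
  wall-clock timings are confined to `run_report.json`.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the full 89-subject
cohort for classifier, age, MiSCH, and high-risk checks; the 200-subject
benchmark for feature selection (60-tree CV forests, 10 folds × 2
reshuffles); 1,000 null data sets of 16 samples with 199 permutations
each for PERMANOVA calibration; 10,000 random simplex/weight draws for
score bounds; and a reduced 20-subject pipeline for the byte-identity
determinism check.

## Known limitations

* The MiSCH combiner is one defensible choice among several; only its
  boundary behavior (0 and 100) and monotonicity are pinned by the
  published description, and the 75/25/15 thresholds are taken as given
  rather than recalibrated.
* PERMANOVA is single-factor; sequential/marginal multi-factor
  partitioning is out of scope, as are phylogeny-aware distances.
* The hyperparameter search space is a documented stand-in; the tuned
  model rarely beats sklearn defaults on the simulated cohorts, which
  are more separable than real data.
* Exact PERMANOVA enumeration is limited to n ≤ 9 by factorial growth.
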