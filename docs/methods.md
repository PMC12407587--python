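# Methods

This note records the models, conventions and design decisions behind
`doppelscan`, in the spirit of a statistical software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Doppelgänger detection

**Model.** Samples are abundance vectors over a common feature set; the
similarity of two samples is their correlation across features. The
detection rule is distribution-free: the cutoff is the empirical maximum of
the between-class (case–control) correlations, and a within-class pair is
flagged iff its correlation is **strictly greater** than that maximum. Ties
at the cutoff are not flagged. Because the cutoff is the between-class
maximum, no between-class pair can be flagged — the procedure has perfect
specificity by construction and its sensitivity is data-driven: it flags
only similarities that the observed between-class spectrum says cannot
occur across disease states.

**Correlation input.** The default representation is per-sample
proportions (`transform="relative"`), with `raw` and `log1p` selectable.
Proportions remove library-size artifacts: two samples sequenced at
different depths from the same community correlate at 1 on proportions but
not on raw counts. The flagged-pair count depends on this choice, so it is
an explicit, documented parameter rather than a hidden convention. Pearson
is the default coefficient (sensitive to the dominant-taxon structure that
makes near-duplicates stand out); Spearman and Kendall are provided for
robustness checks and use the same cutoff rule — the cutoff is always
derived with the same coefficient used for flagging.

**Cutoff validation.** The between- and within-class correlation values are
compared with a two-sided Wilcoxon rank-sum test and summarized as two
histograms over 30 shared equal-width bins spanning the pooled range.
Throughout the package the rank-sum test uses exact null enumeration when
both groups have ≤ 12 tie-free observations, and otherwise the normal
approximation with tie and continuity corrections.

**Degenerate inputs.** A sample whose transformed vector is constant has
undefined correlation and is reported as an error naming the sample.
Detection requires both classes non-empty (otherwise no between-class pair
exists and no cutoff is defined).

**Removal.** Flagged pairs form a graph on samples; resolving them is a
vertex-cover problem. The default `greedy_degree` policy repeatedly deletes
the sample incident to the most unresolved pairs — ties broken toward
smaller library size, then lexicographic id — which keeps the maximum
number of samples on pair chains (for a chain a–b, b–c only b is removed).
A simpler `second_member` policy drops the lexicographically larger member
of every pair. Both are deterministic.

## Synthetic data generator

The generator emulates a 16S-style case/control cohort:

| parameter | default | meaning |
|---|---|---|
| `n_case`, `n_control` | 100, 100 | cohort arms |
| `n_features` | 500 | taxa (OTUs) |
| `n_differential` | 25 | taxa with a class effect (half up, half down in cases) |
| `fold_change` | 3.0 | multiplicative class effect on those taxa |
| `base_abundance_log_mean`, `base_abundance_log_sd` | 0.0, 1.2 | log-normal taxon base abundances |
| `library_size_mean`, `library_size_shape` | 20000, 10 | gamma-distributed sequencing depth |
| `zero_inflation` | 0.05 | independent extra zeroing probability |
| `sample_noise_sd` | 1.0 | per-sample, per-taxon multiplicative log-normal noise |
| `seed` | 0 | full reproducibility |

Counts are drawn multinomially per sample from its class's mean composition
perturbed by the per-sample noise, so the tables are compositional, sparse
and overdispersed relative to pure multinomial sampling — the three
properties downstream methods are sensitive to.

Two dispersion parameters were calibrated jointly against a structural
requirement of the detection problem: the between-class correlation
distribution must terminate clearly below the near-duplicate regime
(r ≈ 0.99), the separation one observes in real cohort histograms and the
premise that makes a maximum-cutoff detector meaningful. With heavier
dominance (`base_abundance_log_sd` = 1.5) a few taxa carry enough mass
that roughly one cohort in twenty contains a chance case–control pair with
r > 0.995 on proportions — indistinguishable from a true duplicate and
unrealistic for independent subjects. The defaults (log-sd 1.2, sample
noise 1.0) keep the between-class maximum ≤ ≈0.985 across 40 simulated
cohorts while spanning ~4–5 orders of magnitude in taxon abundance and
strong inter-individual variability.

**Injection.** A doppelgänger pair is created by copying a randomly chosen
donor: counts are scaled per-feature by exp(N(0, σ²)) (σ =
`noise_sd`), renormalized, and multinomially resampled to the donor's
library size; the draw is retried (up to `max_retries`) until the
donor–copy Pearson correlation on proportions reaches
`target_min_correlation`. Multiplicative noise keeps zeros at zero, and the
copy's library size matches the donor's. The injected samples are appended
with fresh ids and the donor's label; the reduced-diversity character of
real doppelgänger groups is *not* built in — donors are typical samples —
so any diversity difference in simulations is emergent, not forced.

**What the generator does not emulate:** phylogenetic correlation among
taxa, longitudinal/repeated-measure structure, batch effects, and
doppelgängers arising as an atypical convergent subgroup rather than as
literal near-copies. Consequences of the last point are discussed under
*Bootstrap stability* below.

## Leakage dosage experiments

A *dosage level* d is the number of flagged pairs with one member in the
training set and one in the validation set; all other flagged pairs are
kept whole inside training. Splits are class-stratified at
`validation_fraction` (default 0.3; never stated in cohort studies of this
design, so exposed as a parameter), with the lexicographically larger pair
member sent to validation when it belongs to no other flagged pair (the
other member otherwise, so that exactly d pairs straddle). Each level is
repeated `n_repeats` = 50 times with seeds derived deterministically from
(experiment seed, level, repeat).

Classifiers: KNN with k = 5 and Euclidean distance, RBF-kernel SVM at
default regularization, and a 500-tree random forest. KNN and SVM see
features standardized on the training fold (distance and kernel methods are
scale-sensitive); the forest sees raw proportions (scale-invariant).
Metrics: accuracy, F1 and ROC AUC with the case class positive; AUC scores
are the KNN vote fraction, the SVM decision value, and the forest class
probability.

Controls bracket the experiment. The negative control draws accuracies as
Binomial(N, 0.5)/N — random guessing on N validation samples. The positive
control scores the classifiers on a validation set consisting of exact
copies of randomly chosen training samples (min(n_train, nominal
validation size) of them); a 1-NN on this set is a perfect memorizer and
defines the inflation ceiling.

For inflation to be measurable the dosage-0 baseline must sit strictly
between chance and ceiling for every classifier; the simulation used in the
acceptance suite therefore uses a moderate class signal (5% of taxa at
2-fold) on 100+100 samples with 10 injected pairs, where all three
classifiers score ~0.6–0.85 at baseline.

## Association testing and bootstrap stability

Per-feature association uses the two-sided Wilcoxon rank-sum test on
relative abundances (conventions above; features constant across all
samples get p = 1). Benjamini–Hochberg adjustment is available but off by
default, matching the convention of reporting raw per-OTU p-values in
before/after comparisons. The before/after comparison counts features whose
p-values rose, fell, or tied after removal.

Log-fold changes are log₂((mean case proportion + ε)/(mean control
proportion + ε)) with pseudocount ε = 10⁻⁶ — roughly one part per million,
well below any abundance of interest, chosen only to make the ratio finite
for absent taxa (an everywhere-absent feature has LFC exactly 0). Each of
`n_boot` = 100 bootstrap replicates resamples samples with replacement
within class, preserving class sizes; the statistic is the per-feature
variance of LFC across replicates. The percent variance reduction between
two conditions is averaged over features with positive baseline variance
(avoiding 0/0).

**A sign caveat.** Under *duplication* injection — copies of randomly
chosen donors — removing the flagged samples systematically *increases*
bootstrap LFC variance rather than decreasing it: removal shrinks class
sizes (raising the sampling variance of class means by ≈ k/n), and it
converts doubleton carriers of rare taxa back into singletons, making their
presence in resamples less stable. Both effects act in the same direction,
and no generator setting we examined (sparser tables, exact copies,
atypical donors) reverses them. Positive stability gains from removal, as
reported for real cohorts, therefore require doppelgänger samples to form
an atypical subgroup whose double-weighting genuinely inflates resampling
variance — a structure literal near-copy injection does not create. The
acceptance suite asserts the positive-reduction expectation as specified
and documents its failure rather than weakening it; users applying the
bootstrap-stability comparison to real data should interpret the sign
accordingly.

## Co-occurrence networks and attack simulation

Edges connect features whose across-sample correlation on proportions
exceeds the threshold (default 0.7, strict inequality), using the signed
correlation by default (positive co-occurrence) with an absolute-value
option. Constant features are excluded with a warning; isolated nodes are
retained. Average path length is the mean unweighted shortest-path length
over the largest connected component (ties on component size broken by
smallest node label), reported as NaN once that component has fewer than
two nodes; average clustering is the mean local clustering coefficient
with degree-<2 nodes contributing 0. The attack removes nodes uniformly at
random one at a time until none remain, records both metrics after every
removal, and averages per step across `n_replicates` = 100 independent
removal orders (NaN-aware). The three-condition comparison (raw,
doppelgänger-removed, random-removed) removes the *same number* of samples
per class in the random condition as the removal policy did, isolating
which samples were removed from how many.

## Ecology

Richness is the count of features with abundance > 0; Shannon H uses the
natural logarithm over nonzero proportions; Pielou evenness is H/ln(richness),
undefined (NaN) for richness < 2. Bray–Curtis is computed on proportions.
PERMANOVA uses the standard partition of the sum of squared
dissimilarities into among- and within-group components,
F = (SS_among/(k−1))/(SS_within/(n−k)), with
p = (1 + #{permuted F ≥ observed})/(1 + n_permutations) over seeded
whole-label permutations (default 999; p has resolution 1/(n_perm+1)). The
implementation is cross-checked against scikit-bio's in the test suite. A
sample counts as a doppelgänger-group member if it appears in at least one
flagged pair.

## Filtering

Three feature-filter families: total counts (keep features whose summed
count exceeds the threshold — the "library size" of a feature row, i.e. a
per-feature total, not a per-sample depth), prevalence (keep features
present in at least the given fraction of samples), and maximum relative
abundance. For the last, the conventional direction (retain features whose
maximum proportion reaches the threshold) is the default, with the
opposite direction selectable, since "excluding features whose maximum
relative abundance exceeds a threshold" appears in the literature with both
readings. Filters never touch samples or surviving values, and stricter
thresholds keep nested subsets. The robustness sweep re-runs full detection
— including re-deriving the cutoff — after each filter and reports the
pair count plus whether the flagged id-set is unchanged.

## Seeds and problem sizes

All randomness flows from explicit integer seeds; per-module seeds are
derived as the first 4 bytes of SHA-256("seed:module") reduced mod 2³¹, so
subcommands are independently reproducible from one global seed. The test
and acceptance workloads are desk-scale by design: detection oracles on
≤ 12-sample tables (200 draws), injected-pair recovery on 100+100 × 500
tables over 20 seeds, dosage experiments at 50 repeats × 2 levels, null
calibrations at 500 replicates, network oracles on ≤ 10-node graphs, and
PERMANOVA calibration at 99 permutations × 500 replicates.

## Known limitations

- Binary class labels only; no multi-class or cross-dataset search.
- The cutoff is an extreme-value statistic: with very few between-class
  pairs it is noisy, and a single contaminated between-class pair (e.g., a
  mislabeled duplicate) raises the cutoff and masks true doppelgängers.
- Kendall correlation is O(n² samples · m log m) and slow on large cohorts.
- The generator's taxa are independent given the composition; correlation
  structure among taxa is induced only by compositionality and class
  effects, so simulated co-occurrence networks are sparser than real ones
  at the same threshold.
- The bootstrap-stability sign caveat above.
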