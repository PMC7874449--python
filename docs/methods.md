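# Methods

## The model

The unit of analysis is a *feature*: a strain-level draft genome in shotgun
metagenomics, or an OTU/ASV in 16S rRNA data. A **guild** is modelled as a
co-abundance group: a set of features whose abundances rise and fall
together across samples, treated as one ecological functional unit
regardless of taxonomy. The pipeline makes three substantive assumptions:

1. co-abundance is detectable as positive rank correlation (bootstrapped
   Spearman) or, for compositional counts, as positive basis correlation
   (SparCC);
2. a correlation-derived distance `d = 1 − r` orders features so that
   Ward's minimum-variance agglomeration places co-abundant features in
   the same clade;
3. guild membership is decided by a top-down stop rule: a clade is split
   only while its two child clades are *significantly different* under a
   two-group PERMANOVA on the restricted distance matrix; otherwise the
   clade is a guild. This yields a data-driven guild count.

Guild abundance is the exact per-sample sum of member abundances (members
respond concertedly, so the sum is the natural aggregate and conserves
total abundance). Guild–phenotype screening uses Spearman correlation with
Benjamini–Hochberg FDR over all guild × phenotype pairs as a single family
(a per-phenotype family is available via a flag); guilds are categorised
positive / negative / neutral, plus an explicit `mixed` category when
significant associations of both signs coexist, rather than silently
mislabelling such guilds.

## PERMANOVA details

For two groups of sizes n1, n2 (N = n1 + n2) on distances d:

    SS_total   = (1/N) * sum_{i<j} d_ij^2
    SS_within  = sum_g (1/n_g) * sum_{i<j in g} d_ij^2
    pseudo-F   = (SS_total − SS_within) / (SS_within / (N − 2))

The p-value uses the add-one permutation estimator
`p = (1 + #{F_perm >= F_obs}) / (1 + n_perm)`, so p is never 0; ties count
as `>=` (conservative). When the number of distinct relabelings C(N, n1)
does not exceed `n_perm`, all of them are enumerated and the exact p is
reported. Degenerate input (all distances zero) is defined as F = 0,
p = 1. The statistic agrees with `scikit-bio`'s PERMANOVA to machine
precision (cross-checked in the test suite); the permutation units here are
*features*, and the groups are the two child clades of a tree node.

## The selection problem and the calibrated stop rule

The clades tested at a node were *chosen by Ward on the same distance
matrix*, to maximise separation. Because pseudo-F is scale-free, this is
not a small-sample nuisance: on fully exchangeable (structureless)
distances, the Ward-selected top split of a clade of 8 items rejects the
classical label-permutation test at alpha = 0.05 about 91% of the time,
and at 12 items essentially always — at *any* noise amplitude. An
uncorrected recursion therefore keeps splitting homogeneous clades down to
sizes where the exhaustive p-value floor exceeds alpha (6 items and
below), and genuine guilds of 7+ members are shredded.

The default stop rule therefore requires a split to pass **two** tests at
alpha:

* the classical PERMANOVA above (reported in the trail as `p_value`); and
* a selection-calibrated test (`p_selection`): the null distribution is
  the pseudo-F of the split *Ward itself selects* on matrices whose
  off-diagonal entries have been randomly shuffled (exchangeable profiles,
  in the spirit of similarity-profile tests for dendrogram homogeneity).
  Observed F is compared to that null with the add-one estimator.

On exchangeable clades the calibrated test is approximately uniform, so
false splits return to the nominal rate; on genuinely separated clades
both p-values hit the permutation floor and the recursion proceeds. The
classical test is retained both because its exact exhaustive mode makes
small-clade decisions deterministic and because it is the field's familiar
quantity. `selection_adjusted=False` restores the uncorrected behaviour;
a Bonferroni-on-depth option (alpha / 2^depth) is also available, but it
cannot fix the selection problem (the inflation is depth-independent)
while starving deep, genuine splits, so it is off by default.

Per-node random streams are derived from `(seed, node_id)`, so a node's
p-values do not depend on decisions elsewhere in the tree; this makes the
guild count monotone in alpha and the whole partition reproducible.

## Correlation estimators

**Bootstrapped Spearman** (default for genome tables): `n_boot = 1000`
resamples of samples with replacement; the point estimate is the
elementwise median (robust to resample outliers), `support` is the
fraction of resamples agreeing in sign with the median, and with
`filter_nonrobust` (default on) entries whose percentile CI
(`ci_level = 0.95`) spans zero are set exactly to 0 — zeroed, not removed,
so the matrix stays complete and the corresponding distance is the neutral
1. Below 25 samples a warning is emitted: co-abundance networks are not
considered robust under that size.

**SparCC** (for compositional 16S counts, ≥ 4 features): from log-ratio
variances `t_ij = var(log(x_i/x_j))`, basis variances are solved under the
sparse-correlation approximation `[(D−2)I + J] w² = t·1`, and the most
strongly correlated pair above `exclusion_threshold = 0.1` is iteratively
excluded (up to `n_exclusion_iter = 20` rounds) before re-solving. Zeros
are handled with a unit pseudocount, giving a deterministic point estimate;
`n_inner > 1` switches to averaging over Dirichlet resamples of the
composition. Negative basis variances (possible after exclusion) are
clipped to a small positive epsilon with a logged warning; correlations are
clipped to [−1, 1]. At D = 50, n = 200, depth 10⁴ the estimator recovers a
planted basis correlation of 0.8 to within ±0.1; its spurious-correlation
ceiling on independent bases (max |r| ≈ 0.25 over 1225 pairs) equals that
of the oracle correlation computed on the true log-basis, i.e. it is
sampling noise of the max statistic, not compositional artefact.

## The synthetic generator

`simulate_guild_data` emulates the regimes the method is built for:
per-guild latent trajectories `z_g(s) ~ N(0,1)`; member log-abundance
`mu_i + lam·z_g(s) + eps` with `mu_i ~ N(0,1)` (defaults `lam = 1.0`,
`sigma = 0.3`, 5 guilds × 8 features + 20 noise features with private
latents, 60 samples); detection-limit zeros (each feature's lowest
`dropout_prob = 0.3` fraction of abundances set to 0); compositional
closure; multinomial counts at depth 50,000. Phenotypes are linear in
standardised true guild abundance, `y = beta · zscore(A_g) + N(0, sd²)`
(defaults: one guild at beta = +2, one at −2, sd = 0.1); standardising
makes beta comparable across guilds of different mean abundance.

Zeros are modelled as *detection limits*, not independent dropout, for a
substantive reason: zeros in sequencing data occur predominantly where a
feature's abundance falls below detection, and therefore co-vary with the
co-abundance signal itself. Independent Bernoulli zeros at 30% would
destroy within-guild rank correlation (measured: median r drops from
~0.85 to ~0.2) and with it the very structure the generator is supposed to
plant; the detection-limit mechanism keeps marginal sparsity equal to
`dropout_prob` while preserving co-abundance.

What the generator does *not* emulate: phylogenetic correlation between
features, overdispersion beyond multinomial sampling (a Dirichlet option
exists in the SparCC estimator but not the generator), longitudinal
structure, batch effects, and abundance-dependent sequencing biases.
Passing recovery benchmarks on this generator shows the algorithm does
what it claims under its own assumptions — not that real guilds are as
cleanly block-structured as planted ones.

`simulate_cancellation` builds the strain-vs-species scenario: two strains
of one species moving in opposite directions along a latent gradient with
comparable magnitude (linear trajectories `1 ± 0.4u`, clipped at 0.05,
with multiplicative noise), each accompanied by three co-abundant partner
features of other taxa, plus two background guilds; the phenotype is
`effect·u + N(0, 0.3²)` with `effect = 1` by default. Partner magnitudes
are balanced between the up- and down-guilds so the sample totals stay
flat along the gradient — otherwise closure leaks the gradient into every
proportion and the species-level "null" is contaminated by construction.

## Numerical choices and degenerate inputs

* Ward runs on the supplied 1−r distances via the Lance–Williams
  recurrence (`scipy.cluster.hierarchy.linkage(method="ward")` on the
  condensed matrix); no Euclidean embedding is attempted, and tie-breaking
  follows scipy's deterministic merge order.
* `min_clade_size = 2`: singleton clades cannot be meaningfully permuted;
  nodes with a singleton child still record a test but become terminal.
* Prevalence is "strictly greater than": a feature in exactly 20% of
  samples is removed at a 0.2 threshold. Presence means value > 0 — no
  minimum-count detection threshold.
* Missing metadata cells stay missing and are excluded pairwise; pairs
  with fewer than 5 overlapping samples, or a constant series, are
  reported with missing statistics and excluded from the BH family.
* Correlation entries for feature pairs with < 3 overlapping samples fall
  back to r = 0 (neutral distance), with a loud log message.
* Taxon collapse conserves mass exactly; when unclassified features are
  dropped from a relative table the output keeps the exact sums and drops
  the `relative` tag (columns no longer close to 1) with a warning.
* Table writers use 6-significant-digit floats (byte-stable re-writes);
  the partition trail uses shortest round-trip reprs so read∘write is the
  identity.

## Problem sizes used in the shipped benchmarks

The test-suite and acceptance-script runs use 20 simulated datasets for
recovery and cancellation, 500 trials for type-I calibration, 25–50 random
matrices (N ≤ 8) for enumeration exactness, and 3 replicates for SparCC
fidelity; bootstrap correlation uses the full default `n_boot = 1000`.
These sizes give Monte-Carlo standard errors comfortably below the margins
being asserted while keeping a full run on one CPU in the minutes range.

## Known limitations

* The pipeline consumes an already-binned feature table; assembly,
  binning, OTU picking/denoising, and copy-number correction are out of
  scope, as are rarefaction and batch correction.
* PERMANOVA on clades from the same matrix remains a post-selection
  procedure even with the calibrated gate; p-values in the trail are
  decision statistics, not face-value hypothesis tests.
* Guild–phenotype screening is correlational; `positive`/`negative`
  categories are hypotheses about detriment/benefit, not causal claims.
* Categorical phenotypes are accepted in metadata but skipped (with a
  warning) — only continuous phenotypes are correlated.
* Compositional closure can induce real but indirect guild–phenotype
  associations (the worked example in the README shows one); interpreting
  a significant unlinked guild requires this caveat.
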