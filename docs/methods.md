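# Methods

## The soil quality index

The index condenses an entity × indicator table (entities are treatments by
default, replicate samples optionally) into one score per entity in three
steps.

**Membership.** Each indicator is min–max rescaled over the entities,
ascending for nutrients and diversity (SOM, AN, AP, AK, Chao1, Shannon) and
descending for pH and EC, whose lower values indicate better saline–alkaline
soil condition. Endpoints are exact: the extreme-attaining entity maps to 0
or 1. A degenerate indicator (max = min) is mapped to a constant 0.5 rather
than dropped or erroring: it then contributes identically to every entity
and cannot reorder them, preserving continuity as between-entity variance
approaches zero.

**Weights.** PCA is computed by eigendecomposition of the correlation matrix
of the indicator table (equivalently, PCA of column-standardized values), so
the index is invariant to indicator units and to any positive affine
transform of an indicator. Loadings use the factor-loading convention
(eigenvector × √eigenvalue); within each retained component the indicator
weight is its absolute loading normalized to sum to one. Weights are
per-component (W_ij): the loading of indicator i *in a certain component*
defines its weight there, which is the only reading that uses all retained
components' loadings. Eigenvector sign is fixed deterministically
(largest-magnitude entry positive); it is immaterial to the weights, which
take absolute values. Component count m defaults to 4, clamped to the number
of indicators; a cumulative-variance threshold mode is available. With
4 treatment entities the correlation matrix has rank ≤ 3, so the 4th
contribution rate is ≈ 0 and retaining it is harmless.

**Aggregation.** SQI = Σ_j K_j (Σ_i W_ij F_i) with K_j in percent, so the
attainable range is [0, Σ_j K_j] ≤ 100 — the familiar 0–100-point scale for
such indices. Ranking is by descending SQI; exact ties are broken by entity
order and flagged.

If fewer than two indicators vary at all, PCA is undefined; the estimator
falls back to a single uniform component with a warning, leaving all
entities tied (memberships are constant 0.5 in that situation anyway).

Two genuinely open choices are exposed as parameters rather than asserted:
which alpha-diversity indices enter the index (default: Chao1 and Shannon
for both bacteria and fungi; configurable) and whether membership extremes
and PCA operate over treatment means (default, 4 entities) or replicate
samples (12 entities); the result object records which mode produced it.

## Chemistry statistics

Summaries report the sample mean and n−1 standard deviation per treatment ×
indicator — the field-trial convention for "mean ± sd" tables. Treatment
effects use classical one-way ANOVA (F = MS_between/MS_within); an additive
treatment + replicate-block two-way ANOVA is provided as the estimable
analogue of a fixed-effects model with replication when there is one
observation per cell. Degenerate inputs are handled explicitly: all values
identical → F = 0, p = 1; zero within-group variance with unequal means →
p = 0 with a degeneracy flag.

Pairwise comparisons use Tukey's HSD on the studentized range
(Tukey–Kramer for unequal n, via `scipy.stats.tukey_hsd`). Letters are
assigned by the standard sweep over treatments sorted by descending mean:
each maximal run of mutually non-different treatments receives the next
letter, runs nested in an earlier one are absorbed, and "a" marks the
largest-mean group. The resulting partition is a valid cover: treatments
sharing no letter differ at the stated alpha, treatments sharing a letter do
not.

Percent change is 100·(mean_a − mean_b)/mean_b and fold change mean_a/mean_b,
always computed from the treatment means actually supplied.

## Diversity, ordination and distance statistics

Alpha diversity uses bias-corrected Chao1, S_obs + F1(F1−1)/(2(F2+1)),
defined when doubletons are absent; Shannon in natural log (the common
ecology default; base configurable); Pielou evenness H/ln S_obs (0 for a
single taxon). No rarefaction is applied by default; seeded rarefaction to a
chosen depth is available.

Bray–Curtis is computed on relative abundances by default so library-size
differences are not mistaken for community turnover (raw-count mode by
flag). PCoA eigendecomposes the Gower-centered −d²/2 matrix; negative
eigenvalues are excluded both from the coordinates and from the
explained-variance denominator (no Lingoes/Cailliez correction), which keeps
explained percentages interpretable for mildly non-Euclidean distances.

RDA Hellinger-transforms the community table, centers it, standardizes the
indicator matrix, drops collinear columns deterministically left-to-right,
fits multivariate least squares, and reports constrained axes as the PCA of
fitted values with total explained variance as the fitted-to-total trace
ratio.

The Mantel test correlates upper triangles (Pearson) with a one-sided
(positive association) add-one permutation p-value over 999 label
permutations by default, seeded.

The SQI–community coupling uses the regression of pairwise Bray–Curtis
distance on pairwise |ΔSQI|. Because distance pairs are not independent,
significance comes from Mantel-style permutation of sample labels on the SQI
vector. An alternative construction — per-sample mean distance to the
control samples against per-sample SQI — is implemented alongside; neither
is asserted as canonical.

## Co-occurrence networks

OTUs are ranked by mean relative abundance; the top 100 per domain (default;
combined modes selectable) are correlated pairwise (Pearson, on relative
abundances). Edges require |r| > 0.9 and two-tailed p < 0.05, both strict,
with p from t = r√(n−2)/√(1−r²). No multiple-testing correction is applied
by default (the thresholds are conventional raw cutoffs); a
Benjamini–Hochberg mode exists. Constant-abundance OTUs are excluded from
pairing with a warning.

The topology panel reports link counts by sign, average degree 2E/N, density
2E/(N(N−1)), seeded-Louvain modularity on the unweighted unsigned graph,
mean local clustering (0 for degree < 2), and mean shortest-path length over
connected ordered pairs (disconnected pairs excluded). With only 3 samples
in a treatment, p < 0.05 at df = 1 forces |r| ≥ 0.997, so per-treatment
networks at n = 3 carry a loud caveat; pooled-sample networks are the
default for this reason.

## The synthetic scenario

The generator emulates a 4-treatment (bare control CK; tall wheatgrass GF;
chicory JA; alfalfa CP) × 3-replicate trial on severely saline–alkaline
soil.

**Chemistry.** Replicate values are independent normals with the
treatment-level means and SDs of the emulated trial (e.g. control EC
6.70 ± 1.94 mS/m vs ≈1.9 in planted treatments; control AP 1.52 vs ≈12–16
mg/kg), resampled — never clipped, which would bias means — until positive
(pH until inside (0, 14)).

**Communities.** Per domain, a global OTU pool is partitioned across phyla
in proportion to the scenario-average profile; per-OTU base weights are
lognormal (σ = 0.7) for a realistic rank-abundance curve. Each treatment
activates a nested subset of the pool whose size scales with its richness
multiplier vs control (bacteria up to ×1.55, fungi up to ×2.39), and its
mean composition follows its phylum profile. Counts are
Dirichlet-multinomial: α = c·m·S with per-OTU mean concentration c = 50
(the per-OTU parameterization; a total-concentration reading of c would
drown all configured structure in sampling noise) and library size 20,000
reads. Realized Chao1 fold-changes track the multipliers to within ~10%:
Chao1 under-corrects for unseen taxa slightly more in richer treatments at
finite library size, compressing bacterial fold-changes by a few percent —
an inherent property of the estimator, not of the configuration.

**Planted correlation blocks.** Blocks of OTUs share one latent Gaussian
factor per block (latent within-block correlation ρ = 0.995 by default) with
member loadings all positive or alternating in sign. Members respond
*linearly* (amplitude σ = 0.45, clipped at 5% of baseline) rather than
exponentially: an exponential (lognormal) response bounds the Pearson
correlation of anti-correlated pairs far above −1 and can never cross the
|r| > 0.9 edge threshold, while at small amplitudes counting noise
attenuates positive pairs below it; the linear response preserves both sign
and magnitude. Block members get boosted base weight so the top-abundance
filter retains them, and the latent factors are iid across all samples so
planted structure survives pooling.

**What the generator does not emulate** — and what passing tests therefore
do not establish about real data: read-level artifacts (chimeras, primer
bias), phylogenetic structure, zero-inflation beyond the
Dirichlet-multinomial, spatial autocorrelation between plots, and any
within-treatment environmental gradient; chemistry and community are coupled
only through the treatment label, not through continuous covariation.
Network-recovery audits use the *flat* variant of the scenario (equal
richness and shared phylum profiles across treatments), because
treatment-driven covariation in the default scenario produces genuinely
correlated OTU pairs that would be miscounted as false positives.

## Problem sizes and numerical choices

Default simulations use 300 bacterial and 150 fungal control OTUs at 20,000
reads — small enough that a full pipeline run takes seconds while leaving
all estimators in their asymptotically well-behaved regime; stochastic
checks average 8–100 independent scenario realizations depending on the
statistic's variance. Tolerances: exact hand-value oracles at 1e-9;
eigen-based round trips at 1e-9; calibration bands as stated per test.
All randomness flows from a single integer seed through fixed per-stage
streams (seed-sequence derived), making every table byte-reproducible.

## Known limitations

- The index's weights depend on which entities enter the PCA; scores are
  comparable only within one fitted table, not across studies.
- Treatment-mean mode fits a 4-entity PCA: stable and interpretable for a
  ranking, but contribution rates from 4 points are themselves noisy;
  replicate-level mode trades interpretability for more observations.
- Per-treatment networks at 3 replicates are reported only with caveats;
  hundreds-of-edges panels require pooling samples.
- RDA drops collinear indicators rather than regularizing; with 12 samples
  and 6 indicators the fit is usable but near-saturated, and the total
  explained percentage should be read accordingly.
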