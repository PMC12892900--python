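# Methods

This note documents the statistical procedures implemented in `germkit`,
the assumptions behind them, the defaults that matter, and what the
synthetic-data tests do and do not demonstrate about real data.

## Normalization and fold changes

Counts are depth-normalized per cell to a fixed scale factor (default
10,000) and transformed with the natural log1p ("LogNormalize"). Zero
entries stay zero, so sparsity is preserved; a zero-total cell is an error
rather than a silent drop, because quality control is assumed upstream.

Fold changes follow the single-cell convention: de-log the normalized
values, average per group, add a pseudocount of 1 (on the per-10k scale)
to both means, and take log2 of the ratio. Two consequences matter for
interpretation. First, the pseudocount shrinks ratios toward 1 for weakly
expressed genes — a gene needs a baseline mean above roughly 10 per-10k
units before a 4-fold depletion can display |log2FC| > 2. Second, per-cell
depth normalization makes fold changes compositional: transcript mass
gained by upregulated genes deflates every other gene's normalized value
in that condition. Both effects are properties of the convention, not of
any particular dataset.

## Reference differential expression

Single-cell contrasts use a two-sided Wilcoxon rank-sum per gene. For
group sizes up to 8 per side the p-value is exact: all C(n, n_a) label
assignments are enumerated (vectorized as a rank-matrix product) and the
two-sided p is the fraction of assignments whose rank-sum deviates from
its mean at least as much as observed, with midranks for ties. Larger
groups use the tie- and continuity-corrected normal approximation. On
tie-free data the two paths agree within ~0.01 at 8 vs 8; heavy ties
(small discrete counts) can push the disagreement toward ~0.05, a known
limitation of the asymptotic formula at this n, which is why the exact
path exists.

Pseudobulk cohorts with a handful of donors need a different test: the
exact rank-sum p at 4 vs 4 cannot fall below 2/C(8,4) ≈ 0.029, so after
FDR adjustment over thousands of genes nothing can reach 0.05 — the floor
is a property of rank statistics, not of the data. The cohort arm
therefore uses Welch's t on log2(CPM + 1), a standard continuous-p
location test that retains resolution at small n. Genes unexpressed in
both groups are excluded before testing and the count is logged.

Multiplicity control is Benjamini–Hochberg step-up (delegated to
statsmodels behind the `bh_adjust` surface and cross-checked in the test
suite against the min-formula oracle). Adjusted values dominate raw
p-values and are permutation-equivariant.

## Signature derivation

A receptivity signature is derived in two stages. The concordant overlap
keeps genes significant in both the bulk and the single-cell table (FDR <
0.05 each, configurable) whose log2 fold-changes share a sign; genes with
a fold change of exactly zero carry no direction and are excluded. The
dual-threshold filter then keeps genes with |log2FC| strictly greater
than 2 and FDR strictly below 10⁻⁷. By default the filter reads the
single-cell statistics — the signature is named for and localized to the
secretory glandular epithelium, and bulk evidence contributes membership
and direction only — with a `filter_on="both"` flag for the symmetric
variant. Orientation is fixed by passing the receptive stage as the
contrast's first level, so positive log2FC always means receptive-high;
this and every threshold is recorded in the signature's provenance. A
signature with an empty arm is rejected: downstream scoring needs both.

Set overlaps (signature vs. reference panels, cistrome gene lists) use
the upper-tail hypergeometric probability P(X ≥ observed overlap) with
the universe defaulting to the genes tested in both tables.

## Panel scores

The per-cell score of a gene panel is the mean normalized expression of
the panel genes minus the mean over a control pool. Genes are ordered by
mean expression and cut into 24 equal-frequency bins (ties broken by gene
id, so binning is deterministic); for each panel gene, 100 control genes
are drawn from its bin — without replacement when the bin allows it, and
never the gene itself. The pooled (unique) controls define the baseline.
This matches the de-facto standard construction: a random panel scores
≈ 0 by design, and the score is linear in shifts applied to panel genes
whenever no panel gene lands in the control pool. Missing panel genes
are dropped with a warning and recorded, never imputed. The seed is a
required parameter; there is no hidden global randomness.

## Rank enrichment, NES and the GERM score

Preranked enrichment uses the weighted Kolmogorov–Smirnov running sum:
walking the ranked list, a set member increments by |stat|^w normalized
by the in-set total (w = 1 by default) and a non-member decrements by
1/(N − N_hit); ES is the maximum-magnitude deviation, with magnitude ties
resolved to the positive side (a 1e-12 tolerance keeps the full and
hit-position code paths consistent). At w = 0 the statistic reduces to
the classical two-sample KS distance between in-set and out-of-set rank
distributions. If every in-set statistic is zero the hit weights fall
back to equal, keeping the walk defined.

The null is gene permutation: random same-size subsets of the ranked
genes. The sampled p is (1 + b)/(1 + m) where b counts same-sign
permutations at least as extreme and m counts same-sign permutations, so
p never reaches zero and never drops below 1/(n_perm + 1); NES divides ES
by the mean |ES| of same-sign permutations. An exhaustive mode enumerates
all subsets (while C(N, k) ≤ 10⁵) and reports the exact null fraction.
If no permutation shares the observed sign the p floors at 1/(n_perm + 1)
with a warning.

The default ranking statistic is sign(log2FC)·(−log10 p) with p floored
at 1e-300; ties break by |log2FC| then gene id, and the tie rule is
recorded on the ranked list.

The two signature arms combine into score = NES_up − NES_down. The
formula is a design choice (recorded in the result's provenance):
receptive-like profiles rank the up arm high and the down arm low, so the
two terms add, the score is symmetric in the information both arms carry,
and its sign flips (within Monte-Carlo noise) under rank reversal. The
combined p applies Fisher's sum of logs — X² = −2Σ ln pᵢ against
χ²(2k) — to the BH-adjusted arm p-values; cross-dataset meta-analysis
reuses the same combiner over per-dataset combined p-values. Arm seeds
derive deterministically from the caller's seed.

## Stromal classification

Cluster labels are assigned from cross-cluster z-scores (sample SD,
ddof = 1) of the mean normalized expression of SCARA5 and DIO2: DSC when
z(SCARA5) ≥ τ and z(DIO2) < τ, senescent in the mirror case, snDSC when
both clear τ, unclassified otherwise (explicit, never merged). τ defaults
to 0.5. DSC clusters split into CXCL14-high (z ≥ τ) and FOS-high/low at
the median cluster-mean FOS among the remaining DSCs; senescent clusters
split at the median cluster-mean DIO2. Clusters named "proliferative"
pass through unchanged, mirroring pre-labeled proliferative stroma. The
z-rule is a reproducible surrogate for "highest expression" calls made
visually on dot plots; with k of n clusters high on a marker, the high
clusters' z is bounded (≈ 0.65 for 4 of 6), so τ values much above 0.5
would make multi-cluster marker groups unclassifiable by construction.

Composition tables report n(group, stage)/n(stage) and the transposed
normalization (each group's share across stages); proportions sum to one
within the normalizing margin by construction.

## Synthetic endometrium

The generator emulates the statistical structure the pipeline relies on,
not endometrial biology: negative-binomial counts (variance m + φm²,
gene-shared dispersion φ = 0.3) with mean libsize(cell) · π(gene | type,
stage), log-normal library sizes (median 2,500), 11 cell types with a
log-normal per-type expression spread, four stages, deterministic
per-donor cell allocation, and a per-donor pseudobulk cohort with
log-normal donor scaling (σ = 0.15; σ = 0 reproduces exact pseudobulk).

The planted receptivity program (default 120 up + 120 down genes at ±2.5
log2 units, confined to the secretory glandular epithelium in the
mid-secretory stage) is parameterized by target baseline expression
rather than raw weights, for the two fold-change reasons above: the down
arm defaults to 30 per-10k units so a 2⁻²·⁵ depletion remains visible
through the pseudocount, and the up arm is scaled by 2^(−effect) so the
transcript mass the program adds equals the mass it removes, neutralizing
compositional deflation. High baselines are also the realistic regime —
receptivity transcripts are abundant secretory products. Planted and
marker genes are exempt from the per-type expression spread so their
cross-type structure is exactly the planted effect and marker plan.
Stromal marker elevations are large (3–5 log2 units) because the bounded
z geometry above requires a wide high/low gap for the τ rule to separate
clusters reliably.

What the generator does **not** model: doublets, ambient RNA, batch and
donor covariate structure, trajectory/pseudotime structure, gene–gene
correlation beyond compositional coupling, and realistic cluster-label
noise. Passing recovery tests therefore demonstrate that the pipeline's
statistics behave as designed under their own assumptions — overdispersed
counts, depth variation, localized multiplicative effects — not that any
particular real dataset will yield a signature of a given size.

## Problem sizes and numerical choices

The reference study conditions used by the test suite and the acceptance
script are 8,000 genes, ~3,000 cells across four stages, four donors per
stage, and 2,000-permutation enrichment tests; calibration checks use a
4,000-gene two-stage null and 100–200 Monte-Carlo repeats. These sizes
make the full suite run in a couple of minutes on one core while keeping
every Monte-Carlo tolerance (3×SE bands) meaningful. Determinism is part
of the contract: every entry point takes a seed, derived seeds come from
`numpy.random.SeedSequence`, and the CLI manifest contains no timestamps,
so reruns are byte-identical. Exact enumeration paths are capped (rank-sum
at 8 per group, exhaustive permutations at 10⁵ subsets) to bound runtime;
p-values are floored at 1e-300 before logs; BH outputs are clipped at 1.

## Known limitations

- The approximate rank-sum p can deviate from exact by up to ~0.05 under
  heavy ties at n = 8; use larger groups or interpret borderline calls
  with care.
- The GERM score scale depends on the permutation-null normalization, so
  scores are comparable across datasets only under the same n_perm,
  weight and ranking metric.
- `ttest_de` assumes approximately log-normal CPM within groups; with
  strong donor-level composition shifts a mixed model would be more
  appropriate than Welch's t.
- Marker-rule classification presumes clusters are given and markers are
  measured; it does not discover subtypes.
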