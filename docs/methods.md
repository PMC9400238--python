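# Methods

## Pipeline overview

`cenweaver` fits an integrated co-expression network to a genes × samples
TPM matrix in four stages, each materialized and parameterized:

1. **Expression filtering.** Sample outliers are flagged (never dropped)
   by Ward clustering of sample profiles on Euclidean distances; scipy's
   `ward` linkage implements the ward.D2 convention (squared distances
   inside the Lance–Williams update). A sample is flagged when its first
   merge height strictly exceeds the `height_quantile` (default 0.99)
   quantile of all merge heights — identical samples therefore flag
   nothing, and a symmetric configuration (all pairwise distances equal)
   flags nothing because all merge heights coincide. Low-abundance genes
   are then removed by the 3σ rule: the low tail is the lowest
   ⌈`tail_fraction`·N⌉ of the N strictly positive TPM values pooled across
   the whole matrix (default tail 5%); the floor is tail mean + 3 × tail
   sample standard deviation (ddof 1, zero for a singleton). A gene is
   removed only when its maximum TPM is strictly below the floor. Pooling
   positives across the matrix is deliberate: zeros would collapse the
   tail, and a single per-dataset floor matches how a per-species
   expression floor is used in practice. An optional sample→group map
   mean-merges replicate samples before filtering.

2. **Hard-threshold route (PCC + mutual rank).** Pearson correlations are
   computed on the TPM scale via standardized matrix products (optionally
   in row blocks to bound memory; blocked and dense paths agree to float
   round-off). Zero-variance genes are flagged undefined and excluded,
   never NaN-propagated. Two hard filters run on the correlation matrix:
   - *Quantile cuts:* keep pcc ≥ pos_cut or pcc ≤ neg_cut, where the cuts
     are the (1 − top_q) and bottom_q quantiles (linear-interpolation
     convention, pinned for reproducibility) of all defined off-diagonal
     values, optionally tightened by an additive offset. Intervals are
     closed (boundary values kept). The offset applies to both cuts by
     default; `symmetric_offset=False` restricts it to the positive side.
   - *Mutual rank:* directional ranks sort partners by signed PCC
     descending (the convention of the mutual-rank co-expression
     literature), ties broken by lexicographic gene ID for cross-platform
     determinism; `rank_on="abs"` switches to |PCC| ranking so strong
     negative partners also rank highly (useful because these networks
     carry negative edges). MR is the geometric mean of the two
     directional ranks. Retention
     keeps a pair when MR < 30 *or* its smaller directional rank is < 3
     (both strict); `combine="all"` switches OR to AND. OR is the default
     because the two rules are best read as a union of two retention
     passes; both are exposed.
   The two hard filters are unioned into the hard-route edge set.

3. **Soft-threshold route (scale-free power + TOM).** For each β in 1..20
   the unsigned adjacency a = |pcc|^β is formed and per-gene connectivity
   k computed; genes are binned into 10 equal-width connectivity bins and
   log10(bin frequency) regressed on log10(bin mean k). The fit statistic
   is signed R² (negated when the slope is positive); the smallest β with
   signed R² ≥ 0.90 is selected. If no β qualifies the best-fitting β is
   used with a warning. The unsigned TOM with the standard min-denominator
   form then scores all pairs, and pairs with TOM strictly above 0.1
   become candidate edges. Dynamic tree-cut module detection is out of
   scope; its conventional parameters (minModuleSize 30, mergeCutHeight
   0.25, reassignThreshold 0) are accepted and recorded in the manifest
   for provenance only.

4. **Integration and evaluation.** The hard and soft edge sets are merged
   by pair (union by default; intersection available for strict networks),
   concatenating method provenance and keeping all score columns; a shared
   numeric column that genuinely differs between inputs is preserved under
   method-qualified names rather than silently overwritten. Network
   statistics are pure count arithmetic: coverage = genes in network /
   universe, mean connectivity = 2·edges/genes, negative fraction over
   signed edges. Family subnetworks report both "pairs per gene" =
   edges/genes (the convention used when an average of 4.25 co-expressed
   pairs per gene is quoted for 136 edges over 32 genes) and mean
   connectivity = 2·edges/genes, explicitly labeled.

## ROC/AUC evaluation

Gold standards are labeled gene pairs: positives share at least one
annotation term (or, in simulation, a planted module); negatives are a
seeded uniform sample of term-disjoint pairs, size `neg_ratio` × positives.
Pairs absent from an edge set score 0 — absence means "not co-expressed" —
so an edge set is penalized both for missing true pairs and for ranking
spurious ones highly. The AUC is the tie-corrected Mann–Whitney statistic
(average ranks, ties worth half) divided by n_pos·n_neg; the curve is a
threshold sweep over distinct scores. Scores per method: |pcc|, 1/MR, TOM;
for integrated edge sets with heterogeneous provenance the default score is
the per-edge maximum of the min-max-normalized method scores.

The offset grid search evaluates offsets 0, 0.1, 0.2, … up to
`max_offset`, filters edges at each tightened threshold, and reports the
offset maximizing AUC (ties to the smallest; an offset yielding no edges is
recorded with NaN AUC and skipped). Note that tightening can only help when
the un-tightened edge set admits a band of spurious mid-correlation pairs
that outrank weak true pairs; on cleanly separated data the optimum is 0.

## The synthetic generator

The generator emulates the statistical structure the pipeline assumes of a
bulk RNA-seq TPM matrix, with ground truth attached:

- **Latent module profiles** are standardized random walks across samples,
  mimicking developmental/tissue gradients rather than i.i.d. conditions.
  Profiles are Gram–Schmidt-orthogonalized: independent random walks are
  frequently correlated by chance (spurious Brownian correlation, |r| up
  to ~0.8 across 40 samples), which would make cross-module "negative"
  pairs genuinely co-expressed and falsify the planted labels.
- **Module genes** respond linearly on the abundance scale:
  TPM = exp(baseline + ε) · (1 + strength·s·z̃), with baseline uniform on
  [0, 4] nats, ε ~ N(0, noise_sd²), s = −1 with probability
  `anti_corr_fraction` (default 0.2), and z̃ the module profile bounded to
  [−1, 1]. The linear response is deliberate: with noise off, any two
  module genes correlate at exactly +1 or −1 according to their loading
  signs. A log-additive signed loading cannot do this — the Pearson
  correlation of two anti-dependent log-normals is bounded far above −1 —
  so planted anti-correlated pairs would be invisible on the TPM scale the
  pipeline measures. Defaults strength 0.9, noise_sd 0.25 put
  within-module |PCC| near 0.75, typical of tightly co-regulated modules.
- **Background genes** are log-normal noise; **planted low-expression
  genes** are uniform below 0.01 TPM, sized (10 genes × 40 samples = the
  5% tail of 8000 positive values) so the 3σ floor lands above their
  ceiling and the filter's behavior on them is decidable.
- Default scenario: 200 genes = 4×30 module + 70 background + 10 low,
  40 samples, one seed threaded through every draw.

What passing tests on this generator do **not** show about real data: no
count-model (negative-binomial) noise, no batch effects, no
library-size artifacts, no correlated background structure, and modules
are cleanly disjoint — real co-expression is nested and overlapping. The
generator validates the machinery and its thresholds, not biological
discovery performance.

## Numerical conventions and edge cases

- Quantiles: numpy linear interpolation, stated wherever used.
- Rank ties: lexicographic gene ID; degree ties in hub ranking: same.
- PCC values are clipped to [−1, 1] and symmetrized after the blocked
  product; symmetry is enforced to ≤1e−12.
- TOM denominator min(k_i,k_j) + 1 − a_ij is ≥ 1 − a_ij + a_ij = 1 when
  a_ij = 1 (then k ≥ 1) and > 0 otherwise; the all-isolated case yields
  TOM 0 off-diagonal, and the diagonal is 1 by convention.
- Scale-free fit: all-identical connectivities (e.g. duplicated genes,
  |pcc| ≡ 1) are a degenerate fit and raise.
- Enrichment: scipy hypergeometric upper tail P(X ≥ k) (so k = 0 gives
  p = 1), Benjamini–Hochberg across tested terms via statsmodels.
- Determinism: repeated runs with the same seed and config produce
  byte-identical outputs; floats are written with fixed formats
  (`%.17g` for matrices — full round-trip precision — and `%.10g` for
  edge tables and reports).

## Problem sizes

The shipped tests and the acceptance script run on the 200-gene default
scenario (seconds per fit). The correlation, rank, and TOM computations are
dense O(G²) in memory; the blocked PCC product bounds the intermediate
product but the result matrices are still dense, so the practical ceiling
is roughly 20–30k genes on a 16 GB machine. Out-of-core operation for
50k-gene matrices is a known limitation, not implemented.

## Scope notes

Upstream read processing and TPM quantification, homolog identification,
module detection by dynamic tree cut, promoter motif scanning, and
visualization are out of scope; the package consumes a TPM matrix and
optional annotation/family/homolog maps, and emits edge tables and
statistics. Regulatory direction is not modeled: edges are undirected and
carry only a correlation sign.
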