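# Methods

This note documents the statistical models, the synthetic study conditions,
the numerical choices and the known limitations of `rigsa`. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## SNV-to-gene mappings

All interval arithmetic is 0-based half-open internally; readers convert the
1-based inclusive conventions of `.bim`-like variant tables and gene.loc-style
gene models on ingestion, and a SNV at 1-based position `p` lies in `[s, e)`
iff `s ≤ p−1 < e`. This makes union/length arithmetic unambiguous; boundary
behaviour is pinned by tests.

The **baseline model** maps a SNV to a gene when it falls inside the gene
body or within 10 kb of it. Flank features are strand-aware: the upstream
flank covers the region immediately 5′ of the transcription start site, the
downstream flank immediately 3′ of the transcription end site, and neither
overlaps the body. Flanks clip at position 0.

**Regulatory-interaction datasets** are lists of element→gene records.
Processing restricts records to the background gene list, drops
inter-chromosomal records, merges overlapping elements *separately per gene
and source*, and renumbers element identifiers. Locus-pair contact data
(Hi-C-like) are converted to element→gene records symmetrically: if one locus
of a pair overlaps a gene's promoter window (2 kb upstream of the TSS), the
other locus becomes an element of that gene.

**Aggregation** unions, per gene, the SNVs of all its features in genomic
order with deduplication; a SNV's origin is *intragenic* if any baseline
feature of that gene contains it, otherwise *extragenic*. A SNV may map to
several genes with different origins in each.

**Coverage** of a mapping, given a set of summary-statistics SNVs, is the
per-gene union length of features containing at least one such SNV, summed
over genes (base pairs shared between genes count once per gene). An
optional exclusion region (default: none for synthetic genomes; the human
MHC, chr6:28,477,797–33,448,354, is provided as a constant) removes both its
SNVs and any gene whose body overlaps it.

## Summary-statistics processing

Filter order is fixed and covered by a regression test: (1) validity/QC —
single-nucleotide, non-identical, strand-unambiguous alleles (the {A/T, C/G}
pairs are dropped) with finite β, SE > 0, p ∈ (0,1], N > 0; (2) harmonization
against a variant dictionary keyed by (chromosome, position, unordered allele
pair), with a rescue path through the original rs-identifier that overwrites
stale coordinates when the allele pair matches; (3) duplicate removal —
rs-identifiers appearing with *different* statistics are removed entirely,
byte-identical rows collapse to one; (4) dictionary MAF ≥ 1 %; (5) exclusion
region; (6) sample-size outliers more than 5 population SDs from the mean of
the remaining records (two-sided; skipped below 3 records or zero spread).

## Gene scoring

For a gene with `K` mapped SNVs present in the summary statistics, two-sided
p-values become 1-df chi-squares via the upper-tail quantile and the gene
statistic is their mean, `T = (1/K) Σ χ²`. With `z ~ N(0, R)` under the null
(`R` the gene's reference-panel dosage correlation, off-diagonals shrunk by
1e−6 to keep near-duplicate SNVs invertible), `T ~ Σ_k w_k χ²₁` with
`w_k = λ_k(R)/K`.

The tail of this weighted sum is computed by **Ruben's series**: with mixing
parameter β = min w, the law is an infinite *mixture* of central chi-squares
`χ²_{K+2n}(·/β)` with non-negative weights summing to one, so the truncation
error is bounded by the missed mixture mass (tolerance 1e−11). Weights below
5e−3 of the largest are first absorbed into a mean shift of the evaluation
point — a second-order-accurate condensation that keeps the series convergent
under extreme eigenvalue spread. If the series still fails to converge within
20,000 terms the code falls back to Imhof's oscillatory integral and, last,
to a moment-matched gamma. Because the mixture coefficients depend only on
the weights, they are precomputed once per gene and reused across the
permutation control's rescoring passes. p-values of exactly zero are clipped
to 1e−300.

**Adjustment.** Scores on the probit scale (`z = Φ⁻¹(1 − p_raw)`) are
winsorized at the sample mean ± 3 SD and residualized by OLS on four
covariates: log SNV count, within-gene LD (mean off-diagonal |r|; zero for
single-SNV genes), inverse mean minor-allele count (`1 / mean(2·n_panel·MAF)`),
and mean per-SNV sample size. The adjusted score is the residual *plus the
fitted intercept*, preserving the overall probit scale so scores remain
comparable across mappings. The ±3 SD truncation point is a configuration
knob; with fewer than 10 genes the adjustment is skipped. Constant covariates
are dropped; genuinely collinear designs fall back to a tiny ridge penalty
(1e−6).

Gene significance uses Benjamini–Hochberg FDR on the upper-tail p of the
*adjusted* score (α = 0.05).

**Gene–gene correlations.** For genes i, j whose SNV position ranges lie
within a window (default 1 Mb), `cov(T_i, T_j) = (2/(K_i K_j)) Σ_{a∈i,b∈j}
r²_ab` (exact for quadratic forms of Gaussians), and the correlation reduces
to `S_ij / √(S_ii S_jj)` with S the r² sums; entries outside the window are
zero and the matrix is eigenvalue-clipped to positive semi-definite with unit
diagonal.

## Competitive gene-set analysis

Adjusted scores are regressed on [intercept, membership] by GLS with the
gene–gene correlation matrix as error covariance (Cholesky whitening; an
independent statsmodels GLS serves as a cross-check in the tests, never as
the implementation). The one-sided upper-tail p of the membership coefficient
uses a t reference with `n_genes − 2` df; with identity covariance the test
reduces exactly to the pooled two-group t-test. Sets are filtered to a size
range (default 25–200; the desk-scale fixtures use 10–200 because their sets
hold 25–40 genes) after intersection with the scored genes; FDR is adjusted
across the tested collection and the set score is `z_set = Φ⁻¹(1 − p_FDR)`
with p clipped to [1e−300, 1−1e−16].

Redundancy among significant sets is pruned greedily by **Jaccard gene
overlap** (threshold 0.7, ascending p_FDR, ties by set id) — a self-contained
substitute for GO-graph semantic similarity, which is out of scope. When
novel/known/lost sets are counted between two mappings, the union of the two
reduced lists is used and a set significant in both runs counts as known even
if pruned in one (the union-restore rule).

**Gains** between two mappings are score differences over the common scored
universe: probit set scores for sets, adjusted Z for genes; `gain > 0` is
gaining. Entities scored in only one run are excluded and counted.

## EPVP — extragenic p-value push

SNVs in the processed summary statistics are arranged by position within each
chromosome. Per permutation, one offset per chromosome is drawn uniformly
from [0, L−1] (0 allowed; probability 1/L) and the (p, N) pairs are shifted
jointly and circularly: `out[i] = in[(i − offset) mod L]`. Each gene then
reads original values at intragenic positions and shifted values at
extragenic positions, so a shared extragenic SNV receives the same permuted
pair in every gene containing it, per-gene SNV lists never change, and the
shift happens once per permutation rather than per gene (preserving
inter-SNV signal correlation). LD eigenvalues, covariate values other than
mean sample size, and gene–gene correlations are computed once from the
genuine run and reused; per-gene mean sample size is recomputed from the
mixed vector, then the adjustment and the full competitive analysis are
re-run. Default 20 permutations.

Validation of a gaining set compares its genuine score to the permutation
scores: at least 2 sample SDs above the mean is *strongly validated*, 1–2 SD
*mildly validated*, else *invalidated*. Zero permutation SD falls back to the
sign of the difference, with a warning. Count comparisons use a one-sided
one-sample t-test of the permutation counts against the genuine count, and
an exact one-sided binomial (P = 1/2) for novel-versus-lost counts.

## IRED — iterative reduction

Genes of a selected set are ranked by gene-level gain (descending, ties by
gene id), restricted to genes scored in both mappings. At iteration k the
top-k genes are removed from the set (all other sets untouched) and both
mappings' gene-set analyses are re-run in full, including the FDR step across
the whole collection, so `z_set` reflects the reduced set's standing in its
collection. `iterations_to_loss` is the smallest k with set gain ≤ 0; a trace
that never loses within `max_iters` (default |set| − minimum set size) is
censored and counts as robust; a gain is **robust** iff at least 4 removals
are needed. Removal stops early if the reduced set falls below the size
filter. Because removed genes stay in the scored universe (only the set
membership changes), removing a driver whose baseline score was far below the
set average measurably *improves* the baseline run — a genuine property of
the procedure that makes end-to-end driver counting noisy; the deterministic
driver-count checks therefore use constructed score fixtures with
baseline-neutral drivers, while end-to-end robustness is asserted on the
planted-enriched fixture.

## Synthetic study conditions

The generator's defaults define the desk-scale conditions used throughout the
tests and the acceptance script:

- **Reference panel**: 400 samples, one 60 Mb chromosome, 5,000 SNVs in 500
  equicorrelated LD blocks of 10 SNVs with within-block r = 0.45 — at this
  SNV density a block spans roughly 100 kb, a realistic LD-block scale.
  Genotypes are two thresholded latent-Gaussian haplotypes per sample
  (Hardy–Weinberg dosages in {0,1,2}); per-SNV target MAF is uniform on
  [0.05, 0.5] and blocks are redrawn until every empirical MAF clears the 1 %
  floor.
- **Architecture**: 300 non-overlapping genes (20–60 kb bodies, random
  strand), 20 gene sets of 25–40 genes, up to 2 background distal elements
  per gene at 50 kb–1 Mb from the TSS. One enriched set receives 10 causal
  genes, each with one distal element spanning its 3 nearest *clean* SNVs
  (≤ 15 kb; elements are therefore Hi-C-scale). "Clean" means the SNV's whole
  LD block lies outside every gene's baseline footprint, so the baseline
  model misses the planted signal both directly and through LD — the planted
  architecture isolates what augmentation, and only augmentation, can
  recover. A `dispersed_flanks` variant instead places causal SNVs at
  assorted distances up to 100 kb from member genes' TSSs, so the flank
  ladder recovers the signal progressively (used for the coverage-trend
  check).
- **Summary statistics**: per LD block, `z ~ MVN(Rλ, R)` with `R` the
  *empirical* (PSD-regularized) block dosage correlation — matching the LD
  the scoring step sees — and λ the planted per-SNV noncentralities (default
  5.5, the scale of a genome-wide-significant locus). Two-sided
  `p = 2(1 − Φ(|z|))`, β = z·SE with `SE = 1/√(2N·MAF(1−MAF))`, N = 50,000.
  Simulating at the summary-statistics level rather than the phenotype level
  matches the abstraction the whole pipeline consumes and is orders of
  magnitude faster.
- **Negative control**: `reassign_elements_randomly` reassigns every element
  to a random gene on its chromosome, preserving the amount of augmentation
  while destroying its placement.
- **Seeds**: one master seed spawns named child streams ("panel",
  "architecture", "sumstats", "epvp:k", …) so every module is independently
  and jointly reproducible; all three generator operations are
  bit-reproducible for a fixed seed.

What the generator does *not* emulate: recombination-map LD (blocks are
equicorrelated with hard boundaries), allele-frequency/LD coupling,
imputation error, sample-size heterogeneity across SNVs, polygenic
background, and cross-chromosome structure. Passing tests therefore show the
machinery is correct and well-calibrated under clean block LD, not that
real-data augmentation gains will be this unambiguous.

## Numerical choices and degenerate inputs

- Quadratic-form tail tolerance 1e−11 (Ruben), small-weight condensation at
  5e−3 of the maximum weight; probit clipping at [1e−300, 1−1e−16].
- Correlation shrinkage 1e−6 toward zero off-diagonals; monomorphic SNVs are
  an error naming the variant.
- Non-PSD covariance inputs to the GLS are eigenvalue-clipped with a warning;
  an all-member design is an error.
- Zero permutation SD, all-tied Wilcoxon pairs, zero-variance permutation
  counts, and constant trend inputs each have explicit documented behaviour
  (sign rule / p = 1 / exact comparison / error) rather than NaNs.
- Offsets must lie in [0, L); offset 0 is legal and used as the identity
  control, which reproduces the genuine run bit for bit.

## Limitations

- The score-adjustment formulas (winsorization point, residual-plus-intercept
  scale) are this package's documented constructions; they are validated by
  calibration and recovery properties, not by byte-level agreement with any
  external tool.
- EPVP's circular shift can break the concordance between p-value correlation
  and true LD near baseline-model boundaries; no correction is applied.
- The BH-probit set score is piecewise-flat in the FDR step, so set-gain
  trajectories (IRED) can plateau or tie at exactly zero; ≤ 0 counts as lost.
- Redundancy reduction measures gene overlap, not functional similarity.
- Desk-scale fixture sizes (5,000 SNVs, 300 genes, 20 sets, 20 permutations)
  were chosen so the full suite and the acceptance script each run in about a
  minute; all statistics scale to larger inputs without structural change.
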