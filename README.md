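# rigsa

Controlled integration of regulatory interactions into gene-set analyses of
GWAS summary statistics.

## The problem

Gene-set analysis of GWAS data maps single-nucleotide variants (SNVs) to the
genes they might affect, aggregates SNV-level associations into per-gene
scores, and then asks — competitively — which biological processes are
enriched for phenotype association. SNVs are conventionally mapped to genes by
proximity (gene body plus small flanks), yet many causal variants act through
regulatory elements hundreds of kilobases away. Augmenting the proximity
mapping with enhancer–promoter interactions, Hi-C contacts, or similar
regulatory-interaction (RI) datasets promises to recover that distal signal —
but it also inflates mapping size, perturbs per-gene LD structure, and can
make results look better for reasons that have nothing to do with genuine
regulation.

`rigsa` implements the full augmented analysis **and the controls needed to
trust it**:

- **SNV-to-gene mapping** from gene bodies, strand-aware flank ladders
  (U*x*D*y*), and processed RI datasets, with per-gene origin labels
  (*intragenic*: reachable by the baseline body ± 10 kb model; *extragenic*:
  reachable only through augmentation), plus mapping *coverage* (per-gene
  union length of SNV-bearing features).
- **Gene scoring** with the SNP-wise mean statistic: each two-sided SNV
  p-value becomes a 1-df chi-square, the gene statistic is
  `T_g = (1/K) Σ_i χ²₁(p_i)`, and under the null
  `T_g ~ Σ_k (λ_k/K) χ²₁` where `λ_k` are the eigenvalues of the gene's SNV
  correlation matrix `R` from a reference panel. The weighted-chi-square tail
  is evaluated by Ruben's mixture series with Imhof/gamma fallbacks. Scores
  are winsorized and residualized against SNV count, within-gene LD, inverse
  mean minor-allele count, and sample size.
- **Competitive gene-set analysis**: generalized least squares of adjusted
  gene scores on set membership with the LD-induced gene–gene correlation
  matrix as error covariance; one-sided p on the membership coefficient; set
  scores on the probit scale, `z_set = Φ⁻¹(1 − p_FDR)`; Jaccard-overlap
  redundancy pruning; gains between mappings as score differences.
- **EPVP (extragenic p-value push)**: a permutation control that circularly
  shifts SNV p-values and sample sizes within each chromosome and assigns the
  shifted values *only to extragenic SNVs*, preserving every gene's SNV list
  and LD. It yields scores "as if" the augmentation had been random but
  size-matched; gains at least 2 SD above the permutation mean are strongly
  validated, 1–2 SD mildly validated, the rest invalidated.
- **IRED (iterative reduction)**: removes a set's genes cumulatively in order
  of their score gain and re-runs both mappings' gene-set analyses after each
  removal; a gain that survives at least four removals is robust (carried by
  many genes, not an outlier).
- **A synthetic-data generator** producing block-LD reference panels, gene /
  RI / gene-set annotations with *planted* causal SNVs inside distal
  regulatory elements, and marginal GWAS summary statistics
  (`z ~ MVN(Rλ, R)` per LD block) — so the entire pipeline is testable
  without any external data.

## Worked example

```bash
python examples/06_full_pipeline.py
```

prints (seed 1):

```
 mapping  coverage_bp  n_scored_genes  n_sig_genes  n_sig_sets_reduced
    U0D0     11065037             264            0                   0
    U2D2     11191037             271            0                   0
  U10D10     13395037             284            0                   0
  U20D20     18905037             294            0                   0
  U50D50     39265037             300            7                   0
U100D100     70965037             300           18                   0
      RI     14201817             297           11                   1

EPVP (RI augmentation): genuine significant genes 11 vs permutation max 8 (t-test p = 2.61e-12)
  SET001: genuine 5.84 vs permuted -1.50 +/- 0.64 -> strongly_validated
  IRED SET001: iterations to loss 15 (robust=True)

trends: coverage vs significant genes rho = 0.729 (p = 0.0315)
```

Reading it: significant-gene counts grow with mapping coverage (the ρ = 0.73
trend) — big flanks find 18 significant genes but **zero** significant gene
sets, because the extra signal is spread over unrelated genes. The RI
augmentation adds only ~0.8 Mb of coverage yet finds 11 significant genes and
one significant, gaining gene set — exactly the planted one. Its genuine score
sits ~11 SD above the matched-random (EPVP) distribution, and the gain
survives 15 gene removals under IRED: a specific, robust regulatory gain. The
other examples (`examples/01…05`) walk through each stage separately.

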