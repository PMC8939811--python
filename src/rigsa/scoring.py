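"""LD-aware gene scores from mapped SNV p-values (SNP-wise mean statistic).

Each mapped SNV's two-sided p-value is converted to a 1-df chi-square via the
upper-tail quantile; the gene statistic is the mean of these chi-squares.
Under the null the statistic is distributed as ``(1/K) * sum_k lam_k chi2_1``
where ``lam_k`` are the eigenvalues of the gene's SNV correlation matrix ``R``
(from the reference panel), a weighted quadratic form whose upper tail is
evaluated numerically by Imhof's method with a moment-matched gamma fallback.

Gene scores are then adjusted by winsorizing outliers and regressing out
residual effects of SNV count (log), within-gene LD, inverse mean minor-allele
count, and mean sample size; the adjusted score keeps the fitted intercept so
its scale remains comparable across mappings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, stats
from statsmodels.stats.multitest import multipletests

from .mapping import SnvGeneMap
from .simulate import ReferencePanel

__all__ = [
    "LdBlockMatrix",
    "GeneCorrelations",
    "ScoringContext",
    "GeneContext",
    "qf_tail",
    "QuadFormNull",
    "snv_correlation_matrix",
    "score_gene",
    "gene_gene_correlations",
    "adjust_gene_scores",
    "bh_fdr",
    "build_scoring_context",
    "score_genes",
    "rescore_from_vectors",
    "probit_upper",
]

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300
ADJUST_COVARIATES = ["log_n_snvs", "within_gene_ld", "inv_mean_mac", "mean_n"]


@dataclass
class LdBlockMatrix:
    snv_ids: np.ndarray
    R: np.ndarray

    def __post_init__(self) -> None:
        if self.R.shape != (len(self.snv_ids), len(self.snv_ids)):
            raise ValueError("R dimension must equal the number of SNVs")


@dataclass
class GeneCorrelations:
    """Symmetric gene-gene correlation matrix induced by shared/nearby LD."""

    gene_ids: list[str]
    matrix: np.ndarray

    def submatrix(self, gene_ids: list[str]) -> np.ndarray:
        idx = pd.Index(self.gene_ids).get_indexer(gene_ids)
        if (idx < 0).any():
            missing = [g for g, i in zip(gene_ids, idx) if i < 0]
            raise KeyError(f"genes without correlations: {missing[:5]}")
        return self.matrix[np.ix_(idx, idx)]


def probit_upper(p: np.ndarray | float) -> np.ndarray | float:
    """Phi^-1(1 - p) with p clipped away from both endpoints."""
    return stats.norm.isf(np.clip(p, P_FLOOR, 1.0 - 1e-16))


def _ruben_coefficients(
    w: np.ndarray, max_terms: int = 20_000, tol: float = 1e-11
) -> tuple[np.ndarray, float] | None:
    """Mixture weights of Ruben's series for ``sum w_k chi2_1``.

    With beta = min(w) the distribution is an infinite *mixture* of central
    chi-squares chi2_{K+2n}(. / beta) with weights a_n >= 0 summing to 1, so
    the truncation error is bounded by the missed mixture mass.  Returns
    (a, beta) or None if the series has not converged within ``max_terms``.
    """
    beta = w.min()
    ratio = 1.0 - beta / w  # in [0, 1)
    a = np.empty(max_terms)
    a[0] = np.exp(0.5 * np.sum(np.log(beta / w)))
    b = np.empty(max_terms)
    powers = np.ones_like(w)
    for r in range(1, max_terms):
        powers *= ratio
        b[r] = powers.sum()
        a[r] = (b[1 : r + 1][::-1] @ a[:r]) / (2 * r)
        if r % 128 == 0 and 1.0 - a[: r + 1].sum() < tol:
            return a[: r + 1].copy(), float(beta)
    if 1.0 - a.sum() < tol:
        return a, float(beta)
    return None


class QuadFormNull:
    """Precomputed null law of ``sum_k w_k chi2_1`` with a fast tail method.

    The primary representation is Ruben's mixture of central chi-squares
    (exact to ~1e-11 for positive weights); negligible weights are first
    absorbed into a mean shift (a second-order-accurate condensation that
    keeps the series convergent under extreme eigenvalue spread).  When the
    series still fails, the tail falls back to Imhof's oscillatory integral
    and finally to a moment-matched gamma approximation.
    """

    def __init__(self, weights: np.ndarray):
        w = np.asarray(weights, dtype=float)
        w = w[w > 1e-12]
        self.shift = 0.0
        self.method = "one"
        self.w = w
        if w.size == 0:
            return
        small = w < 5e-3 * w.max()
        if small.any() and not np.allclose(w, w[0], rtol=1e-12):
            self.shift = float(w[small].sum())
            w = w[~small]
            self.w = w
        if np.allclose(w, w[0], rtol=1e-12):
            self.method = "chi2"
            self.scale = float(w[0])
            self.df = int(w.size)
            return
        coef = _ruben_coefficients(w)
        if coef is not None:
            a, beta = coef
            self.method = "ruben"
            self.a = a
            self.beta = beta
            self.dfs = w.size + 2 * np.arange(len(a))
            self.missed = 1.0 - float(a.sum())
            return
        self.method = "imhof"

    def tail(self, q: float) -> float:
        """Upper-tail probability P(Q > q)."""
        q = q - self.shift
        if q <= 0 or self.method == "one":
            return 1.0
        if self.method == "chi2":
            return float(stats.chi2.sf(q / self.scale, df=self.df))
        if self.method == "ruben":
            p = float(self.a @ stats.chi2.sf(q / self.beta, df=self.dfs)) + self.missed
            return min(max(p, P_FLOOR), 1.0)
        return self._imhof_tail(q)

    def _imhof_tail(self, q: float) -> float:
        w = self.w

        def integrand(u: float) -> float:
            theta = 0.5 * np.sum(np.arctan(w * u)) - 0.5 * q * u
            rho = np.exp(0.25 * np.sum(np.log1p((w * u) ** 2)))
            return np.sin(theta) / (u * rho)

        try:
            val, err = integrate.quad(integrand, 0.0, np.inf, limit=400)
            p = 0.5 + val / np.pi
            if err < 1e-6 and -1e-8 <= p <= 1 + 1e-8:
                return float(min(max(p, P_FLOOR), 1.0))
        except Exception:  # pragma: no cover - quad rarely raises here
            pass
        mean, var = w.sum(), 2.0 * (w**2).sum()
        shape = mean**2 / var
        scale = var / mean
        return float(min(max(stats.gamma.sf(q, shape, scale=scale), P_FLOOR), 1.0))


def qf_tail(q: float, weights: np.ndarray) -> float:
    """Upper-tail probability of ``sum_k w_k chi2_1`` at ``q``."""
    return QuadFormNull(weights).tail(q)


def snv_correlation_matrix(
    panel: ReferencePanel,
    snv_ids: np.ndarray | list[str],
    shrink: float = 1e-6,
) -> LdBlockMatrix:
    """Pearson correlation of genotype dosages, off-diagonals shrunk by 1-shrink."""
    snv_ids = np.asarray(snv_ids)
    idx = pd.Index(panel.variants["rsid"]).get_indexer(snv_ids)
    if (idx < 0).any():
        missing = snv_ids[idx < 0]
        raise KeyError(f"SNVs not in panel: {list(missing[:5])}")
    geno = panel.genotype_matrix[:, idx].astype(float)
    sd = geno.std(axis=0)
    if (sd == 0).any():
        bad = snv_ids[sd == 0]
        raise ValueError(f"monomorphic SNVs have no correlation: {list(bad[:5])}")
    if len(snv_ids) == 1:
        return LdBlockMatrix(snv_ids, np.array([[1.0]]))
    r = np.corrcoef(geno, rowvar=False)
    r = r * (1.0 - shrink)
    np.fill_diagonal(r, 1.0)
    return LdBlockMatrix(snv_ids, r)


_zero_p_count = 0


def score_gene(pvals: np.ndarray | list[float], R: LdBlockMatrix | np.ndarray) -> tuple[float, float]:
    """SNP-wise mean statistic and its LD-aware p-value for one gene."""
    global _zero_p_count
    p = np.asarray(pvals, dtype=float)
    mat = R.R if isinstance(R, LdBlockMatrix) else np.asarray(R)
    if len(p) != mat.shape[0] or len(p) < 1:
        raise ValueError("number of p-values must equal the dimension of R")
    if (p == 0).any():
        _zero_p_count += int((p == 0).sum())
        p = np.clip(p, P_FLOOR, 1.0)
    chi = stats.chi2.isf(p, df=1)
    t = float(chi.mean())
    k = len(p)
    weights = np.linalg.eigvalsh(mat) / k
    return t, QuadFormNull(weights).tail(t)


def gene_gene_correlations(
    snv_map: SnvGeneMap,
    panel: ReferencePanel,
    window_bp: int = 1_000_000,
    sumstat_snv_ids: set[str] | None = None,
) -> GeneCorrelations:
    """Correlations between gene statistics induced by LD between their SNVs.

    For genes i, j whose SNV position ranges lie within ``window_bp``:
    ``cov(T_i, T_j) = (2 / (K_i K_j)) * sum_{a in i, b in j} r_ab^2`` and the
    within-gene variances analogously, so the correlation reduces to
    ``S_ij / sqrt(S_ii S_jj)`` with ``S`` the r^2 sums.  Entries outside the
    window are zero; the result is eigenvalue-clipped to PSD with unit diagonal.
    """
    var = panel.variants
    rsid_index = pd.Index(var["rsid"])
    geno = panel.genotype_matrix.astype(float)
    Z = (geno - geno.mean(axis=0)) / geno.std(axis=0)
    n = panel.sample_count

    gene_ids: list[str] = []
    gene_idx: list[np.ndarray] = []
    gene_chrom: list[int] = []
    gene_lo: list[int] = []
    gene_hi: list[int] = []
    for gid in sorted(snv_map.genes):
        snvs = snv_map.genes[gid].snv_ids
        if sumstat_snv_ids is not None:
            snvs = np.array([s for s in snvs if s in sumstat_snv_ids])
        if len(snvs) == 0:
            continue
        idx = rsid_index.get_indexer(snvs)
        idx = idx[idx >= 0]
        if len(idx) == 0:
            continue
        gene_ids.append(gid)
        gene_idx.append(idx)
        gene_chrom.append(int(var["chrom"].iloc[idx[0]]))
        pos = var["pos"].to_numpy()[idx]
        gene_lo.append(int(pos.min()))
        gene_hi.append(int(pos.max()))

    m = len(gene_ids)
    mat = np.eye(m)
    self_s = np.empty(m)
    for i in range(m):
        ri = Z[:, gene_idx[i]].T @ Z[:, gene_idx[i]] / n
        self_s[i] = (ri**2).sum()
    for i in range(m):
        for j in range(i + 1, m):
            if gene_chrom[i] != gene_chrom[j]:
                continue
            gap = max(gene_lo[j] - gene_hi[i], gene_lo[i] - gene_hi[j], 0)
            if gap > window_bp:
                continue
            rij = Z[:, gene_idx[i]].T @ Z[:, gene_idx[j]] / n
            s = (rij**2).sum()
            mat[i, j] = mat[j, i] = s / np.sqrt(self_s[i] * self_s[j])

    w, v = np.linalg.eigh(mat)
    if w.min() < 0:
        mat = (v * np.clip(w, 0.0, None)) @ v.T
        d = np.sqrt(np.clip(np.diag(mat), 1e-12, None))
        mat = mat / np.outer(d, d)
        np.fill_diagonal(mat, 1.0)
    return GeneCorrelations(gene_ids, mat)


def adjust_gene_scores(
    scores: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    winsor_sd: float = 3.0,
) -> pd.DataFrame:
    """Winsorize and residualize gene scores against technical covariates.

    ``scores`` must carry ``z_unadjusted``; covariate columns default to the
    ones present in ``scores``.  The adjusted score is the OLS residual plus
    the fitted intercept (scale-preserving).  With fewer than 10 genes the
    adjustment is skipped (with a warning) and scores pass through unchanged.
    """
    out = scores.copy()
    z = out["z_unadjusted"].to_numpy(dtype=float)
    if len(out) < 10:
        logger.warning("adjust_gene_scores: fewer than 10 genes; adjustment skipped")
        out["z_adjusted"] = z
        return out
    cov = covariates if covariates is not None else out[ADJUST_COVARIATES]
    mu, sd = z.mean(), z.std()
    zw = np.clip(z, mu - winsor_sd * sd, mu + winsor_sd * sd) if sd > 0 else z.copy()

    cols = [c for c in cov.columns if np.ptp(cov[c].to_numpy(dtype=float)) > 0]
    X = np.column_stack([np.ones(len(out))] + [cov[c].to_numpy(dtype=float) for c in cols])
    beta, _, rank, _ = np.linalg.lstsq(X, zw, rcond=None)
    if rank < X.shape[1]:
        logger.warning("adjust_gene_scores: collinear covariates; ridge fallback")
        penalty = 1e-6 * np.eye(X.shape[1])
        penalty[0, 0] = 0.0
        beta = np.linalg.solve(X.T @ X + penalty, X.T @ zw)
    resid = zw - X @ beta
    out["z_adjusted"] = resid + beta[0]
    return out


def bh_fdr(pvals: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# end-to-end scoring with a reusable context (shared with the permutation runs)


@dataclass
class GeneContext:
    gene_id: str
    chrom: int
    idx_in_chrom: np.ndarray  # positions of the gene's SNVs in chromosome order
    intragenic: np.ndarray
    weights: np.ndarray  # eigenvalues of R divided by K
    null: QuadFormNull
    log_n_snvs: float
    within_gene_ld: float
    inv_mean_mac: float


@dataclass
class ScoringContext:
    """Everything needed to (re)score genes from per-chromosome (p, n) vectors.

    LD eigenvalues and covariates are computed once from the genuine mapping
    and reference panel; permutation runs reuse them and only swap the
    p-value / sample-size vectors.
    """

    genes: list[GeneContext]
    chrom_rsids: dict[int, np.ndarray]  # sumstat rsids in position order
    chrom_p: dict[int, np.ndarray]
    chrom_n: dict[int, np.ndarray]
    mapping_label: str = "mapping"
    correlations: GeneCorrelations | None = None
    extra: dict = field(default_factory=dict)


def build_scoring_context(
    snv_map: SnvGeneMap,
    sumstats: pd.DataFrame,
    panel: ReferencePanel,
    window_bp: int = 1_000_000,
    compute_correlations: bool = True,
    shrink: float = 1e-6,
) -> ScoringContext:
    """Precompute per-gene LD eigenvalues, covariates and sumstat alignment.

    SNVs mapped to a gene but absent from the summary statistics are removed
    up front; genes left without any SNV receive no score.
    """
    ss = sumstats.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    chrom_rsids: dict[int, np.ndarray] = {}
    chrom_p: dict[int, np.ndarray] = {}
    chrom_n: dict[int, np.ndarray] = {}
    rsid_to_slot: dict[str, tuple[int, int]] = {}
    for c, sub in ss.groupby("chrom", sort=True):
        c = int(c)
        chrom_rsids[c] = sub["rsid"].to_numpy()
        chrom_p[c] = sub["pval"].to_numpy(dtype=float)
        chrom_n[c] = sub["n"].to_numpy(dtype=float)
        for k, rsid in enumerate(chrom_rsids[c]):
            rsid_to_slot[rsid] = (c, k)

    panel_index = pd.Index(panel.variants["rsid"])
    maf = panel.variants["maf"].to_numpy()
    genes: list[GeneContext] = []
    for gid in sorted(snv_map.genes):
        entry = snv_map.genes[gid]
        keep = [i for i, s in enumerate(entry.snv_ids) if s in rsid_to_slot]
        if not keep:
            continue
        snvs = entry.snv_ids[keep]
        intragenic = entry.intragenic[keep]
        slots = [rsid_to_slot[s] for s in snvs]
        chrom = slots[0][0]
        idx_in_chrom = np.array([k for _, k in slots], dtype=int)
        order = np.argsort(idx_in_chrom)
        idx_in_chrom = idx_in_chrom[order]
        snvs = snvs[order]
        intragenic = intragenic[order]

        block = snv_correlation_matrix(panel, snvs, shrink=shrink)
        k = len(snvs)
        weights = np.linalg.eigvalsh(block.R) / k
        if k > 1:
            off = block.R[~np.eye(k, dtype=bool)]
            within_ld = float(np.abs(off).mean())
        else:
            within_ld = 0.0
        pidx = panel_index.get_indexer(snvs)
        mac = 2.0 * panel.sample_count * maf[pidx]
        genes.append(
            GeneContext(
                gene_id=gid,
                chrom=chrom,
                idx_in_chrom=idx_in_chrom,
                intragenic=intragenic,
                weights=weights,
                null=QuadFormNull(weights),
                log_n_snvs=float(np.log(k)),
                within_gene_ld=within_ld,
                inv_mean_mac=float(1.0 / mac.mean()),
            )
        )

    ctx = ScoringContext(
        genes=genes,
        chrom_rsids=chrom_rsids,
        chrom_p=chrom_p,
        chrom_n=chrom_n,
        mapping_label=snv_map.mapping_label,
    )
    if compute_correlations:
        scored = {g.gene_id for g in genes}
        sub = SnvGeneMap(snv_map.mapping_label, {g: snv_map.genes[g] for g in scored})
        ctx.correlations = gene_gene_correlations(
            sub, panel, window_bp=window_bp, sumstat_snv_ids=set(rsid_to_slot)
        )
    return ctx


def rescore_from_vectors(
    ctx: ScoringContext,
    chrom_p: dict[int, np.ndarray] | None = None,
    chrom_n: dict[int, np.ndarray] | None = None,
    adjust: bool = True,
    extragenic_p: dict[int, np.ndarray] | None = None,
    extragenic_n: dict[int, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Score every gene in the context from (possibly permuted) (p, n) vectors.

    When ``extragenic_p``/``extragenic_n`` are given, each gene reads those
    vectors at its *extragenic* SNV positions and the base vectors at its
    intragenic positions (the permutation-control assignment rule).
    """
    chrom_p = chrom_p if chrom_p is not None else ctx.chrom_p
    chrom_n = chrom_n if chrom_n is not None else ctx.chrom_n
    rows = []
    for g in ctx.genes:
        p = chrom_p[g.chrom][g.idx_in_chrom]
        n = chrom_n[g.chrom][g.idx_in_chrom]
        if extragenic_p is not None:
            p = np.where(g.intragenic, p, extragenic_p[g.chrom][g.idx_in_chrom])
        if extragenic_n is not None:
            n = np.where(g.intragenic, n, extragenic_n[g.chrom][g.idx_in_chrom])
        p = np.clip(p, P_FLOOR, 1.0)
        chi = stats.chi2.isf(p, df=1)
        t = float(chi.mean())
        p_raw = g.null.tail(t)
        rows.append(
            {
                "gene_id": g.gene_id,
                "n_snvs": len(p),
                "mean_n": float(n.mean()),
                "t_stat": t,
                "p_raw": p_raw,
                "z_unadjusted": float(probit_upper(p_raw)),
                "log_n_snvs": g.log_n_snvs,
                "within_gene_ld": g.within_gene_ld,
                "inv_mean_mac": g.inv_mean_mac,
            }
        )
    df = pd.DataFrame(rows)
    if adjust and len(df):
        df = adjust_gene_scores(df)
    elif len(df):
        df["z_adjusted"] = df["z_unadjusted"]
    if len(df):
        df["p_adjusted"] = stats.norm.sf(df["z_adjusted"].to_numpy())
        df["p_fdr"] = bh_fdr(np.clip(df["p_adjusted"].to_numpy(), P_FLOOR, 1.0))
    return df


def score_genes(
    snv_map: SnvGeneMap,
    sumstats: pd.DataFrame,
    panel: ReferencePanel,
    window_bp: int = 1_000_000,
    adjust: bool = True,
    compute_correlations: bool = True,
) -> tuple[pd.DataFrame, ScoringContext]:
    """Full gene-scoring pass: build the context and score the genuine data."""
    ctx = build_scoring_context(
        snv_map, sumstats, panel, window_bp=window_bp, compute_correlations=compute_correlations
    )
    return rescore_from_vectors(ctx, adjust=adjust), ctx
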