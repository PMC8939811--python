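"""Competitive gene-set analysis on adjusted gene scores.

For each gene set, membership is regressed on the adjusted gene Z-scores by
generalized least squares with the LD-induced gene-gene correlation matrix as
the error covariance; the one-sided upper-tail p-value of the membership
coefficient (t reference, n_genes - 2 df) tests whether association among the
set's genes exceeds that among all other scored genes.  Set scores are the
probit of one minus the FDR-adjusted p-value, and gains between two mappings
are score differences over the common scored universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .scoring import GeneCorrelations, bh_fdr, probit_upper

__all__ = [
    "GeneSetScore",
    "GainRecord",
    "competitive_gene_set_test",
    "probit_setscore",
    "run_gsa",
    "reduce_redundant_sets",
    "compute_gains",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSetScore:
    set_id: str
    n_genes_tested: int
    beta: float
    p_competitive: float
    p_fdr: float
    z_set: float


@dataclass(frozen=True)
class GainRecord:
    entity_id: str
    score_baseline: float
    score_augmented: float

    @property
    def gain(self) -> float:
        return self.score_augmented - self.score_baseline

    @property
    def gaining(self) -> bool:
        return self.gain > 0


def _psd_cholesky(sigma: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        logger.warning("gene correlation matrix not PSD; clipping eigenvalues")
        w, v = np.linalg.eigh(sigma)
        fixed = (v * np.clip(w, 1e-10, None)) @ v.T
        return np.linalg.cholesky(fixed)


def competitive_gene_set_test(
    z: np.ndarray,
    membership: np.ndarray,
    sigma: GeneCorrelations | np.ndarray | None = None,
) -> tuple[float, float]:
    """GLS enrichment test of member genes' scores against all other genes.

    Returns (beta, one-sided upper-tail p) for the membership coefficient in
    ``z ~ intercept + membership`` with error covariance ``sigma`` (identity
    when None, reducing exactly to the OLS two-group test).
    """
    z = np.asarray(z, dtype=float)
    m = np.asarray(membership, dtype=float)
    if m.sum() < 2 or (1 - m).sum() < 2:
        raise ValueError("need at least 2 member and 2 non-member genes")
    X = np.column_stack([np.ones_like(z), m])
    if sigma is None:
        Xw, zw = X, z
    else:
        mat = sigma.matrix if isinstance(sigma, GeneCorrelations) else np.asarray(sigma)
        L = _psd_cholesky(mat)
        Xw = linalg.solve_triangular(L, X, lower=True)
        zw = linalg.solve_triangular(L, z, lower=True)
    xtx = Xw.T @ Xw
    beta = np.linalg.solve(xtx, Xw.T @ zw)
    resid = zw - Xw @ beta
    df = len(z) - 2
    sigma2 = float(resid @ resid) / df
    se = np.sqrt(sigma2 * np.linalg.inv(xtx)[1, 1])
    tstat = beta[1] / se
    return float(beta[1]), float(stats.t.sf(tstat, df))


def probit_setscore(p_fdr: float | np.ndarray) -> float | np.ndarray:
    """Set score: Phi^-1(1 - p_fdr), with extreme p-values clipped."""
    return probit_upper(p_fdr)


def run_gsa(
    gene_results: pd.DataFrame,
    gene_sets: dict[str, tuple[str, ...]] | list,
    correlations: GeneCorrelations | None = None,
    set_size_range: tuple[int, int] = (25, 200),
) -> pd.DataFrame:
    """Competitive test for every gene set against one mapping's gene scores.

    Sets are filtered to ``set_size_range`` after intersection with the scored
    genes; FDR is adjusted across the tested collection and ``z_set`` is the
    probit set score.  Returns a DataFrame ordered by set_id.
    """
    if not isinstance(gene_sets, dict):
        gene_sets = {gs.set_id: tuple(gs.gene_ids) for gs in gene_sets}
    genes = gene_results["gene_id"].tolist()
    z = gene_results["z_adjusted"].to_numpy(dtype=float)
    gene_pos = {g: i for i, g in enumerate(genes)}

    if correlations is None:
        L = None
    else:
        L = _psd_cholesky(correlations.submatrix(genes))
    X0 = np.ones((len(genes), 1))
    if L is not None:
        X0w = linalg.solve_triangular(L, X0, lower=True)
        zw = linalg.solve_triangular(L, z, lower=True)
    else:
        X0w, zw = X0, z

    rows = []
    for set_id in sorted(gene_sets):
        members = [g for g in gene_sets[set_id] if g in gene_pos]
        if not (set_size_range[0] <= len(members) <= set_size_range[1]):
            continue
        m = np.zeros(len(genes))
        m[[gene_pos[g] for g in members]] = 1.0
        if m.sum() < 2 or (1 - m).sum() < 2:
            continue
        mw = linalg.solve_triangular(L, m, lower=True) if L is not None else m
        Xw = np.column_stack([X0w[:, 0], mw])
        xtx = Xw.T @ Xw
        beta = np.linalg.solve(xtx, Xw.T @ zw)
        resid = zw - Xw @ beta
        df = len(z) - 2
        sigma2 = float(resid @ resid) / df
        se = np.sqrt(sigma2 * np.linalg.inv(xtx)[1, 1])
        p = float(stats.t.sf(beta[1] / se, df))
        rows.append({"set_id": set_id, "n_genes_tested": len(members), "beta": float(beta[1]), "p_competitive": p})
    out = pd.DataFrame(rows, columns=["set_id", "n_genes_tested", "beta", "p_competitive"])
    if len(out):
        out["p_fdr"] = bh_fdr(np.clip(out["p_competitive"].to_numpy(), 1e-300, 1.0))
        out["z_set"] = probit_setscore(out["p_fdr"].to_numpy())
    return out


def reduce_redundant_sets(
    significant_sets: pd.DataFrame,
    gene_sets: dict[str, tuple[str, ...]] | list,
    overlap_threshold: float = 0.7,
) -> list[str]:
    """Greedy redundancy pruning of significant sets by Jaccard gene overlap.

    Sets are visited in ascending ``p_fdr`` order (ties broken by set_id); a
    set is accepted iff its Jaccard overlap with every already-accepted set is
    below ``overlap_threshold``.
    """
    if not isinstance(gene_sets, dict):
        gene_sets = {gs.set_id: tuple(gs.gene_ids) for gs in gene_sets}
    order = significant_sets.sort_values(["p_fdr", "set_id"], kind="mergesort")["set_id"].tolist()
    accepted: list[str] = []
    for set_id in order:
        genes = set(gene_sets[set_id])
        ok = True
        for other in accepted:
            o = set(gene_sets[other])
            jac = len(genes & o) / len(genes | o)
            if jac >= overlap_threshold:
                ok = False
                break
        if ok:
            accepted.append(set_id)
    return accepted


def compute_gains(
    results_baseline: pd.DataFrame,
    results_augmented: pd.DataFrame,
    level: str = "set",
) -> pd.DataFrame:
    """Score gains between two mappings over the common scored universe.

    Set-level gains use the probit set score ``z_set``; gene-level gains use
    the adjusted gene score ``z_adjusted`` (before multiple-testing
    correction).  Entities scored in only one run are excluded (and counted in
    the log).
    """
    if level == "set":
        key, col = "set_id", "z_set"
    elif level == "gene":
        key, col = "gene_id", "z_adjusted"
    else:
        raise ValueError("level must be 'gene' or 'set'")
    b = results_baseline.set_index(key)[col]
    a = results_augmented.set_index(key)[col]
    common = b.index.intersection(a.index)
    dropped = len(b.index.union(a.index)) - len(common)
    if len(common) == 0:
        raise ValueError("no common scored entities between runs")
    if dropped:
        logger.info("compute_gains: excluded %d entities missing from one run", dropped)
    out = pd.DataFrame(
        {
            "entity_id": common,
            "score_baseline": b.loc[common].to_numpy(),
            "score_augmented": a.loc[common].to_numpy(),
        }
    )
    out["gain"] = out["score_augmented"] - out["score_baseline"]
    out["gaining"] = out["gain"] > 0
    return out.reset_index(drop=True)
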