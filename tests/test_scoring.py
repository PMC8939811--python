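"""Gene scoring: quadratic-form null, LD matrices, adjustment, FDR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import rigsa
from rigsa.scoring import (
    QuadFormNull,
    adjust_gene_scores,
    bh_fdr,
    gene_gene_correlations,
    qf_tail,
    score_gene,
    snv_correlation_matrix,
)


class TestQuadFormTail:
    def test_equal_weights_reduce_to_chi_square(self):
        # K independent SNVs, t = 1 -> P(chi2_K >= K)
        for k in (1, 4, 9):
            w = np.full(k, 1.0 / k)
            assert qf_tail(1.0, w) == pytest.approx(stats.chi2.sf(k, df=k), rel=1e-12)

    def test_matches_monte_carlo_for_equicorrelated_gene(self, rng):
        k, r = 5, 0.6
        R = np.full((k, k), r)
        np.fill_diagonal(R, 1.0)
        w = np.linalg.eigvalsh(R) / k
        L = np.linalg.cholesky(R)
        T = ((L @ rng.standard_normal((k, 200_000))) ** 2).mean(axis=0)
        for q in (0.8, 2.0, 4.0):
            mc = float((T > q).mean())
            se = np.sqrt(mc * (1 - mc) / len(T))
            assert abs(qf_tail(q, w) - mc) <= 2 * se

    def test_extreme_weight_spread_still_accurate(self, rng):
        w = np.array([1.0, 0.4, 0.01, 0.0005])
        T = (w[:, None] * rng.standard_normal((4, 400_000)) ** 2).sum(axis=0)
        for q in (1.0, 3.0):
            mc = float((T > q).mean())
            se = np.sqrt(mc * (1 - mc) / len(T))
            assert abs(qf_tail(q, w) - mc) <= 3 * se

    def test_boundary_values(self):
        assert qf_tail(0.0, np.array([0.5, 0.5])) == 1.0
        assert qf_tail(1e6, np.array([0.5, 0.5])) < 1e-12


class TestScoreGene:
    def test_single_snv_identity(self):
        for p in (0.5, 0.01, 1e-8):
            t, p_raw = score_gene([p], np.array([[1.0]]))
            assert p_raw == pytest.approx(p, abs=1e-10)

    def test_order_invariance(self, small_panel):
        snvs = small_panel.variants["rsid"].to_numpy()[:5]
        R = snv_correlation_matrix(small_panel, snvs)
        pvals = np.array([0.9, 0.2, 0.04, 0.5, 0.7])
        t1, p1 = score_gene(pvals, R)
        perm = [3, 0, 4, 2, 1]
        t2, p2 = score_gene(pvals[perm], R.R[np.ix_(perm, perm)])
        assert (t1, p1) == pytest.approx((t2, p2), rel=1e-12)

    def test_lowering_a_pvalue_never_decreases_the_statistic(self):
        R = np.eye(3)
        base, _ = score_gene([0.5, 0.5, 0.5], R)
        lower, _ = score_gene([0.5, 0.05, 0.5], R)
        assert lower > base

    def test_zero_pvalue_clipped_not_fatal(self):
        t, p = score_gene([0.0], np.array([[1.0]]))
        assert 0 < p <= 1 and np.isfinite(t)


class TestSnvCorrelation:
    def test_single_snv(self, small_panel):
        m = snv_correlation_matrix(small_panel, small_panel.variants["rsid"].iloc[:1].to_numpy())
        assert np.array_equal(m.R, [[1.0]])

    def test_duplicate_columns_shrunk_off_diagonal(self, small_panel):
        panel = small_panel
        geno = np.concatenate([panel.genotype_matrix[:, :1]] * 2, axis=1)
        dup = rigsa.ReferencePanel(
            panel.sample_count,
            pd.DataFrame(
                {
                    "rsid": ["a", "b"],
                    "chrom": [1, 1],
                    "pos": [10, 20],
                    "a1": "A",
                    "a2": "G",
                    "maf": 0.2,
                    "block": 0,
                }
            ),
            geno,
        )
        m = snv_correlation_matrix(dup, np.array(["a", "b"]))
        assert m.R[0, 1] == pytest.approx(1 - 1e-6)

    def test_monomorphic_snv_raises_with_name(self, small_panel):
        panel = small_panel
        geno = panel.genotype_matrix.copy()
        geno[:, 0] = 1
        mono = rigsa.ReferencePanel(panel.sample_count, panel.variants.copy(), geno)
        first = panel.variants["rsid"].iloc[0]
        with pytest.raises(ValueError, match=first):
            snv_correlation_matrix(mono, panel.variants["rsid"].to_numpy()[:3])


class TestGeneGeneCorrelations:
    def _map(self, panel, assignment):
        m = rigsa.SnvGeneMap("m")
        idx = pd.Index(panel.variants["rsid"])
        for gid, snvs in assignment.items():
            ii = np.array(idx.get_indexer(snvs))
            m.genes[gid] = rigsa.mapping.GeneSnvs(
                snv_ids=np.asarray(snvs), snv_idx=ii, intragenic=np.ones(len(snvs), bool)
            )
        return m

    def test_identical_snv_sets_give_correlation_one(self, small_panel):
        snvs = small_panel.variants["rsid"].to_numpy()[:3]
        gc = gene_gene_correlations(self._map(small_panel, {"g1": snvs, "g2": snvs}), small_panel)
        assert gc.submatrix(["g1", "g2"])[0, 1] == pytest.approx(1.0)

    def test_distant_genes_are_uncorrelated(self, small_panel):
        v = small_panel.variants["rsid"].to_numpy()
        gc = gene_gene_correlations(
            self._map(small_panel, {"g1": v[:2], "g2": v[-2:]}), small_panel, window_bp=10
        )
        assert gc.submatrix(["g1", "g2"])[0, 1] == 0.0

    def test_matches_empirical_correlation_of_null_statistics(self, small_panel, rng):
        # two 3-SNV genes inside the correlated block: the analytic entry must
        # match the empirical correlation of simulated null mean-chi-square
        # statistics within Monte-Carlo error
        v = small_panel.variants["rsid"].to_numpy()
        gc = gene_gene_correlations(self._map(small_panel, {"g1": v[:3], "g2": v[2:5]}), small_panel)
        got = gc.submatrix(["g1", "g2"])[0, 1]
        geno = small_panel.genotype_matrix[:, :5].astype(float)
        R = np.corrcoef(geno, rowvar=False)
        L = np.linalg.cholesky(R + 1e-10 * np.eye(5))
        z = L @ rng.standard_normal((5, 100_000))
        T1 = (z[:3] ** 2).mean(axis=0)
        T2 = (z[2:5] ** 2).mean(axis=0)
        emp = np.corrcoef(T1, T2)[0, 1]
        se = (1 - emp**2) / np.sqrt(len(T1))
        assert abs(got - emp) <= 3 * se


class TestAdjustment:
    def _scores(self, z, **cov):
        df = pd.DataFrame({"z_unadjusted": z})
        for name in ("log_n_snvs", "within_gene_ld", "inv_mean_mac", "mean_n"):
            df[name] = cov.get(name, 1.0)
        return df

    def test_constant_covariates_pass_through(self, rng):
        z = rng.standard_normal(100)
        out = adjust_gene_scores(self._scores(z))
        # no regression signal: adjusted equals winsorized scores exactly
        mu, sd = z.mean(), z.std()
        zw = np.clip(z, mu - 3 * sd, mu + 3 * sd)
        assert np.allclose(out["z_adjusted"], zw, atol=1e-10)

    def test_planted_covariate_dependence_is_removed(self, rng):
        n = 5000
        logk = rng.uniform(0, 3, n)
        z = 0.8 * logk + rng.standard_normal(n)
        out = adjust_gene_scores(self._scores(z, log_n_snvs=logk))
        r = np.corrcoef(out["z_adjusted"], logk)[0, 1]
        assert abs(r) <= 0.02

    def test_extreme_score_winsorized(self, rng):
        z = np.concatenate([rng.standard_normal(99), [50.0]])
        out = adjust_gene_scores(self._scores(z))
        assert out["z_adjusted"].iloc[-1] < 50.0 / 2

    def test_fewer_than_ten_genes_skips_adjustment(self, rng):
        z = rng.standard_normal(5)
        out = adjust_gene_scores(self._scores(z))
        assert np.array_equal(out["z_adjusted"], z)


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.123]) == pytest.approx([0.123])

    def test_forced_arithmetic(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_matches_brute_force_oracle(self, rng):
        p = rng.uniform(1e-6, 1, 1000)
        got = bh_fdr(p)
        m = len(p)
        order = np.argsort(p)
        brute = np.empty(m)
        # adjusted[i] = min over j with p_j >= p_i of p_j * m / rank_j, capped at 1
        ranked = p[order] * m / (np.arange(m) + 1)
        running = np.minimum.accumulate(ranked[::-1])[::-1]
        brute[order] = np.minimum(running, 1.0)
        assert np.allclose(got, brute, atol=1e-12)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])


class TestCalibration:
    def test_null_gene_pvalues_have_nominal_type_one_error(self):
        # 600 genes over independent LD blocks with lambda=0 summary stats
        panel = rigsa.simulate_reference_panel(300, [(3, 0.5)] * 600, [40_000_000], seed=21)
        ss = rigsa.simulate_sumstats(panel, [], n_gwas=10_000, seed=21)
        m = rigsa.SnvGeneMap("null")
        idx = np.arange(panel.n_variants).reshape(600, 3)
        rsids = panel.variants["rsid"].to_numpy()
        for i, ii in enumerate(idx):
            m.genes[f"g{i:04d}"] = rigsa.mapping.GeneSnvs(
                snv_ids=rsids[ii], snv_idx=ii, intragenic=np.ones(3, bool)
            )
        res, _ = rigsa.score_genes(m, ss, panel, compute_correlations=False, adjust=False)
        frac = float((res["p_raw"] < 0.05).mean())
        se = np.sqrt(0.05 * 0.95 / len(res))
        assert abs(frac - 0.05) <= 3 * se
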