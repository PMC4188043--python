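import numpy as np
import pytest
from scipy import stats

import metaboqtl as mq
from metaboqtl.mixed_model import reml_loglik_at
from conftest import aligned_phenotype


def brute_force_ibs(G):
    n = G.n_strains
    K = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            vals = []
            for s in range(G.n_snps):
                a, b = G.dosage[i, s], G.dosage[j, s]
                if np.isnan(a) or np.isnan(b):
                    continue
                vals.append(1.0 - abs(a - b) / 2.0)
            K[i, j] = np.mean(vals)
    return K


class TestKinship:
    def test_hand_computed_pair(self):
        G = mq.GenotypeMatrix(
            snp_ids=np.array(["r1", "r2", "r3"], dtype=object),
            chrom=np.array(["1"] * 3, dtype=object),
            pos=np.array([1, 2, 3]),
            strains=["A", "B"],
            dosage=np.array([[0.0, 0.0, 2.0], [0.0, 2.0, 2.0]]),
        )
        K = mq.compute_ibs_kinship(G)
        assert K.K[0, 1] == pytest.approx(2.0 / 3.0)

    def test_identical_strains_fully_related(self):
        d = np.array([[0.0, 2.0, 0.0]] * 2)
        G = mq.GenotypeMatrix(
            snp_ids=np.array(["r1", "r2", "r3"], dtype=object),
            chrom=np.array(["1"] * 3, dtype=object),
            pos=np.array([1, 2, 3]),
            strains=["A", "B"],
            dosage=d,
        )
        assert mq.compute_ibs_kinship(G).K[0, 1] == 1.0

    def test_fully_discordant_strains_unrelated(self):
        G = mq.GenotypeMatrix(
            snp_ids=np.array(["r1", "r2"], dtype=object),
            chrom=np.array(["1", "1"], dtype=object),
            pos=np.array([1, 2]),
            strains=["A", "B"],
            dosage=np.array([[0.0, 0.0], [2.0, 2.0]]),
        )
        assert mq.compute_ibs_kinship(G).K[0, 1] == 0.0

    def test_matches_brute_force_with_missing(self):
        rng = np.random.default_rng(0)
        d = rng.choice([0.0, 1.0, 2.0], size=(8, 30)).astype(float)
        d[rng.random(d.shape) < 0.1] = np.nan
        G = mq.GenotypeMatrix(
            snp_ids=np.array([f"r{i}" for i in range(30)], dtype=object),
            chrom=np.array(["1"] * 30, dtype=object),
            pos=np.arange(1, 31),
            strains=[f"s{i}" for i in range(8)],
            dosage=d,
        )
        K = mq.compute_ibs_kinship(G)
        np.testing.assert_allclose(K.K, brute_force_ibs(G), atol=1e-12)

    def test_disjoint_missing_patterns_rejected(self):
        d = np.array([[0.0, np.nan], [np.nan, 2.0]])
        G = mq.GenotypeMatrix(
            snp_ids=np.array(["r1", "r2"], dtype=object),
            chrom=np.array(["1", "1"], dtype=object),
            pos=np.array([1, 2]),
            strains=["A", "B"],
            dosage=d,
        )
        with pytest.raises(ValueError, match="share no"):
            mq.compute_ibs_kinship(G)


class TestREML:
    def test_iid_noise_pushes_genetic_variance_to_boundary(self, default_panel):
        """Pure i.i.d. noise with a structured K: delta goes to the upper
        grid end (all variance residual) and mixed-model p-values track OLS."""
        G, K = default_panel["G"], default_panel["K"]
        rng = np.random.default_rng(42)
        y = rng.normal(size=G.n_strains)
        vc = mq.reml_fit(y, np.ones((y.size, 1)), K.K)
        assert vc.delta > 1e2  # residual dominates genetic variance
        mm = {r.snp_id: r.p_value
              for r in mq.association_scan(y, G, K, mode="null_approx")}
        ols = {r.snp_id: r.p_value for r in mq.ols_scan(y, G)}
        for snp in list(mm)[::7]:
            la, lb = -np.log10(mm[snp]), -np.log10(ols[snp])
            assert la == pytest.approx(lb, rel=0.10, abs=0.05)

    def test_equal_variance_components_recovered(self):
        """y with sigma_g2 = sigma_e2 (delta=1) at n=500: the median REML
        delta over 50 replicates lands in [0.5, 2]."""
        n, m = 500, 300
        deltas = []
        for rep in range(50):
            rng = np.random.default_rng(1000 + rep)
            H = rng.integers(0, 2, size=(n, m)).astype(float)
            fam = np.arange(n) % 10
            for b in range(0, m, 10):
                fa = rng.integers(0, 2, size=10).astype(float)
                mask = rng.random(n) < 0.5
                H[mask, b:b + 10] = fa[fam][mask, None]
            K = 1.0 - (H @ (1 - H).T + (1 - H) @ H.T) / m
            np.fill_diagonal(K, 1.0)
            L = np.linalg.cholesky(K + 1e-6 * np.eye(n))
            y = L @ rng.normal(size=n) + rng.normal(size=n)
            deltas.append(mq.reml_fit(y, np.ones((n, 1)), K).delta)
        assert 0.5 <= np.median(deltas) <= 2.0

    def test_optimum_beats_random_delta_evaluations(self, default_panel):
        G, K = default_panel["G"], default_panel["K"]
        z = default_panel["z"]
        y = aligned_phenotype(z, G, "met001")
        ok = ~np.isnan(y)
        y = y[ok]
        Ksub = K.K[np.ix_(ok.nonzero()[0], ok.nonzero()[0])]
        X = np.ones((y.size, 1))
        vc = mq.reml_fit(y, X, Ksub)
        rng = np.random.default_rng(3)
        lls = [reml_loglik_at(10.0**u, y, X, Ksub)
               for u in rng.uniform(-5, 5, size=1000)]
        assert vc.reml_loglik >= max(lls) - 1e-6

    def test_missing_phenotype_rejected(self, default_panel):
        K = default_panel["K"]
        y = np.zeros(len(K.strains))
        y[0] = np.nan
        with pytest.raises(ValueError, match="complete"):
            mq.reml_fit(y, np.ones((y.size, 1)), K.K)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            mq.reml_fit(np.ones(3), np.ones((3, 2)), np.eye(3))


class TestAssociationScan:
    def test_perfect_signal_underflows(self, default_panel):
        G, K = default_panel["G"], default_panel["K"]
        j = 123
        y = G.dosage[:, j].copy()
        recs = mq.association_scan(y, G, K, mode="exact")
        rec = next(r for r in recs if r.snp_id == str(G.snp_ids[j]))
        assert rec.p_value <= 1e-250
        assert rec.beta == pytest.approx(1.0, abs=1e-8)

    def test_identity_kinship_equals_ols(self):
        cfg = mq.SimulationConfig(n_strains=30, n_snps=50, seed=9)
        G = mq.simulate_genotypes(cfg)
        rng = np.random.default_rng(10)
        y = rng.normal(size=G.n_strains)
        I = mq.KinshipMatrix(strains=list(G.strains), K=np.eye(G.n_strains))
        recs = mq.association_scan(y, G, I, mode="exact")
        n = G.n_strains
        for r in recs:
            g = G.dosage[:, G.snp_index(r.snp_id)]
            X = np.column_stack([np.ones(n), g])
            beta = np.linalg.lstsq(X, y, rcond=None)[0]
            resid = y - X @ beta
            se2 = (resid @ resid) / (n - 2) * np.linalg.inv(X.T @ X)[1, 1]
            p = stats.f.sf(beta[1] ** 2 / se2, 1, n - 2)
            assert abs(p - r.p_value) < 1e-8

    def test_structured_null_ols_inflated_mixed_calibrated(self, default_panel):
        G, K, z, truth = (default_panel[k] for k in ("G", "K", "z", "truth"))
        p_mm, p_ols = [], []
        for met_id in truth.null_set[:20]:
            y = aligned_phenotype(z, G, met_id)
            p_mm += [r.p_value
                     for r in mq.association_scan(y, G, K, mode="null_approx")]
            p_ols += [r.p_value for r in mq.ols_scan(y, G)]
        assert mq.genomic_inflation(p_ols) > 1.2
        assert 0.9 <= mq.genomic_inflation(p_mm) <= 1.1

    def test_type_one_error_controlled(self, default_panel):
        G, K, z, truth = (default_panel[k] for k in ("G", "K", "z", "truth"))
        pvals = []
        for met_id in truth.null_set[:20]:
            y = aligned_phenotype(z, G, met_id)
            pvals += [r.p_value
                      for r in mq.association_scan(y, G, K, mode="null_approx")]
        rate = np.mean(np.asarray(pvals) < 0.01)
        assert 0.005 <= rate <= 0.02

    def test_permuted_labels_give_uniform_p(self, default_panel):
        # p-values within one scan are dependent (shared phenotype, LD), so
        # uniformity is tested over many permutations of a few SNPs drawn
        # from distant LD blocks, which are close to independent draws
        G, K, z = (default_panel[k] for k in ("G", "K", "z"))
        y = aligned_phenotype(z, G, "met000")  # planted QTL, then broken
        pick = np.array([50, 150, 250, 350, 450])
        Gs = mq.GenotypeMatrix(
            snp_ids=G.snp_ids[pick], chrom=G.chrom[pick], pos=G.pos[pick],
            strains=list(G.strains), dosage=G.dosage[:, pick],
        )
        rng = np.random.default_rng(11)
        pvals = []
        for _ in range(200):
            yp = y[rng.permutation(y.size)]
            pvals += [r.p_value
                      for r in mq.association_scan(yp, Gs, K,
                                                   mode="null_approx")]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_monomorphic_snp_skipped(self):
        G = mq.GenotypeMatrix(
            snp_ids=np.array(["r1", "r2"], dtype=object),
            chrom=np.array(["1", "1"], dtype=object),
            pos=np.array([1, 2]),
            strains=["A", "B", "C", "D", "E"],
            dosage=np.array(
                [[0.0, 0], [0, 0], [2, 0], [2, 0], [0, 0]], dtype=float
            ),
        )
        I = mq.KinshipMatrix(strains=list(G.strains), K=np.eye(5))
        y = np.array([0.1, -0.2, 0.3, 0.0, 0.4])
        recs = mq.association_scan(y, G, I, mode="exact")
        assert [r.snp_id for r in recs] == ["r1"]

    def test_null_approx_matches_exact_without_large_effects(self, default_panel):
        """With no large planted effect, the one-time-delta approximation
        tracks per-SNP REML within 15% relative on the -log10 p scale."""
        G, K, z, truth = (default_panel[k] for k in ("G", "K", "z", "truth"))
        checked = 0
        for met_id in truth.null_set[:15]:
            y = aligned_phenotype(z, G, met_id)
            exact = {r.snp_id: r.p_value
                     for r in mq.association_scan(y, G, K, "exact")}
            approx = {r.snp_id: r.p_value
                      for r in mq.association_scan(y, G, K, "null_approx")}
            for s, p in exact.items():
                if min(p, approx[s]) < 1e-4:
                    la, lb = -np.log10(p), -np.log10(approx[s])
                    assert abs(la - lb) / max(la, lb) < 0.15
                    checked += 1
        assert checked > 0

    def test_null_approx_is_conservative_for_large_effects(self, default_panel):
        """When the tested SNP itself carries a large effect, the null-model
        delta absorbs part of the signal, so the approximation loses (never
        gains) significance relative to the exact per-SNP refit."""
        G, K, z, truth = (default_panel[k] for k in ("G", "K", "z", "truth"))
        met_id, snp_id, _ = truth.qtl_map[2]  # planted PVE 0.7
        y = aligned_phenotype(z, G, met_id)
        exact = {r.snp_id: r.p_value for r in mq.association_scan(y, G, K, "exact")}
        approx = {r.snp_id: r.p_value
                  for r in mq.association_scan(y, G, K, "null_approx")}
        assert approx[snp_id] >= exact[snp_id]
        assert exact[snp_id] < 1e-6  # the causal SNP is still found by both
        assert approx[snp_id] < 1e-4


class TestVarianceExplained:
    def test_exact_linear_relation_gives_one(self, default_panel):
        G, K = default_panel["G"], default_panel["K"]
        g = G.dosage[:, 42]
        y = 3.0 * g - 1.0
        assert mq.variance_explained(y, g, K.K) == pytest.approx(1.0, abs=1e-10)

    def test_orthogonal_marker_explains_nothing(self, default_panel):
        G, K = default_panel["G"], default_panel["K"]
        rng = np.random.default_rng(12)
        y = rng.normal(size=G.n_strains)
        g = G.dosage[:, 7]
        assert abs(mq.variance_explained(y, g, K.K)) < 0.1

    def test_zero_variance_phenotype_rejected(self, default_panel):
        G, K = default_panel["G"], default_panel["K"]
        with pytest.raises(ValueError, match="zero variance"):
            mq.variance_explained(np.ones(G.n_strains), G.dosage[:, 0], K.K)

    def test_planted_pve_recovered(self, default_panel):
        G, K, z, truth = (default_panel[k] for k in ("G", "K", "z", "truth"))
        met_id, snp_id, _ = truth.qtl_map[1]  # target PVE 0.5
        y = aligned_phenotype(z, G, met_id)
        g = G.dosage[:, G.snp_index(snp_id)]
        assert mq.variance_explained(y, g, K.K) == pytest.approx(0.5, abs=0.15)
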