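import dataclasses

import numpy as np
import pytest
from scipy import stats

import metaboqtl as mq
from metaboqtl.loci import call_local_eqtls, genotype_r2
from metaboqtl.multiple_testing import pvalue_threshold_at_fdr
from conftest import aligned_phenotype


class TestGenotypeSimulation:
    def test_same_seed_bit_identical(self):
        cfg = mq.SimulationConfig(n_strains=30, n_snps=100, seed=5)
        G1 = mq.simulate_genotypes(cfg)
        G2 = mq.simulate_genotypes(cfg)
        np.testing.assert_array_equal(G1.dosage, G2.dosage)
        assert list(G1.snp_ids) == list(G2.snp_ids)

    def test_homozygous_coding_and_maf_filter(self):
        cfg = mq.SimulationConfig(n_strains=50, n_snps=300, seed=6)
        G = mq.simulate_genotypes(cfg)
        assert set(np.unique(G.dosage)) <= {0.0, 2.0}
        assert np.all(G.maf > 0.05)

    def test_unstructured_panel_has_expected_ibs(self):
        """With no families and single-SNP blocks, genotypes are i.i.d.
        Bernoulli(1/2), so the expected pairwise IBS is exactly 1/2."""
        cfg = mq.SimulationConfig(n_strains=60, n_snps=800, ld_block_size=1,
                                  family_mixing=0.0, seed=7)
        G = mq.simulate_genotypes(cfg)
        K = mq.compute_ibs_kinship(G)
        off = K.K[~np.eye(K.K.shape[0], dtype=bool)]
        # MC sd of the mean off-diagonal entry: 0.5/sqrt(m) per pair, shrunk
        # further by averaging over pairs; allow 3x the per-pair envelope
        mc_sd = 0.5 / np.sqrt(G.n_snps)
        assert abs(off.mean() - 0.5) < 3 * mc_sd

    def test_zero_flip_probability_gives_perfect_block_ld(self):
        cfg = mq.SimulationConfig(n_strains=40, n_snps=100, ld_block_size=50,
                                  ld_block_r=1.0, seed=8)
        G = mq.simulate_genotypes(cfg)
        # SNPs that survived the MAF filter within block one are copies
        first_chrom_block = [
            j for j in range(G.n_snps)
            if G.chrom[j] == "1" and G.pos[j] <= 50 * cfg.snp_spacing_bp
        ]
        for j in first_chrom_block[1:]:
            assert genotype_r2(G.dosage[:, first_chrom_block[0]],
                               G.dosage[:, j]) == pytest.approx(1.0)

    def test_everything_filtered_is_an_error(self):
        cfg = mq.SimulationConfig(n_strains=1, n_snps=20, n_chromosomes=1,
                                  n_families=1, seed=9)
        with pytest.raises(ValueError, match="MAF"):
            mq.simulate_genotypes(cfg)


class TestMetabolomeSimulation:
    def test_same_seed_identical(self, default_panel):
        cfg, G = default_panel["config"], default_panel["G"]
        t1, _ = mq.simulate_metabolome(G, cfg)
        t2, _ = mq.simulate_metabolome(G, cfg)
        np.testing.assert_array_equal(t1.values, t2.values)

    def test_null_metabolites_give_uniform_scan_pvalues(self):
        """No planted signal: mixed-model p-values pooled over metabolites
        are uniform (KS), the null-calibration check."""
        cfg = mq.SimulationConfig(n_strains=60, n_snps=500, n_metabolites=12,
                                  missing_frac=0.0, seed=10)
        G = mq.simulate_genotypes(cfg)
        met, truth = mq.simulate_metabolome(G, cfg)
        assert len(truth.null_set) == 12
        z = mq.preprocess_pipeline(met)
        K = mq.compute_ibs_kinship(G)
        # one representative SNP per LD block to avoid KS over-rejection
        # from dependent tests
        pick = np.arange(0, G.n_snps, 10)
        Gs = mq.GenotypeMatrix(
            snp_ids=G.snp_ids[pick], chrom=G.chrom[pick], pos=G.pos[pick],
            strains=list(G.strains), dosage=G.dosage[:, pick],
        )
        pvals = []
        for met_id in z.variables:
            y = aligned_phenotype(z, Gs, met_id)
            pvals += [r.p_value
                      for r in mq.association_scan(y, Gs, K,
                                                   mode="null_approx")]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_planted_pve_half_recovered(self):
        """Planted PVE 0.5 at n=100: the causal SNP's estimated sample PVE
        averaged over seeds stays within the 0.5 +/- 0.15 envelope."""
        estimates = []
        for seed in range(4):
            cfg = mq.SimulationConfig(n_strains=100, n_snps=300,
                                      planted_qtls=[(0, 150, 0.5)], seed=seed)
            G = mq.simulate_genotypes(cfg)
            met, truth = mq.simulate_metabolome(G, cfg)
            z = mq.preprocess_pipeline(met)
            K = mq.compute_ibs_kinship(G)
            met_id, snp_id, _ = truth.qtl_map[0]
            if snp_id not in set(G.snp_ids):
                continue
            y = aligned_phenotype(z, G, met_id)
            g = G.dosage[:, G.snp_index(snp_id)]
            estimates.append(mq.variance_explained(y, g, K.K))
        assert abs(np.mean(estimates) - 0.5) < 0.15

    def test_heavy_missingness_removed_by_filter(self):
        cfg = mq.SimulationConfig(n_strains=80, n_snps=100, n_metabolites=30,
                                  missing_frac=0.30, seed=11)
        G = mq.simulate_genotypes(cfg)
        met, _ = mq.simulate_metabolome(G, cfg)
        out, dropped = mq.filter_by_missingness(met, 0.20)
        # at 30% missingness nearly every metabolite exceeds the 20% cutoff
        assert len(dropped) > 25

    def test_infeasible_pve_rejected(self):
        with pytest.raises(ValueError, match="PVE"):
            mq.SimulationConfig(planted_qtls=[(0, 0, 1.5)])

    def test_replicate_strains_expanded(self, default_panel):
        met = default_panel["met"]
        counts = {}
        for s in met.strain_of_sample:
            counts[s] = counts.get(s, 0) + 1
        assert counts["strain000"] == 5
        assert counts["strain001"] == 2


class TestTranscriptomeSimulation:
    def test_planted_local_eqtl_recovered(self):
        cfg = mq.SimulationConfig(n_strains=80, n_snps=300, n_transcripts=30,
                                  planted_eqtls=[(0, 100, 0.6)],
                                  missing_frac=0.0, seed=12)
        G = mq.simulate_genotypes(cfg)
        annot = mq.simulate_gene_annotation(G, cfg)
        tx, truth = mq.simulate_transcriptome(G, annot, cfg)
        z = mq.preprocess_pipeline(tx)
        K = mq.compute_ibs_kinship(G)
        records = []
        for tid in z.variables:
            y = aligned_phenotype(z, G, tid)
            records += mq.association_scan(y, G, K, mode="null_approx",
                                           phenotype_id=tid)
        cut = pvalue_threshold_at_fdr([r.p_value for r in records], 0.05)
        eqtls = call_local_eqtls(records, annot, p_threshold=cut)
        tid, snp_id, _ = truth.eqtl_map[0]
        hit = [e for e in eqtls if e.transcript_id == tid]
        assert hit and hit[0].is_local

    def test_null_transcripts_yield_few_eqtls(self):
        cfg = mq.SimulationConfig(n_strains=60, n_snps=200, n_transcripts=40,
                                  missing_frac=0.0, seed=13)
        G = mq.simulate_genotypes(cfg)
        annot = mq.simulate_gene_annotation(G, cfg)
        tx, truth = mq.simulate_transcriptome(G, annot, cfg)
        z = mq.preprocess_pipeline(tx)
        K = mq.compute_ibs_kinship(G)
        records = []
        for tid in z.variables:
            y = aligned_phenotype(z, G, tid)
            records += mq.association_scan(y, G, K, mode="null_approx",
                                           phenotype_id=tid)
        cut = pvalue_threshold_at_fdr([r.p_value for r in records], 0.05)
        eqtls = call_local_eqtls(records, annot, p_threshold=cut) if cut else []
        # with no planted signal the 5% FDR set is expected to be ~empty
        assert len(eqtls) <= 2

    def test_nonlocal_planted_snp_rejected(self):
        cfg = mq.SimulationConfig(n_strains=40, n_snps=200, n_transcripts=5,
                                  planted_eqtls=[(0, 10, 0.5)], seed=14)
        G = mq.simulate_genotypes(cfg)
        annot = mq.simulate_gene_annotation(G, cfg)
        # move the gene far from its planted SNP
        far = mq.GeneAnnotationTable(
            gene_ids=annot.gene_ids,
            chrom=np.array(["19"] * len(annot), dtype=object),
            start=annot.start + 100_000_000,
            end=annot.end + 100_000_000,
        )
        with pytest.raises(ValueError, match="not local"):
            mq.simulate_transcriptome(G, far, cfg)

    def test_same_seed_identical(self):
        cfg = mq.SimulationConfig(n_strains=30, n_snps=100, n_transcripts=8,
                                  seed=15)
        G = mq.simulate_genotypes(cfg)
        annot = mq.simulate_gene_annotation(G, cfg)
        t1, _ = mq.simulate_transcriptome(G, annot, cfg)
        t2, _ = mq.simulate_transcriptome(G, annot, cfg)
        np.testing.assert_array_equal(t1.values, t2.values)


class TestClinicalTraits:
    def test_target_correlation_realized(self):
        cfg = mq.SimulationConfig(n_strains=100, n_snps=100, n_metabolites=5,
                                  n_traits=3, missing_frac=0.0,
                                  trait_correlations=[(0, 0, 0.8)], seed=16)
        G = mq.simulate_genotypes(cfg)
        met, _ = mq.simulate_metabolome(G, cfg)
        traits = mq.simulate_clinical_traits(met, cfg)
        z = mq.preprocess_pipeline(met)
        idx = {s: i for i, s in enumerate(z.strain_ids)}
        m = np.array([z.zvalues[idx[s], 0] for s in traits.strain_of_sample])
        r = mq.bicor(m, traits.values[:, 0])
        assert abs(r - 0.8) < 0.15

    def test_null_traits_give_no_screen_hits(self):
        cfg = mq.SimulationConfig(n_strains=80, n_snps=100, n_metabolites=10,
                                  n_traits=8, missing_frac=0.0, seed=17)
        G = mq.simulate_genotypes(cfg)
        met, _ = mq.simulate_metabolome(G, cfg)
        traits = mq.simulate_clinical_traits(met, cfg)
        z = mq.preprocess_pipeline(met)
        hits = mq.cross_correlate(z.to_table(), traits, 0.05)
        assert len(hits) <= 1

    def test_excessive_rho_rejected(self):
        cfg = mq.SimulationConfig(trait_correlations=[(0, 0, 1.0)])
        G = mq.simulate_genotypes(
            mq.SimulationConfig(n_strains=20, n_snps=50, seed=18))
        met, _ = mq.simulate_metabolome(
            G, mq.SimulationConfig(n_strains=20, n_snps=50, seed=18))
        with pytest.raises(ValueError, match="rho"):
            mq.simulate_clinical_traits(met, cfg)

    def test_same_seed_identical(self):
        cfg = mq.SimulationConfig(n_strains=30, n_snps=50, n_traits=4, seed=19)
        G = mq.simulate_genotypes(cfg)
        met, _ = mq.simulate_metabolome(G, cfg)
        t1 = mq.simulate_clinical_traits(met, cfg)
        t2 = mq.simulate_clinical_traits(met, cfg)
        np.testing.assert_array_equal(t1.values, t2.values)


def test_generator_streams_are_independent():
    """Adding planted eQTLs (a transcriptome concern) does not change the
    genotype or metabolome draws of the same master seed."""
    base = mq.SimulationConfig(n_strains=30, n_snps=100, seed=20)
    more = dataclasses.replace(base, n_transcripts=9,
                               planted_eqtls=[(0, 5, 0.5)])
    G1, G2 = mq.simulate_genotypes(base), mq.simulate_genotypes(more)
    np.testing.assert_array_equal(G1.dosage, G2.dosage)
    m1, _ = mq.simulate_metabolome(G1, base)
    m2, _ = mq.simulate_metabolome(G2, more)
    np.testing.assert_array_equal(m1.values, m2.values)
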