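"""Self-contained diagnostic runs: calibration, recovery and oracle checks.

Each function builds its own synthetic panel from a seed, runs the package
end to end and returns measured quantities.  They are used by the test
suite and by ``scripts/acceptance.py``; sizes are scaled so the whole set
runs in minutes on one CPU (the methods note records the sizes used).
"""

from __future__ import annotations

import math

import numpy as np

from . import (
    GenotypeMatrix,
    SimulationConfig,
    association_scan,
    bicor,
    collapse_to_peaks,
    compute_ibs_kinship,
    estimate_qvalues,
    genomic_inflation,
    genotype_r2,
    ols_scan,
    preprocess_pipeline,
    pvalue_threshold_at_fdr,
    reml_fit,
    simulate_gene_annotation,
    simulate_genotypes,
    simulate_human_summary,
    simulate_metabolome,
    simulate_synteny_map,
    simulate_transcriptome,
    variance_explained,
)
from .loci import call_local_eqtls, find_candidate_genes
from .mixed_model import KinshipMatrix, reml_loglik_at


def _aligned(z, G, variable):
    idx = {s: i for i, s in enumerate(z.strain_ids)}
    j = z.variables.index(variable)
    return np.array([z.zvalues[idx[s], j] for s in G.strains])


def calibration_lambdas(seed: int = 0, n_strains: int = 100,
                        n_snps: int = 2000, n_null: int = 50) -> dict:
    """Genomic-control inflation of the mixed model vs naive OLS on a
    structured all-null panel."""
    cfg = SimulationConfig(n_strains=n_strains, n_snps=n_snps,
                           n_metabolites=n_null, missing_frac=0.0, seed=seed)
    G = simulate_genotypes(cfg)
    met, _ = simulate_metabolome(G, cfg)
    z = preprocess_pipeline(met)
    K = compute_ibs_kinship(G)
    p_mm, p_ols = [], []
    for met_id in z.variables:
        y = _aligned(z, G, met_id)
        p_mm += [r.p_value for r in association_scan(y, G, K, "null_approx")]
        p_ols += [r.p_value for r in ols_scan(y, G)]
    return {
        "lambda_mixed": genomic_inflation(p_mm),
        "lambda_ols": genomic_inflation(p_ols),
        "n_tests": len(p_mm),
    }


def empirical_fdr(seed: int = 0, n_replicates: int = 20, level: float = 0.05,
                  n_strains: int = 100, n_snps: int = 500,
                  n_alt: int = 10, n_null: int = 10,
                  alt_pve: float = 0.5) -> dict:
    """Observed false-discovery proportion among q <= level calls over
    seeded replicate panels with a known null/alternative split.

    A discovery counts as false when its phenotype carries no planted
    signal (LD neighbours of a causal SNP are genuine signal, not error).
    """
    fdps, n_sig_total = [], 0
    for rep in range(n_replicates):
        rep_seed = (seed * 1000 + rep) % (2**31 - 1)
        rng = np.random.default_rng(rep_seed)
        planted = [
            (i, int(rng.integers(0, n_snps * 0.8)), alt_pve)
            for i in range(n_alt)
        ]
        cfg = SimulationConfig(
            n_strains=n_strains, n_snps=n_snps,
            n_metabolites=n_alt + n_null, planted_qtls=planted,
            missing_frac=0.0, seed=rep_seed,
        )
        G = simulate_genotypes(cfg)
        met, truth = simulate_metabolome(G, cfg)
        z = preprocess_pipeline(met)
        K = compute_ibs_kinship(G)
        null_ids = set(truth.null_set)
        records = []
        for met_id in z.variables:
            y = _aligned(z, G, met_id)
            records += association_scan(y, G, K, "null_approx",
                                        phenotype_id=met_id)
        q = estimate_qvalues([r.p_value for r in records]).qvalues
        sig = [r for r, qv in zip(records, q) if qv <= level]
        if sig:
            false = sum(r.phenotype_id in null_ids for r in sig)
            fdps.append(false / len(sig))
            n_sig_total += len(sig)
        else:
            fdps.append(0.0)
    fdps = np.asarray(fdps)
    return {
        "empirical_fdr": float(fdps.mean()),
        "mc_sd": float(fdps.std(ddof=1)),
        "bound": level + 2 * float(fdps.std(ddof=1)) / math.sqrt(n_replicates),
        "n_significant_total": n_sig_total,
        "n_replicates": n_replicates,
    }


def pve_recovery(seed: int = 0, n_reps: int = 5,
                 targets: tuple = (0.3, 0.5, 0.7),
                 n_strains: int = 100, n_snps: int = 600) -> dict:
    """Estimated sample PVE of planted causal SNPs, and whether the peak
    window (1 Mb each side) contains the causal SNP for PVE >= 0.4."""
    estimates: dict[float, list] = {t: [] for t in targets}
    window_hits, window_total = 0, 0
    for rep in range(n_reps):
        rep_seed = (seed * 997 + rep) % (2**31 - 1)
        planted = [
            (i, 100 + i * 200, t) for i, t in enumerate(targets)
        ]
        cfg = SimulationConfig(
            n_strains=n_strains, n_snps=n_snps, n_metabolites=len(targets),
            planted_qtls=planted, missing_frac=0.0, seed=rep_seed,
        )
        G = simulate_genotypes(cfg)
        met, truth = simulate_metabolome(G, cfg)
        z = preprocess_pipeline(met)
        K = compute_ibs_kinship(G)
        records = []
        for met_id in z.variables:
            y = _aligned(z, G, met_id)
            records += association_scan(y, G, K, "null_approx",
                                        phenotype_id=met_id)
        p_cut = pvalue_threshold_at_fdr([r.p_value for r in records], 0.05,
                                        pi0=1.0)
        snp_set = set(G.snp_ids)
        for (met_id, snp_id, _), target in zip(truth.qtl_map, targets):
            if snp_id not in snp_set:
                continue
            y = _aligned(z, G, met_id)
            g = G.dosage[:, G.snp_index(snp_id)]
            estimates[target].append(variance_explained(y, g, K.K))
            if target >= 0.4:
                window_total += 1
                sig = [r for r in records
                       if r.phenotype_id == met_id and r.p_value <= p_cut]
                peaks = collapse_to_peaks(sig, G)
                causal_pos = int(G.pos[G.snp_index(snp_id)])
                causal_chrom = str(G.chrom[G.snp_index(snp_id)])
                if any(pk.chrom == causal_chrom
                       and pk.window[0] <= causal_pos <= pk.window[1]
                       for pk in peaks):
                    window_hits += 1
    return {
        "pve_estimates": {t: float(np.mean(v)) for t, v in estimates.items()},
        "window_hit_rate": window_hits / window_total if window_total else None,
        "n_windows": window_total,
        "n_reps": n_reps,
    }


def ols_oracle_max_diff(seed: int = 0, n_strains: int = 40,
                        n_snps: int = 80) -> float:
    """Largest |p_mixed - p_OLS| with an identity kinship, against a
    from-scratch least-squares F-test."""
    from scipy import stats

    cfg = SimulationConfig(n_strains=n_strains, n_snps=n_snps, seed=seed)
    G = simulate_genotypes(cfg)
    rng = np.random.default_rng(seed + 1)
    y = rng.normal(size=G.n_strains)
    I = KinshipMatrix(strains=list(G.strains), K=np.eye(G.n_strains))
    recs = association_scan(y, G, I, mode="exact")
    n = G.n_strains
    worst = 0.0
    for r in recs:
        g = G.dosage[:, G.snp_index(r.snp_id)]
        X = np.column_stack([np.ones(n), g])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        resid = y - X @ beta
        se2 = (resid @ resid) / (n - 2) * np.linalg.inv(X.T @ X)[1, 1]
        p = float(stats.f.sf(beta[1] ** 2 / se2, 1, n - 2))
        worst = max(worst, abs(p - r.p_value))
    return worst


def reml_brute_force_gap(seed: int = 0, n_random: int = 1000) -> float:
    """REML optimum log-likelihood minus the best of ``n_random`` random
    delta evaluations (non-negative up to the refinement tolerance)."""
    cfg = SimulationConfig(n_strains=100, n_snps=400,
                           planted_qtls=[(0, 200, 0.5)], missing_frac=0.0,
                           seed=seed)
    G = simulate_genotypes(cfg)
    met, _ = simulate_metabolome(G, cfg)
    z = preprocess_pipeline(met)
    K = compute_ibs_kinship(G)
    y = _aligned(z, G, "met000")
    X = np.ones((y.size, 1))
    vc = reml_fit(y, X, K.K)
    rng = np.random.default_rng(seed + 2)
    best = max(reml_loglik_at(10.0**u, y, X, K.K)
               for u in rng.uniform(-5, 5, size=n_random))
    return vc.reml_loglik - best


def oracle_equivalence(seed: int = 0) -> dict:
    """Worst absolute deviation of each core primitive from an independent
    brute-force implementation on random fixtures."""
    rng = np.random.default_rng(seed)

    # IBS kinship vs double loop
    d = rng.choice([0.0, 1.0, 2.0], size=(10, 40)).astype(float)
    d[rng.random(d.shape) < 0.1] = np.nan
    G = GenotypeMatrix(
        snp_ids=np.array([f"r{i}" for i in range(40)], dtype=object),
        chrom=np.array(["1"] * 40, dtype=object),
        pos=np.arange(1, 41),
        strains=[f"s{i}" for i in range(10)],
        dosage=d,
    )
    K = compute_ibs_kinship(G).K
    err_k = 0.0
    for i in range(10):
        for j in range(10):
            if i == j:
                continue
            vals = [1.0 - abs(a - b) / 2.0
                    for a, b in zip(G.dosage[i], G.dosage[j])
                    if not (np.isnan(a) or np.isnan(b))]
            err_k = max(err_k, abs(K[i, j] - np.mean(vals)))

    # genotype R^2 vs direct Pearson
    err_r2 = 0.0
    for _ in range(50):
        g1 = rng.choice([0.0, 2.0], size=20)
        g2 = rng.choice([0.0, 2.0], size=20)
        if len(set(g1)) < 2 or len(set(g2)) < 2:
            continue
        mx, my = g1.mean(), g2.mean()
        num = np.sum((g1 - mx) * (g2 - my))
        den = np.sqrt(np.sum((g1 - mx) ** 2) * np.sum((g2 - my) ** 2))
        err_r2 = max(err_r2, abs(genotype_r2(g1, g2) - (num / den) ** 2))

    # bicor vs direct transcription of the biweight formula
    def ref_bicor(x, y):
        def terms(v):
            med = np.median(v)
            mad = np.median(np.abs(v - med))
            if mad == 0:
                return v - v.mean()
            u = (v - med) / (9 * mad)
            w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
            return (v - med) * w
        a, b = terms(np.asarray(x)), terms(np.asarray(y))
        return float(np.sum(a * b) / np.sqrt(np.sum(a**2) * np.sum(b**2)))

    err_bicor = 0.0
    for _ in range(100):
        n = int(rng.integers(5, 30))
        x = rng.normal(size=n)
        y = 0.4 * x + rng.normal(size=n)
        err_bicor = max(err_bicor, abs(bicor(x, y) - ref_bicor(x, y)))

    # q-values with pi0 = 1 vs a step-up BH enumeration written here
    p = np.concatenate([rng.uniform(size=200), rng.uniform(0, 1e-3, 20)])
    q = estimate_qvalues(p, pi0=1.0).qvalues
    m = p.size
    order = np.argsort(p)
    bh = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        bh[idx] = min(running, 1.0)
    err_q = float(np.max(np.abs(q - bh)))

    # greedy peak collapsing vs exhaustive best-per-component (on fixtures
    # where the definitions coincide; see the loci tests for divergence)
    from .datatypes import AssociationRecord
    import itertools as it

    err_peaks = 0.0
    for trial in range(20):
        base = rng.choice([0.0, 2.0], size=25)
        cols = []
        for _ in range(5):
            g = base.copy()
            flip = rng.random(25) < rng.uniform(0.05, 0.6)
            g[flip] = 2.0 - g[flip]
            if np.all(g == g[0]):
                g[0] = 2.0 - g[0]
            cols.append(g)
        Gp = GenotypeMatrix(
            snp_ids=np.array([f"s{j}" for j in range(5)], dtype=object),
            chrom=np.array(["1"] * 5, dtype=object),
            pos=np.arange(1, 6) * 1000,
            strains=[f"t{i}" for i in range(25)],
            dosage=np.column_stack(cols),
        )
        recs = [
            AssociationRecord(
                phenotype_id="m", snp_id=f"s{j}", chrom="1",
                pos=(j + 1) * 1000, beta=1.0, f_stat=9.0,
                p_value=float(rng.uniform(1e-12, 1e-6)), n_used=25,
            )
            for j in range(5)
        ]
        adj = {j: set() for j in range(5)}
        for a, b in it.combinations(range(5), 2):
            if genotype_r2(cols[a], cols[b]) > 0.5:
                adj[a].add(b)
                adj[b].add(a)
        seen, comps = set(), []
        for j in range(5):
            if j in seen:
                continue
            comp, stack = set(), [j]
            while stack:
                u = stack.pop()
                if u in comp:
                    continue
                comp.add(u)
                stack.extend(adj[u] - comp)
            seen |= comp
            comps.append(comp)
        peaks = collapse_to_peaks(recs, Gp)
        greedy_sets = sorted(
            sorted(int(s[1:]) for s in pk.member_snps) for pk in peaks
        )
        if greedy_sets == sorted(sorted(c) for c in comps):
            oracle = {f"s{min(c, key=lambda j: recs[j].p_value)}"
                      for c in comps}
            if {pk.snp_id for pk in peaks} != oracle:
                err_peaks = 1.0
    return {
        "ibs_kinship": err_k,
        "genotype_r2": err_r2,
        "bicor": err_bicor,
        "qvalue_vs_bh": err_q,
        "peak_collapsing": err_peaks,
    }


def colocalization_demo(seed: int = 0) -> dict:
    """Plant a metabolite QTL and a transcript local eQTL on the same SNP;
    the gene must come back as the sole candidate at the metabolite locus
    (the glycerol-3-phosphate / Gpd2 style of evidence)."""
    causal = 150
    cfg = SimulationConfig(
        n_strains=80, n_snps=300, n_metabolites=4, n_transcripts=6,
        planted_qtls=[(0, causal, 0.6)], planted_eqtls=[(0, causal, 0.6)],
        missing_frac=0.0, seed=seed,
    )
    G = simulate_genotypes(cfg)
    met, truth = simulate_metabolome(G, cfg)
    annot = simulate_gene_annotation(G, cfg)
    tx, tx_truth = simulate_transcriptome(G, annot, cfg)
    zm = preprocess_pipeline(met)
    zt = preprocess_pipeline(tx)
    K = compute_ibs_kinship(G)

    met_id, snp_id, _ = truth.qtl_map[0]
    y = _aligned(zm, G, met_id)
    met_recs = association_scan(y, G, K, "exact", phenotype_id=met_id)
    pool = list(met_recs)
    for other in zm.variables:
        if other != met_id:
            pool += association_scan(_aligned(zm, G, other), G, K,
                                     "null_approx", phenotype_id=other)
    p_cut = pvalue_threshold_at_fdr([r.p_value for r in pool], 0.05, pi0=1.0)
    sig = [r for r in met_recs if r.p_value <= p_cut]
    peaks = collapse_to_peaks(sig, G)

    tx_recs = []
    for tid in zt.variables:
        tx_recs += association_scan(_aligned(zt, G, tid), G, K,
                                    "null_approx", phenotype_id=tid)
    tx_cut = pvalue_threshold_at_fdr([r.p_value for r in tx_recs], 0.05,
                                     pi0=1.0)
    eqtls = call_local_eqtls(tx_recs, annot, p_threshold=tx_cut)
    local = [e for e in eqtls if e.is_local]
    planted_gene = tx_truth.eqtl_map[0][0]
    causal_pos = int(G.pos[G.snp_index(snp_id)])
    target_peaks = [pk for pk in peaks
                    if pk.window[0] <= causal_pos <= pk.window[1]]
    if not target_peaks:
        return {"candidates": [], "planted_gene": planted_gene,
                "is_sole_candidate": False}
    report = find_candidate_genes(target_peaks[0], local)
    genes = [g for g, _ in report.candidate_genes]
    return {
        "candidates": genes,
        "planted_gene": planted_gene,
        "is_sole_candidate": genes == [planted_gene],
    }


def synteny_replication_rate(seed: int = 0, n_loci: int = 100,
                             fraction: float = 0.39) -> dict:
    """Observed cross-species replication rate when ``fraction`` of mouse
    loci are planted as replicated in the simulated human summary."""
    from .synteny import map_to_syntenic_intervals, replication_test

    cfg = SimulationConfig(n_strains=30, n_snps=570, seed=seed)
    G = simulate_genotypes(cfg)
    smap = simulate_synteny_map(G, cfg)
    rng = np.random.default_rng(seed + 3)
    pick = rng.choice(G.n_snps, size=min(n_loci, G.n_snps), replace=False)
    loci = [(f"met{i:03d}", str(G.chrom[j]), int(G.pos[j]))
            for i, j in enumerate(pick)]
    summary, _ = simulate_human_summary(loci, smap, cfg,
                                        replicate_fraction=fraction,
                                        p_threshold=0.05 / len(loci))
    n_rep = 0
    for met_id, chrom, pos in loci:
        intervals = map_to_syntenic_intervals(
            (chrom, max(1, pos - 1_000_000), pos + 1_000_000), smap)
        if replication_test(summary, met_id, intervals,
                            n_loci_tested=len(loci)).replicated:
            n_rep += 1
    return {"replication_rate": n_rep / len(loci), "n_loci": len(loci),
            "n_replicated": n_rep}
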