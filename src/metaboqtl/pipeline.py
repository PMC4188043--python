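"""End-to-end orchestration: simulate -> preprocess -> kinship -> scans ->
FDR -> peaks/PVE -> local eQTLs -> candidates -> correlations -> synteny.

Every stage writes its table to the output directory and the run ends with
a manifest (config hash, seed, package version, per-stage row counts) that
makes the run reproducible: outputs are pure functions of (inputs, config,
seed).  Thresholds default to the study's stated parameters, so the
zero-flag invocation runs in "paper mode".
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from . import io as mio
from .correlation import class_pair_summary, cross_correlate, pairwise_matrix, sign_split
from .datatypes import GenotypeMatrix
from .loci import (
    CANDIDATE_HALF_WINDOW,
    EQTL_FLANK,
    LOCUS_HALF_WINDOW,
    R2_THRESHOLD,
    call_local_eqtls,
    collapse_to_peaks,
    count_distinct_loci,
    find_candidate_genes,
)
from .mixed_model import association_scan, compute_ibs_kinship, variance_explained
from .multiple_testing import (
    estimate_qvalues,
    expected_false_positives,
    pvalue_threshold_at_fdr,
)
from .preprocess import preprocess_pipeline
from .simulate import (
    SimulationConfig,
    simulate_clinical_traits,
    simulate_gene_annotation,
    simulate_genotypes,
    simulate_human_summary,
    simulate_metabolome,
    simulate_synteny_map,
    simulate_transcriptome,
)
from .synteny import replicate_loci

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    out_dir: str = "metaboqtl_run"
    maf_min: float = 0.05
    missing_max: float = 0.20
    fdr_level: float = 0.05
    r2_threshold: float = R2_THRESHOLD
    locus_half_window: int = LOCUS_HALF_WINDOW
    eqtl_flank: int = EQTL_FLANK
    candidate_half_window: int = CANDIDATE_HALF_WINDOW
    scan_mode: str = "exact"
    seed: int = 0
    simulate: bool = True
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    # optional external inputs (used when simulate=False)
    genotype_path: Optional[str] = None
    phenotype_path: Optional[str] = None
    classes_path: Optional[str] = None
    transcript_path: Optional[str] = None
    annotation_path: Optional[str] = None
    traits_path: Optional[str] = None
    annotation_pairs_path: Optional[str] = None
    synteny_path: Optional[str] = None
    human_gwas_path: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 < self.fdr_level < 1):
            raise ValueError("fdr_level must lie in (0, 1)")
        if not (0 <= self.maf_min < 0.5):
            raise ValueError("maf_min must lie in [0, 0.5)")
        if not (0 <= self.missing_max <= 1):
            raise ValueError("missing_max must lie in [0, 1]")
        if not (0 < self.r2_threshold <= 1):
            raise ValueError("r2_threshold must lie in (0, 1]")
        if self.scan_mode not in ("exact", "null_approx"):
            raise ValueError("scan_mode must be 'exact' or 'null_approx'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", {})
        cfg = cls(**raw)
        if sim:
            cfg.simulation = SimulationConfig(**{
                **dataclasses.asdict(cfg.simulation), **sim
            })
        cfg.simulation = dataclasses.replace(cfg.simulation, seed=cfg.seed)
        return cfg

    def canonical(self) -> str:
        """Canonical JSON of the analytic configuration (file locations are
        excluded so the hash identifies the analysis, not the filesystem)."""
        d = dataclasses.asdict(self)
        d.pop("out_dir")
        for k in list(d):
            if k.endswith("_path"):
                d.pop(k)
        return json.dumps(d, sort_keys=True, default=str)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_sha256": hashlib.sha256(config.canonical().encode()).hexdigest(),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
    }

    def stage(name, **counts):
        manifest["stages"][name] = counts
        logger.info("stage %s: %s", name, counts)

    # ---- inputs -----------------------------------------------------------
    truth = None
    if config.simulate:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        G = simulate_genotypes(sim)
        metab, truth = simulate_metabolome(G, sim)
        annot = simulate_gene_annotation(G, sim)
        tx, tx_truth = simulate_transcriptome(G, annot, sim)
        traits = simulate_clinical_traits(metab, sim)
        smap = simulate_synteny_map(G, sim)
        mio.write_genotype_table(G, out / "genotypes.tsv")
        mio.write_phenotype_table(metab, out / "metabolites_raw.tsv",
                                  out / "metabolite_classes.tsv")
        mio.write_phenotype_table(tx, out / "transcripts_raw.tsv")
        mio.write_phenotype_table(traits, out / "clinical_traits.tsv")
        mio.write_gene_annotation(annot, out / "gene_annotation.tsv")
        mio.write_synteny_map(smap, out / "synteny_map.tsv")
        with open(out / "ground_truth.tsv", "w") as fh:
            fh.write("kind\tphenotype\tsnp\trealized_pve\n")
            for m, s, pve in truth.qtl_map:
                fh.write(f"qtl\t{m}\t{s}\t{pve}\n")
            for t, s, pve in tx_truth.eqtl_map:
                fh.write(f"eqtl\t{t}\t{s}\t{pve}\n")
        annotation_pairs = None
        human_summary = None
    else:
        if not config.genotype_path or not config.phenotype_path:
            raise ValueError("genotype_path and phenotype_path required when "
                             "simulate=False")
        G = mio.read_genotype_table(config.genotype_path)
        metab = mio.read_phenotype_table(config.phenotype_path,
                                         config.classes_path)
        tx = (mio.read_phenotype_table(config.transcript_path)
              if config.transcript_path else None)
        annot = (mio.read_gene_annotation(config.annotation_path)
                 if config.annotation_path else None)
        traits = (mio.read_phenotype_table(config.traits_path)
                  if config.traits_path else None)
        smap = (mio.read_synteny_map(config.synteny_path)
                if config.synteny_path else None)
        annotation_pairs = (
            mio.read_pair_table(config.annotation_pairs_path, "metabolite", "gene")
            if config.annotation_pairs_path else None
        )
        human_summary = (mio.read_human_gwas(config.human_gwas_path)
                         if config.human_gwas_path else None)

    G = G.filter_maf(config.maf_min)
    stage("genotypes", n_strains=G.n_strains, n_snps_after_maf=G.n_snps)

    # ---- preprocess -------------------------------------------------------
    z = preprocess_pipeline(metab, config.missing_max)
    stage(
        "preprocess",
        n_metabolites_kept=len(z.variables),
        n_dropped_missingness=z.provenance["missingness_filter"]["n_dropped"],
        n_strains=len(z.strain_ids),
    )
    ztab = z.to_table(metab.class_of_variable)
    mio.write_phenotype_table(ztab, out / "metabolites_z.tsv")
    with open(out / "preprocess_provenance.json", "w") as fh:
        json.dump(z.provenance, fh, indent=2, sort_keys=True)

    # align strains between genotypes and phenotypes
    strain_idx = {s: i for i, s in enumerate(z.strain_ids)}
    common = [s for s in G.strains if s in strain_idx]
    if len(common) < G.n_strains:
        keep = [i for i, s in enumerate(G.strains) if s in strain_idx]
        G = GenotypeMatrix(snp_ids=G.snp_ids, chrom=G.chrom, pos=G.pos,
                           strains=common, dosage=G.dosage[keep, :])
    zmat = np.stack([z.zvalues[strain_idx[s]] for s in G.strains])

    # ---- kinship ----------------------------------------------------------
    K = compute_ibs_kinship(G)
    mio.write_kinship(K.strains, K.K, out / "kinship.tsv")
    stage("kinship", n_strains=len(K.strains))

    # ---- metabolite scan --------------------------------------------------
    records = []
    for j, met_id in enumerate(z.variables):
        records.extend(
            association_scan(zmat[:, j], G, K, mode=config.scan_mode,
                             phenotype_id=met_id)
        )
    stage("metabolite_scan", n_tests=len(records))

    # ---- FDR --------------------------------------------------------------
    pvals = [r.p_value for r in records]
    qres = estimate_qvalues(pvals)
    p_cut = pvalue_threshold_at_fdr(pvals, config.fdr_level)
    records = [
        dataclasses.replace(r, q_value=float(q))
        for r, q in zip(records, qres.qvalues)
    ]
    mio.write_association_results(records, out / "associations.tsv")
    significant = [r for r in records if r.q_value <= config.fdr_level]
    stage(
        "fdr",
        pi0=round(qres.pi0, 4),
        p_threshold=p_cut,
        n_significant=len(significant),
        expected_false_positives=expected_false_positives(
            len(significant), config.fdr_level
        ),
    )

    # ---- peaks + PVE ------------------------------------------------------
    by_pheno: dict[str, list] = {}
    for r in significant:
        by_pheno.setdefault(r.phenotype_id, []).append(r)
    all_peaks = []
    for met_id in sorted(by_pheno):
        peaks = collapse_to_peaks(
            by_pheno[met_id], G, config.r2_threshold, config.locus_half_window
        )
        j = z.variables.index(met_id)
        for pk in peaks:
            g = G.dosage[:, G.snp_index(pk.snp_id)]
            pk.pve = variance_explained(zmat[:, j], g, K.K)
        all_peaks.extend(peaks)
    n_assoc, n_distinct = count_distinct_loci(all_peaks)
    with open(out / "peaks.tsv", "w") as fh:
        fh.write("phenotype\tsnp_id\tchrom\tpos\tp\tpve\twindow_start\t"
                 "window_end\tn_members\n")
        for pk in all_peaks:
            fh.write(
                f"{pk.phenotype_id}\t{pk.snp_id}\t{pk.chrom}\t{pk.pos}\t"
                f"{pk.p_value}\t{pk.pve}\t{pk.window[0]}\t{pk.window[1]}\t"
                f"{len(pk.member_snps)}\n"
            )
    mapped = {pk.phenotype_id for pk in all_peaks}
    stage("peaks", n_peak_associations=n_assoc, n_distinct_loci=n_distinct,
          n_metabolites_mapped=len(mapped),
          mean_pve=round(float(np.mean([pk.pve for pk in all_peaks])), 4)
          if all_peaks else None)

    # ---- ground-truth recovery (synthetic runs) --------------------------
    if truth is not None:
        recovered = 0
        for met_id, snp_id, pve in truth.qtl_map:
            causal_pos = int(G.pos[G.snp_index(snp_id)]) \
                if snp_id in set(G.snp_ids) else None
            hit = any(
                pk.phenotype_id == met_id
                and causal_pos is not None
                and pk.chrom == str(G.chrom[G.snp_index(snp_id)])
                and pk.window[0] <= causal_pos <= pk.window[1]
                for pk in all_peaks
            )
            recovered += bool(hit)
        stage("ground_truth_recovery", n_planted=len(truth.qtl_map),
              n_recovered=recovered)

    # ---- transcript scan + local eQTLs + candidates -----------------------
    if tx is not None and annot is not None:
        ztx = preprocess_pipeline(tx, config.missing_max)
        tx_idx = {s: i for i, s in enumerate(ztx.strain_ids)}
        txmat = np.stack([
            ztx.zvalues[tx_idx[s]] if s in tx_idx
            else np.full(len(ztx.variables), np.nan)
            for s in G.strains
        ])
        tx_records = []
        for j, tid in enumerate(ztx.variables):
            tx_records.extend(
                association_scan(txmat[:, j], G, K, mode=config.scan_mode,
                                 phenotype_id=tid)
            )
        tx_p = [r.p_value for r in tx_records]
        eqtl_cut = pvalue_threshold_at_fdr(tx_p, config.fdr_level)
        eqtls = call_local_eqtls(tx_records, annot, p_threshold=eqtl_cut,
                                 flank=config.eqtl_flank)
        local = [e for e in eqtls if e.is_local]
        with open(out / "eqtls.tsv", "w") as fh:
            fh.write("transcript\tgene\tgene_chrom\tgene_start\tgene_end\t"
                     "peak_snp\tpeak_chrom\tpeak_pos\tp\tis_local\n")
            for e in eqtls:
                fh.write(
                    f"{e.transcript_id}\t{e.gene_id}\t{e.gene_chrom}\t"
                    f"{e.gene_start}\t{e.gene_end}\t{e.peak_snp_id}\t"
                    f"{e.peak_chrom}\t{e.peak_pos}\t{e.p_value}\t"
                    f"{int(e.is_local)}\n"
                )
        stage("local_eqtls", n_transcript_tests=len(tx_records),
              eqtl_p_threshold=eqtl_cut, n_eqtls=len(eqtls),
              n_local=len(local))
        reports = [
            find_candidate_genes(pk, local, config.candidate_half_window,
                                 annotation_pairs)
            for pk in all_peaks
        ]
        with_candidates = [r for r in reports if r.candidate_genes]
        with open(out / "candidates.tsv", "w") as fh:
            fh.write("metabolite\tpeak_snp\tgene\teqtl_p\tco_annotated\n")
            for rep in reports:
                for gene, p in rep.candidate_genes:
                    fh.write(
                        f"{rep.metabolite_id}\t{rep.locus.snp_id}\t{gene}\t{p}"
                        f"\t{int(gene in rep.annotation_matches)}\n"
                    )
        stage("candidates", n_loci=len(all_peaks),
              n_loci_with_candidates=len(with_candidates))
    else:
        stage("local_eqtls", skipped=True)
        stage("candidates", skipped=True)

    # ---- correlations -----------------------------------------------------
    cors = pairwise_matrix(ztab, ("bonferroni", 0.05))
    summary = class_pair_summary(cors)
    stage("metabolite_correlations", n_pairs=len(cors), **summary)
    if traits is not None:
        hits = cross_correlate(ztab, traits, config.fdr_level,
                               pair_kind="metab_trait")
        split = sign_split(hits)
        with open(out / "trait_correlations.tsv", "w") as fh:
            fh.write("metabolite\ttrait\tr\tn\tp\tq\n")
            for h in hits:
                fh.write(f"{h.var_a}\t{h.var_b}\t{h.r}\t{h.n}\t{h.p_value}\t"
                         f"{h.q_value}\n")
        stage("trait_correlations", n_significant=len(hits), **split)
    else:
        stage("trait_correlations", skipped=True)

    # ---- synteny ----------------------------------------------------------
    if smap is not None:
        if human_summary is None and truth is not None:
            loci_list = [
                (pk.phenotype_id, pk.chrom, pk.pos) for pk in all_peaks
            ]
            human_summary, _ = simulate_human_summary(
                loci_list, smap, dataclasses.replace(config.simulation,
                                                     seed=config.seed)
            )
            mio.write_human_gwas(human_summary, out / "human_gwas.tsv")
        if human_summary is not None and all_peaks:
            results = replicate_loci(all_peaks, smap, human_summary)
            n_rep = sum(r.replicated for r in results)
            with open(out / "replication.tsv", "w") as fh:
                fh.write("metabolite\tmouse_chrom\tmouse_start\tmouse_end\t"
                         "threshold\treplicated\tpopulations_supporting\n")
                for r in results:
                    fh.write(
                        f"{r.metabolite_id}\t{r.mouse_locus[0]}\t"
                        f"{r.mouse_locus[1]}\t{r.mouse_locus[2]}\t"
                        f"{r.threshold}\t{int(r.replicated)}\t"
                        f"{r.populations_supporting}\n"
                    )
            stage("synteny", n_loci=len(results), n_replicated=n_rep,
                  replication_rate=round(n_rep / len(results), 4))
        else:
            stage("synteny", skipped=True)
    else:
        stage("synteny", skipped=True)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
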