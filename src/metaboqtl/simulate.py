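"""Synthetic inbred-panel generator with known ground truth.

Emulates the shape of a hybrid mouse diversity panel study: ~100 inbred
strains carrying homozygous biallelic genotypes organised in linkage-
disequilibrium blocks, with discrete strain families inducing population
structure; a liver metabolome of a few hundred variables in eight classes
measured with run-day batch effects, replicate mice for some strains and
missing cells; transcripts with planted local eQTLs; clinical traits built
to correlate with chosen metabolites; and a human GWAS summary table with a
configurable fraction of syntenically replicated loci.

Every generator is a pure function of (config, seed): the master seed
spawns an independent, purpose-labelled stream per generator, so adding a
generator never shifts the draws of another.

The population-structure mechanism is deliberately minimal: strains belong
to discrete families and share family haplotypes at each LD block with
probability ``family_mixing``; null metabolites receive family random
effects.  That is the simplest design under which a naive no-kinship scan
is anti-conservative while the mixed model stays calibrated, which is
exactly what the calibration tests must demonstrate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .datatypes import (
    GeneAnnotationTable,
    GenotypeMatrix,
    HumanGwasRecord,
    HumanGwasSummary,
    PhenotypeTable,
    SyntenyMap,
    SyntenyRecord,
)

METABOLITE_CLASSES = [
    "Lipids",
    "Amino Acids",
    "Carbohydrates",
    "Nucleotides",
    "Peptides",
    "Xenobiotics",
    "Cofactors",
    "Energy",
]

_STREAMS = {
    "genotypes": 0,
    "metabolome": 1,
    "transcriptome": 2,
    "traits": 3,
    "human": 4,
    "annotation": 5,
}


def _rng(seed: int, purpose: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[purpose],))
    )


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic panel.

    Defaults emulate the profiled study design at desk scale: 100 strains
    in structured families, a few thousand SNPs in 10-SNP LD blocks over 19
    autosomes (scaled down from ~1e5), 60 metabolites in the eight standard
    classes measured over 6 run-days, one strain with five biological
    replicates and twenty strains with two.
    """

    n_strains: int = 100
    n_snps: int = 2000
    n_chromosomes: int = 19
    snp_spacing_bp: int = 100_000
    ld_block_size: int = 10
    ld_block_r: float = 0.9          # target founder-copy correlation in a block
    n_families: int = 8
    family_mixing: float = 0.4       # within-family haplotype-sharing probability
    maf_min: float = 0.05
    n_metabolites: int = 60
    n_classes: int = 8
    planted_qtls: list[tuple[int, int, float]] = field(default_factory=list)
    n_transcripts: int = 40
    planted_eqtls: list[tuple[int, int, float]] = field(default_factory=list)
    family_effect_sd: float = 0.7
    noise_sd: float = 0.7
    baseline: float = 10.0
    n_rundays: int = 6
    runday_effect_sd: float = 0.3
    missing_frac: float = 0.02
    replicate_strains: list[tuple[int, int]] = field(default_factory=list)
    trait_correlations: list[tuple[int, int, float]] = field(default_factory=list)
    n_traits: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for _, _, pve in list(self.planted_qtls) + list(self.planted_eqtls):
            if not (0.0 < pve < 1.0):
                raise ValueError(f"target PVE {pve} outside (0, 1)")
        if not (0.0 <= self.missing_frac < 1.0):
            raise ValueError("missing_frac must lie in [0, 1)")
        if not (0.0 <= self.family_mixing < 1.0):
            raise ValueError("family_mixing must lie in [0, 1)")
        for m, _, _ in self.planted_qtls:
            if not (0 <= m < self.n_metabolites):
                raise ValueError(f"planted metabolite index {m} out of range")
        for t, _, _ in self.planted_eqtls:
            if not (0 <= t < self.n_transcripts):
                raise ValueError(f"planted transcript index {t} out of range")


@dataclass
class GroundTruth:
    """Planted signals: (phenotype id, causal SNP id, realized PVE)."""

    qtl_map: list[tuple[str, str, float]] = field(default_factory=list)
    eqtl_map: list[tuple[str, str, float]] = field(default_factory=list)
    null_set: list[str] = field(default_factory=list)


def family_of_strain(config: SimulationConfig) -> np.ndarray:
    """Deterministic family assignment: strain i belongs to family i mod F."""
    return np.arange(config.n_strains) % max(1, config.n_families)


def strain_names(config: SimulationConfig) -> list[str]:
    return [f"strain{i:03d}" for i in range(config.n_strains)]


# ---------------------------------------------------------------- genotypes


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Blockwise LD genotypes with family structure.

    Each LD block has a founder allele per strain: the strain copies its
    family's block haplotype with probability ``family_mixing``, otherwise
    draws independently.  SNPs inside a block copy the founder with per-SNP
    per-strain flip probability (1 - ld_block_r)/2.  SNPs failing the MAF
    filter (> maf_min required) are removed before return.
    """
    rng = _rng(config.seed, "genotypes")
    n, m = config.n_strains, config.n_snps
    fam = family_of_strain(config)
    n_fam = max(1, config.n_families)
    flip_p = (1.0 - config.ld_block_r) / 2.0

    per_chrom = np.full(config.n_chromosomes, m // config.n_chromosomes)
    per_chrom[: m % config.n_chromosomes] += 1

    snp_ids, chroms, positions, columns = [], [], [], []
    snp_counter = 0
    for c in range(config.n_chromosomes):
        mc = int(per_chrom[c])
        j = 0
        while j < mc:
            block = min(config.ld_block_size, mc - j)
            fam_allele = rng.integers(0, 2, size=n_fam) * 2.0
            own = rng.integers(0, 2, size=n) * 2.0
            use_fam = rng.random(n) < config.family_mixing
            founder = np.where(use_fam, fam_allele[fam], own)
            for k in range(block):
                flips = rng.random(n) < flip_p
                g = np.where(flips, 2.0 - founder, founder)
                columns.append(g)
                snp_ids.append(f"rs{snp_counter:06d}")
                chroms.append(str(c + 1))
                positions.append((j + k + 1) * config.snp_spacing_bp)
                snp_counter += 1
            j += block
    G = GenotypeMatrix(
        snp_ids=np.array(snp_ids, dtype=object),
        chrom=np.array(chroms, dtype=object),
        pos=np.array(positions, dtype=np.int64),
        strains=strain_names(config),
        dosage=np.column_stack(columns),
    )
    G = G.filter_maf(config.maf_min)
    if G.n_snps == 0:
        raise ValueError("no polymorphic SNP survived the MAF filter")
    return G


# --------------------------------------------------------------- phenotypes


def _planted_phenotypes(
    G: GenotypeMatrix,
    config: SimulationConfig,
    planted: Sequence[tuple[int, int, float]],
    n_vars: int,
    prefix: str,
    rng: np.random.Generator,
):
    """Strain-level core values with planted SNP effects plus family and
    residual noise; returns (core matrix, realized PVE per planted signal)."""
    n = G.n_strains
    fam = family_of_strain(config)
    # the PVE target is defined at the measured-sample level, so the
    # variance budget includes the intra-strain measurement noise added
    # when cores are expanded to samples (sd = noise_sd / 2)
    nongenetic_var = (
        config.family_effect_sd**2
        + config.noise_sd**2
        + (0.5 * config.noise_sd) ** 2
    )
    core = np.empty((n, n_vars))
    planted_by_var = {v: (s, pve) for v, s, pve in planted}
    realized: dict[int, float] = {}
    for v in range(n_vars):
        fam_eff = rng.normal(0.0, config.family_effect_sd, size=max(1, config.n_families))
        noise = rng.normal(0.0, config.noise_sd, size=n)
        y = fam_eff[fam] + noise
        if v in planted_by_var:
            s_idx, pve = planted_by_var[v]
            g = G.dosage[:, s_idx]
            sg = g.std()
            if sg == 0:
                raise ValueError(f"planted SNP {s_idx} is monomorphic")
            beta = np.sqrt(pve / (1.0 - pve) * nongenetic_var) / sg
            signal = beta * (g - g.mean())
            y = y + signal
            realized[v] = float(np.var(signal) / np.var(y))
        core[:, v] = y
    return core, realized


def _expand_samples(
    core: np.ndarray,
    G: GenotypeMatrix,
    config: SimulationConfig,
    rng: np.random.Generator,
    prefix: str,
    with_batch: bool = True,
):
    """Expand strain-level cores to samples (replicates, run-day batch,
    missingness) and return a sample-level PhenotypeTable."""
    n, n_vars = core.shape
    reps = dict(config.replicate_strains)
    sample_ids, strain_of_sample, rows = [], [], []
    for i, strain in enumerate(G.strains):
        k = max(1, reps.get(i, 1))
        for r in range(k):
            sample_ids.append(f"{strain}_r{r+1}" if k > 1 else strain)
            strain_of_sample.append(strain)
            rows.append(core[i] + rng.normal(0.0, config.noise_sd * 0.5, size=n_vars))
    values = np.asarray(rows) + config.baseline
    rundays = rng.integers(0, max(1, config.n_rundays), size=len(sample_ids))
    # factors are always drawn so batch/no-batch twins share all other draws
    factors = np.exp(
        config.runday_effect_sd
        * rng.normal(0.0, 1.0, size=max(1, config.n_rundays))
    )
    if with_batch and config.runday_effect_sd > 0:
        values = values * factors[rundays][:, None]
    if config.missing_frac > 0:
        mask = rng.random(values.shape) < config.missing_frac
        values[mask] = np.nan
    return sample_ids, strain_of_sample, [f"day{d+1}" for d in rundays], values


def simulate_metabolome(
    G: GenotypeMatrix, config: SimulationConfig
) -> tuple[PhenotypeTable, GroundTruth]:
    """Sample-level metabolite table with planted QTLs and known nulls.

    Per metabolite: y = beta * g + family effect + residual noise at the
    strain level, expanded to replicate samples, shifted to a positive
    baseline, scaled by a multiplicative run-day factor and masked at
    ``missing_frac``.  beta is chosen so the planted SNP explains the
    target PVE of the core variance in expectation; the realized sample
    PVE is recorded in the ground truth.
    """
    rng = _rng(config.seed, "metabolome")
    for _, s_idx, _ in config.planted_qtls:
        if not (0 <= s_idx < G.n_snps):
            raise ValueError(f"planted SNP index {s_idx} not in genotype matrix")
    core, realized = _planted_phenotypes(
        G, config, config.planted_qtls, config.n_metabolites, "met", rng
    )
    sample_ids, strain_of_sample, rundays, values = _expand_samples(
        core, G, config, rng, "met"
    )
    variables = [f"met{v:03d}" for v in range(config.n_metabolites)]
    classes = [METABOLITE_CLASSES[v % min(config.n_classes, len(METABOLITE_CLASSES))]
               for v in range(config.n_metabolites)]
    table = PhenotypeTable(
        sample_ids=sample_ids,
        strain_of_sample=strain_of_sample,
        runday_of_sample=rundays,
        variables=variables,
        values=values,
        class_of_variable=dict(zip(variables, classes)),
    )
    planted_vars = {v for v, _, _ in config.planted_qtls}
    truth = GroundTruth(
        qtl_map=[
            (variables[v], str(G.snp_ids[s]), realized[v])
            for v, s, _ in config.planted_qtls
        ],
        null_set=[variables[v] for v in range(config.n_metabolites)
                  if v not in planted_vars],
    )
    return table, truth


def simulate_gene_annotation(
    G: GenotypeMatrix, config: SimulationConfig, span_bp: int = 50_000
) -> GeneAnnotationTable:
    """Gene spans for the synthetic transcripts.

    Planted-eQTL genes are placed so the gene span starts at their causal
    SNP (guaranteeing the SNP is local); the rest are scattered uniformly
    over the genotyped chromosomes.
    """
    rng = _rng(config.seed, "annotation")
    gene_ids, chroms, starts, ends = [], [], [], []
    planted_by_t = {t: s for t, s, _ in config.planted_eqtls}
    for t in range(config.n_transcripts):
        gene_ids.append(f"gene{t:03d}")
        if t in planted_by_t:
            s = planted_by_t[t]
            chroms.append(str(G.chrom[s]))
            start = int(G.pos[s])
        else:
            j = int(rng.integers(0, G.n_snps))
            chroms.append(str(G.chrom[j]))
            start = int(G.pos[j]) + int(rng.integers(0, span_bp))
        starts.append(start)
        ends.append(start + span_bp)
    return GeneAnnotationTable(
        gene_ids=np.array(gene_ids, dtype=object),
        chrom=np.array(chroms, dtype=object),
        start=np.array(starts),
        end=np.array(ends),
    )


def simulate_transcriptome(
    G: GenotypeMatrix,
    annot: GeneAnnotationTable,
    config: SimulationConfig,
    eqtl_flank: int = 2_000_000,
) -> tuple[PhenotypeTable, GroundTruth]:
    """Transcript table with planted local eQTLs (same noise model as the
    metabolome).  Every planted SNP must lie within ``eqtl_flank`` of its
    gene's span, otherwise the co-localization tests would silently break.
    """
    rng = _rng(config.seed, "transcriptome")
    for t, s_idx, _ in config.planted_eqtls:
        gene_id = f"gene{t:03d}"
        gchrom, gstart, gend = annot.lookup(gene_id)
        if str(G.chrom[s_idx]) != gchrom or not (
            gstart - eqtl_flank <= int(G.pos[s_idx]) <= gend + eqtl_flank
        ):
            raise ValueError(
                f"planted eQTL SNP {G.snp_ids[s_idx]} is not local to {gene_id}"
            )
    core, realized = _planted_phenotypes(
        G, config, config.planted_eqtls, config.n_transcripts, "tx", rng
    )
    cfg_tx = replace(config, replicate_strains=[])
    sample_ids, strain_of_sample, rundays, values = _expand_samples(
        core, G, cfg_tx, rng, "tx"
    )
    variables = [f"gene{t:03d}" for t in range(config.n_transcripts)]
    table = PhenotypeTable(
        sample_ids=sample_ids,
        strain_of_sample=strain_of_sample,
        runday_of_sample=rundays,
        variables=variables,
        values=values,
    )
    planted_vars = {t for t, _, _ in config.planted_eqtls}
    truth = GroundTruth(
        eqtl_map=[
            (variables[t], str(G.snp_ids[s]), realized[t])
            for t, s, _ in config.planted_eqtls
        ],
        null_set=[variables[t] for t in range(config.n_transcripts)
                  if t not in planted_vars],
    )
    return table, truth


def simulate_clinical_traits(
    metabolome: PhenotypeTable, config: SimulationConfig
) -> PhenotypeTable:
    """Clinical traits correlated with chosen metabolites.

    Each configured (trait, metabolite, rho) builds the trait as
    rho * z(metabolite) + sqrt(1 - rho^2) * noise at the strain level;
    unconfigured traits are pure noise.
    """
    rng = _rng(config.seed, "traits")
    for _, _, rho in config.trait_correlations:
        if abs(rho) >= 1.0:
            raise ValueError(f"|rho| must be < 1, got {rho}")
    from .preprocess import average_strain_replicates, normalize_run_days

    # traits track the biological metabolite level, so the run-day batch
    # factor is registered away before strain means are taken
    tbl = metabolome
    if tbl.runday_of_sample is not None:
        tbl = normalize_run_days(tbl)
    strain_tbl = average_strain_replicates(tbl)
    n = strain_tbl.n_samples
    targets = {t: (m, rho) for t, m, rho in config.trait_correlations}
    values = np.empty((n, config.n_traits))
    for t in range(config.n_traits):
        noise = rng.normal(size=n)
        if t in targets:
            m_idx, rho = targets[t]
            mcol = strain_tbl.values[:, m_idx]
            ok = ~np.isnan(mcol)
            z = np.full(n, np.nan)
            z[ok] = (mcol[ok] - mcol[ok].mean()) / mcol[ok].std(ddof=1)
            col = rho * z + np.sqrt(1.0 - rho**2) * noise
        else:
            col = noise
        values[:, t] = col
    return PhenotypeTable(
        sample_ids=[f"{s}" for s in strain_tbl.sample_ids],
        strain_of_sample=list(strain_tbl.strain_of_sample),
        variables=[f"trait{t:02d}" for t in range(config.n_traits)],
        values=values,
    )


# ------------------------------------------------------------------ synteny


def simulate_synteny_map(
    G: GenotypeMatrix, config: SimulationConfig, human_offset: int = 5_000_000
) -> SyntenyMap:
    """One synteny block per mouse chromosome, mapping it wholesale to a
    shifted interval on a 'human' chromosome of the same index."""
    records = []
    for c in sorted(set(str(x) for x in G.chrom), key=lambda s: int(s)):
        on_c = G.pos[G.chrom == c]
        lo, hi = int(on_c.min()), int(on_c.max())
        records.append(
            SyntenyRecord(
                mouse_chrom=c,
                mouse_start=max(1, lo - 1_000_000),
                mouse_end=hi + 1_000_000,
                human_chrom=f"h{c}",
                human_start=max(1, lo - 1_000_000) + human_offset,
                human_end=hi + 1_000_000 + human_offset,
            )
        )
    return SyntenyMap(records=records)


def simulate_human_summary(
    loci: Sequence[tuple[str, str, int]],
    synteny_map: SyntenyMap,
    config: SimulationConfig,
    replicate_fraction: float = 0.39,
    p_threshold: float = 0.05 / 115,
    populations: Sequence[str] = ("KORA", "TwinsUK"),
    n_background: int = 50,
) -> tuple[HumanGwasSummary, list[str]]:
    """Human GWAS summary with a planted fraction of replicated mouse loci.

    ``loci`` is a list of (metabolite_id, mouse_chrom, mouse_pos).  A
    replicated locus receives a record with p below ``p_threshold`` placed
    inside the syntenically mapped human interval (in one population);
    non-replicated loci and background records carry uniform p in (0, 1].
    Returns the summary and the list of metabolites planted as replicated.
    A locus selected for replication that has no syntenic mapping is an
    error.
    """
    from .synteny import map_to_syntenic_intervals

    rng = _rng(config.seed, "human")
    records: list[HumanGwasRecord] = []
    replicated: list[str] = []
    for met, chrom, pos in loci:
        intervals = map_to_syntenic_intervals(
            (chrom, pos - 1_000_000, pos + 1_000_000), synteny_map
        )
        do_rep = rng.random() < replicate_fraction
        if do_rep and not intervals:
            raise ValueError(
                f"locus {met}@{chrom}:{pos} selected for replication but has "
                "no syntenic mapping"
            )
        if not intervals:
            continue
        hchrom, hstart, hend = intervals[0]
        hpos = int(rng.integers(hstart, hend + 1))
        if do_rep:
            p = float(rng.uniform(p_threshold * 1e-4, p_threshold * 0.5))
            replicated.append(met)
            pop = populations[int(rng.integers(0, len(populations)))]
            records.append(HumanGwasRecord(met, hchrom, hpos, p, pop))
        else:
            for pop in populations:
                p = float(min(1.0, rng.uniform(max(p_threshold * 2, 0.01), 1.0)))
                records.append(HumanGwasRecord(met, hchrom, hpos, p, pop))
    for _ in range(n_background):
        blk = synteny_map.records[int(rng.integers(0, len(synteny_map.records)))]
        records.append(
            HumanGwasRecord(
                metabolite_id=f"bg{int(rng.integers(0, 10_000)):04d}",
                human_chrom=blk.human_chrom,
                human_pos=int(rng.integers(blk.human_start, blk.human_end + 1)),
                p_value=float(rng.uniform(1e-6, 1.0)),
                population_label=populations[int(rng.integers(0, len(populations)))],
            )
        )
    return HumanGwasSummary(records=records), replicated
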