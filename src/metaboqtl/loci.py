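"""Locus definition and candidate-gene co-localization.

Significant SNPs for a phenotype are collapsed to "peak SNPs" by a greedy
linkage-disequilibrium rule (keep the strongest association, absorb every
same-chromosome SNP correlated with it at R-squared above a threshold,
repeat).  A locus is a 2 Mb window centred on the peak (1 Mb each side).
Transcript scans yield eQTL records flagged "local" when the peak SNP falls
within 2 Mb of the gene span; candidate genes for a metabolite locus are
those whose local-eQTL peak lies within 1 Mb of the metabolite's peak SNP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .datatypes import (
    AssociationRecord,
    GeneAnnotationTable,
    GenotypeMatrix,
    chrom_sort_key,
)

logger = logging.getLogger(__name__)

MB = 1_000_000
LOCUS_HALF_WINDOW = 1 * MB      # locus = peak +/- 1 Mb
EQTL_FLANK = 2 * MB             # "local" = within gene span +/- 2 Mb
CANDIDATE_HALF_WINDOW = 1 * MB  # candidate search window around metabolite peak
R2_THRESHOLD = 0.5


@dataclass
class LocusPeak:
    phenotype_id: str
    snp_id: str
    chrom: str
    pos: int
    p_value: float
    window: tuple[int, int]
    pve: Optional[float] = None
    member_snps: list[str] = field(default_factory=list)


@dataclass
class EQTLRecord:
    transcript_id: str
    gene_id: str
    gene_chrom: str
    gene_start: int
    gene_end: int
    peak_snp_id: str
    peak_chrom: str
    peak_pos: int
    p_value: float
    is_local: bool


@dataclass
class CandidateGeneReport:
    metabolite_id: str
    locus: LocusPeak
    candidate_genes: list[tuple[str, float]]      # (gene_id, eQTL p)
    annotation_matches: list[str] = field(default_factory=list)


def genotype_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over strains where
    both are nonmissing."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    both = ~(np.isnan(g1) | np.isnan(g2))
    if both.sum() < 3:
        raise ValueError("fewer than 3 shared nonmissing strains")
    a, b = g1[both], g2[both]
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValueError("monomorphic SNP on shared strains")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _record_order_key(r: AssociationRecord):
    # ascending p, ties by (chrom, pos) then snp_id
    return (r.p_value, chrom_sort_key(r.chrom), r.pos, r.snp_id)


def collapse_to_peaks(
    significant_records: Sequence[AssociationRecord],
    G: GenotypeMatrix,
    r2_threshold: float = R2_THRESHOLD,
    half_window: int = LOCUS_HALF_WINDOW,
) -> list[LocusPeak]:
    """Greedy LD collapsing of one phenotype's significant SNPs to peaks.

    Rank by ascending p; the best unabsorbed SNP becomes a peak and absorbs
    every remaining same-chromosome SNP with R-squared above the threshold;
    repeat until all records are assigned.  The member sets partition the
    input.
    """
    records = sorted(significant_records, key=_record_order_key)
    if not records:
        return []
    phenos = {r.phenotype_id for r in records}
    if len(phenos) > 1:
        raise ValueError(
            f"collapse_to_peaks expects one phenotype, got {sorted(phenos)}"
        )
    remaining = list(records)
    peaks: list[LocusPeak] = []
    while remaining:
        best = remaining.pop(0)
        g_best = G.dosage[:, G.snp_index(best.snp_id)]
        members = [best.snp_id]
        still = []
        for r in remaining:
            absorbed = False
            if r.chrom == best.chrom:
                g_r = G.dosage[:, G.snp_index(r.snp_id)]
                try:
                    if genotype_r2(g_best, g_r) > r2_threshold:
                        absorbed = True
                except ValueError:
                    pass
            if absorbed:
                members.append(r.snp_id)
            else:
                still.append(r)
        remaining = still
        peaks.append(
            LocusPeak(
                phenotype_id=best.phenotype_id,
                snp_id=best.snp_id,
                chrom=best.chrom,
                pos=best.pos,
                p_value=best.p_value,
                window=(max(1, best.pos - half_window), best.pos + half_window),
                member_snps=members,
            )
        )
    return peaks


def count_distinct_loci(all_peaks: Sequence[LocusPeak]) -> tuple[int, int]:
    """(total peak associations across phenotypes, distinct peak SNP ids)."""
    n_assoc = len(all_peaks)
    n_distinct = len({p.snp_id for p in all_peaks})
    return n_assoc, n_distinct


def call_local_eqtls(
    transcript_assoc: Sequence[AssociationRecord],
    annot: GeneAnnotationTable,
    p_threshold: float,
    transcript_to_gene: Optional[dict[str, str]] = None,
    flank: int = EQTL_FLANK,
) -> list[EQTLRecord]:
    """Call eQTLs from per-transcript association records.

    The peak SNP per transcript is the record with smallest p (ties broken
    by (chrom, pos, snp_id)); it is kept if p <= ``p_threshold`` and flagged
    local when it lies within ``flank`` of the gene span on the gene's
    chromosome.  ``transcript_to_gene`` defaults to the identity (transcript
    ids are gene ids); unannotated transcripts are skipped with a log entry.
    """
    by_transcript: dict[str, list[AssociationRecord]] = {}
    for r in transcript_assoc:
        by_transcript.setdefault(r.phenotype_id, []).append(r)
    out: list[EQTLRecord] = []
    for tid in sorted(by_transcript):
        gene_id = (transcript_to_gene or {}).get(tid, tid)
        try:
            gchrom, gstart, gend = annot.lookup(gene_id)
        except KeyError:
            logger.info("transcript %s skipped: no gene annotation", tid)
            continue
        peak = min(by_transcript[tid], key=_record_order_key)
        if peak.p_value > p_threshold:
            continue
        is_local = (
            peak.chrom == gchrom
            and gstart - flank <= peak.pos <= gend + flank
        )
        out.append(
            EQTLRecord(
                transcript_id=tid,
                gene_id=gene_id,
                gene_chrom=gchrom,
                gene_start=gstart,
                gene_end=gend,
                peak_snp_id=peak.snp_id,
                peak_chrom=peak.chrom,
                peak_pos=peak.pos,
                p_value=peak.p_value,
                is_local=is_local,
            )
        )
    return out


def find_candidate_genes(
    metabolite_peak: LocusPeak,
    local_eqtls: Sequence[EQTLRecord],
    half_window: int = CANDIDATE_HALF_WINDOW,
    annotation_pairs: Optional[Sequence[tuple[str, str]]] = None,
) -> CandidateGeneReport:
    """Genes whose local-eQTL peak SNP lies within ``half_window`` (inclusive)
    of the metabolite peak SNP on the same chromosome."""
    candidates: list[tuple[str, float]] = []
    for e in local_eqtls:
        if not e.is_local:
            continue
        if e.peak_chrom != metabolite_peak.chrom:
            continue
        if abs(e.peak_pos - metabolite_peak.pos) <= half_window:
            candidates.append((e.gene_id, e.p_value))
    candidates.sort(key=lambda t: (t[1], t[0]))
    matches: list[str] = []
    if annotation_pairs is not None:
        matches = co_annotation_match(
            metabolite_peak.phenotype_id,
            [g for g, _ in candidates],
            annotation_pairs,
        )
    return CandidateGeneReport(
        metabolite_id=metabolite_peak.phenotype_id,
        locus=metabolite_peak,
        candidate_genes=candidates,
        annotation_matches=matches,
    )


def co_annotation_match(
    metabolite_id: str,
    genes_in_locus: Sequence[str],
    annotation_pairs: Sequence[tuple[str, str]],
) -> list[str]:
    """Genes at the locus that are co-annotated with the metabolite in a
    (metabolite, gene) pathway-pair table."""
    annotated = {g for m, g in annotation_pairs if m == metabolite_id}
    return sorted(set(genes_in_locus) & annotated)
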