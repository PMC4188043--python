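"""Shared data containers for the metabolite-QTL pipeline.

Conventions used throughout the package:

* genomic coordinates are 1-based and intervals are inclusive on both ends;
* genotype dosages are biallelic counts in ``{0, 1, 2}`` with ``NaN`` for
  missing (inbred panels are homozygous, so 0/2 dominate; a dosage of 1 is
  accepted for interpolated recombinant-inbred genotypes);
* missing values are ``NaN`` in memory and the literal ``NA`` on disk.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

import numpy as np


def chrom_sort_key(label: str):
    """Sort key for chromosome labels: numeric first (1..19), then X, Y, M."""
    s = str(label)
    m = re.fullmatch(r"(?:chr)?(\d+)", s)
    if m:
        return (0, int(m.group(1)), "")
    return (1, 0, s)


@dataclass
class GenotypeMatrix:
    """Per-strain biallelic dosages with SNP coordinates.

    ``dosage`` is strains x SNPs with values in {0, 1, 2} and NaN for
    missing.  SNPs are kept sorted by (chromosome, position).
    """

    snp_ids: np.ndarray          # (n_snps,) str
    chrom: np.ndarray            # (n_snps,) str
    pos: np.ndarray              # (n_snps,) int, 1-based bp
    strains: list[str]
    dosage: np.ndarray           # (n_strains, n_snps) float

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.strains), len(self.snp_ids)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.strains)} strains x {len(self.snp_ids)} SNPs"
            )
        if np.any(self.pos <= 0):
            raise ValueError("SNP positions must be strictly positive (1-based)")
        ok = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = np.argwhere(~ok)[0]
            raise ValueError(
                f"dosage outside {{0,1,2,NA}} at strain "
                f"{self.strains[bad[0]]!r}, SNP {self.snp_ids[bad[1]]!r}"
            )
        self._sort()

    def _sort(self) -> None:
        order = sorted(
            range(len(self.snp_ids)),
            key=lambda i: (chrom_sort_key(self.chrom[i]), self.pos[i]),
        )
        order = np.asarray(order, dtype=np.intp)
        self.snp_ids = self.snp_ids[order]
        self.chrom = self.chrom[order]
        self.pos = self.pos[order]
        self.dosage = self.dosage[:, order]

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def maf(self) -> np.ndarray:
        """Minor-allele frequency per SNP over nonmissing strains."""
        d = self.dosage
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(d, axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def snp_index(self, snp_id: str) -> int:
        idx = np.nonzero(self.snp_ids == snp_id)[0]
        if idx.size == 0:
            raise KeyError(f"unknown SNP id {snp_id!r}")
        return int(idx[0])

    def filter_maf(self, min_maf: float = 0.05) -> "GenotypeMatrix":
        """Keep SNPs with MAF strictly greater than ``min_maf``."""
        keep = self.maf > min_maf
        return GenotypeMatrix(
            snp_ids=self.snp_ids[keep],
            chrom=self.chrom[keep],
            pos=self.pos[keep],
            strains=list(self.strains),
            dosage=self.dosage[:, keep],
        )


@dataclass
class PhenotypeTable:
    """Sample-level measurements (metabolites, transcripts or clinical traits).

    ``values`` is samples x variables with NaN for missing.  Each sample maps
    to a strain; run-day batch labels are optional.  ``class_of_variable``
    maps every variable to its class (e.g. the eight metabolite classes
    Lipids, Amino Acids, Carbohydrates, Nucleotides, Peptides, Xenobiotics,
    Cofactors, Energy); it may be empty for un-classed tables (transcripts,
    clinical traits).
    """

    sample_ids: list[str]
    strain_of_sample: list[str]
    variables: list[str]
    values: np.ndarray
    runday_of_sample: Optional[list[str]] = None
    class_of_variable: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.variables)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variables)} variables"
            )
        if len(self.sample_ids) != len(set(self.sample_ids)):
            raise ValueError("duplicate sample_id")
        if len(self.strain_of_sample) != len(self.sample_ids):
            raise ValueError("strain_of_sample length mismatch")
        if self.runday_of_sample is not None and len(self.runday_of_sample) != len(
            self.sample_ids
        ):
            raise ValueError("runday_of_sample length mismatch")
        if self.class_of_variable:
            missing = [v for v in self.variables if v not in self.class_of_variable]
            if missing:
                raise ValueError(
                    f"variables absent from the class map: {missing[:5]}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variables(self) -> int:
        return len(self.variables)

    def column(self, variable: str) -> np.ndarray:
        try:
            j = self.variables.index(variable)
        except ValueError:
            raise KeyError(f"unknown variable {variable!r}") from None
        return self.values[:, j]


@dataclass
class GeneAnnotationTable:
    """Gene spans: 1-based inclusive [start, end] per gene."""

    gene_ids: np.ndarray
    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        if np.any(self.start > self.end):
            raise ValueError("gene start must be <= end")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def lookup(self, gene_id: str) -> tuple[str, int, int]:
        idx = np.nonzero(self.gene_ids == gene_id)[0]
        if idx.size == 0:
            raise KeyError(f"unknown gene {gene_id!r}")
        i = int(idx[0])
        return str(self.chrom[i]), int(self.start[i]), int(self.end[i])


@dataclass(frozen=True)
class SyntenyRecord:
    mouse_chrom: str
    mouse_start: int
    mouse_end: int
    human_chrom: str
    human_start: int
    human_end: int

    def __post_init__(self) -> None:
        if self.mouse_start > self.mouse_end or self.human_start > self.human_end:
            raise ValueError("synteny interval start must be <= end")


@dataclass
class SyntenyMap:
    """Blockwise mouse -> human interval correspondence."""

    records: list[SyntenyRecord]


@dataclass(frozen=True)
class HumanGwasRecord:
    metabolite_id: str
    human_chrom: str
    human_pos: int
    p_value: float
    population_label: str

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside (0, 1]")


@dataclass
class HumanGwasSummary:
    """Published human GWAS hits for serum metabolites, one row per test."""

    records: list[HumanGwasRecord]

    def for_metabolite(self, metabolite_id: str) -> list[HumanGwasRecord]:
        return [r for r in self.records if r.metabolite_id == metabolite_id]


@dataclass(frozen=True)
class AssociationRecord:
    """Single-marker mixed-model test result: beta, F and p for one SNP."""

    phenotype_id: str
    snp_id: str
    chrom: str
    pos: int
    beta: float
    f_stat: float
    p_value: float
    n_used: int
    q_value: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside (0, 1]")
        if self.n_used < 3:
            raise ValueError("n_used must be >= 3")
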