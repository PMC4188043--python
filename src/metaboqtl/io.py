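"""Readers and writers for the pipeline's tab-separated formats.

All tables are plain TSV with a header row.  Missing values are the literal
``NA``; empty cells are rejected so silent truncation fails loudly.  Floats
are written at full (round-tripping) precision via pandas.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    AssociationRecord,
    GeneAnnotationTable,
    GenotypeMatrix,
    HumanGwasRecord,
    HumanGwasSummary,
    PhenotypeTable,
    SyntenyMap,
    SyntenyRecord,
    chrom_sort_key,
)


class ParseError(ValueError):
    """Raised on malformed input tables; message names the file and line."""


_NA = "NA"


def _read_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", dtype=str, na_values=[_NA], keep_default_na=False
    )
    return df


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(
            f"{path}: missing required column(s) {missing}; "
            f"found {list(df.columns)}"
        )


def _numeric_column(df: pd.DataFrame, col: str, path) -> np.ndarray:
    # empty cells survive as "" (keep_default_na=False) and are rejected here
    raw = df[col]
    out = pd.to_numeric(raw, errors="coerce")
    bad = out.isna() & raw.notna()
    if bad.any():
        line = int(np.nonzero(bad.to_numpy())[0][0]) + 2  # header is line 1
        raise ParseError(f"{path}, line {line}: non-numeric value in column {col!r}")
    return out.to_numpy(dtype=float)


# ---------------------------------------------------------------- genotypes


def read_genotype_table(path) -> GenotypeMatrix:
    """Read a genotype TSV: snp_id, chrom, pos, then one column per strain.

    Dosages must be 0, 1, 2 or NA; anything else is a :class:`ParseError`
    naming the offending line.
    """
    df = _read_tsv(path)
    _require_columns(df, ["snp_id", "chrom", "pos"], path)
    strains = [c for c in df.columns if c not in ("snp_id", "chrom", "pos")]
    if not strains:
        raise ParseError(f"{path}: no strain columns after snp_id/chrom/pos")
    pos = _numeric_column(df, "pos", path)
    dosage = np.empty((len(strains), len(df)), dtype=float)
    for i, s in enumerate(strains):
        col = _numeric_column(df, s, path)
        bad = ~(np.isnan(col) | np.isin(col, (0.0, 1.0, 2.0)))
        if bad.any():
            line = int(np.nonzero(bad)[0][0]) + 2
            raise ParseError(
                f"{path}, line {line}: dosage outside {{0,1,2,NA}} for strain {s!r}"
            )
        # empty cells arrive as NaN from an empty string only if the field was
        # literally empty; pandas keeps "" as "" with keep_default_na=False,
        # which to_numeric flags as non-numeric above, so nothing to do here.
        dosage[i] = col
    return GenotypeMatrix(
        snp_ids=df["snp_id"].to_numpy(dtype=object),
        chrom=df["chrom"].to_numpy(dtype=object),
        pos=pos.astype(np.int64),
        strains=strains,
        dosage=dosage,
    )


def write_genotype_table(G: GenotypeMatrix, path) -> None:
    df = pd.DataFrame({"snp_id": G.snp_ids, "chrom": G.chrom, "pos": G.pos})
    for i, s in enumerate(G.strains):
        col = G.dosage[i]
        df[s] = [("NA" if np.isnan(v) else str(int(v))) for v in col]
    df.to_csv(path, sep="\t", index=False, na_rep=_NA)


# --------------------------------------------------------------- phenotypes


def read_phenotype_table(path, classes_path=None) -> PhenotypeTable:
    """Read a sample-level phenotype TSV.

    Layout: sample_id, strain, optional runday, then one column per variable.
    ``classes_path`` is a two-column TSV (variable, class); when given, every
    variable in the data must appear in it.
    """
    df = _read_tsv(path)
    _require_columns(df, ["sample_id", "strain"], path)
    meta_cols = ["sample_id", "strain"]
    runday = None
    if "runday" in df.columns:
        meta_cols.append("runday")
        runday = df["runday"].astype(str).tolist()
    variables = [c for c in df.columns if c not in meta_cols]
    sample_ids = df["sample_id"].astype(str).tolist()
    if len(sample_ids) != len(set(sample_ids)):
        dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ParseError(f"{path}: duplicate sample_id {dupes[:3]}")
    values = np.empty((len(df), len(variables)), dtype=float)
    for j, v in enumerate(variables):
        col = _numeric_column(df, v, path)
        values[:, j] = col
    class_map: dict[str, str] = {}
    if classes_path is not None:
        cdf = _read_tsv(classes_path)
        _require_columns(cdf, ["variable", "class"], classes_path)
        class_map = dict(zip(cdf["variable"], cdf["class"]))
        absent = [v for v in variables if v not in class_map]
        if absent:
            raise ParseError(
                f"{path}: variables absent from class map {classes_path}: "
                f"{absent[:5]}"
            )
    return PhenotypeTable(
        sample_ids=sample_ids,
        strain_of_sample=df["strain"].astype(str).tolist(),
        runday_of_sample=runday,
        variables=variables,
        values=values,
        class_of_variable=class_map,
    )


def write_phenotype_table(table: PhenotypeTable, path, classes_path=None) -> None:
    df = pd.DataFrame({"sample_id": table.sample_ids, "strain": table.strain_of_sample})
    if table.runday_of_sample is not None:
        df["runday"] = table.runday_of_sample
    for j, v in enumerate(table.variables):
        df[v] = table.values[:, j]
    df.to_csv(path, sep="\t", index=False, na_rep=_NA)
    if classes_path is not None and table.class_of_variable:
        cdf = pd.DataFrame(
            {
                "variable": table.variables,
                "class": [table.class_of_variable[v] for v in table.variables],
            }
        )
        cdf.to_csv(classes_path, sep="\t", index=False)


# ------------------------------------------------------------- associations


_ASSOC_COLS = ["phenotype", "snp_id", "chrom", "pos", "beta", "f_stat", "p", "q"]


def write_association_results(records: Iterable[AssociationRecord], path) -> None:
    """Write association records as TSV, sorted by (phenotype, chrom, pos)."""
    records = list(records)
    has_q = any(r.q_value is not None for r in records)
    cols = _ASSOC_COLS if has_q else _ASSOC_COLS[:-1]
    rows = sorted(
        records,
        key=lambda r: (r.phenotype_id, chrom_sort_key(r.chrom), r.pos, r.snp_id),
    )
    df = pd.DataFrame(
        {
            "phenotype": [r.phenotype_id for r in rows],
            "snp_id": [r.snp_id for r in rows],
            "chrom": [r.chrom for r in rows],
            "pos": [r.pos for r in rows],
            "beta": [r.beta for r in rows],
            "f_stat": [r.f_stat for r in rows],
            "p": [r.p_value for r in rows],
        }
    )
    if has_q:
        df["q"] = [r.q_value for r in rows]
    df = df[cols]
    df.to_csv(path, sep="\t", index=False, na_rep=_NA)


def read_association_results(path) -> list[AssociationRecord]:
    df = _read_tsv(path)
    _require_columns(df, _ASSOC_COLS[:-1], path)
    out = []
    for _, row in df.iterrows():
        q = None
        if "q" in df.columns and pd.notna(row["q"]):
            q = float(row["q"])
        out.append(
            AssociationRecord(
                phenotype_id=str(row["phenotype"]),
                snp_id=str(row["snp_id"]),
                chrom=str(row["chrom"]),
                pos=int(float(row["pos"])),
                beta=float(row["beta"]),
                f_stat=float(row["f_stat"]),
                p_value=float(row["p"]),
                n_used=int(float(row["n_used"])) if "n_used" in df.columns else 3,
                q_value=q,
            )
        )
    return out


# ----------------------------------------------------------------- kinship


def write_kinship(strains: Sequence[str], K: np.ndarray, path) -> None:
    df = pd.DataFrame(K, index=list(strains), columns=list(strains))
    df.to_csv(path, sep="\t", index_label="strain")


def read_kinship(path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    strains = [str(s) for s in df.columns]
    return strains, df.to_numpy(dtype=float)


# -------------------------------------------------------------- annotation


def read_gene_annotation(path) -> GeneAnnotationTable:
    """Read gene spans; headered (gene_id, chrom, start, end) or headerless
    4-column BED-like TSV."""
    with open(path) as fh:
        first = fh.readline()
    has_header = first.split("\t")[0].strip() == "gene_id"
    if has_header:
        df = _read_tsv(path)
        _require_columns(df, ["gene_id", "chrom", "start", "end"], path)
    else:
        df = pd.read_csv(
            path, sep="\t", header=None, names=["gene_id", "chrom", "start", "end"],
            dtype=str,
        )
    start = _numeric_column(df, "start", path)
    end = _numeric_column(df, "end", path)
    return GeneAnnotationTable(
        gene_ids=df["gene_id"].to_numpy(dtype=object),
        chrom=df["chrom"].to_numpy(dtype=object),
        start=start.astype(np.int64),
        end=end.astype(np.int64),
    )


def write_gene_annotation(annot: GeneAnnotationTable, path) -> None:
    pd.DataFrame(
        {
            "gene_id": annot.gene_ids,
            "chrom": annot.chrom,
            "start": annot.start,
            "end": annot.end,
        }
    ).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------------ synteny


_SYNTENY_COLS = [
    "mouse_chrom", "mouse_start", "mouse_end",
    "human_chrom", "human_start", "human_end",
]


def read_synteny_map(path) -> SyntenyMap:
    df = _read_tsv(path)
    _require_columns(df, _SYNTENY_COLS, path)
    records = [
        SyntenyRecord(
            mouse_chrom=str(r["mouse_chrom"]),
            mouse_start=int(r["mouse_start"]),
            mouse_end=int(r["mouse_end"]),
            human_chrom=str(r["human_chrom"]),
            human_start=int(r["human_start"]),
            human_end=int(r["human_end"]),
        )
        for _, r in df.iterrows()
    ]
    return SyntenyMap(records=records)


def write_synteny_map(smap: SyntenyMap, path) -> None:
    pd.DataFrame(
        [
            {
                "mouse_chrom": r.mouse_chrom,
                "mouse_start": r.mouse_start,
                "mouse_end": r.mouse_end,
                "human_chrom": r.human_chrom,
                "human_start": r.human_start,
                "human_end": r.human_end,
            }
            for r in smap.records
        ],
        columns=_SYNTENY_COLS,
    ).to_csv(path, sep="\t", index=False)


_HUMAN_COLS = ["metabolite_id", "human_chrom", "human_pos", "p_value", "population"]


def read_human_gwas(path) -> HumanGwasSummary:
    df = _read_tsv(path)
    _require_columns(df, _HUMAN_COLS, path)
    records = [
        HumanGwasRecord(
            metabolite_id=str(r["metabolite_id"]),
            human_chrom=str(r["human_chrom"]),
            human_pos=int(r["human_pos"]),
            p_value=float(r["p_value"]),
            population_label=str(r["population"]),
        )
        for _, r in df.iterrows()
    ]
    return HumanGwasSummary(records=records)


def write_human_gwas(summary: HumanGwasSummary, path) -> None:
    pd.DataFrame(
        [
            {
                "metabolite_id": r.metabolite_id,
                "human_chrom": r.human_chrom,
                "human_pos": r.human_pos,
                "p_value": r.p_value,
                "population": r.population_label,
            }
            for r in summary.records
        ],
        columns=_HUMAN_COLS,
    ).to_csv(path, sep="\t", index=False)


def read_pair_table(path, col_a: str, col_b: str) -> list[tuple[str, str]]:
    """Two-column pair table (e.g. metabolite-gene annotation pairs or a
    cross-species metabolite id map)."""
    df = _read_tsv(path)
    _require_columns(df, [col_a, col_b], path)
    return [(str(a), str(b)) for a, b in zip(df[col_a], df[col_b])]
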