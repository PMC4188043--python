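"""Biweight midcorrelation and the correlation screens built on it.

The biweight midcorrelation (bicor) replaces the mean/variance of Pearson
correlation with median/MAD-based soft weights, so single gross outliers are
downweighted rather than dominating the estimate.  For a vector x:

    u_i = (x_i - med(x)) / (9 * mad(x)),   mad = median(|x - med(x)|)
    w_i = (1 - u_i^2)^2 * 1[|u_i| < 1]

and the correlation is the weighted cross-product of the median-centred
vectors, normalized by the weighted norms.  MAD is unscaled (no 1.4826
consistency factor).  When mad(x) = 0 the variable falls back to mean/sd
standardization with a warning.

P-values use the t approximation t = r sqrt((n-2)/(1-r^2)) on n-2 degrees
of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import stats

from .datatypes import PhenotypeTable
from .multiple_testing import bonferroni_threshold, estimate_qvalues

P_FLOOR = 1e-300


@dataclass
class CorrelationRecord:
    var_a: str
    var_b: str
    r: float
    n: int
    p_value: float
    pair_kind: Literal[
        "within_class", "between_class", "metab_transcript", "metab_trait", "other"
    ] = "other"
    q_value: Optional[float] = None
    significant: Optional[bool] = None


def _biweight_terms(x: np.ndarray):
    """Median-centred values times biweight weights, for one variable."""
    med = np.median(x)
    centred = x - med
    mad = np.median(np.abs(centred))
    if mad == 0.0:
        warnings.warn(
            "zero median absolute deviation; falling back to mean/sd "
            "standardization for this variable"
        )
        mu = x.mean()
        sd = x.std()
        if sd == 0.0:
            raise ValueError("constant variable: correlation undefined")
        return x - mu  # weights all 1 under the fallback
    u = centred / (9.0 * mad)
    w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
    return centred * w


def bicor(x: Sequence[float], y: Sequence[float]) -> float:
    """Biweight midcorrelation of two vectors over their shared nonmissing
    observations (at least 3 required)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    both = ~(np.isnan(x) | np.isnan(y))
    if both.sum() < 3:
        raise ValueError("fewer than 3 shared nonmissing observations")
    a = _biweight_terms(x[both])
    b = _biweight_terms(y[both])
    denom = np.sqrt(np.sum(a**2) * np.sum(b**2))
    if denom == 0.0:
        raise ValueError("degenerate weights: correlation undefined")
    r = float(np.sum(a * b) / denom)
    return max(-1.0, min(1.0, r))


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p for a correlation via the t approximation on n-2 df."""
    if n < 3:
        raise ValueError("need n >= 3")
    if not -1.0 <= r <= 1.0:
        raise ValueError("|r| must be <= 1")
    if abs(r) >= 1.0:
        return P_FLOOR
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return float(max(min(p, 1.0), P_FLOOR))


def _pair_kind(table: PhenotypeTable, va: str, vb: str) -> str:
    cls = table.class_of_variable
    if not cls:
        return "other"
    return "within_class" if cls.get(va) == cls.get(vb) else "between_class"


def pairwise_matrix(
    table: PhenotypeTable,
    threshold_policy: tuple[str, float] = ("bonferroni", 0.05),
) -> list[CorrelationRecord]:
    """All unordered variable pairs with bicor, p, and a significance flag.

    ``threshold_policy`` is ``("bonferroni", alpha)`` (threshold alpha over
    the number of pairs) or ``("fdr", level)`` (Storey q-values over the
    pair p-values).  Per-pair casewise deletion; pairs with fewer than 3
    shared observations are dropped.
    """
    policy, level = threshold_policy
    if policy not in ("bonferroni", "fdr"):
        raise ValueError(f"unknown policy {policy!r}")
    records: list[CorrelationRecord] = []
    V = table.values
    for ia, ib in combinations(range(table.n_variables), 2):
        x, y = V[:, ia], V[:, ib]
        both = ~(np.isnan(x) | np.isnan(y))
        n = int(both.sum())
        if n < 3:
            continue
        r = bicor(x, y)
        p = correlation_pvalue(r, n)
        va, vb = table.variables[ia], table.variables[ib]
        records.append(
            CorrelationRecord(
                var_a=va, var_b=vb, r=r, n=n, p_value=p,
                pair_kind=_pair_kind(table, va, vb),
            )
        )
    if records:
        if policy == "bonferroni":
            thr = bonferroni_threshold(len(records), level)
            for rec in records:
                rec.significant = rec.p_value < thr
        else:
            qres = estimate_qvalues([rec.p_value for rec in records])
            for rec, q in zip(records, qres.qvalues):
                rec.q_value = float(q)
                rec.significant = q <= level
    return records


def class_pair_summary(records: Sequence[CorrelationRecord]) -> dict:
    """Within- vs between-class accounting of significant pairs.

    Percentages are reported to the nearest integer, with the between-class
    share defined as 100 minus the rounded within-class share so the two
    always sum to 100.
    """
    sig = [r for r in records if r.significant]
    for r in sig:
        if r.pair_kind not in ("within_class", "between_class"):
            raise ValueError("records lack class labels")
    n_sig = len(sig)
    n_within = sum(r.pair_kind == "within_class" for r in sig)
    n_between = n_sig - n_within
    pct_within = round(100.0 * n_within / n_sig) if n_sig else 0
    return {
        "n_significant": n_sig,
        "n_within": n_within,
        "n_between": n_between,
        "pct_within": pct_within,
        "pct_between": 100 - pct_within if n_sig else 0,
    }


def cross_correlate(
    metab_table: PhenotypeTable,
    other_table: PhenotypeTable,
    fdr_level: float = 0.05,
    pair_kind: str = "metab_trait",
) -> list[CorrelationRecord]:
    """Metabolite x other-variable correlation screen at an FDR level.

    Rows are matched by strain; q-values are computed over all pairs and
    only significant records are returned (with the sign of r preserved).
    """
    strains_a = {s: i for i, s in enumerate(metab_table.strain_of_sample)}
    shared = [s for s in other_table.strain_of_sample if s in strains_a]
    if len(set(shared)) < 3:
        raise ValueError("fewer than 3 shared strains")
    idx_a = [strains_a[s] for s in shared]
    idx_b = [other_table.strain_of_sample.index(s) for s in shared]
    A = metab_table.values[idx_a, :]
    B = other_table.values[idx_b, :]
    records: list[CorrelationRecord] = []
    for ja, va in enumerate(metab_table.variables):
        for jb, vb in enumerate(other_table.variables):
            x, y = A[:, ja], B[:, jb]
            both = ~(np.isnan(x) | np.isnan(y))
            n = int(both.sum())
            if n < 3:
                continue
            r = bicor(x, y)
            records.append(
                CorrelationRecord(
                    var_a=va, var_b=vb, r=r, n=n,
                    p_value=correlation_pvalue(r, n), pair_kind=pair_kind,
                )
            )
    if not records:
        return []
    qres = estimate_qvalues([rec.p_value for rec in records])
    out = []
    for rec, q in zip(records, qres.qvalues):
        rec.q_value = float(q)
        rec.significant = q <= fdr_level
        if rec.significant:
            out.append(rec)
    return out


def sign_split(records: Sequence[CorrelationRecord]) -> dict:
    """Counts and rounded percentages of positive vs negative correlations."""
    n = len(records)
    n_pos = sum(r.r > 0 for r in records)
    n_neg = n - n_pos
    return {
        "n": n,
        "n_positive": n_pos,
        "n_negative": n_neg,
        "pct_positive": round(100.0 * n_pos / n) if n else 0,
        "pct_negative": 100 - round(100.0 * n_pos / n) if n else 0,
    }
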