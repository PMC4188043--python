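"""False-discovery-rate machinery: Storey q-values, FDR-equivalent p-value
thresholds, and Bonferroni helpers.

The q-value estimator follows the smoother approach: pi0 (the null
proportion) is estimated from pi0(lambda) = #{p > lambda} / (m (1 - lambda))
on the grid lambda = 0.05, 0.10, ..., 0.95, smoothed by a cubic spline and
read off at the grid's right end, then clamped to (0, 1].  With pi0 forced
to 1 the q-values reduce exactly to Benjamini-Hochberg adjusted p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import UnivariateSpline


@dataclass
class QValueResult:
    pvalues: np.ndarray
    qvalues: np.ndarray
    pi0: float
    lambda_grid: np.ndarray


_DEFAULT_LAMBDAS = np.round(np.arange(0.05, 0.951, 0.05), 2)


def _estimate_pi0(p: np.ndarray, lambdas: np.ndarray) -> float:
    m = p.size
    pi0_l = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    try:
        spline = UnivariateSpline(lambdas, pi0_l, k=3)
        pi0 = float(spline(lambdas[-1]))
    except Exception:
        warnings.warn("pi0 spline fit failed; falling back to pi0 = 1")
        return 1.0
    if not np.isfinite(pi0) or pi0 <= 0:
        warnings.warn("pi0 estimate out of range; falling back to pi0 = 1")
        return 1.0
    return min(pi0, 1.0)


def estimate_qvalues(
    pvalues: Sequence[float],
    pi0: Optional[float] = None,
    lambdas: np.ndarray = _DEFAULT_LAMBDAS,
) -> QValueResult:
    """Storey q-values for a vector of p-values in (0, 1].

    ``pi0=1`` forces the Benjamini-Hochberg special case.  Inputs of fewer
    than 100 tests skip the spline and use the conservative pi0 = 1 (the
    smoother is unstable on tiny inputs).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    if pi0 is None:
        pi0 = 1.0 if p.size < 100 else _estimate_pi0(p, lambdas)
    if not (0 < pi0 <= 1):
        raise ValueError("pi0 must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q_ranked = pi0 * m * ranked / np.arange(1, m + 1)
    # enforce monotonicity: q_i = min over j >= i of the raw values
    q_ranked = np.minimum.accumulate(q_ranked[::-1])[::-1]
    q_ranked = np.minimum(q_ranked, 1.0)
    q = np.empty_like(q_ranked)
    q[order] = q_ranked
    return QValueResult(pvalues=p, qvalues=q, pi0=float(pi0),
                        lambda_grid=np.asarray(lambdas))


def pvalue_threshold_at_fdr(
    pvalues: Sequence[float], level: float, pi0: Optional[float] = None
) -> float:
    """Largest p-value whose q-value is <= ``level``; 0 if none qualifies.

    This is the mapping from an FDR level to the "genome-wide p-value
    cutoff" reported alongside scan results.
    """
    if not (0 < level < 1):
        raise ValueError("level must lie in (0, 1)")
    res = estimate_qvalues(pvalues, pi0=pi0)
    ok = res.qvalues <= level
    if not ok.any():
        return 0.0
    return float(res.pvalues[ok].max())


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Family-wise threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def expected_false_positives(n_significant: int, fdr_level: float) -> int:
    """Expected false discoveries among ``n_significant`` calls at the given
    FDR level, rounded to the nearest integer for reporting."""
    if n_significant < 0 or fdr_level < 0:
        raise ValueError("inputs must be nonnegative")
    return int(round(n_significant * fdr_level))
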