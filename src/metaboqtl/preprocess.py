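"""Sample-level metabolite processing: missingness filter, run-day
registration, replicate averaging, z-scoring.

The fixed stage order is: (1) drop variables with more than 20% missing
cells across samples; (2) register each run-day's pooled median to one by
dividing every cell of the run-day by that median (exactly inverts a
multiplicative batch effect); (3) average replicate samples of a strain to
one row per strain; (4) z-score each variable with the sample standard
deviation (n-1).  Strains, not samples, are the unit of downstream
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import PhenotypeTable

MISSING_MAX_DEFAULT = 0.20


@dataclass
class StandardizedPhenotype:
    """Strain-level z-scored matrix plus a record of the filters applied."""

    strain_ids: list[str]
    variables: list[str]
    zvalues: np.ndarray
    provenance: dict = field(default_factory=dict)

    def to_table(self, class_of_variable: dict | None = None) -> PhenotypeTable:
        return PhenotypeTable(
            sample_ids=list(self.strain_ids),
            strain_of_sample=list(self.strain_ids),
            variables=list(self.variables),
            values=self.zvalues,
            class_of_variable=class_of_variable or {},
        )


def filter_by_missingness(
    table: PhenotypeTable, max_frac: float = MISSING_MAX_DEFAULT
) -> PhenotypeTable:
    """Drop variables whose missing fraction across samples exceeds
    ``max_frac`` (strict inequality: exactly 20% missing is retained)."""
    if not (0.0 <= max_frac <= 1.0):
        raise ValueError("max_frac must lie in [0, 1]")
    frac = np.isnan(table.values).mean(axis=0)
    keep = frac <= max_frac
    dropped = [v for v, k in zip(table.variables, keep) if not k]
    kept_vars = [v for v, k in zip(table.variables, keep) if k]
    cls = {v: c for v, c in table.class_of_variable.items() if v in kept_vars}
    out = PhenotypeTable(
        sample_ids=list(table.sample_ids),
        strain_of_sample=list(table.strain_of_sample),
        runday_of_sample=(
            list(table.runday_of_sample)
            if table.runday_of_sample is not None
            else None
        ),
        variables=kept_vars,
        values=table.values[:, keep],
        class_of_variable=cls,
    )
    return out, dropped


def normalize_run_days(table: PhenotypeTable) -> PhenotypeTable:
    """Divide every cell of each run-day by the run-day's pooled median
    (median over all nonmissing cells of all variables in that run-day), so
    each run-day's median becomes exactly 1."""
    if table.runday_of_sample is None:
        raise ValueError("run-day labels required")
    values = table.values.copy()
    rundays = np.asarray(table.runday_of_sample)
    for day in np.unique(rundays):
        rows = rundays == day
        cells = values[rows, :]
        finite = cells[~np.isnan(cells)]
        if finite.size == 0:
            raise ValueError(f"run-day {day!r} has no nonmissing cells")
        med = np.median(finite)
        if med <= 0:
            raise ValueError(f"run-day {day!r} median {med} is not positive")
        values[rows, :] = cells / med
    return PhenotypeTable(
        sample_ids=list(table.sample_ids),
        strain_of_sample=list(table.strain_of_sample),
        runday_of_sample=list(table.runday_of_sample),
        variables=list(table.variables),
        values=values,
        class_of_variable=dict(table.class_of_variable),
    )


def average_strain_replicates(table: PhenotypeTable) -> PhenotypeTable:
    """Collapse samples to one row per strain by the mean over nonmissing
    replicates; a cell is missing only if every replicate is missing.
    Strain order follows first appearance."""
    strains: list[str] = []
    for s in table.strain_of_sample:
        if s not in strains:
            strains.append(s)
    values = np.full((len(strains), table.n_variables), np.nan)
    strain_arr = np.asarray(table.strain_of_sample)
    for i, s in enumerate(strains):
        rows = table.values[strain_arr == s, :]
        present = ~np.isnan(rows)
        cnt = present.sum(axis=0)
        sums = np.where(present, rows, 0.0).sum(axis=0)
        values[i] = np.where(cnt > 0, sums / np.maximum(cnt, 1), np.nan)
    return PhenotypeTable(
        sample_ids=strains,
        strain_of_sample=strains,
        variables=list(table.variables),
        values=values,
        class_of_variable=dict(table.class_of_variable),
    )


def standardize(table: PhenotypeTable) -> StandardizedPhenotype:
    """Per-variable z-scores: (value - mean) / sample sd (n-1 denominator).

    Missing stays missing.  Constant variables are an error naming the
    variable.
    """
    values = table.values.astype(float).copy()
    for j, v in enumerate(table.variables):
        col = values[:, j]
        ok = ~np.isnan(col)
        if ok.sum() < 2:
            raise ValueError(f"variable {v!r} has fewer than 2 nonmissing values")
        mu = col[ok].mean()
        sd = col[ok].std(ddof=1)
        if sd == 0:
            raise ValueError(f"variable {v!r} has zero variance")
        values[ok, j] = (col[ok] - mu) / sd
    return StandardizedPhenotype(
        strain_ids=list(table.sample_ids),
        variables=list(table.variables),
        zvalues=values,
        provenance={"standardize": "zscore, sample sd (ddof=1)"},
    )


def preprocess_pipeline(
    table: PhenotypeTable, max_missing: float = MISSING_MAX_DEFAULT
) -> StandardizedPhenotype:
    """Full raw-sample -> strain-level-z pipeline in the fixed order."""
    filtered, dropped = filter_by_missingness(table, max_missing)
    if filtered.runday_of_sample is not None:
        filtered = normalize_run_days(filtered)
    averaged = average_strain_replicates(filtered)
    z = standardize(averaged)
    z.provenance.update(
        {
            "missingness_filter": {
                "max_frac": max_missing,
                "dropped": dropped,
                "n_dropped": len(dropped),
            },
            "runday_normalization": table.runday_of_sample is not None,
            "replicate_averaging": True,
        }
    )
    return z


def replicate_variance_summary(
    table: PhenotypeTable, replicate_strain: str
) -> dict:
    """Within-replicate-strain vs across-panel variance of each variable.

    Quantifies genetic vs non-genetic variability: the designated strain's
    biological replicates carry only non-genetic variance, while variance
    across the panel's strain means includes the genetic component.
    Returns means, medians and their ratios over variables with defined
    variances.  Requires at least 2 replicate samples.
    """
    strain_arr = np.asarray(table.strain_of_sample)
    rep_rows = table.values[strain_arr == replicate_strain, :]
    if rep_rows.shape[0] < 2:
        raise ValueError(
            f"replicate strain {replicate_strain!r} has fewer than 2 samples"
        )
    averaged = average_strain_replicates(table)
    with np.errstate(invalid="ignore", divide="ignore"):
        within = np.nanvar(rep_rows, axis=0, ddof=1)
        panel = np.nanvar(averaged.values, axis=0, ddof=1)
    ok = np.isfinite(within) & np.isfinite(panel)
    within, panel = within[ok], panel[ok]
    return {
        "n_variables": int(ok.sum()),
        "within_mean": float(np.mean(within)),
        "within_median": float(np.median(within)),
        "panel_mean": float(np.mean(panel)),
        "panel_median": float(np.median(panel)),
        "mean_ratio": float(np.mean(panel) / np.mean(within))
        if np.mean(within) > 0
        else np.inf,
        "median_ratio": float(np.median(panel) / np.median(within))
        if np.median(within) > 0
        else np.inf,
    }


def add_ratio_phenotypes(
    z: StandardizedPhenotype, pairs: list[tuple[str, str]]
) -> StandardizedPhenotype:
    """Append log-ratio phenotypes of metabolite pairs for ratio mapping.

    Each pair (a, b) adds a variable ``a/b`` equal to the difference of the
    z-scored variables (the log-ratio of the underlying relative levels up
    to scale), re-standardized.
    """
    cols = [z.zvalues]
    names = list(z.variables)
    for a, b in pairs:
        ia, ib = z.variables.index(a), z.variables.index(b)
        diff = z.zvalues[:, ia] - z.zvalues[:, ib]
        ok = ~np.isnan(diff)
        sd = diff[ok].std(ddof=1)
        if sd == 0:
            raise ValueError(f"ratio {a}/{b} has zero variance")
        diff = (diff - diff[ok].mean()) / sd
        cols.append(diff[:, None])
        names.append(f"{a}/{b}")
    return StandardizedPhenotype(
        strain_ids=list(z.strain_ids),
        variables=names,
        zvalues=np.hstack(cols),
        provenance={**z.provenance, "ratio_phenotypes": [f"{a}/{b}" for a, b in pairs]},
    )
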