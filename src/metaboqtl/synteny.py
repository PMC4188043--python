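"""Cross-species locus replication through a synteny map.

A mouse locus (peak SNP +/- 1 Mb) is projected onto human coordinates by
interval intersection with a blockwise synteny map: every block overlapping
the mouse interval contributes its whole mapped human interval.  The human
GWAS summary is then searched for the same metabolite within those
intervals; the locus replicates when the minimum p in any population is at
or below a Bonferroni threshold alpha / n_loci_tested.  All intervals are
1-based and inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .datatypes import HumanGwasSummary, SyntenyMap


@dataclass
class ReplicationResult:
    metabolite_id: str
    mouse_locus: tuple[str, int, int]
    human_intervals: list[tuple[str, int, int]]
    min_p_by_population: dict[str, float]
    threshold: float
    replicated: bool
    populations_supporting: int
    measured_in_human: bool = True


def map_to_syntenic_intervals(
    mouse_interval: tuple[str, int, int], synteny_map: SyntenyMap
) -> list[tuple[str, int, int]]:
    """Human intervals of every synteny block overlapping the mouse
    interval (inclusive overlap); empty list when none overlaps."""
    chrom, start, end = mouse_interval
    if start > end:
        raise ValueError("mouse interval start must be <= end")
    out = []
    for rec in synteny_map.records:
        if rec.mouse_chrom != str(chrom):
            continue
        if rec.mouse_start <= end and start <= rec.mouse_end:
            out.append((rec.human_chrom, rec.human_start, rec.human_end))
    return out


def replication_test(
    human_summary: HumanGwasSummary,
    metabolite_id: str,
    human_intervals: Sequence[tuple[str, int, int]],
    n_loci_tested: int,
    alpha: float = 0.05,
    mouse_locus: tuple[str, int, int] = ("NA", 0, 0),
) -> ReplicationResult:
    """Bonferroni-controlled replication of one mouse locus in human data.

    The threshold is alpha / n_loci_tested.  Only records of the same
    metabolite falling inside a mapped interval (endpoints inclusive) enter
    the per-population minimum p.  A metabolite absent from the human table
    returns replicated=False with ``measured_in_human=False``.
    """
    if n_loci_tested < 1:
        raise ValueError("n_loci_tested must be >= 1")
    threshold = alpha / n_loci_tested
    recs = human_summary.for_metabolite(metabolite_id)
    if not recs:
        return ReplicationResult(
            metabolite_id=metabolite_id,
            mouse_locus=mouse_locus,
            human_intervals=list(human_intervals),
            min_p_by_population={},
            threshold=threshold,
            replicated=False,
            populations_supporting=0,
            measured_in_human=False,
        )
    min_p: dict[str, float] = {}
    for r in recs:
        inside = any(
            r.human_chrom == str(c) and s <= r.human_pos <= e
            for c, s, e in human_intervals
        )
        if not inside:
            continue
        prev = min_p.get(r.population_label)
        if prev is None or r.p_value < prev:
            min_p[r.population_label] = r.p_value
    supporting = sum(p <= threshold for p in min_p.values())
    return ReplicationResult(
        metabolite_id=metabolite_id,
        mouse_locus=mouse_locus,
        human_intervals=list(human_intervals),
        min_p_by_population=min_p,
        threshold=threshold,
        replicated=supporting >= 1,
        populations_supporting=supporting,
    )


def replicate_loci(
    peaks: Sequence,            # LocusPeak
    synteny_map: SyntenyMap,
    human_summary: HumanGwasSummary,
    metabolite_id_map: Optional[dict[str, str]] = None,
    alpha: float = 0.05,
    half_window: int = 1_000_000,
) -> list[ReplicationResult]:
    """Replication screen over a set of mouse locus peaks.

    ``metabolite_id_map`` translates mouse metabolite ids to the human
    study's identifiers (defaults to identity).  n_loci_tested is the
    number of peaks screened, matching the Bonferroni convention of
    dividing alpha by the loci examined.
    """
    n_loci = len(peaks)
    out = []
    for pk in peaks:
        interval = (pk.chrom, max(1, pk.pos - half_window), pk.pos + half_window)
        intervals = map_to_syntenic_intervals(interval, synteny_map)
        human_id = (metabolite_id_map or {}).get(pk.phenotype_id, pk.phenotype_id)
        res = replication_test(
            human_summary,
            human_id,
            intervals,
            n_loci_tested=n_loci,
            alpha=alpha,
            mouse_locus=interval,
        )
        res.metabolite_id = pk.phenotype_id
        out.append(res)
    return out
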