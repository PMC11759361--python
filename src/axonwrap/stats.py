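"""Condition-level aggregation, screening statistics and hit calling.

Per-field wrapping indices are pooled across all wells and fields of a
condition (the replicate structure of the assay: e.g. 3 wells x 9 fields
= 27 fields per compound), compound means are scaled by the vehicle
(DMSO) control, and a compound is called a hit when its mean WI exceeds
the control mean by more than two standard deviations of the control's
per-field WI values.  Rank order is by scaled WI, descending, ties broken
alphabetically so the ranking is a pure function of the scaled means.

The hypothesis tests mirror the assay's analysis choices: exact
Mann-Whitney (full enumeration) for small samples with a normal
approximation beyond, Kruskal-Wallis with tie correction, and one-way
ANOVA with Bonferroni-adjusted pairwise comparisons.
"""

from __future__ import annotations

import logging
import math
import string
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stack_io import PlateManifest
from .wrapping import FieldMetrics

logger = logging.getLogger(__name__)

EXACT_MW_MAX_N = 12  # full enumeration up to this combined sample size


class StatsError(ValueError):
    pass


@dataclass
class ConditionSummary:
    condition: str
    wi_values: list[float]
    mean_wi: float
    sem_wi: float
    n_fields: int
    sheath_lengths_um: list[float] = field(default_factory=list)


@dataclass
class CompoundResult:
    compound: str
    scaled_wi: float
    hit: bool | None = None
    rank: int | None = None


def aggregate(
    manifest: PlateManifest,
    metrics: Mapping[tuple[str, str], FieldMetrics],
) -> list[ConditionSummary]:
    """Pool per-field metrics to one summary per condition.

    Fields whose WI is undefined (no nuclei) are excluded with a logged
    count.  A condition left with zero valid fields is an error.
    """
    table = manifest.table
    known = {(str(r.well_id), str(r.field_id)) for r in table.itertuples()}
    unknown = [k for k in metrics if k not in known]
    if unknown:
        raise StatsError(f"metrics for fields not in manifest: {unknown[:5]}")

    summaries = []
    for cond, grp in table.groupby("condition", sort=True):
        wi, sheaths, n_excluded = [], [], 0
        for r in grp.itertuples():
            m = metrics.get((str(r.well_id), str(r.field_id)))
            if m is None:
                continue
            if not m.wi_valid:
                n_excluded += 1
                continue
            wi.append(m.wi)
            sheaths.extend(m.sheath_lengths_um)
        if n_excluded:
            logger.warning("condition %s: excluded %d WI-undefined field(s)", cond, n_excluded)
        if not wi:
            raise StatsError(f"condition {cond!r} has zero valid fields")
        arr = np.asarray(wi)
        sem = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else float("nan")
        summaries.append(
            ConditionSummary(
                condition=str(cond),
                wi_values=list(map(float, arr)),
                mean_wi=float(arr.mean()),
                sem_wi=sem,
                n_fields=len(arr),
                sheath_lengths_um=sheaths,
            )
        )
    return summaries


def scale_by_control(
    summaries: Sequence[ConditionSummary], control_label: str = "DMSO"
) -> list[CompoundResult]:
    """Scaled WI = mean WI / mean control WI; the control itself scales to 1."""
    by_label = {s.condition: s for s in summaries}
    control = by_label.get(control_label)
    if control is None:
        raise StatsError(f"control condition {control_label!r} not found")
    if not (control.mean_wi > 0):
        raise StatsError(f"control mean WI must be > 0, got {control.mean_wi}")
    return [
        CompoundResult(compound=s.condition, scaled_wi=s.mean_wi / control.mean_wi)
        for s in summaries
    ]


def call_hits(
    summaries: Sequence[ConditionSummary], control_label: str = "DMSO"
) -> dict[str, bool]:
    """Hit iff mean WI strictly exceeds control mean + 2 sd of control fields."""
    by_label = {s.condition: s for s in summaries}
    control = by_label.get(control_label)
    if control is None:
        raise StatsError(f"control condition {control_label!r} not found")
    if control.n_fields < 2:
        raise StatsError("control needs >= 2 fields to define its sd")
    sd = float(np.std(control.wi_values, ddof=1))
    cut = control.mean_wi + 2.0 * sd
    return {s.condition: bool(s.mean_wi > cut) for s in summaries}


def rank_compounds(results: Sequence[CompoundResult]) -> list[CompoundResult]:
    """Descending scaled WI, ties broken alphabetically; rank 1 = highest."""
    if not results:
        raise StatsError("no compounds to rank")
    ordered = sorted(results, key=lambda r: (-r.scaled_wi, r.compound))
    out = []
    for i, r in enumerate(ordered, start=1):
        out.append(CompoundResult(r.compound, r.scaled_wi, r.hit, rank=i))
    return out


def _u_statistic(ranks_x: np.ndarray, n1: int, n2: int) -> float:
    # number of (x, y) pairs with x > y, ties counting one half
    return float(ranks_x.sum()) - n1 * (n1 + 1) / 2.0


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U (for x) with a two-sided p value.

    Combined n <= 12: exact p by full enumeration of rank assignments
    (midranks handle ties).  Larger samples: normal approximation with tie
    correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise StatsError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_obs = _u_statistic(ranks[:n1], n1, n2)

    if n1 + n2 <= EXACT_MW_MAX_N:
        mu = n1 * n2 / 2.0
        dev_obs = abs(u_obs - mu)
        total = hits = 0
        for idx in combinations(range(n1 + n2), n1):
            u = _u_statistic(ranks[list(idx)], n1, n2)
            total += 1
            if abs(u - mu) >= dev_obs - 1e-12:
                hits += 1
        return u_obs, hits / total

    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction and its chi-square p (k-1 df)."""
    if len(groups) < 3:
        raise StatsError("Kruskal-Wallis needs >= 3 groups")
    if any(len(g) < 1 for g in groups):
        raise StatsError("every group must be non-empty")
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    if np.ptp(pooled) == 0:
        return 0.0, 1.0  # every observation tied; scipy refuses this edge case
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def anova_bonferroni(
    groups: Mapping[str, Sequence[float]]
) -> tuple[float, float, dict[tuple[str, str], float]]:
    """One-way ANOVA plus Bonferroni-adjusted pairwise t tests.

    Pairwise p values are multiplied by the number of pairs C(k, 2) and
    capped at 1.  Identical groups give F = 0 and all adjusted p = 1.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise StatsError("need >= 2 groups")
    arrays = {k: np.asarray(groups[k], float) for k in labels}
    if any(len(a) < 2 for a in arrays.values()):
        raise StatsError("every group needs >= 2 observations")
    pooled = np.concatenate(list(arrays.values()))
    if np.ptp(pooled) == 0:
        raise StatsError("all observations identical; ANOVA undefined")

    within_var = [a.var(ddof=1) for a in arrays.values()]
    if all(v == 0 for v in within_var):
        raise StatsError("zero within-group variance in every group; ANOVA undefined")

    f_stat, p = sps.f_oneway(*arrays.values())
    n_pairs = math.comb(len(labels), 2)
    pairwise: dict[tuple[str, str], float] = {}
    for a, b in combinations(labels, 2):
        if np.array_equal(arrays[a], arrays[b]):
            p_ab = 1.0
        else:
            p_ab = float(sps.ttest_ind(arrays[a], arrays[b]).pvalue)
        pairwise[(a, b)] = min(p_ab * n_pairs, 1.0)
    # identical groups: between-group variance is 0, so F is exactly 0
    if np.isnan(f_stat):
        f_stat, p = 0.0, 1.0
    return float(f_stat), float(p), pairwise


def inner_wells(rows: int = 8, cols: int = 12) -> list[str]:
    """Wells of a plate excluding the outermost perimeter ring, A1-style.

    An 8x12 (96-well) plate keeps the inner 6x10 = 60 wells, the set used
    for the assay to avoid edge-well evaporation.
    """
    if rows < 3 or cols < 3:
        raise StatsError("plate too small: need rows >= 3 and cols >= 3")
    letters = string.ascii_uppercase
    if rows > len(letters):
        raise StatsError("plate has more rows than single-letter labels")
    return [
        f"{letters[r]}{c + 1}"
        for r in range(1, rows - 1)
        for c in range(1, cols - 1)
    ]


def summary_table(summaries: Sequence[ConditionSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "condition": s.condition,
                "mean_WI": s.mean_wi,
                "SEM_WI": s.sem_wi,
                "n_fields": s.n_fields,
                "mean_sheath_um": float(np.mean(s.sheath_lengths_um))
                if s.sheath_lengths_um
                else float("nan"),
            }
            for s in summaries
        ]
    )


def compound_table(results: Sequence[CompoundResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"compound": r.compound, "scaled_WI": r.scaled_wi, "hit": r.hit, "rank": r.rank}
            for r in results
        ]
    )
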