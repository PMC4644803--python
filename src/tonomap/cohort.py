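"""Per-animal summaries and two-group comparisons.

The animal is the unit of analysis: site metrics are aggregated into one
summary row per animal (percentages over its AI responsive sites), and groups
are compared with a pooled-variance two-tailed Student's t-test on the
per-animal values.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig
from .errors import ValidationError

#: metrics compared between groups, in report order
COMPARISON_METRICS = (
    "tonotopic_index",
    "pct_irregular",
    "pct_single",
    "pct_multiflat",
    "pct_hi_thr",
    "pct_band_10.0_50.0",
    "mean_bw10_oct",
    "mean_latency_ms",
)


@dataclass
class AnimalSummary:
    """One animal's aggregate receptive-field statistics (AI sites only)."""

    animal_id: str
    group: str
    n_sites: int
    n_responsive: int
    n_ai: int
    pct_by_band: dict[str, float]
    pct_irregular: float
    pct_single: float
    pct_multiflat: float
    pct_hi_thr: float
    mean_bw10_oct: float
    mean_latency_ms: float
    tonotopic_index: float

    def to_row(self) -> dict:
        row = {
            "animal_id": self.animal_id,
            "group": self.group,
            "n_sites": self.n_sites,
            "n_responsive": self.n_responsive,
            "n_ai": self.n_ai,
        }
        row.update(self.pct_by_band)
        row.update({
            "pct_irregular": self.pct_irregular,
            "pct_single": self.pct_single,
            "pct_multiflat": self.pct_multiflat,
            "pct_hi_thr": self.pct_hi_thr,
            "mean_bw10_oct": self.mean_bw10_oct,
            "mean_latency_ms": self.mean_latency_ms,
            "tonotopic_index": self.tonotopic_index,
        })
        return row


@dataclass
class GroupComparison:
    """Pooled-variance two-sample t-test on per-animal values."""

    metric: str
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    n_a: int
    n_b: int
    t: float
    df: int
    p: float


def band_labels(edges_khz) -> list[str]:
    return [f"pct_band_{lo}_{hi}" for lo, hi in zip(edges_khz, edges_khz[1:])]


def summarize_animal(site_metrics: pd.DataFrame, animal_id: str, group: str,
                     tonotopic_index: Optional[float] = None,
                     config: Optional[RunConfig] = None) -> AnimalSummary:
    """Aggregate one animal's site metrics.

    All percentages are computed over the animal's responsive AI sites.  With
    zero AI sites every statistic is NaN (flagged, not an error).
    """
    config = config or RunConfig()
    df = site_metrics
    n_sites = len(df)
    responsive = df["responsive"].astype(bool)
    in_ai = df["in_ai"].fillna(False).astype(bool) if "in_ai" in df else \
        pd.Series(False, index=df.index)
    ai = df[responsive & in_ai]
    n_ai = len(ai)

    edges = config.band_edges_khz
    labels = band_labels(edges)
    nan = float("nan")
    if n_ai == 0:
        bands = {lab: nan for lab in labels}
        return AnimalSummary(animal_id, group, n_sites, int(responsive.sum()),
                             0, bands, nan, nan, nan, nan, nan, nan,
                             tonotopic_index if tonotopic_index is not None
                             else nan)

    cf_khz = pd.to_numeric(ai["cf_hz"], errors="coerce") / 1000.0
    bands = {}
    for lab, lo, hi in zip(labels, edges, edges[1:]):
        last = hi == edges[-1]
        inside = (cf_khz >= lo) & ((cf_khz <= hi) if last else (cf_khz < hi))
        bands[lab] = 100.0 * inside.mean()

    irr = pd.to_numeric(ai["irregularity"], errors="coerce")
    pct_irregular = 100.0 * (irr > config.irregularity_cutoff).loc[irr.notna()].mean() \
        if irr.notna().any() else nan
    shape = ai["shape"]
    pct_single = 100.0 * (shape == "single_v").mean()
    thr = pd.to_numeric(ai["threshold_db"], errors="coerce")
    pct_hi_thr = 100.0 * (thr > config.hi_threshold_db).mean()
    bw = pd.to_numeric(ai["bw10_oct"], errors="coerce")
    lat = pd.to_numeric(ai["latency_ms"], errors="coerce")

    return AnimalSummary(
        animal_id=animal_id, group=group, n_sites=n_sites,
        n_responsive=int(responsive.sum()), n_ai=n_ai, pct_by_band=bands,
        pct_irregular=float(pct_irregular),
        pct_single=float(pct_single),
        pct_multiflat=float(100.0 - pct_single),
        pct_hi_thr=float(pct_hi_thr),
        mean_bw10_oct=float(bw.mean()) if bw.notna().any() else nan,
        mean_latency_ms=float(lat.mean()) if lat.notna().any() else nan,
        tonotopic_index=float(tonotopic_index)
        if tonotopic_index is not None else nan,
    )


def pooled_group_percentages(site_metrics: pd.DataFrame,
                             config: Optional[RunConfig] = None
                             ) -> pd.DataFrame:
    """Alternative site-pooled percentages per group (not per-animal means)."""
    config = config or RunConfig()
    rows = []
    for grp, df in site_metrics.groupby("group"):
        s = summarize_animal(df, animal_id=f"pooled:{grp}", group=grp,
                             config=config)
        rows.append(s.to_row())
    return pd.DataFrame(rows)


def compare_groups(summaries: pd.DataFrame, metric: str) -> GroupComparison:
    """Student's pooled-variance two-tailed t-test on per-animal values.

    NaN animals are dropped (reducing df); needs >= 2 animals per group.  With
    zero variance in both groups the test degenerates: p = 1 for equal means,
    p = 0 otherwise.
    """
    if metric not in summaries.columns:
        raise ValidationError(f"metric {metric!r} not in summaries")
    groups = list(dict.fromkeys(summaries["group"]))
    if len(groups) != 2:
        raise ValidationError("compare_groups: exactly two groups required")
    ga, gb = groups
    a = pd.to_numeric(summaries.loc[summaries["group"] == ga, metric],
                      errors="coerce").dropna().to_numpy()
    b = pd.to_numeric(summaries.loc[summaries["group"] == gb, metric],
                      errors="coerce").dropna().to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValidationError(
            f"compare_groups: need >= 2 non-missing animals per group for "
            f"{metric!r} (got {len(a)} vs {len(b)})")
    df_ = len(a) + len(b) - 2
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        equal = math.isclose(a.mean(), b.mean())
        t, p = (0.0, 1.0) if equal else (math.inf if a.mean() > b.mean()
                                         else -math.inf, 0.0)
    else:
        t, p = stats.ttest_ind(a, b, equal_var=True)
        t, p = float(t), float(p)
    return GroupComparison(
        metric=metric, group_a=ga, group_b=gb,
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        sem_a=float(a.std(ddof=1) / math.sqrt(len(a))),
        sem_b=float(b.std(ddof=1) / math.sqrt(len(b))),
        n_a=len(a), n_b=len(b), t=t, df=df_, p=p)


def comparison_table(summaries: pd.DataFrame,
                     metrics=COMPARISON_METRICS) -> pd.DataFrame:
    """All standard group contrasts as a tidy table (one row per metric)."""
    rows = []
    for m in metrics:
        if m not in summaries.columns:
            continue
        try:
            c = compare_groups(summaries, m)
        except ValidationError:
            # explicit missing row instead of a silent drop
            groups = list(dict.fromkeys(summaries["group"]))
            nan = float("nan")
            rows.append({"metric": m,
                         "group_a": groups[0] if groups else "",
                         "group_b": groups[1] if len(groups) > 1 else "",
                         "mean_a": nan, "mean_b": nan, "sem_a": nan,
                         "sem_b": nan, "n_a": 0, "n_b": 0,
                         "t": nan, "df": 0, "p": nan})
            continue
        rows.append({
            "metric": c.metric, "group_a": c.group_a, "group_b": c.group_b,
            "mean_a": c.mean_a, "mean_b": c.mean_b,
            "sem_a": c.sem_a, "sem_b": c.sem_b,
            "n_a": c.n_a, "n_b": c.n_b,
            "t": c.t, "df": c.df, "p": c.p,
        })
    return pd.DataFrame(rows)
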