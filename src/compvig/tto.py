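"""Time-to-onset (TTO) analysis: therapy initiation to event onset.

Spontaneous reports carry the event date and the therapy start date, so the
onset interval is a plain calendar-day difference; there is no censoring
(every included report experienced the event), hence descriptive medians,
IQRs and empirical CDFs rather than survival machinery.  Group contrasts
use the Kruskal–Wallis test for three or more groups and the Wilcoxon
rank-sum test for two, with Benjamini–Hochberg adjustment of pairwise
follow-ups.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CaseReport

GROUPINGS = ("outcome_group", "drug_class")


@dataclass(frozen=True)
class TTORecord:
    primaryid: str
    tto_days: int
    outcome_group: str  # fatal / non_fatal
    drug_class: str | None
    pt: str


def compute_tto(
    reports: Sequence[CaseReport],
    event_filter: Callable[[str], bool] | None = None,
) -> tuple[list[TTORecord], dict[str, int]]:
    """One TTORecord per report with both dates and a non-negative interval.

    ``event_filter`` restricts to reports whose reaction set contains a
    qualifying PT (e.g. the CIRVI set); the PT stored is the first
    qualifying one in sorted order.  Returns the records and an exclusion
    tally (missing_dates / negative_interval / no_qualifying_pt).
    """
    records: list[TTORecord] = []
    excluded = {"missing_dates": 0, "negative_interval": 0, "no_qualifying_pt": 0}
    for r in reports:
        if event_filter is not None:
            qualifying = sorted(pt for pt in r.reaction_pts if event_filter(pt))
            if not qualifying:
                excluded["no_qualifying_pt"] += 1
                continue
            pt = qualifying[0]
        else:
            pt = min(r.reaction_pts) if r.reaction_pts else ""
        if r.therapy_start is None or r.event_date is None:
            excluded["missing_dates"] += 1
            continue
        days = (r.event_date - r.therapy_start).days
        if days < 0:
            excluded["negative_interval"] += 1
            continue
        records.append(
            TTORecord(
                primaryid=r.primaryid,
                tto_days=days,
                outcome_group="fatal" if r.fatal else "non_fatal",
                drug_class=r.drug_class,
                pt=pt,
            )
        )
    return records, excluded


def _group_values(records: Sequence[TTORecord], grouping: str) -> dict[str, np.ndarray]:
    if grouping not in GROUPINGS:
        raise ValueError(f"grouping must be one of {GROUPINGS}")
    out: dict[str, list[int]] = {}
    for rec in records:
        key = getattr(rec, grouping)
        if key is None:
            continue
        out.setdefault(str(key), []).append(rec.tto_days)
    return {k: np.asarray(v, dtype=float) for k, v in sorted(out.items())}


def summarize_tto(
    records: Sequence[TTORecord], grouping: str = "outcome_group"
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Per-group n, median and IQR, plus ECDF step-function points.

    Quantiles use linear interpolation between order statistics (the
    common "type 7" rule), pinned so that medians are bit-reproducible.
    """
    groups = _group_values(records, grouping)
    rows = []
    ecdfs: dict[str, pd.DataFrame] = {}
    for name, vals in groups.items():
        q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])  # type-7 default
        rows.append(
            {"group": name, "n": vals.size, "median": med, "q1": q1, "q3": q3}
        )
        xs = np.sort(vals)
        uniq, counts = np.unique(xs, return_counts=True)
        ecdfs[name] = pd.DataFrame(
            {"t": uniq, "F": np.cumsum(counts) / vals.size}
        )
    return pd.DataFrame(rows), ecdfs


def compare_groups(
    records: Sequence[TTORecord], grouping: str = "drug_class"
) -> dict:
    """Kruskal–Wallis (≥3 groups) or Wilcoxon rank-sum (2 groups) on the
    onset times, with BH-adjusted pairwise rank-sum follow-ups.

    Completely tied data (every value identical) degenerate to p = 1 with a
    note rather than an error.
    """
    groups = _group_values(records, grouping)
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    names = list(groups)
    all_vals = np.concatenate(list(groups.values()))
    if np.unique(all_vals).size == 1:
        return {"test": "degenerate", "statistic": 0.0, "p": 1.0,
                "note": "all onset times tied", "pairwise": pd.DataFrame()}

    if len(groups) == 2:
        stat, p = stats.ranksums(groups[names[0]], groups[names[1]])
        test = "wilcoxon-rank-sum"
    else:
        stat, p = stats.kruskal(*groups.values())
        test = "kruskal-wallis"

    pairs = list(combinations(names, 2))
    raw_p = []
    for g1, g2 in pairs:
        if np.unique(np.concatenate([groups[g1], groups[g2]])).size == 1:
            raw_p.append(1.0)
        else:
            raw_p.append(stats.ranksums(groups[g1], groups[g2]).pvalue)
    adj = multipletests(raw_p, method="fdr_bh")[1] if raw_p else []
    pairwise = pd.DataFrame(
        {"group1": [p[0] for p in pairs], "group2": [p[1] for p in pairs],
         "p_raw": raw_p, "p_bh": adj}
    )
    return {"test": test, "statistic": float(stat), "p": float(p), "pairwise": pairwise}
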