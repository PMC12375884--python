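"""The composite criterion elevating a viral PT to a CIRVI adverse event.

A complement-inhibitor-related viral infection adverse event (CIRVI-AE) is
a Preferred Term that passes BOTH clauses of a stratified composite test:

1. a positive ROR signal (lower 95% bound > 1 with ≥3 reports) in the
   overall complement-exposed analysis AND in each inhibitor-subclass
   stratum (C3, C5, Factor B); and
2. at least one of the eight disproportionality methods positive in the
   overall analysis and in at least two of the three subclass analyses.

Clause 2 is read as same-method-throughout by default (the method that is
positive overall must also be the one positive in two subclasses); the
looser any-mix reading is available via ``clause2_mode="mixed"``.  ROR
itself counts as one of the eight methods for clause 2.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .disproportionality import (
    METHODS,
    ContingencyTable,
    MethodResult,
    MgpsHyperparams,
    SignalPanel,
    mgps_fit,
    ror,
    run_panel,
)
from .io import CaseReport

STRATA = ("overall", "C3", "C5", "FactorB")
SUBCLASSES = ("C3", "C5", "FactorB")

#: The four viral PTs the screen is expected to surface.
VIRAL_PTS = frozenset(
    {"Influenza", "Herpes zoster", "Gastroenteritis viral", "Viral infection"}
)


@dataclass
class StratifiedPanelSet:
    """Eight-method panels for one PT in the overall and subclass strata."""

    pt: str
    panels: dict[str, SignalPanel] = field(default_factory=dict)


@dataclass
class CirviEvidence:
    """Audit record: which clauses held and which methods carried clause 2."""

    pt: str
    clause1: bool
    clause2: bool
    ror_flags: dict[str, bool]
    clause2_methods: dict[str, list[str]]  # method -> strata where flagged
    cirvi: bool


def classify_cirvi(
    panel_set: StratifiedPanelSet, *, clause2_mode: str = "same-method"
) -> tuple[bool, CirviEvidence]:
    """Apply the two-part composite criterion to one PT's panel set."""
    missing = [s for s in STRATA if s not in panel_set.panels]
    if missing:
        raise ValueError(f"criterion undefined: missing strata {missing} for {panel_set.pt!r}")
    if clause2_mode not in ("same-method", "mixed"):
        raise ValueError(f"unknown clause2_mode {clause2_mode!r}")

    ror_flags = {s: panel_set.panels[s].flag("ROR") for s in STRATA}
    clause1 = all(ror_flags.values())

    method_strata: dict[str, list[str]] = {}
    for m in METHODS:
        flagged = [s for s in STRATA if panel_set.panels[s].flag(m)]
        if flagged:
            method_strata[m] = flagged

    if clause2_mode == "same-method":
        qualifying = {
            m: strata
            for m, strata in method_strata.items()
            if "overall" in strata and sum(s in SUBCLASSES for s in strata) >= 2
        }
        clause2 = bool(qualifying)
    else:
        overall_any = any("overall" in s for s in method_strata.values())
        sub_hit = sum(
            any(sc in strata for strata in method_strata.values()) for sc in SUBCLASSES
        )
        clause2 = overall_any and sub_hit >= 2
        qualifying = method_strata

    cirvi = clause1 and clause2
    return cirvi, CirviEvidence(
        pt=panel_set.pt,
        clause1=clause1,
        clause2=clause2,
        ror_flags=ror_flags,
        clause2_methods=qualifying,
        cirvi=cirvi,
    )


# ---------------------------------------------------------------------------
# tallying and screening


def _stratum_filter(stratum: str):
    if stratum == "overall":
        return lambda r: r.drug_class is not None
    return lambda r, s=stratum: r.drug_class == s


def tally_tables(
    reports: Sequence[CaseReport],
) -> tuple[dict[str, dict[str, ContingencyTable]], list[str]]:
    """One pass over the reports: per-stratum 2×2 tables for every PT.

    The comparator for each stratum is the rest of the reporting universe
    (other classes plus background), so the overall a-cell equals the sum
    of the three subclass a-cells.
    """
    n = len(reports)
    stratum_margin: Counter = Counter()
    pt_margin: Counter = Counter()
    cell: Counter = Counter()
    for r in reports:
        strata = ["overall", r.drug_class] if r.drug_class else []
        for s in strata:
            stratum_margin[s] += 1
        for pt in r.reaction_pts:
            pt_margin[pt] += 1
            for s in strata:
                cell[(s, pt)] += 1
    pts = sorted(pt_margin)
    tables: dict[str, dict[str, ContingencyTable]] = {s: {} for s in STRATA}
    for s in STRATA:
        m = stratum_margin[s]
        for pt in pts:
            a = cell[(s, pt)]
            tables[s][pt] = ContingencyTable(a, m - a, pt_margin[pt] - a, n - m - pt_margin[pt] + a)
    return tables, pts


def drug_pt_grid(reports: Sequence[CaseReport]) -> list[ContingencyTable]:
    """Unstratified canonical-drug × PT tables for MGPS hyperparameter
    fitting (background drugs included, as in a full reporting database)."""
    n = len(reports)
    drug_margin: Counter = Counter()
    pt_margin: Counter = Counter()
    cell: Counter = Counter()
    for r in reports:
        drug_margin[r.ps_drug] += 1
        for pt in r.reaction_pts:
            pt_margin[pt] += 1
            cell[(r.ps_drug, pt)] += 1
    tables = []
    for (g, pt), a in sorted(cell.items()):
        b = drug_margin[g] - a
        c = pt_margin[pt] - a
        tables.append(ContingencyTable(a, b, c, n - a - b - c))
    return tables


@dataclass
class ScreenResult:
    pt: str
    cirvi: bool
    panel_set: StratifiedPanelSet
    evidence: CirviEvidence


def screen_pt_universe(
    reports: Sequence[CaseReport],
    h: MgpsHyperparams | None = None,
    *,
    seed: int = 0,
    draws: int = 100_000,
    clause2_mode: str = "same-method",
) -> list[ScreenResult]:
    """Screen every PT in the dataset through all eight methods in the
    overall and three subclass strata, and classify CIRVI-AEs.

    Results are sorted by overall ROR descending (NaN last).  Monte Carlo
    sub-seeds are derived deterministically from ``seed`` and the PT's rank
    in the sorted PT list, so results do not depend on report order.
    """
    if h is None:
        h = mgps_fit(drug_pt_grid(reports))
    tables, pts = tally_tables(reports)
    results: list[ScreenResult] = []
    for i, pt in enumerate(pts):
        panels: dict[str, SignalPanel] = {}
        for j, s in enumerate(STRATA):
            sub_seed = int(np.random.SeedSequence([seed, i, j]).generate_state(1)[0])
            panels[s] = run_panel(tables[s][pt], h, draws=draws, seed=sub_seed)
        panel_set = StratifiedPanelSet(pt=pt, panels=panels)
        cirvi, ev = classify_cirvi(panel_set, clause2_mode=clause2_mode)
        results.append(ScreenResult(pt, cirvi, panel_set, ev))

    def _key(r: ScreenResult):
        est = r.panel_set.panels["overall"].results["ROR"].estimate
        return (-(est if est == est else float("-inf")), r.pt)

    results.sort(key=_key)
    return results


def pooled_event_tables(
    reports: Sequence[CaseReport],
    event_pts: frozenset[str] | set[str] = VIRAL_PTS,
    *,
    comparator: str = "rest",
) -> dict[str, ContingencyTable]:
    """Per-stratum 2×2 tables for a pooled event set (any listed PT).

    ``comparator`` picks the c/d cells: ``"rest"`` uses all reports outside
    the stratum (the full-database convention), ``"background"`` restricts
    the comparison to non-complement reports, which is the scale on which
    class-specific signal strengths are planted and compared.
    """
    if comparator not in ("rest", "background"):
        raise ValueError(f"unknown comparator {comparator!r}")
    event_pts = set(event_pts)
    stratum_margin: Counter = Counter()
    stratum_event: Counter = Counter()
    bg_total = bg_event = 0
    n = len(reports)
    event_margin = 0
    for r in reports:
        in_event = bool(r.reaction_pts & event_pts)
        if in_event:
            event_margin += 1
        if r.drug_class is None:
            bg_total += 1
            bg_event += int(in_event)
            continue
        for s in ("overall", r.drug_class):
            stratum_margin[s] += 1
            stratum_event[s] += int(in_event)
    out = {}
    for s in STRATA:
        a, m = stratum_event[s], stratum_margin[s]
        if comparator == "background":
            out[s] = ContingencyTable(a, m - a, bg_event, bg_total - bg_event)
        else:
            out[s] = ContingencyTable(
                a, m - a, event_margin - a, n - m - (event_margin - a)
            )
    return out


def pooled_viral_ror(
    reports: Sequence[CaseReport], event_pts: frozenset[str] | set[str] = VIRAL_PTS
) -> dict[str, MethodResult]:
    """Stratum-level RORs for the combined viral PT set (class forest plot)."""
    return {s: ror(t) for s, t in pooled_event_tables(reports, event_pts).items()}
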