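"""Deduplication and quality screening of assembled FAERS case reports.

FAERS cases are submitted repeatedly (follow-up versions share a CASEID) and
sometimes in near-identical copies by different senders, so spontaneous-
report analyses first collapse each CASEID to its latest version, then drop
content duplicates, remove reports withdrawn via the FDA quarterly deletion
lists, screen out invalid reports, and — for infection-signal specificity —
exclude patients already on systemic anti-infectives in the two weeks before
complement-inhibitor initiation.  Every removal is logged with exactly one
reason so the kept/removed sets partition the input at each stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from pathlib import Path

from .io import CaseReport, _normalize_name

REASONS = (
    "superseded_caseid",
    "content_duplicate",
    "deleted_by_fda",
    "invalid",
    "prior_anti_infective",
)


@dataclass(frozen=True)
class ExclusionLog:
    primaryid: str
    reason: str

    def __post_init__(self) -> None:
        if self.reason not in REASONS:
            raise ValueError(f"unknown exclusion reason {self.reason!r}")


def dedupe_by_case(
    reports: list[CaseReport],
) -> tuple[list[CaseReport], list[ExclusionLog]]:
    """Keep one report per CASEID: latest FDA_DT, then highest PRIMARYID.

    PRIMARYID ties are broken numerically where both parse as integers (the
    FAERS convention), else lexicographically.
    """

    def _pid_key(r: CaseReport):
        try:
            return (1, int(r.primaryid), r.primaryid)
        except ValueError:
            return (0, 0, r.primaryid)

    best: dict[str, CaseReport] = {}
    for r in reports:
        cur = best.get(r.caseid)
        if cur is None:
            best[r.caseid] = r
            continue
        key_new = (r.fda_date or date.min, _pid_key(r))
        key_cur = (cur.fda_date or date.min, _pid_key(cur))
        if key_new > key_cur:
            best[r.caseid] = r
    kept_ids = {r.primaryid for r in best.values()}
    kept = [r for r in reports if r.primaryid in kept_ids]
    removed = [
        ExclusionLog(r.primaryid, "superseded_caseid")
        for r in reports
        if r.primaryid not in kept_ids
    ]
    return kept, removed


def dedup_key(r: CaseReport) -> tuple:
    """The content-duplicate key: sex, age (1 dp), country, event date,
    sorted reactions, PS drug, sorted indications."""
    return (
        r.sex,
        None if r.age_years is None else round(r.age_years, 1),
        r.country,
        r.event_date,
        tuple(sorted(r.reaction_pts)),
        r.ps_drug,
        tuple(sorted(r.indications)),
    )


def dedupe_by_content(
    reports: list[CaseReport],
) -> tuple[list[CaseReport], list[ExclusionLog]]:
    """Drop reports identical on the content key, keeping the highest
    PRIMARYID of each group (mirroring the CASEID tie-break)."""

    def _pid_key(r: CaseReport):
        try:
            return (1, int(r.primaryid), r.primaryid)
        except ValueError:
            return (0, 0, r.primaryid)

    best: dict[tuple, CaseReport] = {}
    for r in reports:
        k = dedup_key(r)
        cur = best.get(k)
        if cur is None or _pid_key(r) > _pid_key(cur):
            best[k] = r
    kept_ids = {r.primaryid for r in best.values()}
    kept = [r for r in reports if r.primaryid in kept_ids]
    removed = [
        ExclusionLog(r.primaryid, "content_duplicate")
        for r in reports
        if r.primaryid not in kept_ids
    ]
    return kept, removed


def apply_deletion_list(
    reports: list[CaseReport], deleted_caseids: set[str]
) -> tuple[list[CaseReport], list[ExclusionLog]]:
    """Remove reports whose CASEID appears on an FDA quarterly deletion list."""
    deleted = {str(c).strip() for c in deleted_caseids}
    kept = [r for r in reports if r.caseid not in deleted]
    removed = [
        ExclusionLog(r.primaryid, "deleted_by_fda")
        for r in reports
        if r.caseid in deleted
    ]
    return kept, removed


def screen_validity(
    reports: list[CaseReport],
) -> tuple[list[CaseReport], list[ExclusionLog]]:
    """Drop invalid reports: no PS drug recorded, or an empty reaction list.

    Background (unmatched-class) reports are valid as long as a PS drug and
    at least one reaction PT are present.
    """
    kept, removed = [], []
    for r in reports:
        if r.ps_drug and r.reaction_pts:
            kept.append(r)
        else:
            removed.append(ExclusionLog(r.primaryid, "invalid"))
    return kept, removed


def load_name_list(path: str | Path) -> set[str]:
    """One name per line, '#' comments allowed; normalised for matching."""
    names: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                names.add(_normalize_name(line))
    return names


def load_deletion_list(path: str | Path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip() and not line.startswith("#")}


def exclude_prior_anti_infective(
    reports: list[CaseReport],
    anti_infective_names: set[str],
    window_days: int = 14,
) -> tuple[list[CaseReport], list[ExclusionLog]]:
    """Exclude reports with a systemic anti-infective started within the
    window before complement-inhibitor initiation.

    The window is [therapy_start − window_days, therapy_start): day −14 is
    inside, the start day itself is not ("within 14 days *prior*").  Reports
    missing either date are retained — exclusion requires positive evidence.
    """
    names = {_normalize_name(n) for n in anti_infective_names}
    kept, removed = [], []
    for r in reports:
        hit = False
        if r.therapy_start is not None:
            for name, start, _role in r.concomitant_drugs:
                if start is None or _normalize_name(name) not in names:
                    continue
                delta = (r.therapy_start - start).days
                if 0 < delta <= window_days:
                    hit = True
                    break
        if hit:
            removed.append(ExclusionLog(r.primaryid, "prior_anti_infective"))
        else:
            kept.append(r)
    return kept, removed


def process_cases(
    reports: list[CaseReport],
    *,
    deleted_caseids: set[str] | None = None,
    anti_infective_names: set[str] | None = None,
    window_days: int = 14,
) -> tuple[list[CaseReport], list[ExclusionLog]]:
    """The full screening chain in the protocol's order.

    CASEID dedup → content dedup → deletion list → validity →
    prior-anti-infective window.  Idempotent, and |kept| + |removed| equals
    the input size with reasons partitioning the removed set.
    """
    log: list[ExclusionLog] = []
    kept, rm = dedupe_by_case(reports)
    log += rm
    kept, rm = dedupe_by_content(kept)
    log += rm
    kept, rm = apply_deletion_list(kept, deleted_caseids or set())
    log += rm
    kept, rm = screen_validity(kept)
    log += rm
    kept, rm = exclude_prior_anti_infective(
        kept, anti_infective_names or set(), window_days
    )
    log += rm
    return kept, log
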