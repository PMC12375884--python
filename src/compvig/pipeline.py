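"""End-to-end orchestration: ingest → process → screen → TTO → risk models.

One YAML config drives a full run; every stage writes tidy TSV outputs plus
a plain-text manifest recording input hashes, the config echo, and row
counts in and out of each stage, which makes a run auditable and exactly
reproducible given the same inputs and seed.
"""

from __future__ import annotations

import hashlib
import logging
from importlib import resources
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .criteria import VIRAL_PTS, pooled_viral_ror, screen_pt_universe
from .io import (
    DrugClassMap,
    MeddraMap,
    assemble_cases,
    read_faers_table,
    CaseReport,
    TABLE_NAMES,
)
from .processing import load_deletion_list, load_name_list, process_cases
from .risk import build_analysis_frame, fit_rcs_logit, stratified_or, univariate_logit
from .synthetic import SyntheticConfig, cohort_to_cases, generate, simulate_cohort
from .tto import compare_groups, compute_tto, summarize_tto

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (paths, seed, stage toggles)."""

    outdir: Path
    input_dir: Path | None = None
    simulate: SyntheticConfig | None = None
    drug_map_path: Path | None = None
    meddra_path: Path | None = None
    deletion_list_path: Path | None = None
    anti_infective_path: Path | None = None
    seed: int = 0
    mc_draws: int = 100_000
    stages: tuple[str, ...] = ("signals", "tto", "risk")

    def __post_init__(self) -> None:
        if (self.input_dir is None) == (self.simulate is None):
            raise ValueError("exactly one of input_dir or simulate must be set")
        for p in (self.input_dir, self.drug_map_path, self.meddra_path,
                  self.deletion_list_path, self.anti_infective_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("simulate", None)
        cfg = cls(
            outdir=Path(raw["outdir"]),
            input_dir=Path(raw["input_dir"]) if raw.get("input_dir") else None,
            simulate=SyntheticConfig(**sim) if sim is not None else None,
            drug_map_path=Path(raw["drug_map"]) if raw.get("drug_map") else None,
            meddra_path=Path(raw["meddra"]) if raw.get("meddra") else None,
            deletion_list_path=Path(raw["deletion_list"]) if raw.get("deletion_list") else None,
            anti_infective_path=Path(raw["anti_infectives"]) if raw.get("anti_infectives") else None,
            seed=int(raw.get("seed", 0)),
            mc_draws=int(raw.get("mc_draws", 100_000)),
            stages=tuple(raw.get("stages", ("signals", "tto", "risk"))),
        )
        return cfg


def descriptive_summary(
    reports: list[CaseReport], meddra: "MeddraMap | None" = None
) -> dict[str, pd.DataFrame]:
    """Demographics, reporter, region, outcome shares and yearly counts.

    Shares are reported against both denominators (all reports, and reports
    with the field known); outcome shares partition all reports into fatal
    (contains DE), non-fatal (other outcome codes) and missing.  With a
    MedDRA map, the share of reports carrying at least one PT whose primary
    SOC is "Infections and infestations" is added.
    """
    n = len(reports)
    if n == 0:
        raise ValueError("no reports to summarise")

    def share_table(values: list[str]) -> pd.DataFrame:
        counts = pd.Series(values).value_counts(dropna=False)
        known = sum(c for v, c in counts.items() if v not in ("unknown", "", None))
        rows = []
        for v, c in counts.items():
            is_known = v not in ("unknown", "", None)
            rows.append(
                {"category": v, "count": int(c), "share_of_all": c / n,
                 "share_of_known": c / known if is_known and known else float("nan")}
            )
        return pd.DataFrame(rows)

    fatal = sum(1 for r in reports if "DE" in r.outcomes)
    nonfatal = sum(1 for r in reports if r.outcomes and "DE" not in r.outcomes)
    missing = n - fatal - nonfatal
    outcome = pd.DataFrame(
        [
            {"category": "fatal", "count": fatal, "share_of_all": fatal / n},
            {"category": "non_fatal", "count": nonfatal, "share_of_all": nonfatal / n},
            {"category": "missing", "count": missing, "share_of_all": missing / n},
        ]
    )
    years = [r.fda_date.year for r in reports if r.fda_date is not None]
    yearly = pd.Series(years).value_counts().sort_index().rename_axis("year").reset_index(name="count")

    ages = [r.age_years for r in reports if r.age_years is not None]
    weights = [r.weight_kg for r in reports if r.weight_kg is not None]
    cont = pd.DataFrame(
        [
            {"variable": "age_years", "n_known": len(ages),
             "median": float(pd.Series(ages).median()) if ages else float("nan")},
            {"variable": "weight_kg", "n_known": len(weights),
             "median": float(pd.Series(weights).median()) if weights else float("nan")},
        ]
    )
    out = {
        "sex": share_table([r.sex for r in reports]),
        "reporter": share_table([r.reporter for r in reports]),
        "country": share_table([r.country or "" for r in reports]),
        "drug_class": share_table([r.drug_class or "background" for r in reports]),
        "outcome": outcome,
        "yearly_counts": yearly,
        "continuous": cont,
    }
    if meddra is not None:
        infection_pts = meddra.pts_in_soc("Infections and infestations")
        n_inf = sum(1 for r in reports if r.reaction_pts & infection_pts)
        out["infection"] = pd.DataFrame(
            [{"category": "infection_related", "count": n_inf,
              "share_of_all": n_inf / n},
             {"category": "other", "count": n - n_inf,
              "share_of_all": (n - n_inf) / n}]
        )
    return out


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all enabled stages in fixed order and write outputs.

    Returns a manifest dict (also written to ``manifest.txt``) with input
    hashes, stage row counts and the config echo.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}}

    drug_map = (
        DrugClassMap.from_tsv(config.drug_map_path)
        if config.drug_map_path
        else DrugClassMap.default()
    )
    meddra = (
        MeddraMap.from_tsv(config.meddra_path) if config.meddra_path else MeddraMap.default()
    )

    stage = "ingest"
    try:
        if config.simulate is not None:
            truth = generate(config.simulate, out / "simulated")
            manifest["simulated"] = truth.params
            tables = {
                name: read_faers_table(out / "simulated" / f"{name}.txt", name)
                for name in TABLE_NAMES
                if (out / "simulated" / f"{name}.txt").exists()
            }
        else:
            tables = {}
            for name in TABLE_NAMES:
                for candidate in (f"{name}.txt", f"{name}.TXT"):
                    p = Path(config.input_dir) / candidate
                    if p.exists():
                        tables[name] = read_faers_table(p, name)
                        manifest.setdefault("input_hashes", {})[candidate] = _hash_file(p)
                        break
        cases = assemble_cases(tables, drug_map, meddra, keep_unmatched=True)
        manifest["stages"]["ingest"] = {"reports": len(cases)}

        stage = "process"
        deleted = (
            load_deletion_list(config.deletion_list_path)
            if config.deletion_list_path
            else set()
        )
        anti = (
            load_name_list(config.anti_infective_path)
            if config.anti_infective_path
            else load_name_list(
                resources.files("compvig.data") / "anti_infectives.tsv"
            )
        )
        kept, excluded = process_cases(
            cases, deleted_caseids=deleted, anti_infective_names=anti
        )
        pd.DataFrame([{"primaryid": e.primaryid, "reason": e.reason} for e in excluded]).to_csv(
            out / "exclusions.tsv", sep="\t", index=False
        )
        manifest["stages"]["process"] = {
            "kept": len(kept),
            "removed": len(excluded),
        }

        stage = "describe"
        complement = [r for r in kept if r.drug_class is not None]
        summary = descriptive_summary(complement, meddra)
        for name, df in summary.items():
            df.to_csv(out / f"describe_{name}.tsv", sep="\t", index=False)
        manifest["stages"]["describe"] = {"complement_reports": len(complement)}

        cirvi_pts: set[str] = set(VIRAL_PTS)
        if "signals" in config.stages:
            stage = "signals"
            results = screen_pt_universe(kept, seed=config.seed, draws=config.mc_draws)
            rows = []
            for res in results:
                for stratum, panel in res.panel_set.panels.items():
                    t = panel.table
                    for method, mr in panel.results.items():
                        rows.append(
                            {"pt": res.pt, "stratum": stratum, "method": method,
                             "estimate": mr.estimate, "ci_low": mr.ci_low,
                             "ci_high": mr.ci_high, "p": mr.p_value,
                             "a": t.a, "b": t.b, "c": t.c, "d": t.d,
                             "flag": mr.flag, "cirvi": res.cirvi}
                        )
            pd.DataFrame(rows).to_csv(out / "signal_panels.tsv", sep="\t", index=False)
            cirvi_pts = {res.pt for res in results if res.cirvi}
            evidence = [
                {"pt": r.pt, "cirvi": r.cirvi, "clause1": r.evidence.clause1,
                 "clause2": r.evidence.clause2,
                 "clause2_methods": dict(r.evidence.clause2_methods)}
                for r in results
            ]
            with open(out / "cirvi_evidence.yaml", "w") as fh:
                yaml.safe_dump(evidence, fh, sort_keys=False)
            pooled = pooled_viral_ror(kept, cirvi_pts or set(VIRAL_PTS))
            pd.DataFrame(
                [{"stratum": s, "ror": m.estimate, "ci_low": m.ci_low,
                  "ci_high": m.ci_high} for s, m in pooled.items()]
            ).to_csv(out / "pooled_viral_ror.tsv", sep="\t", index=False)
            manifest["stages"]["signals"] = {
                "pts_screened": len(results),
                "cirvi_pts": sorted(cirvi_pts),
            }

        if "tto" in config.stages:
            stage = "tto"
            records, excl = compute_tto(
                complement, event_filter=lambda pt: pt in cirvi_pts
            )
            by_outcome, ecdfs = summarize_tto(records, "outcome_group")
            by_outcome.to_csv(out / "tto_by_outcome.tsv", sep="\t", index=False)
            by_class, _ = summarize_tto(records, "drug_class")
            by_class.to_csv(out / "tto_by_class.tsv", sep="\t", index=False)
            ecdf_rows = []
            for g, df in ecdfs.items():
                df = df.assign(group=g)
                ecdf_rows.append(df)
            pd.concat(ecdf_rows).to_csv(out / "tto_ecdf.tsv", sep="\t", index=False)
            manifest["stages"]["tto"] = {"records": len(records), "excluded": excl}
            if len({r.drug_class for r in records}) >= 2:
                comp = compare_groups(records, "drug_class")
                manifest["stages"]["tto"]["class_comparison_p"] = comp["p"]

        if "risk" in config.stages:
            stage = "risk"
            frame = build_analysis_frame(complement, cirvi_pts or set(VIRAL_PTS))
            or_rows = []
            for predictor, ref in (
                ("drug_class", "C3"), ("sex", "F"), ("age_bin", "<18"),
                ("weight_bin", "<45"), ("quarter", "Q1"), ("cirvi", "0"),
            ):
                try:
                    fit = univariate_logit(frame, "fatal", predictor, ref)
                    or_rows.append(fit.or_table)
                except Exception as exc:  # noqa: BLE001 - report, don't die
                    logger.warning("univariate fit on %s skipped: %s", predictor, exc)
            if or_rows:
                pd.concat(or_rows).to_csv(out / "fatality_or.tsv", sep="\t", index=False)
            try:
                rcs = fit_rcs_logit(frame, "fatal", "age_years", ("drug_class", "sex"))
                with open(out / "rcs_age.txt", "w") as fh:
                    fh.write(rcs.summary() + "\n")
            except Exception as exc:  # noqa: BLE001
                logger.warning("RCS age fit skipped: %s", exc)
            strat = stratified_or(frame.assign(sexF=(frame["sex"] == "F").astype(int)),
                                  "fatal", "cirvi", "drug_class")
            strat.to_csv(out / "stratified_or.tsv", sep="\t", index=False)
            manifest["stages"]["risk"] = {"frame_rows": len(frame)}
    except Exception as exc:
        manifest["failed_stage"] = stage
        with open(out / "manifest.txt", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "manifest.txt", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest
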