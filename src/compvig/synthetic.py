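"""Synthetic FAERS-format report generator with planted, recoverable truth.

The generator emulates the structure of the complement-inhibitor reporting
universe: a large background of non-complement reports (so the c/d cells of
disproportionality tables are internal to the dataset), three exposed
classes (C3, C5, Factor B) with C5 carrying most reports, a small catalogue
of MedDRA-style PTs with four viral PTs, FAERS outcome codes, therapy-start
and event dates, demographics with realistic missingness, and injected
duplicate and prior-anti-infective reports that the processing chain must
remove.

Every effect is planted with known size and recorded in a ground-truth
ledger:

* viral-signal odds multipliers — the odds of the combined viral PT set for
  an exposed class versus background; defaults 2.62 (all classes pooled)
  and 3.52 (C3).  A common per-PT odds multiplier is solved per class so
  the pooled class-vs-background reporting odds ratio equals the planted
  value in expectation.
* a fatality logit with class, sex, quarter and CIRVI effects (defaults
  OR 3.55 C5-vs-C3, 0.77 female, 0.88 third quarter, 0.22 CIRVI), a
  U-shaped age term and an L-shaped (decreasing, convex) weight term;
* lognormal onset-time laws with medians 12 days (fatal) and 187 days
  (non-fatal).

All randomness flows from one seed through named sub-streams (demographics,
PT assignment, outcomes, onset times, missingness, injections), so adding a
field to one stream does not silently shift the others, and the same config
plus seed reproduces the output byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit

from .io import RawRecordSet, CaseReport, parse_faers_date

VIRAL_PTS = ("Influenza", "Herpes zoster", "Gastroenteritis viral", "Viral infection")

#: Baseline (background-report) per-report probabilities of each PT.
DEFAULT_PT_CATALOG: dict[str, float] = {
    "Influenza": 0.030,
    "Herpes zoster": 0.015,
    "Gastroenteritis viral": 0.008,
    "Viral infection": 0.012,
    "Pneumonia": 0.020,
    "Urinary tract infection": 0.015,
    "Sepsis": 0.010,
    "Meningococcal sepsis": 0.002,
    "Nasopharyngitis": 0.010,
    "Cellulitis": 0.008,
    "COVID-19": 0.010,
    "Pyrexia": 0.050,
    "Fatigue": 0.060,
    "Asthenia": 0.030,
    "Chills": 0.020,
    "Drug ineffective": 0.050,
    "Haemolysis": 0.015,
    "Anaemia": 0.030,
    "Haemoglobin decreased": 0.020,
    "Headache": 0.050,
    "Dizziness": 0.030,
    "Nausea": 0.050,
    "Vomiting": 0.030,
    "Diarrhoea": 0.040,
    "Abdominal pain": 0.030,
}

#: Canonical drug per class with within-class shares (C5 dominated by the
#: two long-approved agents).
CLASS_DRUGS = {
    "C3": (("pegcetacoplan", 1.0),),
    "C5": (("eculizumab", 0.60), ("ravulizumab", 0.35),
           ("crovalimab", 0.04), ("pozelimab", 0.01)),
    "FactorB": (("iptacopan", 1.0),),
}

N_BACKGROUND_DRUGS = 30


@dataclass(frozen=True)
class TtoLaw:
    """Lognormal onset law parameterised by its median (days) and sigma."""

    median_days: float
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.median_days <= 0 or self.sigma <= 0:
            raise ValueError("onset law needs positive median and sigma")


@dataclass(frozen=True)
class FatalityModel:
    """Log-odds model of a fatal outcome for exposed reports.

    The age term is quadratic (U-shape, minimum at ``age_vertex``); the
    weight term is a decreasing exponential (L-shape).  Class/sex/quarter/
    CIRVI coefficients default to the ln of the planted odds ratios.
    """

    intercept: float = -3.7
    c5_vs_c3: float = math.log(3.55)
    factor_b_vs_c3: float = 0.0
    female: float = math.log(0.77)
    cirvi: float = math.log(0.22)
    q2: float = 0.0
    q3: float = math.log(0.88)
    q4: float = 0.0
    age_curvature: float = 5e-4  # per year^2
    age_vertex: float = 30.0  # years
    weight_amplitude: float = 1.2
    weight_offset: float = 40.0  # kg
    weight_decay: float = 25.0  # kg

    def linear_predictor(
        self,
        drug_class: np.ndarray,
        female: np.ndarray,
        cirvi: np.ndarray,
        quarter: np.ndarray,
        age: np.ndarray,
        weight: np.ndarray,
    ) -> np.ndarray:
        lp = np.full(drug_class.shape, self.intercept, dtype=float)
        lp += np.where(drug_class == "C5", self.c5_vs_c3, 0.0)
        lp += np.where(drug_class == "FactorB", self.factor_b_vs_c3, 0.0)
        lp += np.where(female, self.female, 0.0)
        lp += np.where(cirvi, self.cirvi, 0.0)
        lp += np.where(quarter == 2, self.q2, 0.0)
        lp += np.where(quarter == 3, self.q3, 0.0)
        lp += np.where(quarter == 4, self.q4, 0.0)
        lp += self.age_curvature * (age - self.age_vertex) ** 2
        lp += self.weight_amplitude * np.exp(
            -(weight - self.weight_offset) / self.weight_decay
        )
        return lp


@dataclass
class SyntheticConfig:
    """All planted quantities of one synthetic cohort."""

    n_reports: int = 60_000
    seed: int = 0
    # reporting-universe composition (background carries the c/d cells)
    drug_class_shares: dict[str, float] = field(
        default_factory=lambda: {"background": 0.80, "C3": 0.03, "C5": 0.16, "FactorB": 0.01}
    )
    pt_catalog: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PT_CATALOG))
    viral_pts: tuple[str, ...] = VIRAL_PTS
    planted_viral_multiplier_overall: float = 2.62
    planted_viral_multiplier_c3: float = 3.52
    fatality_model: FatalityModel = field(default_factory=FatalityModel)
    background_fatal_rate: float = 0.0634
    tto_laws: dict[str, TtoLaw] = field(
        default_factory=lambda: {"fatal": TtoLaw(12.0), "non_fatal": TtoLaw(187.0)}
    )
    # demographics (medians ≈ 42 y and 64.2 kg; 45.25% female)
    age_mean: float = 43.0
    age_sd: float = 18.0
    weight_mean: float = 64.2
    weight_sd: float = 15.0
    female_share: float = 0.4525
    reporter_shares: dict[str, float] = field(
        default_factory=lambda: {"CN": 0.7047, "MD": 0.1508, "PH": 0.03,
                                 "OT": 0.08, "LW": 0.005, "": 0.0295}
    )
    us_share: float = 0.8558
    missingness: dict[str, float] = field(
        default_factory=lambda: {"age": 0.12, "weight": 0.30, "sex": 0.02,
                                 "event_date": 0.15, "therapy_start": 0.15}
    )
    outcome_missing_rate: float = 0.10  # non-fatal reports with no OUTC row
    duplicate_injection_rate: float = 0.02
    anti_infective_injection_rate: float = 0.01
    start_date: date = date(2007, 1, 1)
    end_date: date = date(2024, 6, 30)

    def __post_init__(self) -> None:
        shares = self.drug_class_shares
        if abs(sum(shares.values()) - 1.0) > 1e-9 or min(shares.values()) < 0:
            raise ValueError("drug_class_shares must be a probability vector")
        for pt, p in self.pt_catalog.items():
            if not 0.0 <= p < 1.0:
                raise ValueError(f"baseline probability of {pt!r} outside [0, 1)")
        for pt in self.viral_pts:
            if pt not in self.pt_catalog:
                raise ValueError(f"viral PT {pt!r} missing from the catalogue")
        if min(self.planted_viral_multiplier_overall, self.planted_viral_multiplier_c3) <= 0:
            raise ValueError("planted multipliers must be positive")
        for rate in (self.duplicate_injection_rate, self.anti_infective_injection_rate):
            if not 0.0 <= rate < 1.0:
                raise ValueError("injection rates must be in [0, 1)")


# ---------------------------------------------------------------------------
# planted-signal algebra


def sample_onset_days(law: TtoLaw, n: int, seed: int | np.random.Generator) -> np.ndarray:
    """Draw n onset intervals (whole days, nearest-day rounding) from a law."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return np.rint(rng.lognormal(math.log(law.median_days), law.sigma, n)).astype(int)


def plant_viral_signal(base_probability: float, multiplier: float) -> float:
    """Per-report event probability whose odds are ``multiplier`` times the
    background odds."""
    if not 0.0 <= base_probability < 1.0:
        raise ValueError("base probability must be in [0, 1)")
    if multiplier <= 0:
        raise ValueError("odds multiplier must be positive")
    odds = multiplier * base_probability / (1.0 - base_probability)
    p = odds / (1.0 + odds)
    if p >= 1.0:
        raise ValueError("planted probability overflows 1")
    return p


def _pooled_event_probability(base_probs: np.ndarray, per_pt_multiplier: float) -> float:
    """P(any viral PT) when each PT's odds are multiplied by a common m
    (PTs drawn independently)."""
    q = np.array([plant_viral_signal(p, per_pt_multiplier) for p in base_probs])
    return 1.0 - float(np.prod(1.0 - q))


def solve_per_pt_multiplier(base_probs: np.ndarray, target_pooled_or: float) -> float:
    """The common per-PT odds multiplier giving the target pooled
    class-vs-background odds ratio for the combined viral event set."""
    p0 = _pooled_event_probability(base_probs, 1.0)
    odds0 = p0 / (1.0 - p0)

    def gap(m: float) -> float:
        p = _pooled_event_probability(base_probs, m)
        return p / (1.0 - p) / odds0 - target_pooled_or

    return float(brentq(gap, 1e-3, 1e3, xtol=1e-12, rtol=1e-14))


def solved_class_multipliers(config: SyntheticConfig) -> dict[str, float]:
    """Per-PT odds multipliers per exposed class.

    C3 is solved to the planted C3 pooled value; the common C5/FactorB
    multiplier is solved so the pooled exposed-vs-background odds ratio
    equals the planted overall value given the class mix.
    """
    base = np.array([config.pt_catalog[pt] for pt in config.viral_pts])
    m_c3 = solve_per_pt_multiplier(base, config.planted_viral_multiplier_c3)

    shares = config.drug_class_shares
    exposed = shares["C3"] + shares["C5"] + shares["FactorB"]
    w_c3 = shares["C3"] / exposed
    p_c3 = _pooled_event_probability(base, m_c3)
    p0 = _pooled_event_probability(base, 1.0)
    odds0 = p0 / (1.0 - p0)

    def gap(m: float) -> float:
        p_other = _pooled_event_probability(base, m)
        p_mix = w_c3 * p_c3 + (1.0 - w_c3) * p_other
        return p_mix / (1.0 - p_mix) / odds0 - config.planted_viral_multiplier_overall

    m_other = float(brentq(gap, 1e-3, 1e3, xtol=1e-12, rtol=1e-14))
    return {"C3": m_c3, "C5": m_other, "FactorB": m_other}


_CALIBRATION_CACHE: dict[tuple, FatalityModel] = {}


def _calibration_key(config: SyntheticConfig, n_calib: int) -> tuple:
    return (
        tuple(sorted(config.drug_class_shares.items())),
        config.female_share, config.age_mean, config.age_sd,
        config.weight_mean, config.weight_sd,
        config.planted_viral_multiplier_overall, config.planted_viral_multiplier_c3,
        tuple(config.viral_pts),
        tuple(config.pt_catalog[pt] for pt in config.viral_pts),
        tuple(sorted(asdict(config.fatality_model).items())),
        n_calib,
    )


def calibrated_fatality_model(
    config: SyntheticConfig, n_calib: int = 400_000
) -> FatalityModel:
    """Solve the class, sex and CIRVI log-odds coefficients so that the
    large-sample *marginal* (univariate) odds ratios equal the planted
    values.

    A logistic coefficient is non-collapsible: with heterogeneous risk from
    the other covariates, the marginal OR a univariate regression estimates
    is attenuated relative to the conditional coefficient.  The planted
    headline ORs are population summaries of that univariate kind, so the
    conditional coefficients are calibrated by coordinate-wise root finding
    on a fixed quasi-independent covariate sample (internal seed, separate
    from the cohort streams).  The calibration is part of the generator's
    definition and is recorded in the ground-truth ledger.
    """
    import dataclasses

    key = _calibration_key(config, n_calib)
    if key in _CALIBRATION_CACHE:
        return _CALIBRATION_CACHE[key]

    base = config.fatality_model
    rng = np.random.default_rng(np.random.SeedSequence([987654321]))
    shares = config.drug_class_shares
    exposed_total = shares["C3"] + shares["C5"] + shares["FactorB"]
    probs = [shares[c] / exposed_total for c in ("C3", "C5", "FactorB")]
    cls = rng.choice(np.array(["C3", "C5", "FactorB"]), size=n_calib, p=probs)
    female = rng.random(n_calib) < config.female_share
    quarter = rng.integers(1, 5, size=n_calib)
    age = np.clip(rng.normal(config.age_mean, config.age_sd, n_calib), 1.0, 95.0)
    weight = np.clip(
        rng.normal(config.weight_mean, config.weight_sd, n_calib), 35.0, 160.0
    )
    mult = solved_class_multipliers(config)
    viral_base = np.array([config.pt_catalog[pt] for pt in config.viral_pts])
    p_cirvi = {c: _pooled_event_probability(viral_base, m) for c, m in mult.items()}
    cirvi = rng.random(n_calib) < np.vectorize(p_cirvi.get)(cls)

    targets = {
        "c5_vs_c3": base.c5_vs_c3,
        "female": base.female,
        "cirvi": base.cirvi,
    }
    indicators = {
        "c5_vs_c3": (cls == "C5", cls == "C3"),
        "female": (female, ~female),
        "cirvi": (cirvi, ~cirvi),
    }
    model = base

    def marginal_log_or(m: FatalityModel, name: str) -> float:
        lp = m.linear_predictor(cls, female, cirvi, quarter, age, weight)
        p = expit(lp)
        on, off = indicators[name]
        p1, p0 = p[on].mean(), p[off].mean()
        return math.log(p1 / (1 - p1)) - math.log(p0 / (1 - p0))

    for _ in range(4):
        for name, target in targets.items():
            def gap(coef: float, name=name, target=target) -> float:
                trial = dataclasses.replace(model, **{name: coef})
                return marginal_log_or(trial, name) - target

            coef = float(brentq(gap, target - 2.0, target + 2.0, xtol=1e-10))
            model = dataclasses.replace(model, **{name: coef})
    _CALIBRATION_CACHE[key] = model
    return model


# ---------------------------------------------------------------------------
# cohort simulation


def _content_key(row) -> tuple:
    """The content-duplicate key of a cohort row on its emitted fields,
    mirroring the processing chain's key definition."""
    sex = row.sex if row.sex in ("F", "M") else "unknown"
    age = None if pd.isna(row.age) else round(float(row.age), 1)
    indication = (
        "Paroxysmal nocturnal haemoglobinuria" if row.drug_class else "Hypertension"
    )
    return (
        sex, age, row.country, row.event_date,
        tuple(sorted(row.reaction_pts)), str(row.ps_drug).casefold(), (indication,),
    )


@dataclass
class GroundTruth:
    """Everything planted, recomputable without rerunning the generator."""

    params: dict
    cohort: pd.DataFrame

    @property
    def expected_removed_primaryids(self) -> set[str]:
        """PRIMARYIDs the processing chain must remove: injected duplicates,
        accidental content-key collisions among the remaining reports (kept
        row = highest PRIMARYID, as in the protocol), and the
        anti-infective-pretreated originals."""
        c = self.cohort
        case_dups = set(c.loc[c["row_kind"] == "case_dup", "primaryid"])
        survivors = c[~c["primaryid"].isin(case_dups)]
        removed: set[str] = set(case_dups)
        groups: dict[tuple, list[str]] = {}
        for row in survivors.itertuples(index=False):
            groups.setdefault(_content_key(row), []).append(row.primaryid)
        for pids in groups.values():
            if len(pids) > 1:
                removed.update(sorted(pids, key=int)[:-1])
        removed |= set(c.loc[c["anti_infective_planted"], "primaryid"])
        return removed


def _dates_from_days(base: date, offsets: np.ndarray) -> list[date | None]:
    return [base + timedelta(days=int(o)) if o >= 0 else None for o in offsets]


def simulate_cohort(config: SyntheticConfig) -> GroundTruth:
    """Draw the latent cohort: one row per report (originals first, then
    injected duplicates), with both latent truth and emitted fields."""
    n = config.n_reports
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(6)
    rng_demo = np.random.default_rng(streams[0])
    rng_pt = np.random.default_rng(streams[1])
    rng_out = np.random.default_rng(streams[2])
    rng_tto = np.random.default_rng(streams[3])
    rng_miss = np.random.default_rng(streams[4])
    rng_inject = np.random.default_rng(streams[5])

    # --- composition and demographics (stream: demographics)
    classes = np.array(list(config.drug_class_shares))
    cls = rng_demo.choice(classes, size=n, p=list(config.drug_class_shares.values()))
    ps_drug = np.empty(n, dtype=object)
    for c, drugs in CLASS_DRUGS.items():
        idx = np.flatnonzero(cls == c)
        names = [d for d, _ in drugs]
        ps_drug[idx] = rng_demo.choice(names, size=idx.size, p=[s for _, s in drugs])
    bg_idx = np.flatnonzero(cls == "background")
    bg_names = [f"BACKGROUND DRUG {i:02d}" for i in range(1, N_BACKGROUND_DRUGS + 1)]
    ps_drug[bg_idx] = rng_demo.choice(bg_names, size=bg_idx.size)

    age = np.clip(rng_demo.normal(config.age_mean, config.age_sd, n), 1.0, 95.0)
    weight = np.clip(rng_demo.normal(config.weight_mean, config.weight_sd, n), 35.0, 160.0)
    female = rng_demo.random(n) < config.female_share
    occp = rng_demo.choice(
        list(config.reporter_shares), size=n, p=list(config.reporter_shares.values())
    )
    country = np.where(rng_demo.random(n) < config.us_share, "US", "JP")

    span = (config.end_date - config.start_date).days
    start_offset = rng_demo.integers(0, span + 1, size=n)
    therapy_start = np.array(_dates_from_days(config.start_date, start_offset), dtype=object)
    quarter = np.array([(d.month - 1) // 3 + 1 for d in therapy_start])

    # --- PT assignment with planted viral multipliers (stream: PTs)
    multipliers = solved_class_multipliers(config)
    pts_sorted = sorted(config.pt_catalog)
    pt_matrix = np.zeros((n, len(pts_sorted)), dtype=bool)
    for j, pt in enumerate(pts_sorted):
        p = np.full(n, config.pt_catalog[pt])
        if pt in config.viral_pts:
            for c, m in multipliers.items():
                p[cls == c] = plant_viral_signal(config.pt_catalog[pt], m)
        pt_matrix[:, j] = rng_pt.random(n) < p
    none_drawn = ~pt_matrix.any(axis=1)
    # every report must carry at least one reaction PT; the fallback is
    # drawn from the non-viral PTs only so the planted viral margins are
    # untouched (identically in exposed and background reports)
    non_viral = np.array(
        [j for j, pt in enumerate(pts_sorted) if pt not in config.viral_pts]
    )
    fallback = rng_pt.choice(non_viral, size=n)
    pt_matrix[none_drawn, fallback[none_drawn]] = True
    viral_cols = [pts_sorted.index(pt) for pt in config.viral_pts]
    cirvi = pt_matrix[:, viral_cols].any(axis=1)
    reaction_sets = [
        tuple(pts_sorted[j] for j in np.flatnonzero(row)) for row in pt_matrix
    ]

    # --- outcomes (stream: outcomes)
    exposed = cls != "background"
    fatality = calibrated_fatality_model(config)
    lp = fatality.linear_predictor(cls, female, cirvi, quarter, age, weight)
    p_fatal = np.where(exposed, expit(lp), config.background_fatal_rate)
    fatal = rng_out.random(n) < p_fatal
    nonfatal_codes = rng_out.choice(
        ["HO", "LT", "DS", "RI", "OT"], size=n, p=[0.25, 0.05, 0.05, 0.02, 0.63]
    )
    outcome_missing = rng_out.random(n) < config.outcome_missing_rate
    outcomes = [
        ("DE",) if fatal[i] else (() if outcome_missing[i] else (nonfatal_codes[i],))
        for i in range(n)
    ]

    # --- onset times (stream: onset)
    laws = config.tto_laws
    mu = np.where(fatal, math.log(laws["fatal"].median_days), math.log(laws["non_fatal"].median_days))
    sigma = np.where(fatal, laws["fatal"].sigma, laws["non_fatal"].sigma)
    # nearest whole day keeps the median of the discretised law at the
    # planted lognormal median
    tto_days = np.rint(np.exp(rng_tto.normal(mu, sigma))).astype(int)
    event_date = np.array(
        [therapy_start[i] + timedelta(days=int(tto_days[i])) for i in range(n)], dtype=object
    )
    fda_lag = rng_tto.integers(5, 91, size=n)
    fda_date = np.array(
        [event_date[i] + timedelta(days=int(fda_lag[i])) for i in range(n)], dtype=object
    )

    # --- missingness masks (stream: missingness)
    m = config.missingness
    age_emit = np.where(rng_miss.random(n) < m["age"], np.nan, np.round(age, 1))
    weight_emit = np.where(rng_miss.random(n) < m["weight"], np.nan, np.round(weight, 1))
    sex_emit = np.where(
        rng_miss.random(n) < m["sex"], "", np.where(female, "F", "M")
    ).astype(object)
    event_emit = np.where(rng_miss.random(n) < m["event_date"], None, event_date)
    ther_emit = np.where(rng_miss.random(n) < m["therapy_start"], None, therapy_start)

    # --- injections (stream: injections)
    anti = np.zeros(n, dtype=bool)
    has_ther = np.array([d is not None for d in ther_emit])
    cand = np.flatnonzero(has_ther & exposed)
    n_anti = int(round(config.anti_infective_injection_rate * n))
    anti_idx = rng_inject.choice(cand, size=min(n_anti, cand.size), replace=False)
    anti[anti_idx] = True
    anti_lag = rng_inject.integers(1, 15, size=n)  # within (0, 14] days prior
    conco = [
        (("AMOXICILLIN", ther_emit[i] - timedelta(days=int(anti_lag[i])), "C"),)
        if anti[i]
        else ()
        for i in range(n)
    ]

    cohort = pd.DataFrame(
        {
            "primaryid": [str(100000001 + i) for i in range(n)],
            "caseid": [str(50000001 + i) for i in range(n)],
            "row_kind": "original",
            "duplicate_of": None,
            "anti_infective_planted": anti,
            "drug_class": np.where(exposed, cls, None),
            "ps_drug": ps_drug,
            "age_latent": age,
            "weight_latent": weight,
            "female_latent": female,
            "quarter_latent": quarter,
            "cirvi": cirvi,
            "fatal": fatal,
            "p_fatal": p_fatal,
            "tto_days": tto_days,
            "reaction_pts": reaction_sets,
            "outcomes": outcomes,
            "therapy_start_latent": therapy_start,
            "age": age_emit,
            "weight": weight_emit,
            "sex": sex_emit,
            "country": country,
            "occp_cod": occp,
            "therapy_start": ther_emit,
            "event_date": event_emit,
            "fda_date": fda_date,
            "concomitant": conco,
        }
    )

    # duplicate rows: lower PRIMARYID than their source so the stated
    # keep-highest rules always retain the original
    n_dup = int(round(config.duplicate_injection_rate * n))
    dup_src = rng_inject.choice(n, size=n_dup, replace=False)
    dup_kind = rng_inject.random(n_dup) < 0.5
    dup_rows = []
    for j, (i, is_case_dup) in enumerate(zip(dup_src, dup_kind)):
        row = cohort.iloc[i].copy()
        row["primaryid"] = str(90000001 + j)
        row["duplicate_of"] = cohort.iloc[i]["primaryid"]
        if is_case_dup:
            row["row_kind"] = "case_dup"  # same CASEID, earlier FDA_DT
            row["fda_date"] = row["fda_date"] - timedelta(days=30)
        else:
            row["row_kind"] = "content_dup"  # new CASEID, identical content
            row["caseid"] = str(70000001 + j)
        dup_rows.append(row)
    if dup_rows:
        cohort = pd.concat([cohort, pd.DataFrame(dup_rows)], ignore_index=True)

    params = {
        "seed": config.seed,
        "n_reports": config.n_reports,
        "planted_viral_multiplier_overall": config.planted_viral_multiplier_overall,
        "planted_viral_multiplier_c3": config.planted_viral_multiplier_c3,
        "per_pt_multipliers": multipliers,
        "planted_fatality_or": {
            "c5_vs_c3": math.exp(config.fatality_model.c5_vs_c3),
            "female": math.exp(config.fatality_model.female),
            "cirvi": math.exp(config.fatality_model.cirvi),
        },
        "fatality_model_conditional": asdict(fatality),
        "background_fatal_rate": config.background_fatal_rate,
        "tto_medians_days": {k: v.median_days for k, v in config.tto_laws.items()},
        "tto_sigmas": {k: v.sigma for k, v in config.tto_laws.items()},
        "n_injected_duplicates": n_dup,
        "n_injected_anti_infective": int(anti.sum()),
    }
    return GroundTruth(params=params, cohort=cohort)


# ---------------------------------------------------------------------------
# emission as CaseReports and FAERS tables


def _fmt_date(d) -> str:
    return "" if d is None else f"{d.year:04d}{d.month:02d}{d.day:02d}"


def cohort_to_cases(cohort: pd.DataFrame) -> list[CaseReport]:
    """Materialise the cohort directly as CaseReports (identical in content
    to writing FAERS tables and re-assembling them; verified in tests)."""
    cases = []
    for row in cohort.itertuples(index=False):
        cases.append(
            CaseReport(
                primaryid=row.primaryid,
                caseid=row.caseid,
                fda_date=row.fda_date,
                event_date=row.event_date,
                age_years=None if pd.isna(row.age) else float(row.age),
                sex=row.sex if row.sex in ("F", "M") else "unknown",
                weight_kg=None if pd.isna(row.weight) else float(row.weight),
                country=row.country,
                reporter={"CN": "consumer", "MD": "physician", "PH": "pharmacist",
                          "OT": "other-health-professional", "LW": "lawyer"}.get(
                    row.occp_cod, "unknown"),
                ps_drug=str(row.ps_drug).casefold(),
                drug_class=row.drug_class,
                therapy_start=row.therapy_start,
                reaction_pts=frozenset(row.reaction_pts),
                indications=frozenset(
                    {"Paroxysmal nocturnal haemoglobinuria"}
                    if row.drug_class else {"Hypertension"}
                ),
                outcomes=frozenset(row.outcomes),
                concomitant_drugs=tuple(row.concomitant),
            )
        )
    cases.sort(key=lambda c: c.primaryid)
    return cases


def cohort_to_tables(cohort: pd.DataFrame) -> dict[str, RawRecordSet]:
    """Emit the cohort as the five FAERS "$"-delimited tables (plus INDI)."""
    demo_rows, drug_rows, reac_rows, outc_rows, ther_rows, indi_rows = [], [], [], [], [], []
    for row in cohort.itertuples(index=False):
        pid = row.primaryid
        demo_rows.append(
            {
                "PRIMARYID": pid,
                "CASEID": row.caseid,
                "FDA_DT": _fmt_date(row.fda_date),
                "EVENT_DT": _fmt_date(row.event_date),
                "AGE": "" if pd.isna(row.age) else f"{row.age:.1f}",
                "AGE_COD": "" if pd.isna(row.age) else "YR",
                "SEX": row.sex,
                "WT": "" if pd.isna(row.weight) else f"{row.weight:.1f}",
                "WT_COD": "" if pd.isna(row.weight) else "KG",
                "OCCP_COD": row.occp_cod,
                "REPORTER_COUNTRY": row.country,
            }
        )
        name = str(row.ps_drug).upper()
        drug_rows.append(
            {"PRIMARYID": pid, "DRUG_SEQ": "1", "ROLE_COD": "PS",
             "DRUGNAME": name, "PROD_AI": name}
        )
        if row.therapy_start is not None:
            ther_rows.append(
                {"PRIMARYID": pid, "DSG_DRUG_SEQ": "1",
                 "START_DT": _fmt_date(row.therapy_start)}
            )
        for seq, (cname, cstart, crole) in enumerate(row.concomitant, start=2):
            drug_rows.append(
                {"PRIMARYID": pid, "DRUG_SEQ": str(seq), "ROLE_COD": crole,
                 "DRUGNAME": cname, "PROD_AI": cname}
            )
            if cstart is not None:
                ther_rows.append(
                    {"PRIMARYID": pid, "DSG_DRUG_SEQ": str(seq),
                     "START_DT": _fmt_date(cstart)}
                )
        for pt in row.reaction_pts:
            reac_rows.append({"PRIMARYID": pid, "PT": pt})
        for code in row.outcomes:
            outc_rows.append({"PRIMARYID": pid, "OUTC_COD": code})
        indi_rows.append(
            {"PRIMARYID": pid, "INDI_PT": "Paroxysmal nocturnal haemoglobinuria"
             if row.drug_class else "Hypertension"}
        )
    return {
        "DEMO": RawRecordSet("DEMO", pd.DataFrame(demo_rows).astype(str)),
        "DRUG": RawRecordSet("DRUG", pd.DataFrame(drug_rows).astype(str)),
        "REAC": RawRecordSet("REAC", pd.DataFrame(reac_rows).astype(str)),
        "OUTC": RawRecordSet("OUTC", pd.DataFrame(outc_rows).astype(str)),
        "THER": RawRecordSet("THER", pd.DataFrame(ther_rows).astype(str)),
        "INDI": RawRecordSet("INDI", pd.DataFrame(indi_rows).astype(str)),
    }


def generate(config: SyntheticConfig, outdir: str | Path) -> GroundTruth:
    """Write FAERS-format files, the ground-truth ledger and a config echo."""
    from .io import write_faers_table  # local import to avoid cycle at module load

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = simulate_cohort(config)
    tables = cohort_to_tables(truth.cohort)
    for name, rs in tables.items():
        write_faers_table(rs, outdir / f"{name}.txt")
    ledger = truth.cohort.drop(columns=["reaction_pts", "outcomes", "concomitant"]).copy()
    ledger["reaction_pts"] = [";".join(p) for p in truth.cohort["reaction_pts"]]
    ledger["outcomes"] = [";".join(o) for o in truth.cohort["outcomes"]]
    ledger.to_csv(outdir / "ledger.tsv", sep="\t", index=False)
    with open(outdir / "truth.yaml", "w") as fh:
        yaml.safe_dump(truth.params, fh, sort_keys=True)
    return truth
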