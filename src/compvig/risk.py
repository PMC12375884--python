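"""Fatality and viral-infection risk models on the processed case set.

The analysis frame holds one row per complement-exposed report with the
fatal-outcome and CIRVI indicators, demographics, drug class and the
calendar quarter of therapy initiation.  On it the module fits:

* univariate/multivariable binary logistic regressions with categorical
  predictors, reported as odds ratios with Wald 95% CIs;
* restricted cubic spline (RCS) logistic models for continuous predictors
  (age, weight), with the knot count (3–7) selected by AIC and a
  nonlinearity p-value from a likelihood-ratio test against the
  linear-in-x model;
* spline × sex interaction tests (likelihood ratio);
* adjusted probability curves along a predictor grid with the remaining
  covariates held at a fixed profile (the cohort medians by default:
  age 42 years, weight 64.2 kg);
* stratified 2×2 odds ratios with the Haldane–Anscombe +0.5 correction and
  Woolf CIs when a cell is zero, Fisher p-values always on the raw counts;
* crude rates and relative risks with log-scale Wald CIs.

Model objects follow the fit-then-results convention: constructors collect
data, ``fit`` runs the maximum-likelihood estimation (via statsmodels'
Logit), and the returned results object carries estimates, covariance,
AIC and a ``summary`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .criteria import VIRAL_PTS
from .disproportionality import Z95, ContingencyTable, fisher as fisher_test
from .io import CaseReport

AGE_BINS = ((0, 18, "<18"), (18, 65, "18-64"), (65, 75, "65-74"), (75, math.inf, ">=75"))
WEIGHT_BINS = ((0, 45, "<45"), (45, 80, "45-80"), (80, math.inf, ">=80"))
AGE_REF, WEIGHT_REF, QUARTER_REF = "<18", "<45", "Q1"

#: Conventional RCS knot placement quantiles per knot count.
RCS_KNOT_QUANTILES = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
    6: (0.05, 0.23, 0.41, 0.59, 0.77, 0.95),
    7: (0.025, 0.1833, 0.3417, 0.50, 0.6583, 0.8167, 0.975),
}


class SeparationError(RuntimeError):
    """Quasi-complete separation: a level's coefficient diverged."""


def _bin_label(value: float, bins) -> str | None:
    if value is None or not np.isfinite(value):
        return None
    for lo, hi, label in bins:
        if lo <= value < hi:
            return label
    return None


def build_analysis_frame(
    reports: Sequence[CaseReport],
    cirvi_pts: frozenset[str] | set[str] = VIRAL_PTS,
) -> pd.DataFrame:
    """One row per complement-exposed report with model-ready columns."""
    rows = []
    for r in reports:
        if r.drug_class is None:
            continue
        quarter = None
        if r.therapy_start is not None:
            quarter = f"Q{(r.therapy_start.month - 1) // 3 + 1}"
        rows.append(
            {
                "primaryid": r.primaryid,
                "fatal": int(r.fatal),
                "cirvi": int(bool(r.reaction_pts & set(cirvi_pts))),
                "infection_pt": None,
                "age_years": r.age_years if r.age_years is not None else np.nan,
                "weight_kg": r.weight_kg if r.weight_kg is not None else np.nan,
                "sex": r.sex if r.sex in ("F", "M") else None,
                "drug_class": r.drug_class,
                "quarter": quarter,
            }
        )
    frame = pd.DataFrame(rows)
    if not frame.empty:
        frame["age_bin"] = frame["age_years"].map(lambda v: _bin_label(v, AGE_BINS))
        frame["weight_bin"] = frame["weight_kg"].map(lambda v: _bin_label(v, WEIGHT_BINS))
    return frame


# ---------------------------------------------------------------------------
# logistic fits


@dataclass
class LogisticFit:
    """Results of a binary logistic regression.

    ``or_table`` has one row per predictor level (reference OR fixed at 1)
    with Wald 95% CIs; ``params``/``cov`` are on the log-odds scale.
    """

    outcome: str
    terms: list[str]
    params: pd.Series
    cov: pd.DataFrame
    llf: float
    aic: float
    n: int
    converged: bool
    or_table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def odds_ratio(self, level: str) -> float:
        row = self.or_table[self.or_table["level"] == level]
        if row.empty:
            raise KeyError(f"no level {level!r} in the fit")
        return float(row["OR"].iloc[0])

    def summary(self) -> str:
        lines = [f"Logistic regression: {self.outcome} (n={self.n}, AIC={self.aic:.1f})"]
        for row in self.or_table.itertuples(index=False):
            p = "ref" if row.p != row.p else f"p={row.p:.3g}"
            lines.append(
                f"  {row.term}={row.level}: OR {row.OR:.3f} "
                f"({row.ci_low:.3f}-{row.ci_high:.3f}) {p}"
            )
        return "\n".join(lines)


def _fit_logit(y: np.ndarray, design: pd.DataFrame, *, maxiter: int = 100):
    import warnings

    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    model = sm.Logit(y, design)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PerfectSeparationWarning)
            res = model.fit(disp=0, maxiter=maxiter, method="newton",
                            warn_convergence=False)
    except np.linalg.LinAlgError as exc:
        raise SeparationError(f"singular information matrix: {exc}") from exc
    big = res.params.index[np.abs(res.params.values) > 15]
    if not res.mle_retvals["converged"] or len(big):
        name = big[0] if len(big) else "model"
        raise SeparationError(f"quasi-separation or non-convergence at term {name!r}")
    return res


def univariate_logit(
    frame: pd.DataFrame,
    outcome: str,
    predictor: str,
    reference: str | int | None = None,
) -> LogisticFit:
    """Maximum-likelihood logistic fit of a binary outcome on one
    categorical predictor, with per-level ORs against the reference."""
    data = frame[[outcome, predictor]].dropna()
    y = data[outcome].astype(int).to_numpy()
    if y.min() == y.max():
        raise ValueError(f"outcome {outcome!r} has a single class")
    levels = sorted(data[predictor].astype(str).unique())
    if len(levels) < 2:
        raise ValueError(f"predictor {predictor!r} has fewer than two levels")
    ref = str(reference) if reference is not None else levels[0]
    if ref not in levels:
        raise ValueError(f"reference level {ref!r} not present")
    design = pd.DataFrame({"const": np.ones(len(data))}, index=data.index)
    for lvl in levels:
        if lvl != ref:
            design[f"{predictor}[{lvl}]"] = (data[predictor].astype(str) == lvl).astype(float)
    res = _fit_logit(y, design)

    rows = [
        {"term": predictor, "level": ref, "OR": 1.0, "ci_low": np.nan,
         "ci_high": np.nan, "p": np.nan, "n": int((data[predictor].astype(str) == ref).sum())}
    ]
    for lvl in levels:
        if lvl == ref:
            continue
        name = f"{predictor}[{lvl}]"
        coef, se = res.params[name], res.bse[name]
        rows.append(
            {"term": predictor, "level": lvl, "OR": math.exp(coef),
             "ci_low": math.exp(coef - Z95 * se), "ci_high": math.exp(coef + Z95 * se),
             "p": float(res.pvalues[name]),
             "n": int((data[predictor].astype(str) == lvl).sum())}
        )
    return LogisticFit(
        outcome=outcome, terms=[predictor], params=res.params,
        cov=pd.DataFrame(res.cov_params(), index=design.columns, columns=design.columns),
        llf=float(res.llf), aic=float(res.aic), n=len(data),
        converged=True, or_table=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# restricted cubic splines


@dataclass(frozen=True)
class RcsSpec:
    """Knot locations of a restricted cubic spline basis."""

    knots: tuple[float, ...]

    @property
    def k(self) -> int:
        return len(self.knots)


def rcs_basis_from_knots(x: np.ndarray, knots: Sequence[float]) -> np.ndarray:
    """Harrell's truncated-power RCS basis: k−1 columns (x itself plus k−2
    nonlinear terms), linear beyond the boundary knots, columns scaled by
    (t_k − t_1)²."""
    x = np.asarray(x, dtype=float)
    t = np.asarray(knots, dtype=float)
    k = t.size
    scale = (t[-1] - t[0]) ** 2
    cols = [x]

    def cube(u: np.ndarray) -> np.ndarray:
        return np.where(u > 0, u**3, 0.0)

    for j in range(k - 2):
        term = (
            cube(x - t[j])
            - cube(x - t[k - 2]) * (t[k - 1] - t[j]) / (t[k - 1] - t[k - 2])
            + cube(x - t[k - 1]) * (t[k - 2] - t[j]) / (t[k - 1] - t[k - 2])
        )
        cols.append(term / scale)
    return np.column_stack(cols)


def rcs_basis(x: np.ndarray, k: int) -> tuple[np.ndarray, RcsSpec]:
    """Place k knots at the conventional quantiles and build the basis."""
    if k not in RCS_KNOT_QUANTILES:
        raise ValueError("knot count must be in 3..7")
    x = np.asarray(x, dtype=float)
    knots = np.quantile(x, RCS_KNOT_QUANTILES[k])
    if np.unique(knots).size < k or np.unique(x).size < k:
        raise ValueError(f"fewer than {k} distinct values for {k} knots")
    return rcs_basis_from_knots(x, knots), RcsSpec(knots=tuple(knots))


def _adjustment_design(data: pd.DataFrame, adjustments: Sequence[str]) -> pd.DataFrame:
    """Dummy-code categorical adjustments (first level reference), keep
    numeric ones as-is."""
    cols = {}
    for adj in adjustments:
        col = data[adj]
        if pd.api.types.is_numeric_dtype(col):
            cols[adj] = col.astype(float)
        else:
            levels = sorted(col.astype(str).unique())
            for lvl in levels[1:]:
                cols[f"{adj}[{lvl}]"] = (col.astype(str) == lvl).astype(float)
    return pd.DataFrame(cols, index=data.index)


@dataclass
class RcsLogitFit:
    """AIC-selected restricted-cubic-spline logistic fit."""

    outcome: str
    predictor: str
    adjustments: tuple[str, ...]
    spec: RcsSpec
    params: pd.Series
    cov: pd.DataFrame
    llf: float
    aic: float
    n: int
    aic_by_k: dict[int, float]
    nonlinearity_p: float
    column_names: tuple[str, ...]
    adjustment_columns: tuple[str, ...]

    def linear_predictor(
        self, x: np.ndarray, profile: dict[str, object] | None = None
    ) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        basis = rcs_basis_from_knots(x, self.spec.knots)
        lp = self.params["const"] + basis @ self.params.iloc[1 : self.spec.k].to_numpy()
        profile = profile or {}
        for col in self.adjustment_columns:
            if "[" in col:
                adj, lvl = col.split("[", 1)
                lvl = lvl.rstrip("]")
                val = 1.0 if str(profile.get(adj)) == lvl else 0.0
            else:
                val = float(profile.get(col, 0.0))
            lp = lp + self.params[col] * val
        return lp

    def predict_probability(
        self, x: np.ndarray, profile: dict[str, object] | None = None
    ) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.linear_predictor(x, profile)))

    def summary(self) -> str:
        return (
            f"RCS logit: {self.outcome} ~ rcs({self.predictor}, k={self.spec.k})"
            f" + {list(self.adjustments)}; n={self.n}, AIC={self.aic:.1f},"
            f" P-nonlinear={self.nonlinearity_p:.2g}"
        )


def fit_rcs_logit(
    frame: pd.DataFrame,
    outcome: str,
    predictor: str,
    adjustments: Sequence[str] = (),
    k_range: Sequence[int] = (3, 4, 5, 6, 7),
) -> RcsLogitFit:
    """Fit the spline logit for each knot count, keep the AIC minimiser
    (ties to the smaller k), and test nonlinearity by LRT against the
    linear-in-x model with the same adjustments."""
    cols = [outcome, predictor, *adjustments]
    data = frame[cols].dropna()
    y = data[outcome].astype(int).to_numpy()
    x = data[predictor].to_numpy(dtype=float)
    adj = _adjustment_design(data, adjustments)

    max_params = 1 + max(k_range) - 1 + adj.shape[1]
    if len(data) < 10 * max_params:
        raise ValueError(
            f"only {len(data)} complete cases for up to {max_params} parameters"
        )

    fits: dict[int, tuple] = {}
    aic_by_k: dict[int, float] = {}
    errors = []
    for k in sorted(k_range):
        try:
            basis, spec = rcs_basis(x, k)
            design = pd.DataFrame(
                basis,
                columns=[predictor] + [predictor + "'" * j for j in range(1, k - 1)],
                index=data.index,
            )
            design.insert(0, "const", 1.0)
            design = pd.concat([design, adj], axis=1)
            res = _fit_logit(y, design)
            fits[k] = (res, spec, tuple(design.columns))
            aic_by_k[k] = float(res.aic)
        except (SeparationError, np.linalg.LinAlgError, ValueError) as exc:
            errors.append(f"k={k}: {exc}")
    if not fits:
        raise SeparationError("no knot count converged: " + "; ".join(errors))

    best_k = min(aic_by_k, key=lambda k: (aic_by_k[k], k))
    res, spec, col_names = fits[best_k]

    lin_design = pd.DataFrame({"const": 1.0, predictor: x}, index=data.index)
    lin_design = pd.concat([lin_design, adj], axis=1)
    lin_res = _fit_logit(y, lin_design)
    # The nonlinearity test uses the richest candidate basis, not the
    # AIC-selected one: a fixed-df likelihood-ratio test keeps its nominal
    # chi-square null distribution, whereas testing the post-selection
    # model inflates the type-I rate.
    test_k = max(fits)
    test_res = fits[test_k][0]
    lr = 2.0 * (test_res.llf - lin_res.llf)
    df = test_k - 2
    nonlin_p = float(stats.chi2.sf(max(lr, 0.0), df)) if df > 0 else 1.0

    return RcsLogitFit(
        outcome=outcome, predictor=predictor, adjustments=tuple(adjustments),
        spec=spec, params=res.params,
        cov=pd.DataFrame(res.cov_params(), index=col_names, columns=col_names),
        llf=float(res.llf), aic=float(res.aic), n=len(data),
        aic_by_k=aic_by_k, nonlinearity_p=nonlin_p,
        column_names=col_names, adjustment_columns=tuple(adj.columns),
    )


def interaction_test(
    frame: pd.DataFrame,
    outcome: str,
    predictor: str,
    modifier: str = "sex",
    adjustments: Sequence[str] = (),
    k: int = 3,
) -> float:
    """LRT p-value for (spline basis × modifier) effect modification."""
    cols = [outcome, predictor, modifier, *adjustments]
    data = frame[cols].dropna()
    y = data[outcome].astype(int).to_numpy()
    x = data[predictor].to_numpy(dtype=float)
    mod_levels = sorted(data[modifier].astype(str).unique())
    if len(mod_levels) != 2:
        raise ValueError(f"modifier {modifier!r} must have exactly two levels")
    m = (data[modifier].astype(str) == mod_levels[1]).to_numpy(dtype=float)

    basis, _ = rcs_basis(x, k)
    adj = _adjustment_design(data, adjustments)
    base = pd.DataFrame(
        basis, columns=[f"b{j}" for j in range(basis.shape[1])], index=data.index
    )
    base.insert(0, "const", 1.0)
    base[f"{modifier}[{mod_levels[1]}]"] = m
    reduced = pd.concat([base, adj], axis=1)

    full = reduced.copy()
    for j in range(basis.shape[1]):
        full[f"b{j}:{modifier}"] = basis[:, j] * m

    res_red = _fit_logit(y, reduced)
    res_full = _fit_logit(y, full)
    lr = 2.0 * (res_full.llf - res_red.llf)
    return float(stats.chi2.sf(max(lr, 0.0), basis.shape[1]))


def adjusted_curve(
    fit: RcsLogitFit,
    grid: np.ndarray | None = None,
    profile: dict[str, object] | None = None,
    resolution: float = 0.01,
) -> tuple[pd.DataFrame, float]:
    """Adjusted probability curve along the predictor and its minimiser.

    The minimiser is located by refining the grid around the coarse
    minimum down to the requested resolution (0.01 by default).
    """
    if grid is None:
        lo, hi = fit.spec.knots[0], fit.spec.knots[-1]
        grid = np.linspace(lo, hi, 200)
    grid = np.asarray(grid, dtype=float)
    prob = fit.predict_probability(grid, profile)
    curve = pd.DataFrame({"x": grid, "probability": prob})

    lo, hi = grid.min(), grid.max()
    while hi - lo > resolution:
        g = np.linspace(lo, hi, 101)
        p = fit.predict_probability(g, profile)
        i = int(np.argmin(p))
        lo, hi = g[max(i - 1, 0)], g[min(i + 1, g.size - 1)]
    minimizer = round(0.5 * (lo + hi) / resolution) * resolution
    return curve, float(minimizer)


# ---------------------------------------------------------------------------
# stratified 2×2 and crude rates


def stratified_or(
    frame: pd.DataFrame, outcome: str, exposure: str, stratum: str
) -> pd.DataFrame:
    """Per-stratum odds ratios for a binary exposure.

    When any cell of a stratum's 2×2 is zero, the Haldane–Anscombe +0.5
    correction (all four cells) is used for the OR and its Woolf CI; the
    Fisher p-value always uses the raw counts.  Strata with an empty
    exposure or outcome margin are reported as inestimable (NaN OR).
    """
    data = frame[[outcome, exposure, stratum]].dropna()
    rows = []
    for level in sorted(data[stratum].astype(str).unique()):
        sub = data[data[stratum].astype(str) == level]
        e = sub[exposure].astype(int).to_numpy()
        y = sub[outcome].astype(int).to_numpy()
        a = int(((e == 1) & (y == 1)).sum())
        b = int(((e == 1) & (y == 0)).sum())
        c = int(((e == 0) & (y == 1)).sum())
        d = int(((e == 0) & (y == 0)).sum())
        row = {"stratum": level, "a": a, "b": b, "c": c, "d": d,
               "OR": np.nan, "ci_low": np.nan, "ci_high": np.nan,
               "fisher_p": np.nan, "corrected": False}
        if a + b + c + d > 0:
            row["fisher_p"] = fisher_test(ContingencyTable(a, b, c, d)).p_value
        if a + b == 0 or c + d == 0:
            rows.append(row)  # no exposed or no unexposed reports
            continue
        if min(a, b, c, d) == 0:
            aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
            row["corrected"] = True
        else:
            aa, bb, cc, dd = float(a), float(b), float(c), float(d)
        orr = (aa * dd) / (bb * cc)
        se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
        row.update(
            OR=orr,
            ci_low=math.exp(math.log(orr) - Z95 * se),
            ci_high=math.exp(math.log(orr) + Z95 * se),
        )
        rows.append(row)
    return pd.DataFrame(rows)


def crude_rates_and_rr(
    events_a: int, n_a: int | None, events_b: int, n_b: int | None
) -> dict:
    """Crude event rates and their ratio with a log-scale Wald 95% CI.

    ``events``/``n`` may also be given as rates directly by passing
    ``n=None`` and the rate in ``events`` — the CI is then unavailable.
    """
    if n_a is None or n_b is None:
        rate_a = float(events_a)
        rate_b = float(events_b)
        if rate_b == 0:
            raise ZeroDivisionError("reference rate is zero; RR inestimable")
        return {"rate_a": rate_a, "rate_b": rate_b, "rr": rate_a / rate_b,
                "ci_low": None, "ci_high": None}
    if events_b == 0:
        raise ZeroDivisionError("zero events in the reference group; RR inestimable")
    rate_a, rate_b = events_a / n_a, events_b / n_b
    rr = rate_a / rate_b
    se = math.sqrt(1 / events_a - 1 / n_a + 1 / events_b - 1 / n_b)
    return {
        "rate_a": rate_a, "rate_b": rate_b, "rr": rr,
        "ci_low": math.exp(math.log(rr) - Z95 * se),
        "ci_high": math.exp(math.log(rr) + Z95 * se),
    }
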