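"""Eight disproportionality signal-detection methods on 2×2 report tables.

For a drug set and an event set, each report in the database falls in one
cell of

    =============  ==========  ============
    .              target event  other events
    target drug         a            b
    other drugs         c            d
    =============  ==========  ============

and disproportionality asks whether a exceeds its independence expectation
E = (a+b)(a+c)/N.  The suite comprises the frequentist reporting odds ratio
(ROR), proportional reporting ratio (PRR), Yates-corrected chi-square,
Fisher's exact test and an observed-to-expected (O/E) ratio on the log2
scale, plus three shrinkage methods: the Bayesian confidence propagation
neural network information component (BCPNN IC) in its closed-form normal
approximation and by Monte Carlo posterior simulation, and the empirical
Bayes geometric mean (EBGM) of the multi-item gamma Poisson shrinker (MGPS),
whose two-gamma mixture prior is fitted by marginal-likelihood maximisation
across the whole drug×event grid.

Per-method signal flags follow standard pharmacovigilance practice: ROR/PRR
flag when the lower 95% bound exceeds 1 with at least three co-reports;
chi-square needs a ≥ 3, PRR ≥ 2 and χ² ≥ 4; Fisher flags at p < 0.05; the
O/E and both BCPNN variants flag when the lower bound of the log2 measure
exceeds 0; EBGM flags when the 5th posterior percentile (EB05) exceeds 2.
A minimum of three co-reports is required throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import optimize, special, stats

from .io import CaseReport

Z95 = 1.959963984540054  # two-sided 95% normal quantile
LN2 = math.log(2.0)

METHODS = ("ROR", "PRR", "CHI2", "FISHER", "OE", "BCPNN_NORM", "BCPNN_MC", "EBGM")


@dataclass(frozen=True)
class ContingencyTable:
    """Report-level 2×2 counts for one drug-set × event-set pair."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("cell counts must be non-negative integers")
        if self.n == 0:
            raise ValueError("empty table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Independence expectation E = (a+b)(a+c)/N of the a cell."""
        return (self.a + self.b) * (self.a + self.c) / self.n

    def haldane(self) -> tuple[float, float, float, float]:
        """Cells with +0.5 added to all four iff any cell is zero."""
        if min(self.a, self.b, self.c, self.d) == 0:
            return (self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5)
        return (float(self.a), float(self.b), float(self.c), float(self.d))


@dataclass(frozen=True)
class MethodResult:
    method: str
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float | None
    flag: bool

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")


def build_table(
    reports: Sequence[CaseReport],
    drug_filter: Callable[[CaseReport], bool],
    event_filter: Callable[[str], bool],
) -> ContingencyTable:
    """Tally reports into the 2×2; a report is in the event margin iff any
    of its reaction PTs satisfies the event filter, and counts once."""
    if not reports:
        raise ValueError("cannot build a contingency table from no reports")
    a = b = c = d = 0
    for r in reports:
        in_drug = drug_filter(r)
        in_event = any(event_filter(pt) for pt in r.reaction_pts)
        if in_drug and in_event:
            a += 1
        elif in_drug:
            b += 1
        elif in_event:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


# ---------------------------------------------------------------------------
# frequentist methods


def ror(t: ContingencyTable) -> MethodResult:
    """Reporting odds ratio with Woolf 95% CI (Haldane +0.5 on zero cells)."""
    a, b, c, d = t.haldane()
    if min(b, c) == 0.0:
        return MethodResult("ROR", math.nan, math.nan, math.nan, None, False)
    est = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = math.exp(math.log(est) - Z95 * se), math.exp(math.log(est) + Z95 * se)
    return MethodResult("ROR", est, lo, hi, None, lo > 1.0 and t.a >= 3)


def prr_chi2(t: ContingencyTable) -> tuple[MethodResult, MethodResult]:
    """Proportional reporting ratio and Yates-corrected Pearson chi-square."""
    a, b, c, d = t.haldane()
    if a + b == 0 or c + d == 0 or a == 0 or c == 0:
        prr_res = MethodResult("PRR", math.nan, math.nan, math.nan, None, False)
        prr_val = math.nan
    else:
        prr_val = (a / (a + b)) / (c / (c + d))
        se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
        lo = math.exp(math.log(prr_val) - Z95 * se)
        hi = math.exp(math.log(prr_val) + Z95 * se)
        prr_res = MethodResult("PRR", prr_val, lo, hi, None, lo > 1.0 and t.a >= 3)

    chi2_val = yates_chi2(t)
    chi2_flag = t.a >= 3 and not math.isnan(prr_val) and prr_val >= 2.0 and chi2_val >= 4.0
    p = math.nan if math.isnan(chi2_val) else float(stats.chi2.sf(chi2_val, 1))
    chi2_res = MethodResult("CHI2", chi2_val, math.nan, math.nan, p, chi2_flag)
    return prr_res, chi2_res


def yates_chi2(t: ContingencyTable) -> float:
    """Yates-corrected Pearson statistic Σ (max(|O−E|−½, 0))²/E on the raw
    counts; NaN when a margin is empty."""
    obs = np.array([[t.a, t.b], [t.c, t.d]], dtype=float)
    rows, cols = obs.sum(axis=1), obs.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        return math.nan
    exp = np.outer(rows, cols) / t.n
    dev = np.maximum(np.abs(obs - exp) - 0.5, 0.0)
    return float((dev**2 / exp).sum())


def fisher(t: ContingencyTable) -> MethodResult:
    """Two-sided Fisher exact test (minimum-likelihood two-sided rule);
    the odds ratio shown is the sample ad/bc for reference."""
    _, p = stats.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="two-sided")
    est = math.nan
    if t.b * t.c > 0:
        est = (t.a * t.d) / (t.b * t.c)
    return MethodResult("FISHER", est, math.nan, math.nan, float(p), p < 0.05 and t.a >= 3)


def obs_exp(t: ContingencyTable) -> MethodResult:
    """Observed-to-expected ratio on the log2 scale with Wald 95% CI.

    estimate = log2(a/E); the half-width 1.96/(ln2·√a) comes from the
    Poisson delta method on ln a.  A lower bound above 0 (i.e. the ratio's
    CI excluding 1) flags a signal.
    """
    if t.a == 0:
        return MethodResult("OE", math.nan, math.nan, math.nan, None, False)
    est = math.log2(t.a / t.expected)
    half = Z95 / (LN2 * math.sqrt(t.a))
    return MethodResult("OE", est, est - half, est + half, None, est - half > 0 and t.a >= 3)


# ---------------------------------------------------------------------------
# BCPNN information component


def bcpnn_normal(t: ContingencyTable) -> MethodResult:
    """Closed-form posterior mean and variance of the information component
    IC = log2 p11/(p1.·p.1) under the standard BCPNN prior
    (α1 = β1 = 1, α = β = 2, γ11 = 1, γ scaled to the margins)."""
    a, n1_, n_1, n = t.a, t.a + t.b, t.a + t.c, t.n
    a1 = b1 = 1.0
    al = be = 2.0
    g11 = 1.0
    g = g11 * (n + al) * (n + be) / ((n1_ + a1) * (n_1 + b1))
    e_ic = math.log2(
        (a + g11) * (n + al) * (n + be) / ((n + g) * (n1_ + a1) * (n_1 + b1))
    )
    v_ic = (
        (n - a + g - g11) / ((a + g11) * (1 + n + g))
        + (n - n1_ + al - a1) / ((n1_ + a1) * (1 + n + al))
        + (n - n_1 + be - b1) / ((n_1 + b1) * (1 + n + be))
    ) / (LN2**2)
    sd = math.sqrt(v_ic)
    lo, hi = e_ic - Z95 * sd, e_ic + Z95 * sd
    return MethodResult("BCPNN_NORM", e_ic, lo, hi, None, lo > 0 and t.a >= 3)


def bcpnn_mc(
    t: ContingencyTable, draws: int = 100_000, seed: int | None = 0
) -> MethodResult:
    """Monte Carlo IC: Dirichlet(1,1,1,1) prior on the four cell
    probabilities, posterior Dirichlet(counts+1); IC025 is the empirical
    2.5th percentile of the simulated IC."""
    if draws < 1000:
        raise ValueError("need at least 1000 posterior draws")
    rng = np.random.default_rng(seed)
    p = rng.dirichlet([t.a + 1, t.b + 1, t.c + 1, t.d + 1], size=draws)
    ic = np.log2(p[:, 0] / ((p[:, 0] + p[:, 1]) * (p[:, 0] + p[:, 2])))
    lo, med, hi = np.quantile(ic, [0.025, 0.5, 0.975])
    return MethodResult("BCPNN_MC", float(med), float(lo), float(hi), None, lo > 0 and t.a >= 3)


# ---------------------------------------------------------------------------
# MGPS / EBGM


@dataclass(frozen=True)
class MgpsHyperparams:
    """Two-gamma mixture prior on the relative reporting rate λ:
    λ ~ w·Gamma(α1, rate β1) + (1−w)·Gamma(α2, rate β2)."""

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    w: float
    loglik: float = math.nan

    def __post_init__(self) -> None:
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("hyperparameters must be positive")
        if not 0.0 < self.w < 1.0:
            raise ValueError("mixing weight must be in (0, 1)")


MGPS_START = MgpsHyperparams(0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)


class MgpsConvergenceError(RuntimeError):
    def __init__(self, msg: str, best: MgpsHyperparams, grad_norm: float):
        super().__init__(msg)
        self.best = best
        self.grad_norm = grad_norm


def _nb_logpmf(a: np.ndarray, e: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    # marginal of Poisson(λE) with λ ~ Gamma(alpha, rate beta): negative binomial
    return (
        special.gammaln(alpha + a)
        - special.gammaln(alpha)
        - special.gammaln(a + 1.0)
        + alpha * np.log(beta / (beta + e))
        + a * np.log(e / (beta + e))
    )


def mgps_marginal_loglik(
    a: np.ndarray, e: np.ndarray, h: MgpsHyperparams
) -> float:
    l1 = _nb_logpmf(a, e, h.alpha1, h.beta1) + math.log(h.w)
    l2 = _nb_logpmf(a, e, h.alpha2, h.beta2) + math.log(1.0 - h.w)
    return float(np.logaddexp(l1, l2).sum())


def mgps_fit(tables: Iterable[ContingencyTable]) -> MgpsHyperparams:
    """Maximise the two-component negative-binomial marginal likelihood of
    the observed a-counts given their expectations, from the conventional
    MGPS start (0.2, 0.1, 2.0, 4.0, 1/3)."""
    tables = list(tables)
    a = np.array([t.a for t in tables], dtype=float)
    e = np.array([t.expected for t in tables], dtype=float)
    keep = np.isfinite(e) & (e > 0)
    a, e = a[keep], e[keep]
    if a.size < 20:
        raise ValueError("MGPS fitting needs at least 20 drug×event tables with E > 0")

    def unpack(theta: np.ndarray) -> MgpsHyperparams:
        a1, b1, a2, b2 = np.exp(theta[:4])
        w = 1.0 / (1.0 + math.exp(-theta[4]))
        return MgpsHyperparams(a1, b1, a2, b2, w)

    def neg(theta: np.ndarray) -> float:
        try:
            return -mgps_marginal_loglik(a, e, unpack(theta))
        except (OverflowError, ValueError):
            return 1e12

    start = MGPS_START
    theta0 = np.array(
        [
            math.log(start.alpha1),
            math.log(start.beta1),
            math.log(start.alpha2),
            math.log(start.beta2),
            math.log(start.w / (1 - start.w)),
        ]
    )
    res = optimize.minimize(neg, theta0, method="Nelder-Mead",
                            options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-8})
    best = unpack(res.x)
    ll_best = mgps_marginal_loglik(a, e, best)
    ll_start = mgps_marginal_loglik(a, e, start)
    grad = optimize.approx_fprime(res.x, neg, 1e-6)
    if ll_best < ll_start:
        raise MgpsConvergenceError(
            "MGPS optimisation failed to improve on the starting values",
            best, float(np.linalg.norm(grad)),
        )
    return MgpsHyperparams(best.alpha1, best.beta1, best.alpha2, best.beta2,
                           best.w, loglik=ll_best)


def _posterior_mix(t: ContingencyTable, h: MgpsHyperparams):
    """Posterior of λ given a, E: two-gamma mixture with updated weight."""
    e = t.expected
    l1 = float(_nb_logpmf(np.array([t.a], float), np.array([e]), h.alpha1, h.beta1)[0])
    l2 = float(_nb_logpmf(np.array([t.a], float), np.array([e]), h.alpha2, h.beta2)[0])
    log_q = math.log(h.w) + l1 - float(np.logaddexp(math.log(h.w) + l1,
                                                    math.log(1 - h.w) + l2))
    q = math.exp(log_q)
    shapes = (h.alpha1 + t.a, h.alpha2 + t.a)
    rates = (h.beta1 + e, h.beta2 + e)
    return q, shapes, rates


def _mix_cdf(x: float, q: float, shapes, rates) -> float:
    return q * stats.gamma.cdf(x, a=shapes[0], scale=1.0 / rates[0]) + (
        1.0 - q
    ) * stats.gamma.cdf(x, a=shapes[1], scale=1.0 / rates[1])


def mix_quantile(p: float, q: float, shapes, rates, tol: float = 1e-6) -> float:
    """Quantile of the posterior mixture by bisection on its CDF."""
    lo = 0.0
    hi = max(
        stats.gamma.ppf(p, a=shapes[0], scale=1.0 / rates[0]),
        stats.gamma.ppf(p, a=shapes[1], scale=1.0 / rates[1]),
    ) + 1.0
    while _mix_cdf(hi, q, shapes, rates) < p:
        hi *= 2.0
    while hi - lo > tol * max(1.0, hi):
        mid = 0.5 * (lo + hi)
        if _mix_cdf(mid, q, shapes, rates) < p:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def ebgm_score(t: ContingencyTable, h: MgpsHyperparams) -> MethodResult:
    """EBGM = exp E[ln λ | a, E] under the posterior mixture; EB05/EB95 are
    the 5th/95th posterior percentiles (bisection to 1e-6)."""
    if t.expected <= 0:
        raise ValueError("EBGM requires a positive expected count")
    q, shapes, rates = _posterior_mix(t, h)
    mean_log = q * (special.digamma(shapes[0]) - math.log(rates[0])) + (1 - q) * (
        special.digamma(shapes[1]) - math.log(rates[1])
    )
    ebgm = math.exp(mean_log)
    eb05 = mix_quantile(0.05, q, shapes, rates)
    eb95 = mix_quantile(0.95, q, shapes, rates)
    return MethodResult("EBGM", ebgm, eb05, eb95, None, eb05 > 2.0 and t.a >= 3)


# ---------------------------------------------------------------------------
# the eight-method panel


@dataclass
class SignalPanel:
    """All eight MethodResults for one drug-set × event-set table."""

    table: ContingencyTable
    results: dict[str, MethodResult] = field(default_factory=dict)

    def flag(self, method: str) -> bool:
        return self.results[method].flag

    @property
    def any_flag(self) -> bool:
        return any(r.flag for r in self.results.values())


def run_panel(
    t: ContingencyTable,
    h: MgpsHyperparams,
    *,
    draws: int = 100_000,
    seed: int | None = 0,
) -> SignalPanel:
    """Run all eight methods on one table (MGPS hyperparameters fitted
    beforehand on the full drug×event grid)."""
    prr_res, chi2_res = prr_chi2(t)
    results = {
        "ROR": ror(t),
        "PRR": prr_res,
        "CHI2": chi2_res,
        "FISHER": fisher(t),
        "OE": obs_exp(t),
        "BCPNN_NORM": bcpnn_normal(t),
        "BCPNN_MC": bcpnn_mc(t, draws=draws, seed=seed),
        "EBGM": ebgm_score(t, h),
    }
    return SignalPanel(table=t, results=results)


def run_panel_reports(
    reports: Sequence[CaseReport],
    drug_filter: Callable[[CaseReport], bool],
    event_filter: Callable[[str], bool],
    h: MgpsHyperparams,
    *,
    draws: int = 100_000,
    seed: int | None = 0,
) -> SignalPanel:
    return run_panel(build_table(reports, drug_filter, event_filter), h,
                     draws=draws, seed=seed)
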