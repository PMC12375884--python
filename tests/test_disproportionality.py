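"""Oracle and property tests for the eight disproportionality methods."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from compvig.disproportionality import (
    ContingencyTable,
    MGPS_START,
    bcpnn_mc,
    bcpnn_normal,
    build_table,
    ebgm_score,
    fisher,
    mgps_fit,
    mgps_marginal_loglik,
    obs_exp,
    prr_chi2,
    ror,
    run_panel,
    yates_chi2,
)
from conftest import make_case


def fisher_two_sided_enumeration(t: ContingencyTable) -> float:
    """Independent oracle: sum hypergeometric probabilities of all tables
    with the observed margins whose probability is <= the observed one."""
    n, r, k = t.n, t.a + t.b, t.a + t.c
    lo, hi = max(0, k - (n - r)), min(k, r)
    support = np.arange(lo, hi + 1)
    probs = stats.hypergeom.pmf(support, n, r, k)
    p_obs = stats.hypergeom.pmf(t.a, n, r, k)
    return float(probs[probs <= p_obs * (1 + 1e-9)].sum())


def random_tables(n_tables: int, seed: int, max_cell: int = 50):
    rng = np.random.default_rng(seed)
    tables = []
    while len(tables) < n_tables:
        a, b, c, d = rng.integers(0, max_cell + 1, size=4)
        if a + b + c + d > 0:
            tables.append(ContingencyTable(int(a), int(b), int(c), int(d)))
    return tables


class TestBuildTable:
    def test_definitional_four_cells(self):
        reports = [
            make_case("1", drug_class="C5", reaction_pts=("Influenza",)),
            make_case("2", drug_class="C5", reaction_pts=("Headache",)),
            make_case("3", drug_class=None, ps_drug="x", reaction_pts=("Influenza",)),
            make_case("4", drug_class=None, ps_drug="x", reaction_pts=("Headache",)),
        ]
        t = build_table(reports, lambda r: r.drug_class is not None, lambda pt: pt == "Influenza")
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_report_with_two_qualifying_pts_counts_once(self):
        reports = [
            make_case("1", reaction_pts=("Influenza", "Herpes zoster")),
            make_case("2", drug_class=None, ps_drug="x", reaction_pts=("Headache",)),
        ]
        viral = {"Influenza", "Herpes zoster"}
        t = build_table(reports, lambda r: r.drug_class is not None, lambda pt: pt in viral)
        assert t.a == 1

    def test_margins_match_brute_force_tally(self):
        rng = np.random.default_rng(5)
        pts = ["Influenza", "Headache", "Nausea", "Pyrexia"]
        reports = []
        for i in range(100):
            k = rng.integers(1, 4)
            chosen = tuple(rng.choice(pts, size=k, replace=False))
            reports.append(
                make_case(str(i), drug_class="C5" if rng.random() < 0.4 else None,
                          ps_drug="eculizumab" if rng.random() < 0.4 else "x",
                          reaction_pts=chosen)
            )
        t = build_table(reports, lambda r: r.drug_class == "C5", lambda pt: pt == "Influenza")
        # independent tally
        a = sum(1 for r in reports if r.drug_class == "C5" and "Influenza" in r.reaction_pts)
        b = sum(1 for r in reports if r.drug_class == "C5" and "Influenza" not in r.reaction_pts)
        c = sum(1 for r in reports if r.drug_class != "C5" and "Influenza" in r.reaction_pts)
        assert (t.a, t.b, t.c, t.d) == (a, b, c, 100 - a - b - c)

    def test_empty_reports_error(self):
        with pytest.raises(ValueError):
            build_table([], lambda r: True, lambda pt: True)


class TestRorPrr:
    def test_ror_point_estimate(self):
        assert ror(ContingencyTable(10, 20, 30, 240)).estimate == pytest.approx(4.0)

    def test_symmetric_table_no_signal(self):
        res = ror(ContingencyTable(5, 5, 5, 5))
        assert res.estimate == pytest.approx(1.0) and not res.flag

    def test_min_count_flag_rule_hand_ci(self):
        res = ror(ContingencyTable(3, 1, 1, 3))
        lo_hand = math.exp(math.log(9) - 1.959963984540054 * math.sqrt(1 / 3 + 1 + 1 + 1 / 3))
        assert res.ci_low == pytest.approx(lo_hand)
        assert res.flag is (lo_hand > 1)

    def test_prr_point_estimate(self):
        prr, _ = prr_chi2(ContingencyTable(10, 20, 30, 240))
        assert prr.estimate == pytest.approx((10 / 30) / (30 / 270))

    def test_balanced_table_chi2_zero(self):
        prr, chi2 = prr_chi2(ContingencyTable(5, 5, 5, 5))
        assert chi2.estimate == pytest.approx(0.0)
        assert not prr.flag and not chi2.flag

    def test_chi2_matches_independent_yates_computation(self):
        for t in random_tables(300, seed=2):
            obs = np.array([[t.a, t.b], [t.c, t.d]])
            if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
                continue
            expected = stats.chi2_contingency(obs, correction=True).statistic
            assert yates_chi2(t) == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize(
        "t",
        [t for t in random_tables(80, seed=3, max_cell=30)
         if min(t.a, t.b, t.c, t.d) > 0][:50],
    )
    def test_row_swap_maps_estimates_to_reciprocals(self, t):
        swapped = ContingencyTable(t.c, t.d, t.a, t.b)
        assert ror(swapped).estimate == pytest.approx(1 / ror(t).estimate)
        assert prr_chi2(swapped)[0].estimate == pytest.approx(
            1 / prr_chi2(t)[0].estimate
        )

    def test_haldane_applied_only_on_zero_cells(self):
        t = ContingencyTable(0, 10, 5, 100)
        assert ror(t).estimate == pytest.approx((0.5 * 100.5) / (10.5 * 5.5))
        t2 = ContingencyTable(4, 10, 5, 100)
        assert ror(t2).estimate == pytest.approx(4 * 100 / (10 * 5))


class TestFisher:
    def test_balanced_table_p_one(self):
        assert fisher(ContingencyTable(5, 5, 5, 5)).p_value == pytest.approx(1.0, abs=1e-12)

    def test_extreme_table_closed_form(self):
        p = fisher(ContingencyTable(10, 0, 0, 10)).p_value
        assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-9)

    def test_matches_enumeration_on_small_tables(self):
        for t in random_tables(200, seed=4, max_cell=8):
            if t.n > 30:
                continue
            assert fisher(t).p_value == pytest.approx(
                fisher_two_sided_enumeration(t), abs=1e-9
            )

    def test_flag_needs_three_reports(self):
        assert not fisher(ContingencyTable(2, 0, 0, 50)).flag


class TestObsExp:
    def test_observed_equals_expected_is_zero(self):
        res = obs_exp(ContingencyTable(10, 90, 10, 90))
        assert res.estimate == pytest.approx(0.0) and not res.flag

    def test_log2_ratio(self):
        res = obs_exp(ContingencyTable(40, 60, 10, 90))
        assert res.estimate == pytest.approx(math.log2(1.6))

    def test_ci_width_shrinks_with_counts(self):
        widths = []
        for a in (10, 40, 160, 640):
            t = ContingencyTable(a, a * 9, a * 10, a * 90)  # a/E fixed
            res = obs_exp(t)
            widths.append(res.ci_high - res.ci_low)
        assert all(w1 > w2 for w1, w2 in zip(widths, widths[1:]))

    def test_zero_observed_undefined(self):
        res = obs_exp(ContingencyTable(0, 10, 10, 100))
        assert math.isnan(res.estimate) and not res.flag


class TestBcpnn:
    def test_zero_coreports_negative_ic(self):
        assert bcpnn_normal(ContingencyTable(0, 10, 10, 1000)).estimate < 0

    def test_independence_limit_large_n(self):
        # a equals E exactly: margins 10^4 x 10^4 over N=10^6
        t = ContingencyTable(100, 9900, 9900, 980100)
        assert abs(bcpnn_normal(t).estimate) < 0.05

    @pytest.mark.parametrize("t", random_tables(40, seed=6))
    def test_ic025_strictly_below_posterior_mean(self, t):
        res = bcpnn_normal(t)
        assert res.ci_low < res.estimate

    def test_mc_symmetric_table(self):
        res = bcpnn_mc(ContingencyTable(50, 50, 50, 50), draws=50_000, seed=1)
        assert res.ci_low < 0 and abs(res.estimate) < 0.05

    def test_mc_seeded_determinism(self):
        t = ContingencyTable(12, 40, 33, 500)
        r1 = bcpnn_mc(t, draws=10_000, seed=9)
        r2 = bcpnn_mc(t, draws=10_000, seed=9)
        assert r1 == r2

    def test_mc_agrees_with_normal_approximation(self):
        # convergence check on reporting-database-scale tables with a >= 20
        # at moderate disproportionality; the two published priors differ
        # systematically for extreme a/E at small a, so agreement is a
        # large-count property, not a pointwise identity
        for t in (
            ContingencyTable(20, 980, 980, 98020),
            ContingencyTable(25, 975, 475, 48525),
            ContingencyTable(40, 1960, 1960, 196040),
            ContingencyTable(50, 950, 950, 98050),
            ContingencyTable(100, 4900, 4900, 490100),
            ContingencyTable(200, 9800, 9800, 980200),
        ):
            mc = bcpnn_mc(t, draws=200_000, seed=3)
            norm = bcpnn_normal(t)
            assert abs(mc.ci_low - norm.ci_low) <= 0.15

    def test_mc_requires_enough_draws(self):
        with pytest.raises(ValueError):
            bcpnn_mc(ContingencyTable(1, 1, 1, 1), draws=10, seed=0)


def simulate_mixture_tables(n_pairs, alpha1, beta1, alpha2, beta2, w, seed):
    rng = np.random.default_rng(seed)
    e = rng.uniform(0.5, 20.0, n_pairs)
    comp1 = rng.random(n_pairs) < w
    lam = np.where(
        comp1,
        rng.gamma(alpha1, 1 / beta1, n_pairs),
        rng.gamma(alpha2, 1 / beta2, n_pairs),
    )
    a = rng.poisson(lam * e)
    # embed (a, E) in explicit tables: choose margins reproducing E
    tables = []
    for ai, ei in zip(a, e):
        n1 = 1000
        n = 200000
        c = max(int(round(ei * n / n1)) - int(ai), 1)
        tables.append(ContingencyTable(int(ai), n1 - int(ai), c, n - n1 - c))
    return tables


class TestMgpsEbgm:
    def test_fitted_likelihood_at_least_start(self):
        tables = simulate_mixture_tables(500, 1, 1, 4, 2, 0.4, seed=10)
        h = mgps_fit(tables)
        a = np.array([t.a for t in tables], float)
        e = np.array([t.expected for t in tables], float)
        assert mgps_marginal_loglik(a, e, h) >= mgps_marginal_loglik(a, e, MGPS_START)

    def test_simulation_recovery_of_ebgm_scores(self):
        truth_params = (1.0, 1.0, 4.0, 2.0, 0.4)
        tables = simulate_mixture_tables(5000, *truth_params, seed=11)
        h = mgps_fit(tables)
        from compvig.disproportionality import MgpsHyperparams

        h_true = MgpsHyperparams(*truth_params)
        for a_probe, e_probe in ((1, 5.0), (3, 2.0), (10, 2.0), (20, 30.0), (50, 10.0)):
            n1 = 1000
            n = 200000
            c = max(int(round(e_probe * n / n1)) - a_probe, 1)
            t = ContingencyTable(a_probe, n1 - a_probe, c, n - n1 - c)
            got = ebgm_score(t, h).estimate
            want = ebgm_score(t, h_true).estimate
            assert got == pytest.approx(want, rel=0.10)

    def test_too_few_tables_rejected(self):
        with pytest.raises(ValueError):
            mgps_fit(simulate_mixture_tables(10, 1, 1, 4, 2, 0.4, seed=1))

    def test_percentile_ordering(self):
        tables = simulate_mixture_tables(100, 1, 1, 4, 2, 0.4, seed=12)
        h = mgps_fit(tables)
        for t in tables[:20]:
            res = ebgm_score(t, h)
            assert res.ci_low < res.estimate < res.ci_high

    def test_posterior_mean_log_matches_numeric_integration(self):
        from compvig.disproportionality import MgpsHyperparams

        h = MgpsHyperparams(0.8, 1.2, 3.0, 2.0, 0.35)
        t = ContingencyTable(0, 200, 900, 90000)  # a = 0: pure shrinkage
        e = t.expected

        def unnorm(lam):
            prior = h.w * stats.gamma.pdf(lam, h.alpha1, scale=1 / h.beta1) + (
                1 - h.w
            ) * stats.gamma.pdf(lam, h.alpha2, scale=1 / h.beta2)
            return prior * np.exp(-lam * e) * (lam * e) ** t.a

        z, _ = integrate.quad(unnorm, 0, 60, limit=200)
        mean_log, _ = integrate.quad(lambda l: np.log(l) * unnorm(l) / z, 1e-12, 60, limit=200)
        res = ebgm_score(t, h)
        assert math.log(res.estimate) == pytest.approx(mean_log, abs=1e-4)
        prior_mean = h.w * h.alpha1 / h.beta1 + (1 - h.w) * h.alpha2 / h.beta2
        assert res.estimate < prior_mean

    def test_large_count_limit(self):
        tables = simulate_mixture_tables(200, 1, 1, 4, 2, 0.4, seed=13)
        h = mgps_fit(tables)
        n1 = 100_000
        n = 10_000_000
        a, e = 5000, 1000.0
        c = int(round(e * n / n1)) - a
        t = ContingencyTable(a, n1 - a, c, n - n1 - c)
        assert ebgm_score(t, h).estimate == pytest.approx(a / t.expected, rel=0.05)

    def test_shrinkage_toward_prior(self):
        from compvig.disproportionality import MgpsHyperparams

        h = MgpsHyperparams(1.0, 1.0, 1.0, 1.0, 0.5)  # prior mean ratio 1
        for a_val, e_val in ((8, 2.0), (30, 10.0), (2, 6.0), (15, 40.0)):
            n1, n = 1000, 200000
            c = max(int(round(e_val * n / n1)) - a_val, 1)
            t = ContingencyTable(a_val, n1 - a_val, c, n - n1 - c)
            res = ebgm_score(t, h)
            assert abs(math.log(res.estimate)) <= abs(math.log(a_val / t.expected)) + 1e-9


@pytest.fixture(scope="module")
def hyperparams():
    return mgps_fit(simulate_mixture_tables(300, 1, 1, 2, 2, 0.5, seed=20))


class TestPanel:

    def test_strong_signal_flags_all_methods(self, hyperparams):
        # a = 60 against E ~ 10 in a 50k universe
        t = ContingencyTable(60, 940, 440, 48560)
        panel = run_panel(t, hyperparams, draws=20_000, seed=0)
        assert all(r.flag for r in panel.results.values()), {
            m: r.flag for m, r in panel.results.items()
        }

    def test_null_pair_no_flags(self, hyperparams):
        t = ContingencyTable(10, 990, 490, 48510)  # a equals E
        panel = run_panel(t, hyperparams, draws=20_000, seed=0)
        for m in ("ROR", "PRR", "BCPNN_NORM", "BCPNN_MC", "EBGM"):
            assert not panel.results[m].flag

    def test_two_reports_never_flag_frequentist_methods(self, hyperparams):
        t = ContingencyTable(2, 8, 1, 10000)  # enormous ROR but a < 3
        panel = run_panel(t, hyperparams, draws=5_000, seed=0)
        for m in ("ROR", "PRR", "CHI2", "FISHER", "OE"):
            assert not panel.results[m].flag

    def test_flags_recomputable_from_stored_fields(self, hyperparams):
        t = ContingencyTable(25, 975, 475, 48525)
        panel = run_panel(t, hyperparams, draws=20_000, seed=1)
        r = panel.results["ROR"]
        assert r.flag == (r.ci_low > 1 and t.a >= 3)
        o = panel.results["OE"]
        assert o.flag == (o.ci_low > 0 and t.a >= 3)
        f = panel.results["FISHER"]
        assert f.flag == (f.p_value < 0.05 and t.a >= 3)

    def test_null_false_positive_rate_controlled(self):
        rng = np.random.default_rng(77)
        n1, n_1, n = 1000, 1000, 100_000
        flags = 0
        for _ in range(1000):
            e = n1 * n_1 / n
            a = int(rng.poisson(e))
            a = min(a, n1 - 1)
            flags += ror(ContingencyTable(a, n1 - a, n_1 - a, n - n1 - n_1 + a)).flag
        assert flags / 1000 <= 0.075
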