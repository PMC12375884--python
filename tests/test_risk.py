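"""Logistic fits, restricted cubic splines, stratified tables, crude rates."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from compvig.disproportionality import ContingencyTable, fisher
from compvig.risk import (
    SeparationError,
    adjusted_curve,
    build_analysis_frame,
    crude_rates_and_rr,
    fit_rcs_logit,
    interaction_test,
    rcs_basis,
    rcs_basis_from_knots,
    stratified_or,
    univariate_logit,
)


def frame_from_counts(a: int, b: int, c: int, d: int) -> pd.DataFrame:
    """Exposed/unexposed × outcome frame with the given 2×2 counts."""
    rows = (
        [{"y": 1, "x": "exposed"}] * a
        + [{"y": 0, "x": "exposed"}] * b
        + [{"y": 1, "x": "ref"}] * c
        + [{"y": 0, "x": "ref"}] * d
    )
    return pd.DataFrame(rows)


class TestUnivariateLogit:
    @pytest.mark.parametrize("cells", [(20, 35, 12, 70), (8, 40, 30, 22), (15, 15, 15, 45)])
    def test_single_factor_mle_equals_closed_form_or(self, cells):
        a, b, c, d = cells
        fit = univariate_logit(frame_from_counts(a, b, c, d), "y", "x", "ref")
        assert fit.odds_ratio("exposed") == pytest.approx(a * d / (b * c), abs=1e-8)

    def test_balanced_data_or_one(self):
        fit = univariate_logit(frame_from_counts(25, 25, 25, 25), "y", "x", "ref")
        assert math.log(fit.odds_ratio("exposed")) == pytest.approx(0.0, abs=1e-6)

    def test_reference_level_or_is_one(self):
        fit = univariate_logit(frame_from_counts(20, 30, 10, 40), "y", "x", "ref")
        assert fit.odds_ratio("ref") == 1.0

    def test_quasi_separation_raises(self):
        with pytest.raises(SeparationError):
            univariate_logit(frame_from_counts(30, 0, 0, 30), "y", "x", "ref")

    def test_single_class_outcome_rejected(self):
        frame = pd.DataFrame({"y": [1, 1, 1, 1], "x": ["a", "a", "b", "b"]})
        with pytest.raises(ValueError):
            univariate_logit(frame, "y", "x")


class TestRcsBasis:
    def test_k_minus_one_columns(self):
        x = np.linspace(0, 100, 500)
        for k in (3, 4, 5, 6, 7):
            basis, spec = rcs_basis(x, k)
            assert basis.shape == (500, k - 1)
            assert spec.k == k

    def test_tail_linearity_outside_boundary_knots(self):
        rng = np.random.default_rng(2)
        knots = (10.0, 30.0, 50.0, 70.0, 90.0)
        coefs = rng.normal(size=4)
        for grid in (np.linspace(-50, 9, 60), np.linspace(91, 200, 60)):
            y = rcs_basis_from_knots(grid, knots) @ coefs
            assert np.max(np.abs(np.diff(y, 2))) < 1e-8

    def test_perfect_recovery_of_a_spline_function(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 100, 400)
        basis, spec = rcs_basis(x, 5)
        coefs = rng.normal(size=4)
        y = basis @ coefs + 2.5
        design = np.column_stack([np.ones_like(x), basis])
        sol, *_ = np.linalg.lstsq(design, y, rcond=None)
        assert np.abs(design @ sol - y).max() < 1e-8

    def test_too_few_distinct_values(self):
        with pytest.raises(ValueError):
            rcs_basis(np.array([1.0, 1.0, 2.0, 2.0]), 3)


class TestRcsLogit:
    @staticmethod
    def simulate(n, seed, curve="linear"):
        rng = np.random.default_rng(seed)
        age = rng.uniform(1, 95, n)
        sex = np.where(rng.random(n) < 0.5, "F", "M")
        if curve == "linear":
            lp = -3 + 0.02 * age
        else:  # U-shape, vertex 30
            lp = -3 + 1e-3 * (age - 30.0) ** 2
        y = (rng.random(n) < expit(lp)).astype(int)
        return pd.DataFrame({"fatal": y, "age_years": age, "sex": sex})

    def test_aic_selection_rule(self):
        frame = self.simulate(8000, 1, curve="ushape")
        fit = fit_rcs_logit(frame, "fatal", "age_years")
        assert fit.aic == min(fit.aic_by_k.values())
        assert fit.aic_by_k[fit.spec.k] == fit.aic

    def test_u_shape_detected_and_vertex_recovered(self):
        frame = self.simulate(20_000, 2, curve="ushape")
        fit = fit_rcs_logit(frame, "fatal", "age_years")
        assert fit.nonlinearity_p < 0.001
        _, minimizer = adjusted_curve(fit)
        assert abs(minimizer - 30.0) <= 5.0

    def test_linear_truth_not_rejected_typically(self):
        # a light calibration check; the full 200-replicate rate is part of
        # the acceptance suite
        ps = []
        for seed in range(10):
            frame = self.simulate(8000, 100 + seed, curve="linear")
            ps.append(fit_rcs_logit(frame, "fatal", "age_years").nonlinearity_p)
        assert sum(p < 0.05 for p in ps) <= 2

    def test_monotone_truth_gives_monotone_curve(self):
        frame = self.simulate(15_000, 3, curve="linear")
        fit = fit_rcs_logit(frame, "fatal", "age_years")
        curve, _ = adjusted_curve(fit, grid=np.linspace(10, 90, 100))
        assert (curve["probability"].diff().dropna() > -1e-6).all()
        assert curve["probability"].between(0, 1).all()

    def test_affine_rescaling_invariance(self):
        frame = self.simulate(10_000, 4, curve="ushape")
        fit1 = fit_rcs_logit(frame, "fatal", "age_years", k_range=(4,))
        frame2 = frame.assign(age_years=frame["age_years"] * 2.0 + 10.0)
        fit2 = fit_rcs_logit(frame2, "fatal", "age_years", k_range=(4,))
        g = np.linspace(10, 90, 50)
        p1 = fit1.predict_probability(g)
        p2 = fit2.predict_probability(g * 2.0 + 10.0)
        assert np.allclose(p1, p2, atol=1e-6)

    def test_complete_case_floor_enforced(self):
        frame = self.simulate(50, 5)
        with pytest.raises(ValueError, match="complete cases"):
            fit_rcs_logit(frame, "fatal", "age_years")

    def test_interaction_null_on_duplicated_sexes(self):
        base = self.simulate(6000, 6, curve="ushape").assign(sex="M")
        mirrored = base.assign(sex="F")
        frame = pd.concat([base, mirrored], ignore_index=True)
        p = interaction_test(frame, "fatal", "age_years", "sex")
        assert p > 0.99

    def test_interaction_detected_when_planted(self):
        rng = np.random.default_rng(7)
        n = 20_000
        age = rng.uniform(1, 95, n)
        female = rng.random(n) < 0.5
        slope = np.where(female, 0.04, -0.04)  # sign flip by sex
        y = (rng.random(n) < expit(-2 + slope * (age - 48))).astype(int)
        frame = pd.DataFrame(
            {"fatal": y, "age_years": age, "sex": np.where(female, "F", "M")}
        )
        assert interaction_test(frame, "fatal", "age_years", "sex") < 0.01


class TestStratifiedOr:
    def _frame(self, cells_by_stratum):
        rows = []
        for stratum, (a, b, c, d) in cells_by_stratum.items():
            rows += [{"y": 1, "e": 1, "s": stratum}] * a
            rows += [{"y": 0, "e": 1, "s": stratum}] * b
            rows += [{"y": 1, "e": 0, "s": stratum}] * c
            rows += [{"y": 0, "e": 0, "s": stratum}] * d
        return pd.DataFrame(rows)

    def test_haldane_correction_hand_value(self):
        out = stratified_or(self._frame({"g": (0, 10, 5, 100)}), "y", "e", "s")
        row = out.iloc[0]
        assert row["corrected"]
        assert row["OR"] == pytest.approx(50.25 / 57.75, abs=5e-5)
        assert round(row["OR"], 4) == 0.8701

    def test_no_zero_cells_uncorrected(self):
        out = stratified_or(self._frame({"g": (8, 12, 6, 24)}), "y", "e", "s")
        row = out.iloc[0]
        assert not row["corrected"]
        assert row["OR"] == pytest.approx(8 * 24 / (12 * 6))

    def test_fisher_p_always_on_raw_counts(self):
        out = stratified_or(self._frame({"g": (0, 10, 5, 100)}), "y", "e", "s")
        raw_p = fisher(ContingencyTable(0, 10, 5, 100)).p_value
        assert out.iloc[0]["fisher_p"] == pytest.approx(raw_p, abs=1e-12)

    def test_empty_margin_inestimable(self):
        out = stratified_or(self._frame({"g": (0, 0, 5, 100)}), "y", "e", "s")
        assert math.isnan(out.iloc[0]["OR"])


class TestCrudeRates:
    def test_printed_rates_ratio(self):
        out = crude_rates_and_rr(4.33, None, 6.34, None)
        assert round(out["rr"], 2) == 0.68

    def test_counts_give_rates_and_wald_ci(self):
        out = crude_rates_and_rr(50, 1000, 80, 1000)
        assert out["rate_a"] == 0.05 and out["rate_b"] == 0.08
        assert out["ci_low"] < out["rr"] < out["ci_high"]

    def test_equal_rates_rr_one(self):
        assert crude_rates_and_rr(10, 100, 20, 200)["rr"] == pytest.approx(1.0)

    def test_group_swap_reciprocal(self):
        ab = crude_rates_and_rr(30, 500, 60, 700)["rr"]
        ba = crude_rates_and_rr(60, 700, 30, 500)["rr"]
        assert ab * ba == pytest.approx(1.0)

    def test_zero_reference_events_inestimable(self):
        with pytest.raises(ZeroDivisionError):
            crude_rates_and_rr(5, 100, 0, 100)


class TestAnalysisFrame:
    def test_quarter_age_and_weight_binning(self, cohort60k):
        complement = [r for r in cohort60k["kept"] if r.drug_class is not None]
        frame = build_analysis_frame(complement)
        by_id = {r.primaryid: r for r in complement}
        sample = frame.dropna(subset=["quarter"]).head(50)
        for row in sample.itertuples(index=False):
            month = by_id[row.primaryid].therapy_start.month
            assert row.quarter == f"Q{(month - 1) // 3 + 1}"
        aged = frame.dropna(subset=["age_years"]).head(200)
        for row in aged.itertuples(index=False):
            if row.age_years < 18:
                assert row.age_bin == "<18"
            elif row.age_years >= 75:
                assert row.age_bin == ">=75"

    def test_cirvi_indicator_from_viral_pts(self, cohort60k):
        complement = [r for r in cohort60k["kept"] if r.drug_class is not None]
        frame = build_analysis_frame(complement)
        from compvig.criteria import VIRAL_PTS

        by_id = {r.primaryid: r for r in complement}
        for row in frame.head(300).itertuples(index=False):
            assert row.cirvi == int(
                bool(by_id[row.primaryid].reaction_pts & set(VIRAL_PTS))
            )
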