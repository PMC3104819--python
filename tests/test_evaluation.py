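"""Tests for ROC readouts, quintile calibration and the sensitivity analysis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ntscreen.evaluation import (
    CalibrationError,
    ScoreSet,
    SensitivityScenario,
    default_scenarios,
    dr_at_fpr,
    fpr_at_dr,
    median_risk_by_status,
    performance_table,
    quintile_calibration,
    roc_from_scores,
    sensitivity_analysis,
)
from ntscreen.mom_method import MoMParams, likelihood_ratio_mom
from ntscreen.risk_engine import parse_one_in_n


def brute_force_roc(affected, unaffected):
    """Oracle: evaluate DR/FPR at every pooled score threshold directly."""
    thresholds = sorted(set(list(affected) + list(unaffected)), reverse=True)
    pts = [(np.inf, 0.0, 0.0)]
    for t in thresholds:
        dr = sum(a >= t for a in affected) / len(affected)
        fpr = sum(u >= t for u in unaffected) / len(unaffected)
        pts.append((t, dr, fpr))
    return pts


class TestROC:
    def test_perfect_separation(self):
        roc = roc_from_scores(ScoreSet([10.0, 9.0], [1.0, 0.5]))
        # DR reaches 1 while FPR is still 0
        i = np.argmax(roc.dr == 1.0)
        assert roc.fpr[i] == 0.0

    def test_single_tied_score_gives_endpoints_only(self):
        roc = roc_from_scores(ScoreSet([1.0, 1.0], [1.0, 1.0, 1.0]))
        assert len(roc.thresholds) == 2  # (0,0) then the single threshold
        assert roc.dr[-1] == 1.0 and roc.fpr[-1] == 1.0

    def test_toy_cohort_hand_enumeration(self):
        """affected {3,2}, unaffected {1,0.5,0.1}: hand enumeration of all
        thresholds gives DR 1.0 already at FPR 0 (threshold 2), so
        dr_at_fpr(1/3) is 1.0 and the minimum FPR achieving DR 1.0 is 0."""
        roc = roc_from_scores(ScoreSet([3.0, 2.0], [1.0, 0.5, 0.1]))
        assert dr_at_fpr(roc, 1 / 3) == 1.0
        assert fpr_at_dr(roc, 1.0) == 0.0

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(data=st.data())
    def test_matches_brute_force_enumeration(self, data):
        """Sweep ROC equals the all-thresholds oracle exactly on random
        cohorts of up to 50 records (with ties)."""
        score = st.floats(0.01, 10.0).map(lambda x: round(x, 1))
        aff = data.draw(st.lists(score, min_size=1, max_size=25))
        unaff = data.draw(st.lists(score, min_size=1, max_size=25))
        roc = roc_from_scores(ScoreSet(aff, unaff))
        oracle = brute_force_roc(aff, unaff)
        assert len(roc.thresholds) == len(oracle)
        for (t, dr, fpr), tt, dd, ff in zip(oracle, roc.thresholds, roc.dr, roc.fpr):
            assert t == tt
            assert dr == pytest.approx(dd, abs=0)
            assert fpr == pytest.approx(ff, abs=0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ScoreSet([], [1.0])


class TestReadouts:
    def test_accept_everyone(self):
        roc = roc_from_scores(ScoreSet([2.0, 1.0], [1.5, 0.5]))
        assert dr_at_fpr(roc, 1.0) == 1.0

    def test_exact_threshold_fpr(self):
        roc = roc_from_scores(ScoreSet([3.0, 2.0], [1.0, 0.5, 0.1]))
        # DR 0.5 is achieved exactly at threshold 3 with FPR 0
        assert fpr_at_dr(roc, 0.5) == 0.0

    def test_unreachable_fpr_returns_boundary(self):
        roc = roc_from_scores(ScoreSet([1.0], [1.0]))
        # all scores tie: only FPR 0 (empty) or 1 exist; target 0.5 -> DR 0
        assert dr_at_fpr(roc, 0.5) == 0.0

    def test_interpolated_readout_between_points(self):
        roc = roc_from_scores(ScoreSet([3.0, 2.0], [1.0, 0.5, 0.1]))
        # between (FPR 0, DR 1 at t=2) and (FPR 1/3, DR 1 at t=1): flat
        assert dr_at_fpr(roc, 0.2, interpolate=True) == pytest.approx(1.0)

    def test_performance_table_columns(self):
        roc = roc_from_scores(ScoreSet([3.0, 2.0], [1.0, 0.5, 0.1]))
        table = performance_table(roc)
        assert table.shape == (1, 9)
        assert table.iloc[0]["dr_pct_at_fpr_5"] <= 100.0


class TestQuintileCalibration:
    def test_counts_104_affected(self, rng):
        """104 affected pregnancies with distinct risks split 21/21/21/21/20
        from highest to lowest risk."""
        risks = ScoreSet(rng.uniform(1e-4, 0.99, 104), rng.uniform(1e-5, 0.5, 5000))
        table = quintile_calibration(risks)
        assert [r.n_affected for r in table.rows] == [21, 21, 21, 21, 20]

    def test_counts_conserved_and_exhaustive(self, rng):
        n_aff, n_unaff = 104, 3000
        risks = ScoreSet(rng.uniform(1e-4, 0.99, n_aff), rng.uniform(1e-5, 0.5, n_unaff))
        table = quintile_calibration(risks)
        assert sum(r.n_affected for r in table.rows) == n_aff
        assert sum(r.n_total for r in table.rows) == n_aff + n_unaff

    def test_identical_risks_rejected(self):
        with pytest.raises(CalibrationError):
            quintile_calibration(ScoreSet(np.full(104, 0.1), np.full(10, 0.05)))

    def test_bound_texts_bracket_categories(self, rng):
        risks = ScoreSet(rng.uniform(1e-4, 0.99, 104), rng.uniform(1e-5, 0.5, 1000))
        rows = quintile_calibration(risks).rows
        assert rows[0].category_bound.startswith("≥")
        assert rows[-1].category_bound.startswith("≤")

    def test_calibrated_by_construction_cohort(self, rng):
        """When risks are the true conditional probabilities, per-category
        median risk tracks observed prevalence within a factor of 1.5 in at
        least 4 of 5 categories."""
        # construct a population where the assigned risk IS the truth:
        # draw risk r from a skewed distribution, then the status with
        # probability r
        n = 40000
        r = 10 ** rng.uniform(-3.5, -0.3, n)
        affected = rng.random(n) < r
        if affected.sum() < 5:
            pytest.skip("degenerate draw")
        risks = ScoreSet(r[affected], r[~affected])
        rows = quintile_calibration(risks).rows
        ok = sum(
            1 for row in rows
            if row.observed_prevalence_p > 0
            and 1 / 1.5 <= row.median_expected_risk_p / row.observed_prevalence_p <= 1.5
        )
        assert ok >= 4


class TestMedianRisk:
    def test_single_record_each(self):
        aff, unaff = median_risk_by_status(ScoreSet([0.5], [0.001]))
        assert aff == "1 in 2.0"
        assert unaff == "1 in 1000"

    def test_even_count_uses_lower_median(self):
        # risks 0.1 and 0.5: lower median risk is 0.1 -> "1 in 10"
        aff, _ = median_risk_by_status(ScoreSet([0.5, 0.1], [0.001]))
        assert aff == "1 in 10"

    def test_affected_median_exceeds_unaffected(self, rng):
        aff = rng.beta(2, 5, 501)
        unaff = rng.beta(1, 200, 5001)
        a, u = median_risk_by_status(ScoreSet(aff, unaff))
        assert parse_one_in_n(a) > parse_one_in_n(u)


class TestSensitivity:
    @pytest.fixture
    def mom_setup(self, rng):
        mp = {
            11: MoMParams(11, 49.0, 0.28, 0.24, 0.0, 0.1),
            12: MoMParams(12, 62.0, 0.22, 0.23, 0.0, 0.1),
            13: MoMParams(13, 76.0, 0.16, 0.22, 0.0, 0.1),
        }
        mom = {
            "affected": 10 ** rng.normal(0.25, 0.24, 100),
            "unaffected": 10 ** rng.normal(0.0, 0.1, 2000),
        }
        weeks = {
            "affected": rng.choice([11, 12, 13], 100),
            "unaffected": rng.choice([11, 12, 13], 2000),
        }
        return mp, mom, weeks

    def test_identity_scenario_reproduces_baseline(self, mom_setup):
        mp, mom, weeks = mom_setup
        base = sensitivity_analysis(mom, weeks, mp,
                                    scenarios=[SensitivityScenario("affected_sd", 1.0)])
        scores = ScoreSet(likelihood_ratio_mom(mom["affected"], weeks["affected"], mp),
                          likelihood_ratio_mom(mom["unaffected"], weeks["unaffected"], mp))
        expected = performance_table(roc_from_scores(scores))
        assert base[0][1].equals(expected)

    def test_default_scenarios_cover_all_six(self):
        scs = default_scenarios()
        assert len(scs) == 6
        assert {(s.target, s.factor) for s in scs} == {
            (t, f) for t in ("affected_median_mom", "affected_sd", "unaffected_sd")
            for f in (0.8, 1.2)
        }

    def test_median_shift_moves_lrs_monotonically_about_crossover(self, mom_setup):
        """Raising the affected median MoM by 20% shifts the affected
        Gaussian right by d = log10(1.2): the LR rises for every record with
        log10 MoM above the midpoint (old mean + d/2) and falls for every
        record below it — the closed-form Gaussian shift algebra."""
        mp, mom, weeks = mom_setup
        d = np.log10(1.2)
        shifted = SensitivityScenario("affected_median_mom", 1.2).apply(mp)
        base_lr = likelihood_ratio_mom(mom["affected"], weeks["affected"], mp)
        new_lr = likelihood_ratio_mom(mom["affected"], weeks["affected"], shifted)
        crossover = np.array([mp[int(w)].mean_log_mom_affected + d / 2
                              for w in weeks["affected"]])
        above = np.log10(mom["affected"]) > crossover
        assert np.all(new_lr[above] > base_lr[above])
        assert np.all(new_lr[~above] < base_lr[~above])

    def test_widening_sds_does_not_improve_detection(self, params, config):
        """Scoring model-true data with both SDs inflated 20% does not raise
        DR at 5% FPR beyond Monte Carlo noise."""
        from ntscreen.interface import score_cohort
        from ntscreen.synthetic_data import CohortSpec, simulate_cohort

        cfg = config
        cohort = simulate_cohort(
            CohortSpec(params=params, n_affected=300, n_unaffected=6000, seed=31))
        scored = score_cohort(cohort, cfg)
        by = {s: scored.loc[scored.status == s, "mom"].to_numpy()
              for s in ("affected", "unaffected")}
        weeks = {s: scored.loc[scored.status == s, "week"].to_numpy()
                 for s in ("affected", "unaffected")}
        from ntscreen.mom_method import derive_mom_params

        mp = derive_mom_params(params, cfg.anchors)
        results = sensitivity_analysis(
            by, weeks, mp,
            scenarios=[SensitivityScenario("affected_sd", 1.0),
                       SensitivityScenario("affected_sd", 1.2),
                       SensitivityScenario("unaffected_sd", 1.2)])
        base_dr = results[0][1].iloc[0]["dr_pct_at_fpr_5"]
        se_pct = 100 * np.sqrt(0.65 * 0.35 / 300)  # binomial MC noise on DR
        for sc, table in results[1:]:
            assert table.iloc[0]["dr_pct_at_fpr_5"] <= base_dr + 2 * se_pct, sc
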