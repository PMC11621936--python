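"""Kaplan-Meier, log-rank, Cox HR and the marker screens."""

import numpy as np
import pandas as pd
import pytest

from phosphodyn import simulate, survival

from _oracles import km_hand


class TestMedianSplit:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([1, 2, 3, 4, 5], [False, False, False, True, True]),
            ([1, 2, 3, 4], [False, False, True, True]),
        ],
    )
    def test_tie_policy_at_median(self, values, expected):
        assert list(survival.median_split(values)) == expected

    def test_all_equal_warns_all_negative(self):
        with pytest.warns(UserWarning, match="median"):
            labels = survival.median_split([2.0, 2.0, 2.0])
        assert not labels.any()

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            survival.median_split([1.0])


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        curve = survival.km_estimate([1, 2, 3], [1, 1, 1])
        s = dict(zip(curve.table["time"], curve.table["survival"]))
        assert s[1.0] == pytest.approx(2 / 3)
        assert s[2.0] == pytest.approx(1 / 3)
        assert s[3.0] == pytest.approx(0.0)

    def test_all_censored_curve_stays_at_one(self):
        curve = survival.km_estimate([5, 8, 12], [0, 0, 0])
        assert curve.survival_at(100) == 1.0

    def test_worked_product_limit_example(self):
        # {6, 7+, 10, 15+, 19}: S(10) = (4/5)(2/3) = 0.5333
        curve = survival.km_estimate([6, 7, 10, 15, 19], [1, 0, 1, 0, 1])
        assert curve.survival_at(10) == pytest.approx(8 / 15, abs=1e-9)

    def test_matches_hand_product_limit_on_random_data(self):
        rng = np.random.default_rng(17)
        times = rng.exponential(10, size=60).round(1) + 0.1
        events = rng.integers(0, 2, size=60)
        curve = survival.km_estimate(times, events)
        hand = km_hand(times, events)
        ours = dict(zip(curve.table["time"], curve.table["survival"]))
        for t, s in hand.items():
            assert ours[t] == pytest.approx(s, abs=1e-12)

    def test_curve_monotone_from_one_with_greenwood_variance(self):
        rng = np.random.default_rng(3)
        curve = survival.km_estimate(rng.exponential(12, 50), rng.integers(0, 2, 50))
        s = curve.table["survival"].to_numpy()
        assert (np.diff(s) <= 1e-12).all() and s[0] <= 1.0
        assert (curve.table["greenwood_var"] >= 0).all()


class TestLogrank:
    def test_identical_groups_give_p_one(self):
        t, e = [3, 5, 8, 11], [1, 0, 1, 1]
        chi2, p = survival.logrank(t, e, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_symmetric_in_group_order(self):
        a, ea = [2, 4, 9, 12], [1, 1, 0, 1]
        b, eb = [1, 3, 5, 6], [1, 0, 1, 1]
        assert survival.logrank(a, ea, b, eb)[0] == pytest.approx(
            survival.logrank(b, eb, a, ea)[0]
        )

    def test_strong_separation_detected(self):
        rng = np.random.default_rng(8)
        a = rng.exponential(50, 100)
        b = rng.exponential(10, 100)
        chi2, p = survival.logrank(a, np.ones(100), b, np.ones(100))
        assert p < 1e-6


class TestCoxHR:
    @pytest.fixture
    def cohort(self):
        df, _ = simulate.gen_cohort(
            800, hr_by_stratum={"all": 0.5}, censor_rate=0.005, seed=21
        )
        return df

    def test_planted_hr_recovered(self, cohort):
        est = survival.cox_hr(cohort, "arm", positive="S-1")
        assert 0.35 < est.hr < 0.7
        assert est.ci95[0] < 0.5 < est.ci95[1]

    def test_duplicating_records_leaves_hr_essentially_unchanged(self, cohort):
        """Duplication invariance holds up to the Efron tie correction.

        Doubling every record turns each event time into a tie, so under
        Efron handling the partial likelihood is not literally identical —
        the estimate moves by O(1/n), not exactly zero.
        """
        est1 = survival.cox_hr(cohort, "arm", positive="S-1")
        est2 = survival.cox_hr(
            pd.concat([cohort, cohort], ignore_index=True), "arm", positive="S-1"
        )
        assert est2.hr == pytest.approx(est1.hr, rel=5e-3)

    def test_flipping_binary_coding_inverts_hr(self, cohort):
        a = survival.cox_hr(cohort, "arm", positive="S-1")
        b = survival.cox_hr(cohort, "arm", positive="surgery")
        assert b.hr == pytest.approx(1 / a.hr, rel=1e-9)
        assert b.ci95[0] == pytest.approx(1 / a.ci95[1], rel=1e-9)

    def test_constant_covariate_rejected(self, cohort):
        cohort = cohort.assign(flat=1.0)
        with pytest.raises(ValueError, match="constant"):
            survival.cox_hr(cohort, "flat")

    def test_separation_is_flagged_not_trusted(self):
        # everyone in group 1 fails early, group 0 late: monotone likelihood
        df = pd.DataFrame(
            {
                "time_months": [1, 2, 3, 4, 50, 60, 70, 80],
                "event": [1] * 8,
                "g": [1, 1, 1, 1, 0, 0, 0, 0],
            }
        )
        est = survival.cox_hr(df, "g")
        assert est.flagged
        assert est.ci95 == (0.0, np.inf)


class TestSubgroupAnalysis:
    def test_single_stratum_matches_cox_hr(self):
        df, _ = simulate.gen_cohort(400, hr_by_stratum={"only": 0.6}, seed=4)
        table = survival.subgroup_analysis(df, "stratum", "arm", treated="S-1")
        direct = survival.cox_hr(df, "arm", positive="S-1")
        assert len(table) == 1
        assert table.iloc[0]["hr"] == pytest.approx(direct.hr, rel=1e-9)

    def test_planted_stratum_effects_ordered(self):
        correct = 0
        for seed in range(10):
            df, _ = simulate.gen_cohort(
                1200, hr_by_stratum={"A": 0.5, "B": 1.0}, seed=400 + seed
            )
            table = survival.subgroup_analysis(df, "stratum", "arm", treated="S-1")
            hrs = table.set_index("stratum")["hr"]
            correct += hrs["A"] < hrs["B"]
        assert correct >= 9

    def test_unestimable_stratum_omitted_with_warning(self):
        df, _ = simulate.gen_cohort(200, hr_by_stratum={"A": 1.0}, seed=2)
        df.loc[df["stratum"] == "A", "stratum"] = "A"
        df = pd.concat(
            [df, pd.DataFrame({
                "id": ["X1"], "arm": ["surgery"], "stratum": ["empty-ish"],
                "time_months": [5.0], "event": [1],
            })],
            ignore_index=True,
        )
        with pytest.warns(UserWarning, match="omitted"):
            table = survival.subgroup_analysis(df, "stratum", "arm", treated="S-1")
        assert list(table["stratum"]) == ["A"]


class TestHazardScreen:
    def test_planted_protective_gene_ranks_lowest(self):
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(900 + seed)
            n = 300
            protective = rng.normal(size=n)
            high = protective > np.median(protective)
            lam = np.where(high, 0.5, 1.0) * (np.log(2) / 30)
            times = rng.exponential(1 / lam)
            cens = rng.exponential(200, size=n)
            records = pd.DataFrame(
                {
                    "time_months": np.minimum(times, cens),
                    "event": (times <= cens).astype(int),
                }
            )
            expr = pd.DataFrame(
                rng.normal(size=(n, 20)), columns=[f"null{i}" for i in range(20)]
            )
            expr["prot"] = protective
            out = survival.hazard_screen(expr, records)
            wins += out.iloc[0]["gene"] == "prot"
        assert wins >= 8

    def test_constant_gene_skipped_with_warning(self):
        records = pd.DataFrame(
            {"time_months": [1, 2, 3, 4, 5, 6], "event": [1, 1, 0, 1, 0, 1]}
        )
        expr = pd.DataFrame({"flat": np.ones(6), "ok": [1, 2, 3, 4, 5, 6]})
        with pytest.warns(UserWarning, match="constant"):
            out = survival.hazard_screen(expr, records)
        assert list(out["gene"]) == ["ok"]

    def test_null_genes_cover_one_mostly(self):
        rng = np.random.default_rng(77)
        n = 250
        records = pd.DataFrame(
            {
                "time_months": rng.exponential(30, n),
                "event": np.ones(n, dtype=int),
            }
        )
        expr = pd.DataFrame(
            rng.normal(size=(n, 40)), columns=[f"g{i}" for i in range(40)]
        )
        out = survival.hazard_screen(expr, records)
        covered = ((out["ci_lo"] <= 1) & (out["ci_hi"] >= 1)).mean()
        assert covered >= 0.85
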