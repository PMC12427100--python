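import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test as lifelines_logrank

from lipidprog import (
    ClinicalTable,
    cox_univariate,
    km_curve,
    logrank_test,
    median_stratify,
    screen_features,
    simulate_survival,
)
from lipidprog.errors import ConstantFeatureError, NoEventsError, NoSharedSamplesError
from lipidprog.survival import logrank_o_minus_e
from tests.conftest import log10_matrix
from tests.oracles import efron_loglik_oracle, golden_section_max, km_oracle


class TestMedianStratify:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([1, 2, 3, 4], ["low", "low", "high", "high"]),
            ([1, 2, 2, 5], ["low", "low", "low", "high"]),  # ties to low
        ],
    )
    def test_tie_rule(self, values, expected):
        out = median_stratify(pd.Series(values, index=list("abcd")))
        assert out.tolist() == expected

    def test_constant_feature_raises(self):
        with pytest.raises(ConstantFeatureError):
            median_stratify(pd.Series([7.0, 7.0, 7.0, 7.0]))


class TestLogrank:
    def test_identical_groups_statistic_zero(self, toy_clinical):
        groups = pd.Series(["g1", "g2"] * 3, index=toy_clinical.sample_ids)
        clin2 = ClinicalTable(
            pd.DataFrame(
                {"time": [5, 5, 9, 9, 13, 13], "event": [1, 1, 1, 1, 0, 0]},
                index=toy_clinical.sample_ids,
            )
        )
        stat, p = logrank_test(groups, clin2)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_six_subject_fixture_matches_hand_risk_table(self, toy_clinical):
        """O-E and variance computed by hand from the risk table.

        Group B = {P2, P4, P6}: events at t=5 (A), t=8 (A and B tied),
        t=16 (A); censoring at 12 (B) and 20 (B).
        """
        groups = pd.Series(["A", "B", "A", "B", "A", "B"], index=toy_clinical.sample_ids)
        # t=5:  n=6, nB=3, d=1, dB=0 -> e=0.5, v=1*(3/6)*(3/6)*(5/5)=0.25
        # t=8:  n=5, nB=3, d=2, dB=1 -> e=1.2, v=2*(3/5)*(2/5)*(3/4)=0.36
        # t=16: n=2, nB=1, d=1, dB=0 -> e=0.5, v=0.25
        o_minus_e = (0 - 0.5) + (1 - 1.2) + (0 - 0.5)
        var = 0.25 + 0.36 + 0.25
        stat_expect = o_minus_e**2 / var
        stat, p = logrank_test(groups, toy_clinical)
        assert stat == pytest.approx(stat_expect, abs=1e-12)

    def test_matches_lifelines(self):
        _, clin = simulate_survival(60, np.log(2.0), seed=5)
        rng = np.random.default_rng(5)
        groups = pd.Series(rng.choice(["x", "y"], 60), index=clin.sample_ids)
        stat, p = logrank_test(groups, clin)
        mask = groups == "y"
        ref = lifelines_logrank(
            clin.time[mask], clin.time[~mask],
            event_observed_A=clin.event[mask], event_observed_B=clin.event[~mask],
        )
        assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_permutation_null_agrees_with_chisquare(self):
        """Empirical permutation p of the observed statistic ~ chi2(1) p."""
        groups, clin = simulate_survival(40, np.log(1.8), censor_rate=0.2, seed=9)
        labels = groups.map({0.0: "low", 1.0: "high"})
        stat_obs, p_obs = logrank_test(labels, clin)
        rng = np.random.default_rng(1)
        perm_stats = []
        vals = labels.to_numpy().copy()
        for _ in range(1000):
            rng.shuffle(vals)
            s, _ = logrank_test(pd.Series(vals, index=labels.index), clin)
            perm_stats.append(s)
        p_perm = float(np.mean(np.asarray(perm_stats) >= stat_obs))
        assert p_perm == pytest.approx(p_obs, abs=0.03)

    def test_no_events_raises(self):
        clin = ClinicalTable(
            pd.DataFrame({"time": [1.0, 2.0], "event": [0, 0]}, index=["a", "b"])
        )
        with pytest.raises(NoEventsError):
            logrank_test(pd.Series({"a": "x", "b": "y"}), clin)


class TestCox:
    def test_identical_survival_hr_one(self):
        times = [3.0, 6.0, 9.0, 12.0, 15.0, 18.0]
        clin = ClinicalTable(
            pd.DataFrame({"time": times * 2, "event": [1] * 12},
                         index=[f"s{i}" for i in range(12)])
        )
        groups = pd.Series([0] * 6 + [1] * 6, index=clin.sample_ids)
        # group 1 has exactly the same event times as group 0
        clin.table.loc[[f"s{i}" for i in range(6, 12)], "time"] = times
        res = cox_univariate(groups, clin)
        assert res.hr == pytest.approx(1.0, abs=1e-6)
        assert res.ci_low < 1.0 < res.ci_high

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_beta_matches_brute_force_partial_likelihood(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(6, 11)
        clin = ClinicalTable(
            pd.DataFrame(
                {
                    "time": np.round(rng.exponential(10, n), 1) + 0.5,
                    "event": rng.uniform(size=n) < 0.8,
                },
                index=[f"s{i}" for i in range(n)],
            )
        )
        if not clin.event.any():
            pytest.skip("degenerate draw")
        x = rng.integers(0, 2, n)
        if x.min() == x.max() or clin.event[x == 0].sum() == 0 or clin.event[x == 1].sum() == 0:
            pytest.skip("separation draw")
        groups = pd.Series(x, index=clin.sample_ids)
        res = cox_univariate(groups, clin)
        beta_oracle = golden_section_max(
            lambda b: efron_loglik_oracle(b, clin.time, clin.event, x)
        )
        assert res.beta == pytest.approx(beta_oracle, abs=1e-4)

    def test_matches_lifelines_efron(self):
        groups, clin = simulate_survival(120, np.log(2.0), seed=3)
        res = cox_univariate(groups, clin)
        df = pd.DataFrame({"T": clin.time, "E": clin.event.astype(int), "x": groups})
        cph = CoxPHFitter().fit(df, "T", "E")
        assert res.beta == pytest.approx(float(cph.params_.iloc[0]), abs=1e-6)
        assert res.se == pytest.approx(float(cph.standard_errors_.iloc[0]), abs=1e-6)

    def test_separation_flagged_not_fatal(self):
        clin = ClinicalTable(
            pd.DataFrame(
                {"time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0], "event": [1, 1, 1, 0, 0, 0]},
                index=[f"s{i}" for i in range(6)],
            )
        )
        groups = pd.Series([0, 0, 0, 1, 1, 1], index=clin.sample_ids)
        res = cox_univariate(groups, clin)
        assert res.separation and res.hr == 0.0

    def test_hr_recovery_mid_size(self):
        groups, clin = simulate_survival(500, np.log(2.0), censor_rate=0.2, seed=11)
        res = cox_univariate(groups, clin)
        assert 1.6 < res.hr < 2.5
        assert res.ci_low < 2.0 < res.ci_high


class TestKM:
    def test_all_events_product_limit(self):
        clin = ClinicalTable(
            pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": [1, 1, 1]},
                         index=["a", "b", "c"])
        )
        curves = km_curve(pd.Series({"a": "g", "b": "g", "c": "g"}), clin)
        sf = curves["g"].set_index("time")["survival"]
        assert sf.loc[1.0] == pytest.approx(2 / 3)
        assert sf.loc[2.0] == pytest.approx(1 / 3)
        assert sf.loc[3.0] == pytest.approx(0.0)

    def test_no_events_in_one_group_flat_curve(self):
        clin = ClinicalTable(
            pd.DataFrame({"time": [5.0, 6.0, 7.0, 8.0], "event": [0, 0, 1, 1]},
                         index=list("abcd"))
        )
        curves = km_curve(pd.Series({"a": "g0", "b": "g0", "c": "g1", "d": "g1"}), clin)
        assert (curves["g0"]["survival"] == 1.0).all()

    def test_censoring_after_last_event_no_drop(self):
        clin = ClinicalTable(
            pd.DataFrame({"time": [1.0, 2.0, 9.0], "event": [1, 1, 0]},
                         index=list("abc"))
        )
        curves = km_curve(pd.Series({"a": "g", "b": "g", "c": "g"}), clin)
        sf = curves["g"]
        assert sf["survival"].iloc[-1] == pytest.approx(sf.set_index("time")["survival"].loc[2.0])

    def test_matches_definition_oracle_random(self):
        _, clin = simulate_survival(50, 0.5, seed=21)
        curves = km_curve(pd.Series("g", index=clin.sample_ids), clin)
        sf = curves["g"].set_index("time")["survival"]
        for t, s in km_oracle(clin.time, clin.event):
            assert sf.loc[t] == pytest.approx(s, abs=1e-12)
        assert (np.diff(curves["g"]["survival"]) <= 1e-12).all()
        assert curves["g"]["survival"].between(0, 1).all()


class TestScreen:
    def test_direction_consistent_with_o_minus_e(self, small_clean):
        clean, _, clinical, _, _ = small_clean
        screen = screen_features(clean, clinical)
        for _, row in screen.sample(25, random_state=0).iterrows():
            if row["reason"] or not np.isfinite(row["hr"]):
                continue
            strata = median_stratify(clean.data.loc[row["feature_id"]])
            ome = logrank_o_minus_e(strata, clinical, high_label="high")
            if abs(ome) > 1e-9 and abs(row["hr"] - 1) > 1e-9:
                assert (row["hr"] > 1) == (ome > 0)

    def test_planted_detrimental_species_flagged(self):
        from lipidprog import SyntheticConfig, generate_cohort, preprocess

        cfg = SyntheticConfig(n_samples=200, n_species=40,
                              class_composition={"PC": 20, "PC O-": 20},
                              n_genes=10, n_module_genes=2,
                              subtype_log_hr=np.log(2.5), seed=17)
        lipids, _, clin, truth = generate_cohort(cfg)
        clean = preprocess(lipids)
        screen = screen_features(clean, clin).set_index("feature_id")
        planted = [s for s in truth.planted_species if s in screen.index]
        frac = (screen.loc[planted, "direction"] == "detrimental").mean()
        assert frac >= 0.9

    def test_empty_intersection_hard_error(self, small_clean):
        clean, _, clinical, _, _ = small_clean
        other = ClinicalTable(
            pd.DataFrame({"time": [1.0] * 4, "event": [1] * 4},
                         index=[f"zz{i}" for i in range(4)])
        )
        with pytest.raises(NoSharedSamplesError):
            screen_features(clean, other)

    def test_constant_species_reported_ns(self):
        _, clin = simulate_survival(20, 0.0, seed=2)
        vals = np.random.default_rng(0).normal(size=(3, 20))
        vals[1] = 5.0
        m = log10_matrix(vals, samples=clin.sample_ids)
        screen = screen_features(m, clin)
        row = screen[screen.feature_id == "sp1"].iloc[0]
        assert row["direction"] == "ns" and row["reason"] == "ConstantFeatureError"
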