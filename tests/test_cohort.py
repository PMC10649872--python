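"""Tumor stratification, Kaplan-Meier estimation, log-rank, clinical splits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitosig.cohort import (
    CLASS_NAMES,
    SurvivalCohort,
    clinical_splits,
    cluster_tumors,
    km_estimate,
    logrank_test,
)
from mitosig.scqpcr import signature_score
from mitosig.signatures import MGS
from mitosig.simulate import SimConfig, simulate_cohort


class TestClusterTumors:
    def test_three_separated_classes_recovered_and_named_by_score(self):
        expr, _, truth = simulate_cohort(200, config=SimConfig(seed=1, noise_sd=0.8))
        classes = cluster_tumors(expr, list(expr.data.columns), MGS)
        assert (classes.labels == truth).mean() > 0.97
        # names must track descending mean MGS score
        scores = signature_score(expr, MGS)
        means = scores.groupby(classes.labels).mean()
        assert means["MGS.High"] > means["MGS.Int"] > means["MGS.Low"]
        ordered = classes.class_scores.reindex(list(CLASS_NAMES))
        assert (ordered.diff().dropna() < 0).all()

    def test_duplicated_tumor_lands_in_same_class(self):
        expr, _, _ = simulate_cohort(80, config=SimConfig(seed=2))
        data = expr.data.copy()
        data.loc["dup"] = data.iloc[0]
        from mitosig.containers import ExpressionMatrix

        classes = cluster_tumors(ExpressionMatrix(data), list(data.columns), MGS)
        assert classes.labels["dup"] == classes.labels.iloc[0]

    def test_missing_panel_gene_rejected(self):
        expr, _, _ = simulate_cohort(30, config=SimConfig(seed=3))
        with pytest.raises(ValueError, match="absent"):
            cluster_tumors(expr, ["nope"], MGS)

    def test_k_exceeding_tumor_count_rejected(self):
        expr, _, _ = simulate_cohort(30, config=SimConfig(seed=3))
        from mitosig.containers import ExpressionMatrix

        tiny = ExpressionMatrix(expr.data.iloc[:2])
        with pytest.raises(ValueError):
            cluster_tumors(tiny, list(expr.data.columns), MGS)


class TestKaplanMeier:
    def test_no_events_stays_at_one(self):
        km = km_estimate([3.0, 5.0, 9.0], [0, 0, 0])
        assert (km["survival"] == 1.0).all()

    def test_product_limit_hand_values(self):
        km = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        assert km["survival"].tolist() == pytest.approx([2 / 3, 1 / 3, 0.0])

    def test_censored_then_event_hand_value(self):
        # n=2: censored at t=1, event at t=2 -> S(2) = 0
        km = km_estimate([1.0, 2.0], [0, 1])
        assert km.loc[km["time"] == 2.0, "survival"].item() == pytest.approx(0.0)

    def test_equals_empirical_survival_without_censoring(self, rng):
        times = rng.exponential(10.0, size=200).round(3)
        km = km_estimate(times, np.ones_like(times, dtype=int))
        for t, s in zip(km["time"], km["survival"]):
            assert s == pytest.approx((times > t).mean(), abs=1e-12)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


class TestLogrank:
    def test_identical_groups_chi2_zero_p_one(self):
        times = np.array([1.0, 2.0, 3.0, 4.0] * 2)
        events = np.array([1, 0, 1, 1] * 2)
        groups = np.array(["a"] * 4 + ["b"] * 4)
        out = logrank_test(times, events, groups)
        assert out["chi2"] == pytest.approx(0.0, abs=1e-12)
        assert out["df"] == 1
        assert out["p_value"] == pytest.approx(1.0)

    def test_matches_hypergeometric_hand_oracle(self, rng):
        from .conftest import logrank_two_group_oracle

        for _ in range(10):
            n = 40
            times = rng.exponential(5.0, size=n).round(1)  # rounded -> ties
            events = rng.integers(0, 2, size=n)
            groups = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
            if events[: n // 2].sum() == 0 or events[n // 2:].sum() == 0:
                continue
            out = logrank_test(times, events, groups)
            assert out["chi2"] == pytest.approx(
                logrank_two_group_oracle(times, events, groups), rel=1e-9
            )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_invariant_to_monotone_time_transform(self, seed):
        rng = np.random.default_rng(seed)
        times = rng.exponential(5.0, size=30) + 0.1
        events = rng.integers(0, 2, size=30)
        groups = rng.choice(["a", "b"], size=30)
        if len(np.unique(groups)) < 2 or events.sum() == 0:
            return
        base = logrank_test(times, events, groups)
        warped = logrank_test(np.log1p(times) ** 2, events, groups)
        assert warped["chi2"] == pytest.approx(base["chi2"], rel=1e-9)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1.0, 2.0], [1, 1], ["a", "a"])


class TestClinicalSplits:
    def make_cohort(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        table = pd.DataFrame(
            {
                "time": rng.exponential(20, size=n),
                "event": rng.integers(0, 2, size=n),
                "mycn_status": rng.choice(
                    ["amplified", "non-amplified", "unknown"], size=n
                ),
                "stage": rng.choice(["1-3", "4"], size=n),
                "age_group": rng.choice(["<=18m", ">18m"], size=n),
            },
            index=[f"t{i}" for i in range(n)],
        )
        return SurvivalCohort(table)

    def test_shifted_high_risk_strata_detected(self):
        cohort = self.make_cohort()
        t = cohort.table
        rng = np.random.default_rng(1)
        scores = pd.Series(rng.normal(size=len(t)), index=t.index)
        scores[t["mycn_status"] == "amplified"] += 3.0
        scores[t["stage"] == "4"] += 3.0
        scores[t["age_group"] == ">18m"] += 3.0
        out = clinical_splits(scores, cohort)
        assert set(out.index) == {"MYCN", "Stage", "Age"}
        assert (out["p_value"] < 0.01).all()
        assert (out["median_high_risk"] > out["median_low_risk"]).all()

    def test_unknown_mycn_excluded_from_that_split_only(self):
        cohort = self.make_cohort()
        t = cohort.table
        scores = pd.Series(np.arange(len(t), dtype=float), index=t.index)
        out = clinical_splits(scores, cohort)
        known = (t["mycn_status"] != "unknown").sum()
        assert out.loc["MYCN", "n_high_risk"] + out.loc["MYCN", "n_low_risk"] == known
        assert out.loc["Stage", "n_high_risk"] + out.loc["Stage", "n_low_risk"] == len(t)

    def test_no_covariates_rejected(self):
        table = pd.DataFrame({"time": [1.0, 2.0], "event": [1, 0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="covariate"):
            clinical_splits(pd.Series([0.1, 0.2], index=["a", "b"]), SurvivalCohort(table))


class TestSurvivalCohortValidation:
    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            SurvivalCohort(pd.DataFrame({"time": [-1.0], "event": [1]}))

    def test_nonbinary_event_rejected(self):
        with pytest.raises(ValueError):
            SurvivalCohort(pd.DataFrame({"time": [1.0], "event": [2]}))


def test_end_to_end_high_class_has_worst_survival():
    """Simulated cohort (n=475, hazard ratios 3/1.5/1): the recovered
    MGS.High stratum has the lowest KM curve and log-rank p < 0.01."""
    expr, table, _ = simulate_cohort(475, config=SimConfig(seed=11, noise_sd=1.0))
    classes = cluster_tumors(expr, list(expr.data.columns), MGS)
    t = table.loc[classes.labels.index]
    out = logrank_test(t["time"], t["event"], classes.labels.to_numpy())
    assert out["p_value"] < 0.01
    curves = {}
    horizon = t["time"].max()
    grid = np.linspace(0, horizon, 50)
    for name in CLASS_NAMES:
        sub = t[classes.labels == name]
        km = km_estimate(sub["time"], sub["event"])
        step = np.concatenate([[1.0], km["survival"].to_numpy()])
        knots = np.concatenate([[0.0], km["time"].to_numpy()])
        curves[name] = np.array([step[np.searchsorted(knots, g, side="right") - 1] for g in grid])
    assert (curves["MGS.High"] <= curves["MGS.Int"] + 1e-9).all()
    assert curves["MGS.High"].mean() < curves["MGS.Low"].mean()
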