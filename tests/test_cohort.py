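"""Cohort rules, competing-risk estimation and matching, validated by hand
computation and by lifelines as the independent estimator."""

import numpy as np
import pandas as pd
import pytest
from lifelines import AalenJohansenFitter, KaplanMeierFitter

from ecatlas import cohort as ch
from ecatlas import syndata as sd


def _records(times, events, **extra):
    n = len(times)
    base = {
        "patient_id": [f"PT{i}" for i in range(n)],
        "time_years": times,
        "event": events,
        "group": extra.pop("group", ["control"] * n),
    }
    base.update(extra)
    return pd.DataFrame(base)


class TestAssignGroups:
    def test_exactly_one_year_is_excluded(self):
        df = pd.DataFrame(
            {
                "patient_id": ["a", "b", "c"],
                "exposure": ["0.0-1.0", "0.0-1.5", ""],
                "age": [60.0] * 3,
                "bmi": [25.0] * 3,
                "stage": ["I"] * 3,
                "grade": [2] * 3,
            }
        )
        kept, excl = ch.assign_groups(df)
        assert set(kept["patient_id"]) == {"b", "c"}
        assert kept.set_index("patient_id").loc["b", "group"] == "metformin"
        assert kept.set_index("patient_id").loc["c", "group"] == "control"
        assert excl.iloc[0]["reason"] == "early_discontinuation"

    def test_registry_arithmetic(self):
        reg = sd.simulate_registry(seed=0)
        kept, excl = ch.assign_groups(reg)
        assert len(kept) == 4648
        assert excl["reason"].value_counts().to_dict() == {
            "missing_metadata": 265,
            "early_discontinuation": 11,
        }
        assert (kept["group"] == "metformin").sum() == 358

    def test_interrupted_intake_never_accumulates(self):
        df = pd.DataFrame(
            {
                "patient_id": ["a"],
                "exposure": ["0.0-0.8;1.0-1.9"],  # two sub-year intervals
                "age": [60.0], "bmi": [25.0], "stage": ["I"], "grade": [2],
            }
        )
        kept, excl = ch.assign_groups(df)
        assert kept.empty and excl.iloc[0]["reason"] == "early_discontinuation"


class TestImputeCause:
    def test_relapse_determines_imputed_cause(self):
        df = _records(
            [1.0, 2.0, 3.0],
            [1, 2, 1],
            relapse_observed=[True, False, True],
            cause_known=[False, False, True],
        )
        df.loc[1, "event"] = 1  # unknown cause, no relapse -> becomes 2
        out = ch.impute_cause(df)
        assert out.loc[0, "event"] == 1
        assert out.loc[1, "event"] == 2
        assert out.loc[2, "event"] == 1
        # all causes known -> identity
        pd.testing.assert_frame_equal(ch.impute_cause(out), out)

    def test_unknown_cause_on_censored_record_errors(self):
        df = _records([1.0], [0], relapse_observed=[False], cause_known=[False])
        with pytest.raises(ValueError):
            ch.impute_cause(df)


class TestCumulativeIncidence:
    def test_hand_computed_four_patient_fixture(self):
        # times 1,2,3,4 with events 1,2,1,0
        df = _records([1.0, 2.0, 3.0, 4.0], [1, 2, 1, 0])
        est = ch.cumulative_incidence(df, event_of_interest=1)
        # t=1: n=4, d1=1 -> CIF = 1/4, S = 3/4
        # t=2: n=3, d2=1 -> CIF unchanged, S = 3/4 * 2/3 = 1/2
        # t=3: n=2, d1=1 -> CIF = 1/4 + 1/2 * 1/2 = 1/2
        assert est.at(1.0) == pytest.approx(0.25)
        assert est.at(2.5) == pytest.approx(0.25)
        assert est.at(3.0) == pytest.approx(0.5)
        assert est.at(10.0) == pytest.approx(0.5)

    def test_reduces_to_one_minus_km_without_competing_events(self):
        rng = np.random.default_rng(0)
        times = rng.exponential(5.0, 80).round(3)
        events = rng.choice([0, 1], 80, p=[0.3, 0.7])
        df = _records(times, events)
        est = ch.cumulative_incidence(df, event_of_interest=1)
        km = KaplanMeierFitter().fit(times, events)
        for t in (1.0, 3.0, 7.0, 12.0):
            assert est.at(t) == pytest.approx(1.0 - float(km.predict(t)), abs=1e-9)

    def test_all_censored_gives_zero(self):
        df = _records([1.0, 2.0, 3.0], [0, 0, 0])
        est = ch.cumulative_incidence(df)
        assert np.all(est.cif == 0.0)

    def test_matches_lifelines_aalen_johansen(self):
        rng = np.random.default_rng(1)
        times = rng.exponential(4.0, 120)
        events = rng.choice([0, 1, 2], 120, p=[0.3, 0.4, 0.3])
        df = _records(times, events)
        est = ch.cumulative_incidence(df, event_of_interest=1)
        ajf = AalenJohansenFitter(calculate_variance=False)
        ajf.fit(times, events, event_of_interest=1)
        cif = ajf.cumulative_density_
        for t in (1.0, 2.0, 5.0, 9.0):
            ref = float(cif[cif.index <= t].iloc[-1, 0]) if (cif.index <= t).any() else 0.0
            assert est.at(t) == pytest.approx(ref, abs=1e-9)

    def test_partition_identity(self):
        df = sd.simulate_cohort(400, 400, 0.7, 1.2, seed=9)
        cif1 = ch.cumulative_incidence(df, event_of_interest=1)
        cif2 = ch.cumulative_incidence(df, event_of_interest=2)
        km = KaplanMeierFitter().fit(df["time_years"], (df["event"] != 0).astype(int))
        for t in (2.0, 6.0, 11.0):
            total = cif1.at(t) + cif2.at(t) + float(km.predict(t))
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_at_risk_counts_reported(self):
        df = sd.simulate_cohort(100, 100, 1.0, 1.0, seed=2)
        est = ch.cumulative_incidence(df)
        assert list(est.at_risk.index) == [5.0, 8.0, 10.0, 14.0]
        assert (est.at_risk.diff().dropna() <= 0).all()


def closed_form_logrank(times, events, group):
    """Textbook two-group log-rank chi-square."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    group = np.asarray(group)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (group == 1)).sum()
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestLogrank:
    def test_identical_groups_give_null(self):
        times = [1.0, 2.0, 3.0, 4.0] * 2
        events = [1, 0, 1, 0] * 2
        group = ["a"] * 4 + ["b"] * 4
        df = _records(times, events, group=group)
        chi2, p = ch.logrank(df)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_closed_form(self):
        rng = np.random.default_rng(3)
        times = rng.exponential(5.0, 60).round(2)
        events = rng.choice([0, 1], 60, p=[0.4, 0.6])
        group01 = rng.choice([0, 1], 60)
        df = _records(times, events, group=np.where(group01 == 1, "a", "b"))
        chi2, _ = ch.logrank(df)
        assert chi2 == pytest.approx(
            closed_form_logrank(times, events, group01), rel=1e-9
        )

    def test_null_pvalues_uniform(self):
        from scipy import stats

        ps = [
            ch.logrank(sd.simulate_cohort(50, 50, 1.0, 1.0, seed=s))[1]
            for s in range(150)
        ]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_empty_group_errors(self):
        df = _records([0.0, 1.0], [0, 1], group=["a", "b"])
        with pytest.raises(ValueError):
            ch.logrank(df)


class TestKMSummaries:
    def test_no_events_gives_unit_survival(self):
        df = _records([6.0, 12.0, 15.0], [0, 0, 0])
        out = ch.km_summaries(df)
        assert (out["survival"] == 1.0).all()

    def test_matches_hand_product(self):
        # deaths at 2 (1/4) and 6 (1/2 among 2 at risk)
        df = _records([2.0, 4.0, 6.0, 8.0], [1, 0, 1, 0])
        out = ch.km_summaries(df, times=(5.0, 10.0)).set_index("time")
        assert out.loc[5.0, "survival"] == pytest.approx(3 / 4)
        assert out.loc[10.0, "survival"] == pytest.approx(3 / 4 * 1 / 2)
        assert bool(out.loc[10.0, "beyond_follow_up"])

    def test_monotone_non_increasing(self):
        df = sd.simulate_cohort(150, 150, 0.8, 1.0, seed=4)
        out = ch.km_summaries(df, times=(2.0, 5.0, 8.0, 11.0, 14.0))
        assert (np.diff(out["survival"]) <= 1e-12).all()


class TestMatching:
    def _pool(self, rows):
        return pd.DataFrame(
            rows, columns=["patient_id", "age", "bmi", "stage", "grade"]
        )

    def test_exact_duplicates_match_at_distance_zero(self):
        treated = self._pool([["t1", 60.0, 25.0, "I", 2]])
        pool = self._pool(
            [["c1", 60.0, 25.0, "I", 2], ["c2", 60.0, 25.0, "I", 2],
             ["c3", 80.0, 35.0, "I", 2]]
        )
        matches, short = ch.match_controls(treated, pool, ratio=2)
        assert set(matches["control_id"]) == {"c1", "c2"}
        assert (matches["distance"] == 0.0).all()
        assert short.empty

    def test_matches_brute_force_nearest_neighbours(self):
        rng = np.random.default_rng(5)
        treated = self._pool(
            [[f"t{i}", rng.normal(60, 5), rng.normal(26, 2), "I", 2] for i in range(3)]
        )
        pool = self._pool(
            [[f"c{i}", rng.normal(60, 5), rng.normal(26, 2), "I", 2] for i in range(12)]
        )
        matches, _ = ch.match_controls(treated, pool, ratio=2)
        # independent greedy replay
        both = pd.concat([treated, pool])
        scale = {c: both[c].std(ddof=0) for c in ("age", "bmi")}
        avail = pool.copy()
        expected = {}
        for _, t in treated.sort_values("patient_id").iterrows():
            d = np.sqrt(
                ((avail["age"] - t["age"]) / scale["age"]) ** 2
                + ((avail["bmi"] - t["bmi"]) / scale["bmi"]) ** 2
            )
            chosen = avail.assign(d=d).sort_values(["d", "patient_id"]).head(2)
            expected[t["patient_id"]] = set(chosen["patient_id"])
            avail = avail[~avail["patient_id"].isin(chosen["patient_id"])]
        for tid, grp in matches.groupby("treated_id"):
            assert set(grp["control_id"]) == expected[tid]

    def test_exact_covariates_block_cross_stratum_matches(self):
        treated = self._pool([["t1", 60.0, 25.0, "III", 3]])
        pool = self._pool([["c1", 60.0, 25.0, "I", 3], ["c2", 61.0, 25.0, "III", 3]])
        matches, short = ch.match_controls(treated, pool, ratio=2)
        assert list(matches["control_id"]) == ["c2"]
        assert short.iloc[0]["n_controls"] == 1

    def test_empty_pool_errors(self):
        treated = self._pool([["t1", 60.0, 25.0, "I", 2]])
        with pytest.raises(ValueError):
            ch.match_controls(treated, treated.iloc[:0], ratio=2)


class TestHazardReduction:
    def test_printed_conversion_and_edges(self):
        assert round(ch.hazard_reduction(0.686), 1) == 31.4
        assert ch.hazard_reduction(1.0) == 0.0
        assert ch.hazard_reduction(0.5) == 50.0
        assert ch.hazard_reduction(1.25) == pytest.approx(-25.0)
        with pytest.raises(ValueError):
            ch.hazard_reduction(0.0)


def test_cause_specific_rate_ratio_recovers_planted_hr():
    df = sd.simulate_cohort(2000, 2000, hr_bc=0.5, hr_competing=1.0, seed=6)
    def rate(sub):
        return (sub["event"] == 1).sum() / sub["time_years"].sum()
    ratio = rate(df[df["group"] == "metformin"]) / rate(df[df["group"] == "control"])
    assert abs(ratio - 0.5) / 0.5 < 0.10
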