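import itertools

import numpy as np
import pandas as pd
import pytest

from mvsubtype.clinical import (
    concordance_index,
    conversion_curves,
    filter_conversion_records,
    fit_cox,
    logrank_test,
    progression_curves,
    ranksum_battery,
)


# ----- oracles -------------------------------------------------------------

def efron_partial_loglik(beta, time, event, x):
    """Partial log-likelihood for one covariate, no ties in event times."""
    order = np.argsort(time)
    time, event, x = time[order], event[order], x[order]
    ll = 0.0
    for i in range(len(time)):
        if event[i] != 1:
            continue
        at_risk = time >= time[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[at_risk])))
    return ll


def naive_concordance(risk, time, event):
    conc = comp = 0.0
    n = len(risk)
    for i, j in itertools.permutations(range(n), 2):
        if event[i] == 1 and time[i] < time[j]:
            comp += 1
            if risk[i] > risk[j]:
                conc += 1
            elif risk[i] == risk[j]:
                conc += 0.5
    return conc / comp


def hand_logrank(time, event, groups):
    """Observed-minus-expected tabulation at each distinct event time."""
    uniq = np.unique(groups)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == uniq[0])).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (groups == uniq[0])).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


# ----- rank-sum battery ----------------------------------------------------

class TestRanksumBattery:
    def test_exact_enumeration_example(self):
        # {1,2,3} vs {4,5,6}: all 20 rank splits, two-sided p = 2/20
        measures = pd.DataFrame({"m": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]})
        labels = np.array([0, 0, 0, 1, 1, 1])
        res = ranksum_battery(measures, labels)
        assert res.loc[0, "p_value"] == pytest.approx(0.1, abs=1e-12)

    def test_identical_groups_p_one(self):
        measures = pd.DataFrame({"m": [1.0, 1.0, 1.0, 1.0]})
        res = ranksum_battery(measures, np.array([0, 0, 1, 1]))
        assert res.loc[0, "p_value"] == pytest.approx(1.0)

    def test_empty_group_flagged_untested(self):
        measures = pd.DataFrame({"m": [1.0, 2.0, np.nan, np.nan]})
        res = ranksum_battery(measures, np.array([0, 0, 1, 1]))
        assert not res.loc[0, "tested"]
        assert not res.loc[0, "significant"]

    def test_bonferroni_threshold(self, rng):
        measures = pd.DataFrame(
            rng.normal(size=(40, 11)), columns=[f"m{i}" for i in range(11)]
        )
        labels = np.array([0] * 20 + [1] * 20)
        res = ranksum_battery(measures, labels, alpha=0.01)
        for _, row in res.iterrows():
            assert row["significant"] == (row["p_value"] < 0.01 / 11)

    def test_familywise_error_calibrated(self):
        # 11 null measures: familywise rejection at 0.01/11 near 0.01
        rng = np.random.default_rng(99)
        labels = np.array([0] * 30 + [1] * 30)
        fwer_hits = 0
        reps = 1000
        for _ in range(reps):
            measures = pd.DataFrame(
                rng.normal(size=(60, 11)), columns=[f"m{i}" for i in range(11)]
            )
            res = ranksum_battery(measures, labels, alpha=0.01)
            fwer_hits += bool(res["significant"].any())
        assert fwer_hits / reps == pytest.approx(0.01, abs=0.005)

    def test_more_than_two_groups_rejected(self, rng):
        measures = pd.DataFrame({"m": rng.normal(size=6)})
        with pytest.raises(ValueError):
            ranksum_battery(measures, np.array([0, 1, 2, 0, 1, 2]))


# ----- Cox model -----------------------------------------------------------

class TestFitCox:
    def test_matches_grid_search_oracle(self):
        # 6 subjects, binary covariate, no censoring, no ties; event times
        # interleaved across groups so the partial-likelihood maximum is
        # interior (fully separated groups would push beta to infinity)
        df = pd.DataFrame(
            {
                "time_months": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                "event": [1, 1, 1, 1, 1, 1],
                "grp": [1.0, 0.0, 1.0, 0.0, 1.0, 0.0],
            }
        )
        fit = fit_cox(df, ["grp"], strength=0.0)
        beta_hat = fit.coefficients["grp"] / df["grp"].std(ddof=0)
        grid = np.linspace(-4, 4, 80001)
        lls = [
            efron_partial_loglik(
                b, df["time_months"].to_numpy(), df["event"].to_numpy(),
                df["grp"].to_numpy(),
            )
            for b in grid
        ]
        beta_oracle = grid[int(np.argmax(lls))]
        assert beta_hat == pytest.approx(beta_oracle, abs=1e-3)

    def test_partial_likelihood_at_fit_beats_zero(self):
        rng = np.random.default_rng(4)
        x = rng.integers(0, 2, 40).astype(float)
        t = rng.exponential(1.0 / np.exp(0.8 * x))
        df = pd.DataFrame({"time_months": t, "event": 1, "grp": x})
        fit = fit_cox(df, ["grp"], strength=0.0)
        beta = fit.coefficients["grp"] / df["grp"].std(ddof=0)
        ll_hat = efron_partial_loglik(beta, t, np.ones(40, int), x)
        ll_zero = efron_partial_loglik(0.0, t, np.ones(40, int), x)
        assert ll_hat >= ll_zero

    def test_constant_covariates_zero_beta_half_concordance(self):
        df = pd.DataFrame(
            {
                "time_months": [1.0, 2.0, 3.0, 4.0],
                "event": [1, 1, 1, 0],
                "c1": 0.0,
                "c2": 0.0,
            }
        )
        fit = fit_cox(df, ["c1", "c2"])
        assert (fit.coefficients == 0).all()
        assert fit.concordance == 0.5
        assert fit.dropped_constant == ["c1", "c2"]

    def test_no_events_rejected(self):
        df = pd.DataFrame({"time_months": [1.0, 2.0], "event": [0, 0], "x": [0.0, 1.0]})
        with pytest.raises(ValueError, match="event"):
            fit_cox(df, ["x"])


class TestConcordance:
    def test_perfect_ordering(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        risk = np.array([4.0, 3.0, 2.0, 1.0])
        assert concordance_index(risk, time, np.ones(4, int)) == 1.0

    def test_reversed_ordering(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        risk = np.array([1.0, 2.0, 3.0, 4.0])
        assert concordance_index(risk, time, np.ones(4, int)) == 0.0

    def test_matches_pair_enumeration_oracle(self, rng):
        n = 15
        risk = rng.normal(size=n)
        time = rng.exponential(size=n)
        event = rng.integers(0, 2, n)
        event[0] = 1
        assert concordance_index(risk, time, event) == pytest.approx(
            naive_concordance(risk, time, event), abs=1e-12
        )

    def test_risk_ties_count_half(self):
        time = np.array([1.0, 2.0])
        risk = np.array([1.0, 1.0])
        assert concordance_index(risk, time, np.array([1, 1])) == 0.5


class TestLogrank:
    def test_identical_duplicated_groups(self):
        time = np.array([1.0, 2.0, 3.0, 4.0] * 2)
        event = np.array([1, 1, 0, 1] * 2)
        groups = np.array([0] * 4 + [1] * 4)
        chi2, p, _ = logrank_test(time, event, groups)
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_matches_hand_tabulation(self, rng):
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        event = np.array([1, 1, 1, 0, 1, 1, 0, 1])
        groups = np.array([0, 1, 0, 1, 0, 1, 0, 1])
        chi2, p, nl2p = logrank_test(time, event, groups)
        assert chi2 == pytest.approx(hand_logrank(time, event, groups), abs=1e-10)
        assert nl2p == pytest.approx(-np.log2(p))

    def test_label_swap_invariance(self, rng):
        time = rng.exponential(size=30)
        event = rng.integers(0, 2, 30)
        event[:2] = 1
        groups = np.array([0] * 15 + [1] * 15)
        chi2_a, _, _ = logrank_test(time, event, groups)
        chi2_b, _, _ = logrank_test(time, event, 1 - groups)
        assert chi2_a == pytest.approx(chi2_b, abs=1e-10)

    def test_one_empty_group_rejected(self, rng):
        with pytest.raises(ValueError):
            logrank_test(rng.exponential(size=5), np.ones(5, int), np.zeros(5, int))


class TestConversionCurves:
    @pytest.fixture
    def fit(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=60)
        t = rng.exponential(1.0 / np.exp(0.5 * x)) * 10
        return fit_cox(
            pd.DataFrame({"time_months": t, "event": 1, "x": x}), ["x"],
            strength=0.01,
        )

    def test_survival_one_at_time_zero(self, fit):
        curves = conversion_curves(fit, {"g": pd.Series({"x": 0.0})})
        first = curves[curves["time_months"] == 0.0]
        assert (first["survival"] == 1.0).all()

    def test_curves_nonincreasing(self, fit):
        curves = conversion_curves(
            fit, {"lo": pd.Series({"x": -1.0}), "hi": pd.Series({"x": 1.0})}
        )
        for _, grp in curves.groupby("group"):
            assert np.all(np.diff(grp["survival"].to_numpy()) <= 1e-12)

    def test_zero_coefficient_gives_identical_groups(self):
        df = pd.DataFrame(
            {"time_months": [1.0, 2.0, 3.0, 4.0], "event": [1, 1, 1, 1], "x": 0.0}
        )
        fit = fit_cox(df, ["x"])
        curves = conversion_curves(
            fit, {"a": pd.Series({"x": 0.0}), "b": pd.Series({"x": 0.0})}
        )
        a = curves[curves["group"] == "a"]["survival"].to_numpy()
        b = curves[curves["group"] == "b"]["survival"].to_numpy()
        np.testing.assert_allclose(a, b)


class TestProgressionCurves:
    def _long(self, records):
        return pd.DataFrame(records, columns=["sample_id", "month", "measure", "value"])

    def test_constant_value_flat_zero_width(self):
        records = [(f"s{i}", m, "adas", 5.0) for i in range(4) for m in (0, 6, 12)]
        labels = pd.Series({f"s{i}": 1 for i in range(4)})
        curves = progression_curves(self._long(records), labels)
        assert (curves["mean"] == 5.0).all()
        np.testing.assert_allclose(curves["ci_high"] - curves["ci_low"], 0.0)

    def test_hand_averaged_toy(self):
        records = [
            ("a", 0, "m", 1.0), ("b", 0, "m", 3.0), ("c", 0, "m", 5.0),
            ("d", 0, "m", 2.0), ("e", 0, "m", 4.0), ("f", 0, "m", 6.0),
        ]
        labels = pd.Series({"a": 1, "b": 1, "c": 1, "d": 2, "e": 2, "f": 2})
        curves = progression_curves(self._long(records), labels)
        assert curves.loc[curves["subtype"] == 1, "mean"].iloc[0] == 3.0
        assert curves.loc[curves["subtype"] == 2, "mean"].iloc[0] == 4.0

    def test_ci_width_shrinks_as_sqrt_n(self):
        # alternating +/-1 values fix the sample sd, so the width follows
        # the closed form 2 * 1.96 * sd / sqrt(n) exactly
        for n in (10, 40, 160):
            records = [(f"s{i}", 0, "m", (-1.0) ** i) for i in range(n)]
            labels = pd.Series({f"s{i}": 1 for i in range(n)})
            curves = progression_curves(self._long(records), labels)
            width = float(curves["ci_high"].iloc[0] - curves["ci_low"].iloc[0])
            sd = np.sqrt(n / (n - 1))
            assert width == pytest.approx(2 * 1.96 * sd / np.sqrt(n), abs=1e-10)

    def test_underpowered_months_flagged(self):
        records = [("a", 0, "m", 1.0)]
        labels = pd.Series({"a": 1})
        curves = progression_curves(self._long(records), labels)
        assert curves["underpowered"].iloc[0]

    def test_horizon_filter(self):
        records = [("a", 0, "m", 1.0), ("a", 72, "m", 2.0), ("b", 0, "m", 0.0)]
        labels = pd.Series({"a": 1, "b": 1})
        curves = progression_curves(self._long(records), labels, horizon=60)
        assert set(curves["month"]) == {0}


def test_filter_conversion_records():
    visits = pd.DataFrame(
        {"sample_id": list("abcd"),
         "diagnosis": ["MCI", "CN", "AD", "MCI_TO_AD"]}
    )
    kept = filter_conversion_records(visits)
    assert list(kept["sample_id"]) == ["a", "c", "d"]
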