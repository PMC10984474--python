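"""AUC, cutoff optimization, survival comparison, direction calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stromascape import (
    DegenerateInputError,
    best_cutoff,
    classify_direction,
    combined_stratification,
    cox_fit,
    evaluate_gene,
    km_estimate,
    logrank_test,
    rank_by_auc,
    roc_auc_death,
)
from stromascape.prognosis import PrognosticResult, best_cutoff_logrank

from _oracles import auc_pairs_brute, auc_trapezoid, km_brute, logrank_brute, youden_brute


# -- AUC -----------------------------------------------------------------


def test_auc_perfect_separation_and_ties():
    assert roc_auc_death([1, 2, 5, 6], [0, 0, 1, 1]) == pytest.approx(1.0)
    assert roc_auc_death([3, 3, 3, 3], [0, 1, 0, 1]) == pytest.approx(0.5)


def test_auc_matches_exhaustive_pairs():
    values = [4.0, 7.0, 7.0, 2.0, 9.0, 1.0, 6.0, 7.0]
    events = [0, 1, 0, 0, 1, 0, 1, 1]
    assert roc_auc_death(values, events) == pytest.approx(
        auc_pairs_brute(values, events), abs=1e-10
    )


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_auc_rank_statistic_equals_trapezoidal_roc_area(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(6, 40))
    values = np.round(rng.normal(0, 1, n), 1)  # rounding forces ties
    events = rng.integers(0, 2, n)
    if events.sum() in (0, n):
        events[0] = 1 - events[0]
    assert roc_auc_death(values, events) == pytest.approx(
        auc_trapezoid(values, events), abs=1e-10
    )


def test_auc_single_class_is_degenerate():
    with pytest.raises(DegenerateInputError):
        roc_auc_death([1, 2, 3], [1, 1, 1])


# -- cutoff --------------------------------------------------------------


def test_cutoff_perfect_separation():
    res = best_cutoff([1.0, 2.0, 5.0, 6.0], [0, 0, 1, 1])
    assert 2.0 < res.cutoff < 5.0
    assert res.j == pytest.approx(1.0)


def test_cutoff_matches_exhaustive_search():
    rng = np.random.default_rng(3)
    values = np.round(rng.normal(5, 2, 10), 2)
    events = np.array([1, 0, 1, 0, 0, 1, 0, 1, 0, 0])
    res = best_cutoff(values, events)
    oracle_cut, oracle_j = youden_brute(values, events)
    assert res.cutoff == pytest.approx(oracle_cut)
    assert res.j == pytest.approx(oracle_j)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_cutoff_agrees_with_oracle_on_random_data(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(8, 30))
    values = np.round(rng.normal(0, 1, n), 1)
    events = rng.integers(0, 2, n)
    if events.sum() in (0, n):
        events[0] = 1 - events[0]
    if len(np.unique(values)) < 2:
        values[0] += 1.0
    res = best_cutoff(values, events)
    oracle_cut, oracle_j = youden_brute(values, events)
    assert res.j == pytest.approx(oracle_j, abs=1e-10)
    assert res.cutoff == pytest.approx(oracle_cut)


def test_cutoff_translation_equivariance():
    values = np.array([1.0, 4.0, 2.0, 8.0, 5.0, 9.0, 3.0, 7.0])
    events = np.array([0, 1, 0, 1, 0, 1, 0, 1])
    base = best_cutoff(values, events)
    shifted = best_cutoff(values + 11.5, events)
    assert shifted.cutoff == pytest.approx(base.cutoff + 11.5)
    assert shifted.j == pytest.approx(base.j)


def test_cutoff_constant_values_degenerate():
    with pytest.raises(DegenerateInputError):
        best_cutoff([5.0, 5.0, 5.0, 5.0], [0, 1, 0, 1])


def test_minp_logrank_cutoff_mode_runs():
    rng = np.random.default_rng(8)
    n = 60
    values = rng.normal(0, 1, n)
    times = rng.exponential(20 * np.exp(-values), n)
    events = np.ones(n, dtype=int)
    res = best_cutoff_logrank(values, times, events)
    assert res.n_high + res.n_low == n


# -- Kaplan-Meier --------------------------------------------------------


def test_km_hand_computed_product_limit():
    # 1 death, then a censoring, a death, a censoring:
    # S(1) = 3/4, S(3) = 3/4 * 1/2 = 3/8
    times = [1.0, 2.0, 3.0, 4.0]
    events = [1, 0, 1, 0]
    km = km_estimate(times, events)["all"]
    assert float(km.predict(1.0)) == pytest.approx(3 / 4)
    assert float(km.predict(3.0)) == pytest.approx(3 / 8)
    oracle = km_brute(times, events)
    assert float(km.predict(2.5)) == pytest.approx(oracle(2.5))


def test_km_no_events_stays_at_one():
    km = km_estimate([5.0, 8.0, 2.0], [0, 0, 0])["all"]
    assert float(km.predict(8.0)) == pytest.approx(1.0)


def test_km_all_deaths_at_one_time_drops_to_zero():
    km = km_estimate([1.0, 1.0, 1.0], [1, 1, 1])["all"]
    assert float(km.predict(1.0)) == pytest.approx(0.0)


def test_km_without_censoring_is_empirical_survival():
    rng = np.random.default_rng(12)
    times = rng.exponential(10, 25)
    km = km_estimate(times, np.ones(25, dtype=int))["all"]
    for q in [np.min(times), np.median(times), np.max(times)]:
        empirical = (times > q).mean()
        assert float(km.predict(q)) == pytest.approx(empirical, abs=1e-12)


# -- log-rank ------------------------------------------------------------


def test_logrank_identical_groups_null():
    times = [2.0, 4.0, 6.0, 2.0, 4.0, 6.0]
    events = [1, 0, 1, 1, 0, 1]
    groups = ["a", "a", "a", "b", "b", "b"]
    res = logrank_test(times, events, groups)
    assert res.chi2 == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0)


def test_logrank_matches_brute_force_tabulation():
    rng = np.random.default_rng(4)
    times = np.round(rng.exponential(10, 12), 1)
    events = rng.integers(0, 2, 12)
    events[:2] = 1
    groups = np.array(["a"] * 6 + ["b"] * 6)
    res = logrank_test(times, events, groups)
    chi2, p = logrank_brute(times, events, groups)
    assert res.chi2 == pytest.approx(chi2, abs=1e-10)
    assert res.p == pytest.approx(p, abs=1e-10)


def test_logrank_label_swap_invariance():
    rng = np.random.default_rng(9)
    times = rng.exponential(10, 20)
    events = rng.integers(0, 2, 20)
    events[0] = 1
    groups = np.array(["x"] * 11 + ["y"] * 9)
    swapped = np.where(groups == "x", "y", "x")
    assert logrank_test(times, events, groups).p == pytest.approx(
        logrank_test(times, events, swapped).p
    )


def test_logrank_monotone_time_relabeling_invariance():
    rng = np.random.default_rng(10)
    times = rng.exponential(10, 16)
    events = rng.integers(0, 2, 16)
    events[:3] = 1
    groups = np.array(["a"] * 8 + ["b"] * 8)
    base = logrank_test(times, events, groups)
    warped = logrank_test(np.sqrt(times), events, groups)  # monotone map
    assert warped.chi2 == pytest.approx(base.chi2, abs=1e-9)


def test_logrank_empty_group_is_error():
    with pytest.raises(ValueError):
        logrank_test([1.0, 2.0], [1, 1], ["a", "a"])


# -- Cox -----------------------------------------------------------------


def test_cox_sign_agrees_with_logrank_direction():
    rng = np.random.default_rng(21)
    n = 120
    group = rng.integers(0, 2, n)
    times = rng.exponential(np.where(group == 1, 5.0, 15.0))
    events = np.ones(n, dtype=int)
    df = pd.DataFrame({"time_months": times, "event": events, "g": group.astype(float)})
    res = cox_fit(df, covariates=["g"])
    assert res.at["g", "beta"] > 0  # group 1 dies faster -> positive log-HR
    lr = logrank_test(times, events, np.where(group == 1, "high", "low"))
    assert lr.p < 0.05


def test_cox_constant_covariate_rejected():
    df = pd.DataFrame({"time_months": [1.0, 2, 3, 4], "event": [1, 0, 1, 1],
                       "c": [2.0, 2.0, 2.0, 2.0]})
    with pytest.raises(DegenerateInputError):
        cox_fit(df, covariates=["c"])


def test_cox_null_covariate_small_beta():
    """Under the null (covariate independent of hazard, n = 1000) the
    estimate is near zero with a CI covering 0."""
    rng = np.random.default_rng(33)
    n = 1000
    z = rng.normal(0, 1, n)
    times = rng.exponential(10.0, n)
    df = pd.DataFrame({"time_months": times, "event": np.ones(n, dtype=int), "z": z})
    res = cox_fit(df, covariates=["z"])
    assert abs(res.at["z", "beta"]) < 0.1
    assert res.at["z", "ci_lower"] < 1.0 < res.at["z", "ci_upper"]


def test_cox_multivariate_with_categorical_covariates():
    rng = np.random.default_rng(44)
    n = 200
    z = rng.normal(0, 1, n)
    times = rng.exponential(10 * np.exp(-0.8 * z))
    df = pd.DataFrame(
        {
            "time_months": times,
            "event": np.ones(n, dtype=int),
            "z": z,
            "sex": rng.choice(["M", "F"], n),
            "age": rng.normal(65, 10, n),
        }
    )
    res = cox_fit(df)
    assert res.at["z", "hr"] > 1.5
    assert any(v.startswith("sex_") for v in res.index)


# -- direction, ranking, combination ------------------------------------


@pytest.mark.parametrize(
    "p,hr,expected",
    [
        (0.01, 2.0, "negative"),
        (0.01, 0.5, "positive"),
        (0.2, 2.0, "ns"),
        (0.049, 1.0, "ns"),
        (float("nan"), 2.0, "ns"),
    ],
)
def test_classify_direction(p, hr, expected):
    assert classify_direction(p, hr, alpha=0.05) == expected


def test_rank_by_auc_orders_and_breaks_ties():
    def pr(gene, auc):
        return PrognosticResult(gene, auc, 0.0, 1, 1, 0.0, 1.0, 1.0, "ns")

    ranked = rank_by_auc([pr("g1", 0.7), pr("g2", 0.6), pr("g3", 0.65)])
    assert [r.gene for r in ranked] == ["g1", "g3", "g2"]
    ranked = rank_by_auc([pr("b", 0.6), pr("a", 0.6)])
    assert [r.gene for r in ranked] == ["a", "b"]


def test_combined_stratification_degenerate_stratum():
    """An A-stratum whose members all fall on one side of B's cutoff is a
    not-evaluable sentinel, not an error."""
    rng = np.random.default_rng(55)
    n = 40
    a = np.concatenate([np.zeros(n - 1), [100.0]])  # a_high stratum of size 1
    b = rng.normal(0, 1, n)
    times = rng.exponential(10, n)
    events = np.concatenate([[0, 0, 0], np.ones(n - 3, dtype=int)])
    res = combined_stratification(a, b, times, events, min_group_frac=0.0)
    assert not res.strata["a_high"].evaluable
    assert res.strata["a_low"].evaluable


def test_evaluate_gene_bundles_consistent_fields():
    rng = np.random.default_rng(66)
    n = 150
    z = rng.normal(0, 1, n)
    event_times = rng.exponential(20 * np.exp(-0.9 * z))
    events = (event_times <= 15.0).astype(int)  # administrative censoring
    times = np.minimum(event_times, 15.0)
    res = evaluate_gene("G", z, times, events)
    assert res.n_high + res.n_low == n
    assert 0 <= res.auc <= 1
    assert res.direction in ("negative", "positive", "ns")
    assert res.auc > 0.5  # hazard increases with z, so deaths sit higher
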