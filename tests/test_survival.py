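"""Cox screening, K=2 grouping and log-rank, cross-checked against lifelines."""

import numpy as np
import pandas as pd
import pytest

from subpathsig.datatypes import DataError
from subpathsig.survival import (
    cox_multivariate,
    cox_univariate,
    cox_univariate_table,
    kmeans2_samples,
    logrank_test,
    split_two_groups,
)


def _simulate_ph(n, beta, seed, censor=0.3):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    lam = 0.1 * np.exp(beta * x)
    t_event = rng.exponential(1.0 / lam)
    t_cens = rng.exponential(1.0 / (0.1 * censor / (1 - censor)), size=n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return x, time, event


def test_negating_covariate_negates_coefficient():
    x, t, e = _simulate_ph(150, -0.4, seed=1)
    a = cox_univariate(x, t, e)
    b = cox_univariate(-x, t, e)
    assert a.coef == pytest.approx(-b.coef, abs=1e-10)
    assert a.se == pytest.approx(b.se, rel=1e-10)


def test_matches_lifelines_on_untied_data():
    """Breslow and Efron coincide without ties; lifelines is the oracle."""
    from lifelines import CoxPHFitter

    x, t, e = _simulate_ph(200, -0.5, seed=2)
    ours = cox_univariate(x, t, e)
    df = pd.DataFrame({"x": x, "time": t, "event": e})
    cph = CoxPHFitter().fit(df, duration_col="time", event_col="event")
    assert ours.coef == pytest.approx(float(cph.params_["x"]), abs=1e-6)
    assert ours.se == pytest.approx(float(cph.standard_errors_["x"]), abs=1e-6)
    assert ours.p == pytest.approx(float(cph.summary.loc["x", "p"]), abs=1e-6)


def test_recovers_planted_effect_within_three_se():
    x, t, e = _simulate_ph(500, -0.5, seed=3)
    fit = cox_univariate(x, t, e)
    assert abs(fit.coef - (-0.5)) < 3 * fit.se
    assert fit.hr < 1 and fit.ci[1] < 1


def test_hr_and_ci_consistency():
    x, t, e = _simulate_ph(100, 0.3, seed=4)
    fit = cox_univariate(x, t, e)
    assert fit.hr == pytest.approx(np.exp(fit.coef))
    lo, hi = fit.ci
    assert lo == pytest.approx(np.exp(fit.coef - 1.96 * fit.se))
    assert hi == pytest.approx(np.exp(fit.coef + 1.96 * fit.se))


def test_degenerate_inputs_flagged_not_raised():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    t = np.array([1.0, 2.0, 3.0, 4.0])
    no_events = cox_univariate(x, t, np.zeros(4))
    assert no_events.flag == "no_events" and no_events.p == 1.0
    constant = cox_univariate(np.ones(4), t, np.ones(4))
    assert constant.flag == "constant" and constant.p == 1.0


def test_breslow_ties_handled():
    # heavy ties in time; just require a clean, finite fit
    rng = np.random.default_rng(5)
    x = rng.normal(size=80)
    t = np.ceil(rng.exponential(5.0 * np.exp(-0.5 * x)))
    e = np.ones(80)
    fit = cox_univariate(x, t, e)
    assert fit.flag == "" and np.isfinite(fit.se)


def test_multivariate_single_column_matches_univariate():
    x, t, e = _simulate_ph(150, -0.4, seed=6)
    surv = pd.DataFrame({"time": t, "event": e}, index=[f"s{i}" for i in range(150)])
    X = pd.DataFrame({"x": x}, index=surv.index)
    multi = cox_multivariate(X, surv)["x"]
    uni = cox_univariate_table(X["x"], surv)
    assert multi.coef == pytest.approx(uni.coef, abs=5e-3)
    assert multi.se == pytest.approx(uni.se, rel=5e-3)


def test_multivariate_noise_covariate_barely_moves_signature():
    rng = np.random.default_rng(77)
    x, t, e = _simulate_ph(500, -0.5, seed=7)
    surv = pd.DataFrame({"time": t, "event": e}, index=[f"s{i}" for i in range(500)])
    X1 = pd.DataFrame({"sig": x}, index=surv.index)
    X2 = X1.assign(noise=rng.normal(size=500))
    a = cox_multivariate(X1, surv)["sig"]
    b = cox_multivariate(X2, surv)["sig"]
    assert abs(a.coef - b.coef) < 3 * a.se


def test_multivariate_collinear_flagged():
    x, t, e = _simulate_ph(60, -0.4, seed=8)
    surv = pd.DataFrame({"time": t, "event": e}, index=[f"s{i}" for i in range(60)])
    X = pd.DataFrame({"a": x, "b": x}, index=surv.index)  # exact duplicate
    res = cox_multivariate(X, surv)
    assert all(r.flag == "no_convergence" for r in res.values())


def test_multivariate_expands_categoricals():
    x, t, e = _simulate_ph(120, -0.3, seed=9)
    surv = pd.DataFrame({"time": t, "event": e}, index=[f"s{i}" for i in range(120)])
    X = pd.DataFrame(
        {"sig": x, "subtype": np.where(x > 0, "classical", "basal")}, index=surv.index
    )
    res = cox_multivariate(X, surv)
    assert set(res) == {"sig", "subtype=classical"}


def test_split_two_groups_separated_clusters():
    vals = pd.Series([0.0, 0.1, 0.2, 5.0, 5.1, 5.2], index=list("abcdef"))
    labels = split_two_groups(vals)
    assert set(labels[["a", "b", "c"]]) == {"low"}
    assert set(labels[["d", "e", "f"]]) == {"high"}


def test_split_invariant_to_sample_order():
    rng = np.random.default_rng(10)
    vals = pd.Series(rng.normal(size=50), index=[f"s{i}" for i in range(50)])
    shuffled = vals.sample(frac=1.0, random_state=1)
    a = split_two_groups(vals).sort_index()
    b = split_two_groups(shuffled).sort_index()
    assert (a == b).all()


def test_split_boundary_near_zero_on_standard_normal():
    rng = np.random.default_rng(11)
    vals = pd.Series(rng.normal(size=1000))
    labels = split_two_groups(vals)
    boundary = (vals[labels == "low"].max() + vals[labels == "high"].min()) / 2
    assert abs(boundary) < 0.3


def test_split_constant_rejected():
    with pytest.raises(DataError):
        split_two_groups(pd.Series([1.0] * 10))


def test_logrank_identical_groups_null():
    t = np.array([1.0, 2.0, 3.0, 4.0])
    e = np.array([1, 1, 0, 1])
    surv = pd.DataFrame(
        {"time": np.r_[t, t], "event": np.r_[e, e]}, index=[f"s{i}" for i in range(8)]
    )
    labels = pd.Series(["a"] * 4 + ["b"] * 4, index=surv.index)
    chi2, p = logrank_test(labels, surv)
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_logrank_label_swap_invariant():
    x, t, e = _simulate_ph(100, -0.8, seed=12)
    surv = pd.DataFrame({"time": t, "event": e}, index=[f"s{i}" for i in range(100)])
    labels = pd.Series(np.where(x > 0, "high", "low"), index=surv.index)
    swapped = labels.map({"high": "low", "low": "high"})
    assert logrank_test(labels, surv) == pytest.approx(logrank_test(swapped, surv))


def test_logrank_detects_planted_split():
    hits = 0
    for seed in range(50):
        x, t, e = _simulate_ph(500, -0.5, seed=100 + seed)
        surv = pd.DataFrame({"time": t, "event": e}, index=[f"s{i}" for i in range(500)])
        labels = split_two_groups(pd.Series(x, index=surv.index))
        _, p = logrank_test(labels, surv)
        hits += p < 0.05
    assert hits >= 45


def test_kmeans2_samples_matches_split_on_single_row():
    vals = pd.Series([0.0, 0.1, 0.2, 5.0, 5.1, 5.2], index=list("abcdef"))
    single = pd.DataFrame([vals])
    a = kmeans2_samples(single)
    b = split_two_groups(vals)
    assert (a == b).all()


def test_type_one_error_calibrated():
    """Null covariates reject at ~5%: fraction of p<0.05 within [0.02, 0.09]."""
    rng = np.random.default_rng(13)
    _, t, e = _simulate_ph(500, 0.0, seed=14)
    hits = sum(
        cox_univariate(rng.normal(size=500), t, e).p < 0.05 for _ in range(200)
    )
    assert 0.02 <= hits / 200 <= 0.09
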