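"""Cox proportional-hazards screening and two-group survival comparison.

The univariate fit is a hand-rolled Newton maximisation of the Cox partial
likelihood with Breslow tie handling — it is called once per (feature,
cohort) pair during screening, so it is written directly on numpy arrays.
Multivariate fits delegate to :class:`lifelines.CoxPHFitter`.  Degenerate
inputs (no events, constant covariate, non-convergence) come back as flagged
results with p = 1 rather than exceptions, so combination scoring over
thousands of features never aborts on a single bad row.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CoxFitResult, DataError

_NEWTON_TOL = 1e-8
_MAX_ITER = 100


def _flagged(flag: str, n: int, n_events: int) -> CoxFitResult:
    return CoxFitResult(coef=0.0, se=np.inf, p=1.0, n=n, n_events=n_events, flag=flag)


def cox_univariate(x, time, event) -> CoxFitResult:
    """Single-covariate Cox fit (Breslow ties, Newton iteration, Wald p).

    Parameters are per-sample arrays of equal length: a real covariate,
    positive follow-up times, and a 0/1 event indicator.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=float)
    if not (x.shape == t.shape == d.shape):
        raise DataError("cox_univariate: mismatched array lengths")
    n = x.size
    n_events = int(d.sum())
    if n_events < 2:
        return _flagged("no_events", n, n_events)
    if np.ptp(x) == 0:
        return _flagged("constant", n, n_events)

    order = np.argsort(t, kind="stable")
    x, t, d = x[order], t[order], d[order]
    # risk set of an event at time t_i = all samples with t_j >= t_i;
    # with ascending sort those are suffixes, aligned on tied times
    first_at_time = np.searchsorted(t, t, side="left")
    ev = d == 1
    xc = x - x.mean()  # centring stabilises exp() without changing the MLE

    beta = 0.0
    for _ in range(_MAX_ITER):
        eta = np.exp(beta * xc)
        s0 = np.cumsum(eta[::-1])[::-1]
        s1 = np.cumsum((xc * eta)[::-1])[::-1]
        s2 = np.cumsum((xc * xc * eta)[::-1])[::-1]
        i0, i1, i2 = s0[first_at_time][ev], s1[first_at_time][ev], s2[first_at_time][ev]
        mu = i1 / i0
        score = float(np.sum(xc[ev] - mu))
        info = float(np.sum(i2 / i0 - mu * mu))
        if not np.isfinite(score) or not np.isfinite(info) or info <= 0:
            return _flagged("no_convergence", n, n_events)
        step = score / info
        # damp wild early steps; keeps Newton within the likelihood's basin
        step = float(np.clip(step, -5.0, 5.0))
        beta += step
        if abs(step) < _NEWTON_TOL:
            se = 1.0 / np.sqrt(info)
            z = beta / se
            p = float(2.0 * stats.norm.sf(abs(z)))
            return CoxFitResult(coef=float(beta), se=float(se), p=p, n=n, n_events=n_events)
    return _flagged("no_convergence", n, n_events)


def cox_univariate_table(x, survival: pd.DataFrame) -> CoxFitResult:
    """Convenience wrapper aligning a covariate Series on a survival table."""
    s = pd.Series(x)
    s = s.reindex(survival.index)
    if s.isna().any():
        raise DataError("covariate missing for some survival samples")
    return cox_univariate(s.to_numpy(), survival["time"].to_numpy(), survival["event"].to_numpy())


def _expand_categoricals(X: pd.DataFrame) -> pd.DataFrame:
    """Indicator contrasts against the first level in sorted order."""
    out = {}
    for col in X.columns:
        s = X[col]
        if s.dtype.kind in "biufc":
            out[col] = s.astype(float)
        else:
            levels = sorted(s.astype(str).unique())
            for lv in levels[1:]:
                out[f"{col}={lv}"] = (s.astype(str) == lv).astype(float)
    return pd.DataFrame(out, index=X.index)


def cox_multivariate(X: pd.DataFrame, survival: pd.DataFrame) -> dict[str, CoxFitResult]:
    """Joint Cox fit over a covariate table; one result per expanded column.

    Categorical columns are expanded to indicators against the first sorted
    level.  Non-convergence (e.g. collinear covariates) returns every column
    flagged rather than raising.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    Xe = _expand_categoricals(X.loc[survival.index])
    n = len(survival)
    n_events = int(survival["event"].sum())
    df = Xe.copy()
    df["time"] = survival["time"].to_numpy(float)
    df["event"] = survival["event"].to_numpy(float)
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except (ConvergenceError, ValueError, np.linalg.LinAlgError):
        return {c: _flagged("no_convergence", n, n_events) for c in Xe.columns}
    out = {}
    for c in Xe.columns:
        out[c] = CoxFitResult(
            coef=float(cph.params_[c]),
            se=float(cph.standard_errors_[c]),
            p=float(cph.summary.loc[c, "p"]),
            n=n,
            n_events=n_events,
        )
    return out


def split_two_groups(activity) -> pd.Series:
    """Deterministic 1-d K-means (K=2) labels, ``high`` vs ``low``.

    Centroids start at the 25th/75th percentiles and Lloyd iterations run to
    convergence (<= 100 rounds); the cluster with the greater mean activity is
    ``high``.  Constant input cannot be split and raises.
    """
    a = pd.Series(activity, dtype=float)
    if len(a) < 4:
        raise DataError("split_two_groups needs >= 4 samples")
    x = a.to_numpy()
    if np.ptp(x) == 0:
        raise DataError("split_two_groups: constant activity")
    centers = np.percentile(x, [25.0, 75.0]).astype(float)
    if centers[0] == centers[1]:
        centers = np.array([x.min(), x.max()], dtype=float)
    assign = None
    for _ in range(100):
        new_assign = np.abs(x[:, None] - centers[None, :]).argmin(axis=1)
        for j in (0, 1):
            if np.any(new_assign == j):
                centers[j] = x[new_assign == j].mean()
        if assign is not None and np.array_equal(new_assign, assign):
            break
        assign = new_assign
    high = centers.argmax()
    labels = np.where(assign == high, "high", "low")
    return pd.Series(labels, index=a.index)


def kmeans2_samples(matrix: pd.DataFrame) -> pd.Series:
    """K=2 Euclidean clustering of samples on standardised feature rows.

    Used to split a cohort on a multi-feature signature.  Rows (features) are
    z-scored, initial centroids are the samples with the lowest/highest mean
    standardised activity, and Lloyd iterations run to convergence.  Labels
    are ``high``/``low`` by mean activity of the cluster.
    """
    X = matrix.to_numpy(float)
    if X.shape[1] < 4:
        raise DataError("kmeans2_samples needs >= 4 samples")
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = ((X - X.mean(axis=1, keepdims=True)) / sd).T  # samples x features
    proj = Z.mean(axis=1)
    if np.ptp(proj) == 0:
        raise DataError("kmeans2_samples: degenerate (constant) signature")
    centers = np.vstack([Z[proj.argmin()], Z[proj.argmax()]])
    assign = None
    for _ in range(100):
        d2 = ((Z[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_assign = d2.argmin(axis=1)
        for j in (0, 1):
            if np.any(new_assign == j):
                centers[j] = Z[new_assign == j].mean(axis=0)
        if assign is not None and np.array_equal(new_assign, assign):
            break
        assign = new_assign
    means = [proj[assign == j].mean() if np.any(assign == j) else -np.inf for j in (0, 1)]
    high = int(np.argmax(means))
    return pd.Series(np.where(assign == high, "high", "low"), index=matrix.columns)


def logrank_test(labels, survival: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, p)."""
    from lifelines.statistics import logrank_test as _lr

    lab = pd.Series(labels).reindex(survival.index)
    groups = lab.unique()
    if len(groups) != 2:
        raise DataError("logrank_test needs exactly two nonempty groups")
    m = lab == groups[0]
    if survival["event"].sum() < 1:
        raise DataError("logrank_test needs at least one event")
    res = _lr(
        survival.loc[m, "time"],
        survival.loc[~m, "time"],
        event_observed_A=survival.loc[m, "event"],
        event_observed_B=survival.loc[~m, "event"],
    )
    return float(res.test_statistic), float(res.p_value)
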