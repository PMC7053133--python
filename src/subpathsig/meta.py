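"""Inverse-variance meta-analysis of per-cohort hazard ratios.

Pooling happens on the log-HR scale.  Cochran's Q and I² quantify
heterogeneity; the model is chosen by the I² < 50% rule (fixed-effect below,
DerSimonian-Laird random-effects at or above).  Leave-one-out sensitivity,
platform subgroup pooling and funnel-plot data export round out the module.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import DataError, MetaResult, StudyEstimate

I2_THRESHOLD = 50.0


def _arrays(estimates: list[StudyEstimate]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if len(estimates) < 2:
        raise DataError("meta-analysis needs >= 2 studies")
    y = np.array([e.loghr for e in estimates], dtype=float)
    se = np.array([e.se for e in estimates], dtype=float)
    return y, se, [e.study for e in estimates]


def pool_fixed(estimates: list[StudyEstimate]) -> MetaResult:
    """Fixed-effect pooling with inverse-variance weights 1/SE²."""
    y, se, ids = _arrays(estimates)
    w = 1.0 / se**2
    pooled = float(np.sum(w * y) / np.sum(w))
    q, df, i2, tau2 = heterogeneity(estimates)
    return MetaResult(
        pooled_loghr=pooled,
        se=float(1.0 / np.sqrt(np.sum(w))),
        q=q,
        df=df,
        i2=i2,
        tau2=tau2,
        model="fixed",
        weights=pd.Series(w / w.sum(), index=ids),
    )


def heterogeneity(estimates: list[StudyEstimate]) -> tuple[float, int, float, float]:
    """Cochran's Q about the fixed pooled value, I² and DL tau².

    I² = max(0, (Q - df)/Q) * 100; tau² is the DerSimonian-Laird moment
    estimator floored at zero.
    """
    y, se, _ = _arrays(estimates)
    w = 1.0 / se**2
    pooled = np.sum(w * y) / np.sum(w)
    q = float(np.sum(w * (y - pooled) ** 2))
    df = len(y) - 1
    i2 = 0.0 if q == 0 else max(0.0, (q - df) / q) * 100.0
    c = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
    return q, df, float(i2), float(tau2)


def pool_random(estimates: list[StudyEstimate]) -> MetaResult:
    """DerSimonian-Laird random-effects pooling (weights 1/(SE² + tau²))."""
    y, se, ids = _arrays(estimates)
    q, df, i2, tau2 = heterogeneity(estimates)
    w = 1.0 / (se**2 + tau2)
    pooled = float(np.sum(w * y) / np.sum(w))
    return MetaResult(
        pooled_loghr=pooled,
        se=float(1.0 / np.sqrt(np.sum(w))),
        q=q,
        df=df,
        i2=i2,
        tau2=tau2,
        model="random",
        weights=pd.Series(w / w.sum(), index=ids),
    )


def pool_auto(estimates: list[StudyEstimate], i2_threshold: float = I2_THRESHOLD) -> MetaResult:
    """Fixed-effect pooling when I² < threshold, random-effects otherwise."""
    _, _, i2, _ = heterogeneity(estimates)
    return pool_fixed(estimates) if i2 < i2_threshold else pool_random(estimates)


def sensitivity_leave_one_out(estimates: list[StudyEstimate]) -> pd.DataFrame:
    """Re-pool (auto model) with each study excluded in turn.

    Rows are indexed by the omitted study; columns summarise the pooled
    estimate and heterogeneity of the remaining set.  Needs >= 3 studies.
    """
    if len(estimates) < 3:
        raise DataError("leave-one-out needs >= 3 studies")
    rows = {}
    for e in estimates:
        rest = [s for s in estimates if s is not e]
        r = pool_auto(rest)
        rows[e.study] = {
            "pooled_loghr": r.pooled_loghr,
            "pooled_hr": r.pooled_hr,
            "ci_low": r.ci_hr[0],
            "ci_high": r.ci_hr[1],
            "i2": r.i2,
            "model": r.model,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def subgroup_pool(estimates: list[StudyEstimate]) -> dict[str, MetaResult]:
    """Pool within each subgroup label plus an ``overall`` entry.

    A single-study subgroup cannot be pooled; it is reported as-is with a
    ``single_study`` flag (its own estimate, Q undefined as 0, I² 0).
    """
    out: dict[str, MetaResult] = {}
    groups: dict[str, list[StudyEstimate]] = {}
    for e in estimates:
        groups.setdefault(e.subgroup or "unlabelled", []).append(e)
    for name, members in sorted(groups.items()):
        if len(members) == 1:
            (m,) = members
            out[name] = MetaResult(
                pooled_loghr=m.loghr,
                se=m.se,
                q=0.0,
                df=0,
                i2=0.0,
                tau2=0.0,
                model="fixed",
                weights=pd.Series([1.0], index=[m.study]),
                flag="single_study",
            )
        else:
            out[name] = pool_auto(members)
    out["overall"] = pool_auto(estimates)
    return out


def funnel_data(estimates: list[StudyEstimate], pooled: MetaResult, n_grid: int = 50) -> dict[str, pd.DataFrame]:
    """Plot-ready funnel tables: per-study points and 95% pseudo-CI bounds.

    The bounds are ``pooled ± 1.96·SE`` evaluated over an SE grid from 0 to
    the largest study SE, the triangle a funnel plot draws.
    """
    y, se, ids = _arrays(estimates)
    points = pd.DataFrame({"study": ids, "loghr": y, "se": se})
    grid = np.linspace(0.0, float(se.max()), n_grid)
    bounds = pd.DataFrame(
        {
            "se": grid,
            "lower": pooled.pooled_loghr - 1.96 * grid,
            "upper": pooled.pooled_loghr + 1.96 * grid,
        }
    )
    return {"points": points, "bounds": bounds}
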