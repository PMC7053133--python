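"""Drug-sensitivity and chemotherapy-response association.

Signature activity is correlated (Spearman) with log IC50 across cell lines
of a molecular subtype; significance comes from a subtype-permutation test:
random cell-line subsets of the same size are drawn from the whole panel and
the p-value is the fraction of null correlations strictly below the observed
one (``p = N/B``, ``B`` = 10,000 draws by default).  That tail is one-sided
and only meaningful when the observed correlation is negative (higher
activity, greater sensitivity); a two-sided summary is also reported.
Patient response groups (CR/PR/SD/PD) are compared by Wilcoxon rank-sum.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

from .datatypes import DataError, PermutationResult

RESPONSE_LEVELS = ("CR", "PR", "SD", "PD")
DEFAULT_B = 10_000


def spearman_activity_ic50(activity, ic50_values) -> float:
    """Spearman rank correlation of activity vs IC50 (average-rank ties).

    IC50 is analysed on the log scale; being rank-based the correlation is
    unchanged, but callers conventionally pass log10(IC50).
    """
    a = np.asarray(activity, dtype=float)
    y = np.asarray(ic50_values, dtype=float)
    if a.shape != y.shape:
        raise DataError("activity and IC50 arrays differ in length")
    if a.size < 4:
        raise DataError("need >= 4 paired observations")
    if np.ptp(a) == 0 or np.ptp(y) == 0:
        raise DataError("constant vector: correlation undefined")
    rho, _ = stats.spearmanr(a, y)
    return float(rho)


def _rank_corr_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Spearman correlation of two (B, m) matrices."""
    ra = rankdata(a, method="average", axis=1)
    rb = rankdata(b, method="average", axis=1)
    ra = ra - ra.mean(axis=1, keepdims=True)
    rb = rb - rb.mean(axis=1, keepdims=True)
    num = (ra * rb).sum(axis=1)
    den = np.sqrt((ra**2).sum(axis=1) * (rb**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def subtype_permutation_test(
    activity, ic50, subtype_mask, b: int = DEFAULT_B, seed: int = 0
) -> PermutationResult:
    """Subtype-subset permutation test of the activity-IC50 correlation.

    The observed Spearman rho is computed on the samples flagged by
    ``subtype_mask``; ``b`` random subsets of the same size are drawn without
    replacement from *all* samples and the one-sided p is the fraction of
    null correlations strictly below the observed value.  Identical seeds
    give identical results.
    """
    a = np.asarray(activity, dtype=float)
    y = np.asarray(ic50, dtype=float)
    mask = np.asarray(subtype_mask, dtype=bool)
    if not (a.shape == y.shape == mask.shape):
        raise DataError("activity, IC50 and mask must have equal length")
    m = int(mask.sum())
    if m < 2 or m >= a.size:
        raise DataError(f"subtype subset size {m} must be in [2, n_samples)")
    observed = float(_rank_corr_rows(a[mask][None, :], y[mask][None, :])[0])
    if np.isnan(observed):
        raise DataError("constant subtype subset: observed correlation undefined")

    rng = np.random.default_rng(seed)
    # b subsets of size m without replacement, drawn via row-wise argpartition
    keys = rng.random((b, a.size))
    idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
    null = _rank_corr_rows(a[idx], y[idx])
    null = np.nan_to_num(null, nan=0.0)  # constant subset rows count as rho=0
    n_below = int(np.sum(null < observed))
    two_sided = float(np.mean(np.abs(null) >= abs(observed)))
    return PermutationResult(
        observed_rho=observed,
        b=b,
        n_below=n_below,
        p=n_below / b,
        seed=seed,
        two_sided_p=two_sided,
    )


def response_group_test(
    activity, response_labels, group_a=("CR", "PR", "SD"), group_b=("PD",)
) -> tuple[float, float]:
    """Wilcoxon rank-sum of activity between pooled response groups.

    Exact null distribution when both groups have <= 10 samples and no tied
    activities; tie-corrected normal approximation otherwise.  Returns
    (rank-sum statistic W of group_a, two-sided p).
    """
    a = pd.Series(activity, dtype=float)
    lab = pd.Series(response_labels).reindex(a.index)
    xa = a[lab.isin(group_a)].to_numpy()
    xb = a[lab.isin(group_b)].to_numpy()
    if xa.size == 0 or xb.size == 0:
        raise DataError("both response groups must be nonempty")
    pooled = np.concatenate([xa, xb])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (xa.size <= 10 and xb.size <= 10 and not has_ties) else "asymptotic"
    u, p = stats.mannwhitneyu(xa, xb, alternative="two-sided", method=method)
    w = float(u + xa.size * (xa.size + 1) / 2)  # U -> rank-sum of group_a
    return w, float(p)


def enumerate_subset_correlations(activity, ic50, subset_size: int) -> np.ndarray:
    """Spearman rho for every subset of the given size (exhaustive oracle)."""
    from itertools import combinations

    a = np.asarray(activity, dtype=float)
    y = np.asarray(ic50, dtype=float)
    out = []
    for combo in combinations(range(a.size), subset_size):
        ii = np.array(combo)
        ra = rankdata(a[ii])
        ry = rankdata(y[ii])
        ra = ra - ra.mean()
        ry = ry - ry.mean()
        den = np.sqrt((ra**2).sum() * (ry**2).sum())
        out.append(0.0 if den == 0 else float((ra * ry).sum() / den))
    return np.array(out)
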