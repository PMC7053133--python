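"""Integrated prognostic scoring and frequency-based signature selection.

The discovery procedure screens every feature (gene, subpathway, pathway) by
univariate Cox in each training cohort, averages -log10 Cox p-values over
every 5-, 6- or 7-cohort combination of the training sets (the integrated
prognostic score, *ipScore*), ranks each combination's features, and selects
candidates that appear in the top 30 of at least 20 of the 29 combinations.
Serial cumulative sets (sizes 3..30 from a ranked list) and K=2 log-rank
assessment on held-out cohorts measure how robustness accumulates with
signature size.
"""

from __future__ import annotations

import warnings
from itertools import combinations as _combinations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .activity import ActivityMatrix
from .datatypes import DataError
from .survival import cox_univariate_table, kmeans2_samples, logrank_test, split_two_groups

P_FLOOR = 1e-300
TOP_K = 30
FREQ_CUTOFF = 20
COMBINATION_SIZES = frozenset({5, 6, 7})


def enumerate_combinations(cohort_ids: list[str], sizes=COMBINATION_SIZES) -> list[tuple[str, ...]]:
    """All distinct cohort subsets of the given sizes, in deterministic order.

    Seven cohorts with sizes {5, 6, 7} give the canonical 21 + 7 + 1 = 29
    training-set combinations.
    """
    ids = list(cohort_ids)
    for s in sizes:
        if s > len(ids):
            raise DataError(f"combination size {s} exceeds {len(ids)} cohorts")
        if s < 1:
            raise DataError("combination sizes must be >= 1")
    out: list[tuple[str, ...]] = []
    for s in sorted(sizes):
        out.extend(tuple(c) for c in _combinations(ids, s))
    return out


def ip_score(pvalues) -> float:
    """Integrated prognostic score: mean of -log10(p) over cohorts.

    p-values below 1e-300 are clipped there so a numerically-zero p cannot
    dominate the mean with an infinity.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise DataError("ip_score needs at least one p-value")
    if np.any(p <= 0) or np.any(p > 1):
        raise DataError("p-values must lie in (0, 1]")
    return float(np.mean(-np.log10(np.clip(p, P_FLOOR, 1.0))))


def screen_cox_pvalues(activity: ActivityMatrix, survival: pd.DataFrame) -> pd.Series:
    """Univariate Cox p for every activity row against one cohort's survival."""
    out = {}
    for fid, row in activity.normalized.iterrows():
        out[fid] = cox_univariate_table(row, survival).p
    return pd.Series(out, name="p")


def ip_score_table(pvalue_matrix: pd.DataFrame, combos: list[tuple[str, ...]]) -> pd.DataFrame:
    """ipScore of every feature in every cohort combination.

    ``pvalue_matrix`` is features x cohorts of per-cohort Cox p-values;
    returns features x combinations (columns named by joined cohort ids).
    """
    logs = -np.log10(pvalue_matrix.clip(lower=P_FLOOR))
    cols = {}
    for combo in combos:
        cols["+".join(combo)] = logs[list(combo)].mean(axis=1)
    return pd.DataFrame(cols, index=pvalue_matrix.index)


def rank_and_topk(ipscores: pd.Series, k: int = TOP_K) -> list[str]:
    """Top-k feature ids by descending ipScore; ties broken lexicographically."""
    s = ipscores.sort_index().sort_values(ascending=False, kind="stable")
    if len(s) < k:
        warnings.warn(f"only {len(s)} features scored; returning all", stacklevel=2)
    return list(s.index[:k])


def serial_sets(ranked: list[str], min_size: int = 3, max_size: int = TOP_K) -> list[list[str]]:
    """Cumulative prefix sets of a ranked list: sizes 3, 4, ..., 30.

    A full top-30 list yields 28 serial sets (1st-3rd, 1st-4th, ..., 1st-30th).
    """
    if len(ranked) < max_size:
        warnings.warn(
            f"ranked list has {len(ranked)} < {max_size} features; truncating the series",
            stacklevel=2,
        )
    top = min(len(ranked), max_size)
    if top < min_size:
        raise DataError(f"need >= {min_size} ranked features")
    return [list(ranked[:n]) for n in range(min_size, top + 1)]


def assess_set_on_cohort(
    feature_ids, activity: ActivityMatrix, survival: pd.DataFrame
) -> tuple[float, float]:
    """Log-rank p of the K=2 sample split induced by a signature set.

    Samples are clustered (K-means, K = 2, Euclidean on standardised feature
    rows) on the set's activity profile; the two clusters are compared by
    log-rank.  Returns (chi-square, p).
    """
    ids = list(feature_ids)
    missing = [f for f in ids if f not in activity.normalized.index]
    if missing:
        raise DataError(f"features absent from activity matrix: {missing[:5]}")
    sub = activity.normalized.loc[ids]
    if isinstance(sub, pd.Series):
        sub = sub.to_frame().T
    if len(ids) == 1:
        # a one-feature signature is exactly the univariate K=2 split
        labels = split_two_groups(sub.iloc[0])
    else:
        labels = kmeans2_samples(sub)
    return logrank_test(labels, survival)


def frequency_select(
    top_lists: dict[str, list[str]], cutoff: int = FREQ_CUTOFF, exclude_self: bool = False
) -> pd.DataFrame:
    """Count each feature's appearances across the combinations' top-k lists.

    Returns a frame indexed by feature id with ``count`` (membership over all
    lists) and ``selected`` (count >= cutoff), sorted by descending count.
    ``exclude_self=True`` instead reports, for each feature, the maximum over
    combinations of its appearances in the *other* lists (count - 1 when it
    appears at all) — a documented variant of the same tally.
    """
    if not top_lists:
        raise DataError("frequency_select needs at least one top list")
    counts: dict[str, int] = {}
    for lst in top_lists.values():
        for fid in set(lst):
            counts[fid] = counts.get(fid, 0) + 1
    ser = pd.Series(counts, name="count")
    if exclude_self:
        ser = (ser - 1).clip(lower=0)
    out = pd.DataFrame({"count": ser})
    out["selected"] = out["count"] >= cutoff
    # descending count, ties by feature id
    return out.sort_index(kind="stable").sort_values("count", ascending=False, kind="stable")


def relevance_enrichment(candidate_genes, reference_genes, universe) -> float:
    """Upper-tail hypergeometric p for candidate/reference gene overlap.

    P(X >= observed overlap) when ``len(candidate)`` genes are drawn from a
    universe containing ``len(reference)`` reference (e.g. disease-associated)
    genes.
    """
    uni = set(universe)
    if not uni:
        raise DataError("empty gene universe")
    cand = set(candidate_genes) & uni
    ref = set(reference_genes) & uni
    overlap = len(cand & ref)
    if not cand:
        return 1.0
    return float(hypergeom.sf(overlap - 1, len(uni), len(ref), len(cand)))
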