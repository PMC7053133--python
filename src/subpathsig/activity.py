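"""Single-sample functional activity scoring.

The scoring follows a rank-weighting scheme in the FAIME family.  For each
sample, genes are ranked in descending order of expression (rank 1 = highest;
ties share the average rank).  Each gene receives the weight

    w = r * exp(sign * r / |N|)

with ``|N|`` the number of genes and ``sign = +1`` by default (``sign = -1``
gives weights that decrease with rank instead).  A feature set's raw activity
in a sample is the mean weight of its member genes minus the mean weight of
all non-member genes; raw activities are then z-normalised per feature across
samples (population SD).  Gene-level "activity" is the expression value
itself, normalised the same way.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datatypes import DataError, FeatureSet, GENE


@dataclass
class WeightVector:
    """Per-gene ranks and weights for one sample."""

    ranks: pd.Series
    weights: pd.Series


@dataclass
class ActivityMatrix:
    """Features x samples activity scores.

    ``raw`` holds the in-set minus out-of-set contrasts, ``normalized`` the
    per-feature z-scores.  ``qc`` records, per feature, how many listed genes
    were absent from the expression matrix and whether the raw row was
    constant (in which case the normalised row is all zeros).
    """

    raw: pd.DataFrame
    normalized: pd.DataFrame
    feature_means: pd.Series
    feature_sds: pd.Series
    qc: pd.DataFrame


def _descending_ranks(values: np.ndarray, axis: int = 0) -> np.ndarray:
    # rank 1 = highest expression; average ranks on ties
    return rankdata(-values, method="average", axis=axis)


def rank_weights(sample_expression, sign: int = +1) -> WeightVector:
    """Rank-based exponential weights for a single sample.

    Parameters
    ----------
    sample_expression
        Expression values for one sample (Series or 1-d array, >= 2 genes,
        all finite).
    sign
        +1 reproduces ``w = r * exp(r/|N|)`` (weights increase with rank);
        -1 selects the decreasing variant ``w = r * exp(-r/|N|)``.
    """
    x = pd.Series(sample_expression, dtype=float)
    if len(x) < 2:
        raise DataError("rank_weights needs at least 2 genes")
    if not np.isfinite(x.to_numpy()).all():
        raise DataError("rank_weights: non-finite expression values")
    if sign not in (+1, -1):
        raise ValueError("sign must be +1 or -1")
    r = _descending_ranks(x.to_numpy())
    w = r * np.exp(sign * r / len(x))
    return WeightVector(
        ranks=pd.Series(r, index=x.index), weights=pd.Series(w, index=x.index)
    )


def feature_activity(weights: WeightVector, feature: FeatureSet) -> float:
    """Raw activity: mean in-set weight minus mean out-of-set weight.

    Feature genes absent from the weight vector's universe are dropped; an
    empty effective set or an empty complement is an error.
    """
    universe = weights.weights.index
    members = [g for g in feature.genes if g in universe]
    if not members:
        raise DataError(f"feature {feature.id}: no genes present in expression universe")
    if len(members) == len(universe):
        raise DataError(f"feature {feature.id}: complement is empty")
    in_mask = universe.isin(members)
    w = weights.weights.to_numpy()
    return float(w[in_mask].mean() - w[~in_mask].mean())


def normalize_activity(raw_scores) -> tuple[np.ndarray, bool]:
    """z-score one feature's raw activities across samples (population SD).

    Returns ``(normalised, constant_flag)``; a constant row cannot be scaled
    and comes back as zeros with ``constant_flag=True``.
    """
    x = np.asarray(raw_scores, dtype=float)
    if x.size < 2:
        raise DataError("normalize_activity needs >= 2 samples")
    sd = x.std()  # population convention (ddof=0)
    if sd == 0:
        return np.zeros_like(x), True
    return (x - x.mean()) / sd, False


def score_matrix(
    expression: pd.DataFrame, features: list[FeatureSet], sign: int = +1
) -> ActivityMatrix:
    """Activity of every feature in every sample of an expression matrix.

    Subpathway/pathway features go through the rank-weight contrast; gene
    level features use the expression row directly.  Each feature row is then
    z-normalised across samples.
    """
    if expression.index.has_duplicates or expression.columns.has_duplicates:
        raise DataError("expression matrix has duplicate gene or sample ids")
    values = expression.to_numpy(float)
    if not np.isfinite(values).all():
        raise DataError("expression matrix contains non-finite values")
    n_genes, n_samples = values.shape
    if n_genes < 2:
        raise DataError("need >= 2 genes to rank")
    if n_samples < 2:
        raise DataError("need >= 2 samples to normalise across")

    ranks = _descending_ranks(values, axis=0)
    weights = ranks * np.exp(sign * ranks / n_genes)

    gene_pos = {g: i for i, g in enumerate(expression.index)}
    raw = np.empty((len(features), n_samples))
    n_missing = np.zeros(len(features), dtype=int)
    for fi, feat in enumerate(features):
        if feat.level == GENE:
            (gene,) = feat.genes
            if gene not in gene_pos:
                raise DataError(f"gene feature {feat.id} absent from expression matrix")
            raw[fi] = values[gene_pos[gene]]
            continue
        idx = [gene_pos[g] for g in feat.genes if g in gene_pos]
        n_missing[fi] = len(feat.genes) - len(idx)
        if not idx:
            raise DataError(f"feature {feat.id}: no genes present in expression universe")
        if len(idx) == n_genes:
            raise DataError(f"feature {feat.id}: complement is empty")
        mask = np.zeros(n_genes, dtype=bool)
        mask[idx] = True
        raw[fi] = weights[mask].mean(axis=0) - weights[~mask].mean(axis=0)

    means = raw.mean(axis=1)
    sds = raw.std(axis=1)
    constant = sds == 0
    norm = np.zeros_like(raw)
    nz = ~constant
    norm[nz] = (raw[nz] - means[nz, None]) / sds[nz, None]

    ids = [f.id for f in features]
    return ActivityMatrix(
        raw=pd.DataFrame(raw, index=ids, columns=expression.columns),
        normalized=pd.DataFrame(norm, index=ids, columns=expression.columns),
        feature_means=pd.Series(means, index=ids),
        feature_sds=pd.Series(sds, index=ids),
        qc=pd.DataFrame(
            {"n_missing_genes": n_missing, "constant_row": constant}, index=ids
        ),
    )
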