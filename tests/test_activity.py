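"""Rank-weight activity scoring against hand-computed and naive oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata, spearmanr

from subpathsig.activity import (
    feature_activity,
    normalize_activity,
    rank_weights,
    score_matrix,
)
from subpathsig.datatypes import DataError, FeatureSet


def naive_score(expr: pd.DataFrame, genes: set, sign: int = +1) -> np.ndarray:
    """Independent transcription of the scoring formulas, sample by sample."""
    out = []
    n = expr.shape[0]
    for s in expr.columns:
        x = expr[s]
        r = rankdata(-x.to_numpy())
        w = pd.Series(r * np.exp(sign * r / n), index=x.index)
        inw = w[w.index.isin(genes)]
        outw = w[~w.index.isin(genes)]
        out.append(inw.mean() - outw.mean())
    raw = np.array(out)
    return (raw - raw.mean()) / raw.std()


def test_two_gene_weights_match_hand_computation():
    wv = rank_weights(pd.Series([5.0, 1.0], index=["a", "b"]))
    assert wv.ranks.tolist() == [1.0, 2.0]
    np.testing.assert_allclose(wv.weights.to_numpy(), [1.6487212707, 5.4365636569], rtol=1e-9)


def test_decreasing_variant_flips_exponent_sign():
    wv = rank_weights(pd.Series([5.0, 1.0]), sign=-1)
    np.testing.assert_allclose(
        wv.weights.to_numpy(), [1 * np.exp(-0.5), 2 * np.exp(-1.0)], rtol=1e-12
    )


def test_weights_are_rank_based():
    x = pd.Series([0.2, 3.1, 1.5, -2.0])
    same = rank_weights(np.exp(x) + 7.0)  # strictly monotone transform
    np.testing.assert_array_equal(rank_weights(x).weights, same.weights)


def test_ties_share_average_rank():
    wv = rank_weights(pd.Series([2.0, 2.0, 1.0]))
    assert wv.ranks.tolist() == [1.5, 1.5, 3.0]


def test_single_gene_and_nonfinite_rejected():
    with pytest.raises(DataError):
        rank_weights(pd.Series([1.0]))
    with pytest.raises(DataError):
        rank_weights(pd.Series([1.0, np.nan]))


def test_feature_activity_hand_example():
    wv = rank_weights(pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd")))
    wv.weights[:] = [1.0, 2.0, 3.0, 4.0]  # fixed weights on genes a..d
    got = feature_activity(
        wv, FeatureSet(id="f", level="subpathway", genes=frozenset(["c", "d"]), parent="p")
    )
    assert got == pytest.approx((3.0 + 4.0) / 2 - (1.0 + 2.0) / 2)


def test_equal_weights_give_zero_activity():
    wv = rank_weights(pd.Series([1.0, 2.0, 3.0], index=list("abc")))
    wv.weights[:] = 5.0
    f = FeatureSet(id="f", level="subpathway", genes=frozenset("a"), parent="p")
    assert feature_activity(wv, f) == pytest.approx(0.0)


def test_complement_sign_identity():
    """sPA(N\\S) == -sPA(S): the contrast flips sign exactly under complement."""
    rng = np.random.default_rng(0)
    wv = rank_weights(pd.Series(rng.normal(size=10), index=[f"g{i}" for i in range(10)]))
    s = frozenset(["g0", "g3", "g7"])
    comp = frozenset(wv.weights.index) - s
    f_s = FeatureSet(id="s", level="subpathway", genes=s, parent="p")
    f_c = FeatureSet(id="c", level="subpathway", genes=comp, parent="p")
    assert feature_activity(wv, f_c) == pytest.approx(-feature_activity(wv, f_s))


def test_missing_genes_dropped_and_empty_set_rejected():
    wv = rank_weights(pd.Series([1.0, 2.0, 3.0], index=list("abc")))
    f = FeatureSet(id="f", level="subpathway", genes=frozenset(["a", "zz"]), parent="p")
    only_a = FeatureSet(id="g", level="subpathway", genes=frozenset(["a"]), parent="p")
    assert feature_activity(wv, f) == feature_activity(wv, only_a)
    with pytest.raises(DataError):
        feature_activity(wv, FeatureSet(id="h", level="subpathway", genes=frozenset(["zz"]), parent="p"))
    with pytest.raises(DataError):
        feature_activity(wv, FeatureSet(id="i", level="subpathway", genes=frozenset("abc"), parent="p"))


def test_normalize_two_points_population_sd():
    z, flag = normalize_activity([1.0, 3.0])
    np.testing.assert_allclose(z, [-1.0, 1.0])
    assert not flag


def test_normalize_constant_row_flagged_and_single_sample_rejected():
    z, flag = normalize_activity([2.0, 2.0, 2.0])
    assert flag and np.all(z == 0)
    with pytest.raises(DataError):
        normalize_activity([1.0])


def test_normalize_zscore_property():
    rng = np.random.default_rng(1)
    z, _ = normalize_activity(rng.normal(size=50))
    assert z.mean() == pytest.approx(0.0, abs=1e-12)
    assert z.std() == pytest.approx(1.0, rel=1e-12)


@pytest.mark.parametrize("sign", [+1, -1])
def test_score_matrix_equals_naive_oracle(toy_expression, sign):
    genes = {"a", "b"}
    feats = [FeatureSet(id="f", level="subpathway", genes=frozenset(genes), parent="p")]
    am = score_matrix(toy_expression, feats, sign=sign)
    np.testing.assert_allclose(
        am.normalized.loc["f"].to_numpy(), naive_score(toy_expression, genes, sign), rtol=1e-10
    )


def test_gene_level_activity_is_normalised_expression(toy_expression):
    feats = [FeatureSet(id="c", level="gene", genes=frozenset("c"))]
    am = score_matrix(toy_expression, feats)
    row = toy_expression.loc["c"].to_numpy()
    np.testing.assert_allclose(
        am.normalized.loc["c"].to_numpy(), (row - row.mean()) / row.std(), rtol=1e-12
    )


def test_quantile_transform_leaves_activity_unchanged(toy_expression, toy_features):
    am1 = score_matrix(toy_expression, toy_features[:2])
    transformed = np.exp(toy_expression / 2.0)  # strictly monotone
    am2 = score_matrix(transformed, toy_features[:2])
    np.testing.assert_allclose(am1.normalized.to_numpy(), am2.normalized.to_numpy(), atol=1e-12)


def test_sample_permutation_permutes_columns_only(toy_expression, toy_features):
    am1 = score_matrix(toy_expression, toy_features)
    perm = ["s3", "s1", "s2"]
    am2 = score_matrix(toy_expression[perm], toy_features)
    np.testing.assert_allclose(
        am1.normalized[perm].to_numpy(), am2.normalized.to_numpy(), atol=1e-12
    )


def test_duplicate_feature_rows_identical(toy_expression):
    f = FeatureSet(id="f", level="subpathway", genes=frozenset("ab"), parent="p")
    g = FeatureSet(id="g", level="subpathway", genes=frozenset("ab"), parent="p")
    am = score_matrix(toy_expression, [f, g])
    np.testing.assert_array_equal(
        am.normalized.loc["f"].to_numpy(), am.normalized.loc["g"].to_numpy()
    )


def test_random_set_null_mean_near_zero():
    """Exchangeability: mean raw activity over random sets is ~0 (within 3 SE)."""
    rng = np.random.default_rng(5)
    n_genes = 200
    expr = pd.Series(rng.normal(size=n_genes), index=[f"g{i}" for i in range(n_genes)])
    wv = rank_weights(expr)
    draws = []
    for _ in range(1000):
        genes = frozenset(rng.choice(expr.index, size=20, replace=False))
        f = FeatureSet(id="r", level="subpathway", genes=genes, parent="p")
        draws.append(feature_activity(wv, f))
    draws = np.array(draws)
    se = draws.std(ddof=1) / np.sqrt(len(draws))
    assert abs(draws.mean()) < 3 * se


def test_planted_activity_tracks_latent_factor(small_bundle):
    """The planted set's activity is strongly coupled to the latent factor.

    Under either exponent sign the weight r*exp(sign*r/|N|) grows with the
    rank number over 1..|N|, so the highest-expressed gene carries the
    smallest weight and in-set activity moves opposite to the factor; what
    matters downstream is that the coupling is strong (|rho| > 0.5).
    """
    cohort = small_bundle.cohorts[0]
    z = small_bundle.latent[cohort.name]
    for sign in (+1, -1):
        am = score_matrix(cohort.expression, [small_bundle.planted_set], sign=sign)
        rho, _ = spearmanr(am.normalized.iloc[0], z)
        assert rho < -0.5
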