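"""Entropy weighting, TOPSIS, product adjustment, parent aggregation.

The brute-force oracle below implements the entropy and TOPSIS formulas
with plain Python loops, independently of the vectorized module code, and
is the reference the module must match to 1e-12 on small matrices.
"""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from opswatch import (
    MCDAResult,
    NormalizedMatrix,
    SyntheticConfig,
    ToxicityMatrix,
    TransformationMap,
    adjusted_product_scores,
    aggregate_parent_products,
    composite_toxicity_scores,
    entropy_weights,
    generate_products,
    generate_toxicity,
    orient_normalize,
    topsis_scores,
)
from opswatch.synthetic import with_seed

from conftest import random_toxicity


# ---------------------------------------------------------------------------
# brute-force oracle (plain loops, no numpy)
# ---------------------------------------------------------------------------


def brute_entropy(rows):
    n, m = len(rows), len(rows[0])
    e = []
    for j in range(m):
        col = [r[j] for r in rows]
        s = sum(col)
        if s == 0:
            e.append(1.0)
            continue
        h = 0.0
        for x in col:
            p = x / s
            if p > 0:
                h -= p * math.log(p)
        e.append(h / math.log(n))
    deg = [1.0 - x for x in e]
    total = sum(deg)
    return e, [x / total for x in deg]


def brute_topsis(rows, weights):
    m = len(weights)
    v = [[weights[j] * r[j] for j in range(m)] for r in rows]
    best = [max(row[j] for row in v) for j in range(m)]
    worst = [min(row[j] for row in v) for j in range(m)]
    out = []
    for row in v:
        dp = math.sqrt(sum((row[j] - best[j]) ** 2 for j in range(m)))
        dm = math.sqrt(sum((row[j] - worst[j]) ** 2 for j in range(m)))
        out.append((dp, dm, dm / (dp + dm)))
    return out


def _normalized(values, columns=None):
    values = np.asarray(values, dtype=float)
    columns = columns or [f"i{j}" for j in range(values.shape[1])]
    return NormalizedMatrix(
        pd.DataFrame(values, columns=columns,
                     index=[f"e{i}" for i in range(values.shape[0])])
    )


# ---------------------------------------------------------------------------
# orientation normalization
# ---------------------------------------------------------------------------


def test_cost_column_flips():
    frame = pd.DataFrame({"IGC50": [10.0, 20.0]}, index=["a", "b"])
    R = orient_normalize(ToxicityMatrix(frame))
    np.testing.assert_allclose(R.frame["IGC50"], [1.0, 0.0])


def test_benefit_column_keeps_endpoints():
    frame = pd.DataFrame({"DILI": [0.0, 0.4, 1.0]}, index=list("abc"))
    R = orient_normalize(ToxicityMatrix(frame))
    np.testing.assert_allclose(R.frame["DILI"], [0.0, 0.4, 1.0])


def test_normalization_idempotent_on_endpoints():
    T = random_toxicity(5, seed=21)
    R1 = orient_normalize(T)
    # applying min-max again to already-[0,1] benefit columns changes nothing
    R2 = orient_normalize(
        ToxicityMatrix(R1.frame, {c: "benefit" for c in R1.frame.columns})
    )
    pd.testing.assert_frame_equal(R1.frame, R2.frame)
    assert R1.frame.to_numpy().min() == 0.0
    assert R1.frame.to_numpy().max() == 1.0


def test_constant_column_becomes_half_with_warning():
    frame = pd.DataFrame({"DILI": [0.3, 0.3, 0.3], "AMES toxicity": [0, 0.5, 1]},
                         index=list("abc"))
    with pytest.warns(UserWarning, match="constant"):
        R = orient_normalize(ToxicityMatrix(frame))
    np.testing.assert_allclose(R.frame["DILI"], 0.5)


def test_negative_probability_indicator_rejected():
    bad = pd.DataFrame({"DILI": [0.5, 0.7]}, index=["a", "b"])
    Tbad = ToxicityMatrix(bad)
    Tbad.frame.loc["a", "DILI"] = -0.1  # corrupt after construction
    with pytest.raises(ValueError, match="negative probability"):
        orient_normalize(Tbad)


# ---------------------------------------------------------------------------
# entropy weights
# ---------------------------------------------------------------------------


def test_constant_column_gets_zero_weight():
    R = _normalized([[0.2, 0.5], [0.9, 0.5], [0.4, 0.5]])
    ew = entropy_weights(R)
    assert ew.weights.iloc[1] == pytest.approx(0.0, abs=1e-12)
    assert ew.weights.iloc[0] == pytest.approx(1.0, abs=1e-12)


def test_entropy_hand_oracle():
    """Column (1, 0, 1): e = ln2/ln3; constant column: e = 1, w = 0."""
    R = _normalized([[1.0, 0.5], [0.0, 0.5], [1.0, 0.5]])
    ew = entropy_weights(R)
    assert ew.entropy.iloc[0] == pytest.approx(math.log(2) / math.log(3), abs=1e-12)
    assert ew.entropy.iloc[1] == pytest.approx(1.0, abs=1e-12)
    np.testing.assert_allclose(ew.weights, [1.0, 0.0], atol=1e-12)


def test_lower_entropy_means_higher_weight():
    rng = np.random.default_rng(22)
    R = _normalized(rng.uniform(size=(30, 6)))
    ew = entropy_weights(R)
    order_by_entropy = ew.entropy.sort_values().index
    order_by_weight = ew.weights.sort_values(ascending=False).index
    assert list(order_by_entropy) == list(order_by_weight)
    assert ew.weights.sum() == pytest.approx(1.0, abs=1e-9)
    assert (ew.weights >= 0).all()


def test_equal_concentration_columns_get_near_uniform_weights():
    """Beta(1, 1) indicators at n = 500 weigh within 0.02 of uniform."""
    from opswatch.data import PROBABILITY_INDICATORS

    params = {k: (1.0, 1.0) for k in PROBABILITY_INDICATORS}
    params.update({"BCF": (1.0, 0.6), "IGC50": (2.0, 0.7),
                   "LC50DM": (1.5, 0.7), "LC50FM": (1.8, 0.7)})
    devs = []
    for seed in range(10):
        cfg = SyntheticConfig(seed=300 + seed, indicator_params=params)
        T = generate_toxicity(cfg, [f"M{i}" for i in range(500)])
        sub = ToxicityMatrix(T.frame[list(PROBABILITY_INDICATORS)])
        ew = entropy_weights(orient_normalize(sub))
        devs.append(float((ew.weights - 1 / 20).abs().max()))
    assert max(devs) < 0.02


def test_all_constant_matrix_is_degenerate():
    R = _normalized([[0.5, 0.5], [0.5, 0.5]])
    with pytest.raises(ValueError, match="degenerate"):
        entropy_weights(R)


def test_most_dispersed_indicator_wins_weight(default_cfg):
    """The planted high-dispersion indicator takes the largest weight."""
    wins = 0
    for seed in range(20):
        cfg = with_seed(default_cfg, 100 + seed)
        T = generate_toxicity(cfg, [f"M{i}" for i in range(54)])
        ew = entropy_weights(orient_normalize(T))
        wins += ew.weights.idxmax() == "ototoxicity"
    assert wins >= 18


# ---------------------------------------------------------------------------
# TOPSIS
# ---------------------------------------------------------------------------


def _uniform_weights(columns):
    w = pd.Series(1.0 / len(columns), index=columns, name="weight")
    e = pd.Series(0.5, index=columns, name="entropy")
    from opswatch.mcda import EntropyWeights

    return EntropyWeights(entropy=e, weights=w)


def test_dominant_entity_scores_one():
    R = _normalized([[1.0, 1.0, 1.0], [0.0, 0.0, 0.0]])
    res = topsis_scores(R, _uniform_weights(R.frame.columns))
    np.testing.assert_allclose(res.closeness, [1.0, 0.0], atol=1e-12)


def test_topsis_hand_oracle():
    """Rows (1,1), (0,0), (1,0) with equal weights give C = (1, 0, 0.5)."""
    R = _normalized([[1.0, 1.0], [0.0, 0.0], [1.0, 0.0]])
    res = topsis_scores(R, _uniform_weights(R.frame.columns))
    np.testing.assert_allclose(res.closeness, [1.0, 0.0, 0.5], atol=1e-12)
    assert (res.frame["d_plus"] >= 0).all()
    assert (res.frame["d_minus"] >= 0).all()


def test_weight_scale_invariance():
    rng = np.random.default_rng(23)
    R = _normalized(rng.uniform(size=(6, 4)))
    ew = entropy_weights(R)
    res1 = topsis_scores(R, ew)
    from opswatch.mcda import EntropyWeights

    scaled = EntropyWeights(ew.entropy, (ew.weights * 7.0) / (ew.weights * 7.0).sum())
    res2 = topsis_scores(R, scaled)
    np.testing.assert_allclose(res1.closeness, res2.closeness, atol=1e-12)


def test_identical_entities_rejected():
    R = _normalized([[0.5, 0.2], [0.5, 0.2]])
    with pytest.raises(ValueError, match="no discrimination"):
        topsis_scores(R, _uniform_weights(R.frame.columns))


def test_permutation_equivariance():
    rng = np.random.default_rng(24)
    R = _normalized(rng.uniform(size=(8, 5)))
    ew = entropy_weights(R)
    res = topsis_scores(R, ew)
    perm = rng.permutation(8)
    Rp = NormalizedMatrix(R.frame.iloc[perm])
    resp = topsis_scores(Rp, entropy_weights(Rp))
    np.testing.assert_allclose(
        resp.closeness.loc[res.closeness.index], res.closeness, atol=1e-12
    )


def test_module_matches_brute_force_oracle():
    """Vectorized entropy/TOPSIS equals the loop oracle to 1e-12."""
    rng = np.random.default_rng(25)
    corpus = [rng.uniform(size=(n, m)) for n in (2, 4, 6) for m in (2, 3, 4)]
    corpus.append(np.array([[1.0, 1.0], [0.0, 0.0], [1.0, 0.0]]))
    for values in corpus:
        R = _normalized(values)
        ew = entropy_weights(R)
        e_ref, w_ref = brute_entropy(values.tolist())
        np.testing.assert_allclose(ew.entropy, e_ref, atol=1e-12)
        np.testing.assert_allclose(ew.weights, w_ref, atol=1e-12)
        res = topsis_scores(R, ew)
        ref = brute_topsis(values.tolist(), list(ew.weights))
        np.testing.assert_allclose(res.frame["d_plus"], [r[0] for r in ref],
                                   atol=1e-12)
        np.testing.assert_allclose(res.frame["d_minus"], [r[1] for r in ref],
                                   atol=1e-12)
        np.testing.assert_allclose(res.closeness, [r[2] for r in ref],
                                   atol=1e-12)


# ---------------------------------------------------------------------------
# product adjustment and aggregation
# ---------------------------------------------------------------------------


def test_adjusted_scores_multiply_mean_by_closeness():
    T = random_toxicity(2, seed=26)
    res = MCDAResult(
        pd.DataFrame(
            {"d_plus": [0.1, 0.7], "d_minus": [0.9, 0.3],
             "closeness": [0.9, 0.3]},
            index=T.frame.index,
        )
    )
    adjusted = adjusted_product_scores(T, res)
    means = orient_normalize(T).frame.mean(axis=1)
    np.testing.assert_allclose(adjusted, means * [0.9, 0.3])


def test_zero_closeness_zeroes_adjusted_score():
    T = random_toxicity(3, seed=27)
    res = MCDAResult(
        pd.DataFrame(
            {"d_plus": [1, 1, 0.5], "d_minus": [0, 1, 0.5],
             "closeness": [0.0, 0.5, 0.5]},
            index=T.frame.index,
        )
    )
    adjusted = adjusted_product_scores(T, res)
    assert adjusted.iloc[0] == 0.0


def test_adjusted_scores_name_mismatch():
    T = random_toxicity(2, seed=28)
    res = MCDAResult(
        pd.DataFrame({"d_plus": [1.0], "d_minus": [0.0], "closeness": [0.0]},
                     index=["other"])
    )
    with pytest.raises(ValueError, match="entity names"):
        adjusted_product_scores(T, res)


def test_aggregation_arithmetic():
    cols = ["DILI", "AMES toxicity"]
    parents = ToxicityMatrix(
        pd.DataFrame([[0.4, 0.4]], index=["p"], columns=cols)
    )
    products = ToxicityMatrix(
        pd.DataFrame([[0.8, 0.8], [0.0, 0.0]], index=["t1", "t2"], columns=cols)
    )
    tmap = TransformationMap({"p": ["t1", "t2"]})
    combined = aggregate_parent_products(parents, products, tmap)
    np.testing.assert_allclose(combined.frame.loc["p"], [0.4, 0.4])


def test_parent_without_products_unchanged():
    cols = ["DILI"]
    parents = ToxicityMatrix(
        pd.DataFrame([[0.3], [0.6]], index=["p", "q"], columns=cols)
    )
    products = ToxicityMatrix(pd.DataFrame([[0.9]], index=["t"], columns=cols))
    combined = aggregate_parent_products(
        parents, products, TransformationMap({"p": ["t"], "q": []})
    )
    assert combined.frame.loc["q", "DILI"] == 0.6
    assert combined.frame.loc["p", "DILI"] == pytest.approx(0.6)


def test_identity_products_leave_parents_unchanged(default_cfg):
    """With parent_mix 1 the combined matrix equals the parent matrix."""
    cfg = with_seed(SyntheticConfig(parent_mix=1.0), 29)
    parents = generate_toxicity(cfg, [f"M{i}" for i in range(12)])
    tmap, products = generate_products(cfg, parents)
    combined = aggregate_parent_products(parents, products, tmap)
    pd.testing.assert_frame_equal(combined.frame, parents.frame,
                                  check_names=False)


def test_missing_product_rejected():
    cols = ["DILI"]
    parents = ToxicityMatrix(pd.DataFrame([[0.3]], index=["p"], columns=cols))
    products = ToxicityMatrix(pd.DataFrame([[0.9]], index=["t"], columns=cols))
    with pytest.raises(ValueError, match="ghost"):
        aggregate_parent_products(
            parents, products, TransformationMap({"p": ["t", "ghost"]})
        )


def test_composite_scores_in_unit_interval(default_cfg):
    parents = generate_toxicity(default_cfg, [f"M{i}" for i in range(30)])
    tmap, products = generate_products(default_cfg, parents)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scores, weights = composite_toxicity_scores(parents, products, tmap)
    assert ((scores >= 0) & (scores <= 1)).all()
    assert weights.weights.sum() == pytest.approx(1.0)
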