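import itertools

import numpy as np
import pandas as pd
import pytest

import binsim
from binsim import (
    ContingencyQuadruple,
    Partition,
    ari_matrix,
    co_membership_stability,
    correlation_matrix,
    count_quadruple,
    exemplar_correlation_table,
    partition_ari,
)


def make_partition(labels, cluster_ids):
    """Build a Partition directly from cluster ids (exemplar = first member)."""
    cluster_ids = list(cluster_ids)
    exemplars = {}
    for i, c in enumerate(cluster_ids):
        exemplars.setdefault(c, i)
    assignment = [exemplars[c] for c in cluster_ids]
    return Partition(
        labels=tuple(labels),
        exemplars=tuple(sorted(exemplars.values())),
        assignment=tuple(assignment),
        objective=float("nan"),
    )


# ---------------------------------------------------------------- correlations

def test_correlation_hand_example():
    frame = pd.DataFrame({"x": [1.0, 2.0, 4.0], "y": [1.0, 3.0, 2.0]})
    res = correlation_matrix(frame)
    # hand Pearson r: cov = 1/3*(0*(-1)+ ... ) computed directly
    x, y = frame["x"], frame["y"]
    r = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
        ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
    )
    assert res.matrix.loc["x", "y"] == pytest.approx(r)
    assert res.matrix.loc["x", "x"] == 1.0


def test_constant_column_dropped():
    rng = np.random.default_rng(0)
    frame = pd.DataFrame({"x": rng.random(50), "y": rng.random(50), "c": 3.0})
    res = correlation_matrix(frame)
    assert ("c", "zero_variance") in res.dropped
    assert res.kept_keys == ("x", "y")


def test_undefined_heavy_column_dropped():
    rng = np.random.default_rng(1)
    frame = pd.DataFrame(
        {"x": rng.random(100), "y": rng.random(100), "z": rng.random(100)}
    )
    frame.loc[:10, "y"] = np.nan   # ~10% undefined
    res = correlation_matrix(frame)
    assert ("y", "undefined_values") in res.dropped
    assert res.kept_keys == ("x", "z")


def test_sparse_nans_handled_pairwise():
    rng = np.random.default_rng(2)
    frame = pd.DataFrame(rng.random((2000, 4)), columns=list("wxyz"))
    frame.loc[[3, 800], "y"] = np.nan  # 0.1%: retained, complete-case
    res = correlation_matrix(frame)
    assert res.kept_keys == ("w", "x", "y", "z")
    pd.testing.assert_frame_equal(
        res.matrix, frame.corr(), check_exact=False, atol=1e-12
    )


def test_affine_columns_correlate_exactly():
    rng = np.random.default_rng(3)
    x = rng.random(1000)
    res = correlation_matrix(pd.DataFrame({"x": x, "y": 2 * x - 1, "z": rng.random(1000)}))
    assert abs(res.matrix.loc["x", "y"] - 1) < 1e-12


def test_too_few_trials_rejected():
    with pytest.raises(ValueError):
        correlation_matrix(pd.DataFrame({"x": [1.0, 2.0]}))


# ------------------------------------------------------------------------ ARI

def test_ari_identical_and_permuted():
    p1 = make_partition("abcd", [0, 0, 1, 1])
    p2 = make_partition("abcd", [1, 1, 0, 0])
    assert partition_ari(p1, p1) == 1.0
    assert partition_ari(p1, p2) == 1.0


def test_ari_crossed_partitions_pair_count_value():
    # {1,1,2,2} vs {1,2,1,2}: 0 co-clustered pairs in both, expectation 2/3,
    # max 2 -> ARI = (0 - 2/3)/(2 - 2/3) = -1/2
    assert partition_ari([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(-0.5)


def test_ari_requires_same_label_set():
    p1 = make_partition("abc", [0, 0, 1])
    p2 = make_partition("abd", [0, 0, 1])
    with pytest.raises(ValueError):
        partition_ari(p1, p2)


def test_ari_matches_by_label_not_position():
    p1 = make_partition(["a", "b", "c", "d"], [0, 0, 1, 1])
    p2 = make_partition(["d", "c", "b", "a"], [1, 1, 0, 0])
    assert partition_ari(p1, p2) == 1.0


def _set_partitions(items):
    """All set partitions of a tuple of items (restricted-growth strings)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in _set_partitions(rest):
        for i, block in enumerate(smaller):
            yield smaller[:i] + [block + [first]] + smaller[i + 1:]
        yield [[first]] + smaller


def _pair_counting_ari(ids1, ids2):
    """Independent oracle: enumerate all item pairs and apply the adjusted
    pair-counting formula directly."""
    n = len(ids1)
    together_both = together_1 = together_2 = 0
    for i, j in itertools.combinations(range(n), 2):
        t1 = ids1[i] == ids1[j]
        t2 = ids2[i] == ids2[j]
        together_1 += t1
        together_2 += t2
        together_both += t1 and t2
    total = n * (n - 1) / 2
    expected = together_1 * together_2 / total
    maximum = (together_1 + together_2) / 2
    if maximum == expected:
        return 1.0 if together_both == maximum else 0.0
    return (together_both - expected) / (maximum - expected)


@pytest.mark.parametrize("n_items", [3, 4, 5])
def test_ari_exhaustive_vs_pair_counting_oracle(n_items):
    items = tuple(range(n_items))
    parts = []
    for blocks in _set_partitions(items):
        ids = [0] * n_items
        for c, block in enumerate(blocks):
            for i in block:
                ids[i] = c
        parts.append(ids)
    for ids1 in parts:
        for ids2 in parts:
            assert partition_ari(ids1, ids2) == pytest.approx(
                _pair_counting_ari(ids1, ids2), abs=1e-12
            )


def test_ari_cross_checked_against_sklearn():
    from sklearn.metrics import adjusted_rand_score

    rng = np.random.default_rng(4)
    for _ in range(50):
        a = rng.integers(0, 3, 20)
        b = rng.integers(0, 3, 20)
        assert partition_ari(a, b) == pytest.approx(
            adjusted_rand_score(a, b), abs=1e-12
        )


def test_partition_ari_agrees_with_ari_coefficient():
    """Two binary attributes are 2-cluster partitions of the observations;
    the partition-agreement ARI must equal the coefficient form evaluated on
    their contingency quadruple."""
    rng = np.random.default_rng(5)
    for _ in range(25):
        x1 = rng.integers(0, 2, 30)
        x2 = rng.integers(0, 2, 30)
        if len(set(x1)) < 2 or len(set(x2)) < 2:
            continue
        q = count_quadruple(x1, x2)
        assert partition_ari(x1, x2) == pytest.approx(
            binsim.evaluate("ari", q), abs=1e-10
        )


def test_ari_matrix_structure():
    p = make_partition("abcde", [0, 0, 1, 1, 1])
    q = make_partition("abcde", [0, 1, 0, 1, 1])
    mat = ari_matrix({"one": p, "two": q, "three": p})
    assert mat.shape == (3, 3)
    assert (np.diag(mat.to_numpy()) == 1.0).all()
    assert mat.loc["one", "three"] == 1.0
    assert mat.loc["one", "two"] == mat.loc["two", "one"]


# -------------------------------------------------------------------- stability

def test_co_membership_counts():
    p1 = make_partition("wxyz", [0, 0, 1, 1])
    p2 = make_partition("wxyz", [0, 0, 0, 1])
    rep = co_membership_stability({"a": p1, "b": p2})
    assert rep.co_membership_counts.loc["w", "x"] == 2
    assert rep.co_membership_counts.loc["w", "y"] == 1
    assert rep.co_membership_counts.loc["w", "w"] == 2
    assert rep.threshold == rep.n_partitions == 2
    assert ("w", "x") in [tuple(s[:2]) for s in rep.subsets]
    assert rep.subset_containing("w") == ("w", "x")
    assert rep.subset_containing("y") == ("y",)   # singleton -> ungrouped
    assert "y" in rep.ungrouped


def test_full_threshold_subsets_are_cliques():
    rng = np.random.default_rng(6)
    labels = [f"i{j}" for j in range(12)]
    parts = {
        t: make_partition(labels, rng.integers(0, 3, 12)) for t in range(5)
    }
    rep = co_membership_stability(parts)
    counts = rep.co_membership_counts
    for subset in rep.subsets:
        for x, y in itertools.combinations(subset, 2):
            assert counts.loc[x, y] == rep.n_partitions


def test_lower_threshold_uses_maximal_cliques():
    p1 = make_partition("abcd", [0, 0, 0, 1])
    p2 = make_partition("abcd", [0, 0, 1, 1])
    p3 = make_partition("abcd", [0, 1, 1, 1])
    rep = co_membership_stability({1: p1, 2: p2, 3: p3}, threshold=2)
    # counts: ab=2, bc=2, cd=2, ac=1, bd=1, ad=0 -> maximal cliques {a,b},{b,c},{c,d}
    assert set(rep.subsets) == {("a", "b"), ("b", "c"), ("c", "d")}


# ------------------------------------------------------------- exemplar table

def test_exemplar_table_and_missing_key_error():
    rng = np.random.default_rng(7)
    frame = pd.DataFrame(rng.random((100, 3)), columns=["p", "q", "r"])
    res = correlation_matrix(frame)
    table = exemplar_correlation_table({"cond": res}, [("p", "q"), ("q", "r")])
    assert list(table.columns) == ["p~q", "q~r"]
    assert table.loc["cond", "p~q"] == res.matrix.loc["p", "q"]
    with pytest.raises(KeyError, match="missing"):
        exemplar_correlation_table({"cond": res}, [("p", "missing")])
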