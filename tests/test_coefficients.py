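import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import binsim
from binsim import ContingencyQuadruple, evaluate, evaluate_all, evaluate_trials
from binsim.coefficients import (
    attribute_similarity,
    coefficient_metadata,
    keys,
    loevinger_h_values,
    odds_ratio_values,
    registry,
)

Q = ContingencyQuadruple

positive_cells = st.integers(min_value=1, max_value=40)
positive_quadruples = st.tuples(
    positive_cells, positive_cells, positive_cells, positive_cells
)

# Every coefficient evaluated by hand on the quadruple (a,b,c,d) = (2,1,1,6):
# n = 10, margins 3/3/7/7, ad - bc = 11, chi2 = 1210/441,
# pair counts N=45, A=16, B=8, C=8, D=13.
_CHI2 = 1210 / 441
HAND_VALUES_2116 = {
    "dice_i": 2 / 3,
    "dice_ii": 2 / 3,
    "jaccard": 1 / 2,
    "sw_jaccard": 3 / 4,
    "gleason": 2 / 3,
    "kulczynski_i": 1.0,
    "kulczynski_ii": 2 / 3,
    "driver_kroeber": 2 / 3,
    "braun_blanquet": 2 / 3,
    "simpson": 2 / 3,
    "sorgenfrei": 4 / 9,
    "mountford": 2 / 3,
    "fager_mcgowan": 2 / 3 - 0.5 / math.sqrt(3),
    "sokal_sneath_i": 1 / 3,
    "mcconnaughey": 1 / 3,
    "johnson": 4 / 3,
    "van_der_maarel": 1 / 3,
    "ct4": math.log(3) / math.log(5),
    "russell_rao": 0.2,
    "ct3": math.log(3) / math.log(11),
    "sokal_michener": 0.8,
    "rogers_tanimoto": 2 / 3,
    "sokal_sneath_ii": 8 / 9,
    "sokal_sneath_iii": 4.0,
    "faith": 0.5,
    "gower_legendre": 8 / 9,
    "gower": 8 / 21,
    "austin_colwell": 2 / math.pi * math.asin(math.sqrt(0.8)),
    "ct1": math.log(9) / math.log(11),
    "hamann": 0.6,
    "peirce_i": 11 / 21,
    "peirce_ii": 11 / 21,
    "yule_q": 11 / 13,
    "yule_w": (math.sqrt(12) - 1) / (math.sqrt(12) + 1),
    "pearson_i": _CHI2,
    "pearson_ii": math.sqrt(_CHI2 / (10 + _CHI2)),
    "phi": 11 / 21,
    "michael": 11 / 17,
    "cole_i": 11 / 21,
    "cole_ii": 11 / 21,
    "cohen": 11 / 21,
    "maxwell_pilliner": 11 / 21,
    "dennis": 11 / math.sqrt(90),
    "dispersion": 0.11,
    "ct5": (math.log(13) - math.log(2)) / math.log(26),
    "stiles": math.log10(360 / 441),
    "scott": 11 / 21,   # (4*12 - 4) / (6 * 14), consistent with 2*RG - 1
    "tetrachoric": math.cos(math.pi / (1 + math.sqrt(12))),
    "odds_ratio": 12.0,
    "rand": 29 / 45,
    "ari": 2 / 7,
    "loevinger_h": -1 / 9,
    "sokal_sneath_iv": 16 / 21,
    "sokal_sneath_v": 4 / 7,
    "rogot_goldberg": 16 / 21,
    "baroni_urbani_buser_i": (math.sqrt(12) + 2) / (math.sqrt(12) + 4),
    "peirce_iii": 0.3,
    "hawkins_dotson": 0.625,
    "tarantula": 14 / 3,
    "harris_lahey": 5.75,
    "forbes_i": 20 / 9,
    "baroni_urbani_buser_ii": math.sqrt(12) / (math.sqrt(12) + 4),
    "fossum": 2.5,
    "forbes_ii": 11 / 21,
    "eyraud": 1100 / 441,
    "tarwid": 11 / 29,
    "goodman_kruskal_i": 1 / 3,
    "anderberg": 0.1,
    "goodman_kruskal_ii": 1 / 3,
    "gilbert_wells": math.log(20 / 9),
    "ct2": (math.log(11) - math.log(3)) / math.log(11),
}


def test_registry_metadata():
    meta = coefficient_metadata()
    assert len(meta) == 71
    assert len({m.appendix_id for m in meta}) == 71
    assert [m.appendix_id for m in meta] == list(range(1, 72))
    no_d = [m for m in meta if m.family == "cooccurrence_no_d"]
    assert len(no_d) == 18
    assert all(not m.uses_negative_matches for m in no_d)
    reg = registry()
    assert not reg["jaccard"].uses_negative_matches
    assert reg["rand"].family == "pair_counting"
    assert reg["ari"].family == "pair_counting"
    assert reg["pearson_i"].family == "chi_square_type"


@pytest.mark.parametrize("key", sorted(HAND_VALUES_2116))
def test_hand_computed_values(key):
    assert evaluate(key, Q(2, 1, 1, 6)) == pytest.approx(HAND_VALUES_2116[key], abs=1e-12)


def test_hand_values_cover_whole_registry():
    assert set(HAND_VALUES_2116) == set(keys())


def test_independence_quadruple():
    s = evaluate_all(Q(1, 1, 1, 1))
    assert len(s) == 71
    assert s["phi"] == 0
    assert s["jaccard"] == pytest.approx(1 / 3)
    assert s["sokal_michener"] == 0.5
    assert s["hamann"] == 0
    assert s["odds_ratio"] == 1


def test_undefined_values_are_nan_not_errors():
    s = evaluate_all(Q(0, 0, 0, 4))
    assert np.isnan(s["jaccard"])       # a + b + c = 0
    assert s["sokal_michener"] == 1.0
    assert np.isnan(evaluate("odds_ratio", Q(3, 0, 2, 5)))   # bc = 0
    assert np.isnan(evaluate("tarantula", Q(3, 1, 0, 6)))    # c(a+b) = 0
    assert np.isnan(evaluate("kulczynski_i", Q(4, 0, 0, 6)))  # b + c = 0


def test_unknown_key_raises():
    with pytest.raises(KeyError):
        evaluate("sokal", Q(1, 1, 1, 1))


def test_domain_scan_positive_cells():
    """With every cell >= 1 only the Stiles knife-edge can be undefined."""
    quads = np.array(list(itertools.product(range(1, 6), repeat=4)))
    frame = evaluate_trials(quads)
    nan_cols = frame.columns[frame.isna().any()].tolist()
    assert nan_cols == ["stiles"]
    # and the Stiles holes are exactly the |ad - bc| == n/2 quadruples
    a, b, c, d = quads.T
    knife = np.abs(np.abs(a * d - b * c) - (a + b + c + d) / 2) == 0
    assert (frame["stiles"].isna().to_numpy() == knife).all()


@given(positive_quadruples)
def test_affine_identities(t):
    s = evaluate_all(Q(*t))
    assert s["hamann"] == pytest.approx(2 * s["sokal_michener"] - 1, abs=1e-10)
    assert s["scott"] == pytest.approx(2 * s["rogot_goldberg"] - 1, abs=1e-10)
    assert s["van_der_maarel"] == pytest.approx(2 * s["gleason"] - 1, abs=1e-10)
    assert s["johnson"] == pytest.approx(2 * s["kulczynski_ii"], abs=1e-10)
    assert s["mcconnaughey"] == pytest.approx(s["johnson"] - 1, abs=1e-10)
    assert s["sokal_sneath_ii"] == pytest.approx(s["gower_legendre"], abs=1e-12)
    assert s["baroni_urbani_buser_ii"] == pytest.approx(
        2 * s["baroni_urbani_buser_i"] - 1, abs=1e-10
    )


@given(positive_quadruples)
def test_range_hints(t):
    s = evaluate_all(Q(*t))
    for key in ("jaccard", "gleason", "sokal_michener", "russell_rao"):
        assert 0 <= s[key] <= 1
    for key in ("phi", "hamann", "yule_q", "cohen"):
        assert -1 - 1e-12 <= s[key] <= 1 + 1e-12


@given(positive_quadruples)
def test_symmetry_under_attribute_swap(t):
    q = Q(*t)
    sym = ("jaccard", "phi", "sokal_michener", "gleason", "yule_q", "scott",
           "kulczynski_ii", "driver_kroeber", "rand", "ari", "odds_ratio")
    left = evaluate_all(q)
    right = evaluate_all(q.swapped())
    for key in sym:
        assert left[key] == pytest.approx(right[key], abs=1e-12)


@given(st.integers(1, 30), st.integers(1, 30))
def test_perfect_match_limit(a, d):
    s = evaluate_all(Q(a, 0, 0, d))
    for key in ("jaccard", "sokal_michener", "phi", "yule_q"):
        assert s[key] == pytest.approx(1.0)


def test_goodman_kruskal_zero_iff_tau_equal():
    """Brute force over all quadruples with n <= 12: where defined,
    GK-I = 0 <=> tau1 = tau2; the formula is undefined exactly when its
    denominator 2n - tau2 vanishes (one attribute constant both ways)."""
    for t in itertools.product(range(13), repeat=4):
        n = sum(t)
        if not 0 < n <= 12:
            continue
        a, b, c, d = t
        tau1 = max(a, b) + max(c, d) + max(a, c) + max(b, d)
        tau2 = max(a + c, b + d) + max(a + b, c + d)
        v = evaluate("goodman_kruskal_i", Q(*t))
        if tau2 == 2 * n:
            assert np.isnan(v)
        else:
            assert (v == 0) == (tau1 == tau2)


def test_loevinger_variants():
    # hand value with supplied population rates: 1 - b/(n pi1 pi2)
    v = loevinger_h_values(
        np.array([2.0]), np.array([1.0]), np.array([1.0]), np.array([6.0]),
        base_rates=(0.2, 0.6),
    )
    assert v[0] == pytest.approx(1 - 1 / (10 * 0.2 * 0.6))
    m = loevinger_h_values(
        np.array([2.0]), np.array([1.0]), np.array([1.0]), np.array([6.0]),
        base_rates=(0.2, 0.6), variant="mokken",
    )
    assert m[0] == pytest.approx(1 - 1 / (10 * 0.2 * 0.4))
    with pytest.raises(ValueError):
        loevinger_h_values(1, 1, 1, 1, base_rates=(0.9, 0.1))
    with pytest.raises(ValueError):
        loevinger_h_values(1, 1, 1, 1, variant="bogus")


def test_loevinger_margin_fallback_uses_smaller_margin_mismatch():
    # margins r1 = .6 > r2 = .4 -> the error cell is c, rates swap
    v = loevinger_h_values(np.array([3.0]), np.array([3.0]),
                           np.array([1.0]), np.array([3.0]))
    assert v[0] == pytest.approx(1 - 1 / (10 * 0.4 * 0.6))


def test_odds_ratio_haldane():
    assert np.isnan(odds_ratio_values(3, 0, 2, 5)[()])
    v = odds_ratio_values(3, 0, 2, 5, haldane=True)
    assert v[()] == pytest.approx((3.5 * 5.5) / (0.5 * 2.5))


def test_evaluate_trials_shape_and_order():
    quads = np.array([[2, 1, 1, 6], [1, 1, 1, 1]])
    frame = evaluate_trials(quads)
    assert frame.shape == (2, 71)
    assert list(frame.columns) == keys()
    assert frame.loc[0, "jaccard"] == 0.5


def test_attribute_similarity_matches_pairwise_counts(rng):
    X = rng.integers(0, 2, size=(40, 5))
    sim = attribute_similarity(X, "jaccard")
    assert sim.shape == (5, 5)
    from binsim import count_quadruple

    for i in range(5):
        for j in range(5):
            expected = evaluate("jaccard", count_quadruple(X[:, i], X[:, j]))
            got = sim.iloc[i, j]
            assert got == pytest.approx(expected, nan_ok=True)


def test_attribute_similarity_rejects_nonbinary():
    with pytest.raises(ValueError):
        attribute_similarity(np.array([[0, 2], [1, 0]]), "jaccard")
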