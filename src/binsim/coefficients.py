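"""Registry of 71 binary similarity coefficients on 2x2 contingency tables.

Every coefficient maps a quadruple ``(a, b, c, d)`` to a real number.  The
registry covers the co-occurrence family (with and without negative
matches), the association family (built on the table determinant
``ad - bc``), chi-square-type measures, the pair-counting Rand and adjusted
Rand indices, Loevinger's H, and an assortment of logarithmic and
trigonometric variants.

Undefined values
----------------
A coefficient is *undefined* on a quadruple when a denominator vanishes or a
logarithm/square-root argument leaves its domain (for example Jaccard on
``(0, 0, 0, d)``, or the odds ratio when ``bc = 0``).  Evaluation never
raises for such quadruples: the value is NaN, which downstream correlation
code treats by complete-case handling.  Where a formula has a finite
continuous limit (the tetrachoric approximation as ``bc -> 0``) the limit is
returned.

Base rates
----------
Loevinger's H is defined through the base rates ``pi1 <= pi2`` of the two
attributes.  When the population rates are known (as in a designed
simulation) they should be supplied via ``base_rates=``; otherwise the
sample margins ``(a+b)/n`` and ``(a+c)/n`` are used.  See
:func:`loevinger_h_values` for the variants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .quadruples import ContingencyQuadruple

__all__ = [
    "CoefficientDefinition",
    "FAMILIES",
    "registry",
    "coefficient_metadata",
    "keys",
    "labels",
    "evaluate",
    "evaluate_all",
    "evaluate_trials",
    "loevinger_h_values",
    "odds_ratio_values",
    "attribute_similarity",
]

FAMILIES = (
    "cooccurrence_no_d",
    "cooccurrence_with_d",
    "association",
    "chi_square_type",
    "pair_counting",
    "other",
)


@dataclass(frozen=True)
class CoefficientDefinition:
    key: str
    label: str
    appendix_id: int
    family: str
    uses_negative_matches: bool
    range_hint: Optional[Tuple[float, float]]
    func: Callable[..., np.ndarray]


_REGISTRY: Dict[str, CoefficientDefinition] = {}


def _register(key, label, appendix_id, family, uses_d, range_hint=None, needs_rates=False):
    def deco(fn):
        if needs_rates:
            func = fn
        else:
            def func(a, b, c, d, base_rates=None, _fn=fn):
                return _fn(a, b, c, d)
        if key in _REGISTRY:
            raise ValueError(f"duplicate coefficient key {key!r}")
        _REGISTRY[key] = CoefficientDefinition(
            key=key, label=label, appendix_id=appendix_id, family=family,
            uses_negative_matches=uses_d, range_hint=range_hint, func=func,
        )
        return fn
    return deco


def _chi2(a, b, c, d):
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (a + c) * (b + d) * (c + d))


# --- co-occurrence coefficients that do not use negative matches (A.1-A.18) ---

@_register("dice_i", "Dice I", 1, "cooccurrence_no_d", False, (0, 1))
def _dice_i(a, b, c, d):
    return a / (a + b)


@_register("dice_ii", "Dice II", 2, "cooccurrence_no_d", False, (0, 1))
def _dice_ii(a, b, c, d):
    return a / (a + c)


@_register("jaccard", "Jaccard", 3, "cooccurrence_no_d", False, (0, 1))
def _jaccard(a, b, c, d):
    return a / (a + b + c)


@_register("sw_jaccard", "SWJaccard", 4, "cooccurrence_no_d", False, (0, 1))
def _sw_jaccard(a, b, c, d):
    return 3 * a / (3 * a + b + c)


@_register("gleason", "Gleason", 5, "cooccurrence_no_d", False, (0, 1))
def _gleason(a, b, c, d):
    return 2 * a / (2 * a + b + c)


@_register("kulczynski_i", "Kulczynski I", 6, "cooccurrence_no_d", False, (0, np.inf))
def _kulczynski_i(a, b, c, d):
    return a / (b + c)


@_register("kulczynski_ii", "Kulczynski II", 7, "cooccurrence_no_d", False, (0, 1))
def _kulczynski_ii(a, b, c, d):
    return 0.5 * (a / (a + b) + a / (a + c))


@_register("driver_kroeber", "Driver and Kroeber", 8, "cooccurrence_no_d", False, (0, 1))
def _driver_kroeber(a, b, c, d):
    return a / np.sqrt((a + b) * (a + c))


@_register("braun_blanquet", "Braun-Blanquet", 9, "cooccurrence_no_d", False, (0, 1))
def _braun_blanquet(a, b, c, d):
    return a / np.maximum(a + b, a + c)


@_register("simpson", "Simpson", 10, "cooccurrence_no_d", False, (0, 1))
def _simpson(a, b, c, d):
    return a / np.minimum(a + b, a + c)


@_register("sorgenfrei", "Sorgenfrei", 11, "cooccurrence_no_d", False, (0, 1))
def _sorgenfrei(a, b, c, d):
    return a**2 / ((a + b) * (a + c))


@_register("mountford", "Mountford", 12, "cooccurrence_no_d", False)
def _mountford(a, b, c, d):
    return 2 * a / (a * b + a * c + 2 * b * c)


@_register("fager_mcgowan", "Fager and McGowan", 13, "cooccurrence_no_d", False)
def _fager_mcgowan(a, b, c, d):
    return a / np.sqrt((a + b) * (a + c)) - 0.5 / np.sqrt(np.maximum(a + b, a + c))


@_register("sokal_sneath_i", "Sokal and Sneath I", 14, "cooccurrence_no_d", False, (0, 1))
def _sokal_sneath_i(a, b, c, d):
    return a / (a + 2 * b + 2 * c)


@_register("mcconnaughey", "McConnaughey", 15, "cooccurrence_no_d", False, (-1, 1))
def _mcconnaughey(a, b, c, d):
    return (a**2 - b * c) / ((a + b) * (a + c))


@_register("johnson", "Johnson", 16, "cooccurrence_no_d", False, (0, 2))
def _johnson(a, b, c, d):
    return a / (a + b) + a / (a + c)


@_register("van_der_maarel", "Van der Maarel", 17, "cooccurrence_no_d", False, (-1, 1))
def _van_der_maarel(a, b, c, d):
    return (2 * a - b - c) / (2 * a + b + c)


@_register("ct4", "Consonni and Todeschini IV", 18, "cooccurrence_no_d", False, (0, 1))
def _ct4(a, b, c, d):
    return np.log1p(a) / np.log1p(a + b + c)


# --- ratio-of-a-to-n coefficients (A.19-A.20) ---

@_register("russell_rao", "Russell and Rao", 19, "cooccurrence_with_d", True, (0, 1))
def _russell_rao(a, b, c, d):
    return a / (a + b + c + d)


@_register("ct3", "Consonni and Todeschini III", 20, "cooccurrence_with_d", True, (0, 1))
def _ct3(a, b, c, d):
    return np.log1p(a) / np.log1p(a + b + c + d)


# --- total-matches coefficients (A.21-A.30) ---

@_register("sokal_michener", "Sokal and Michener", 21, "cooccurrence_with_d", True, (0, 1))
def _sokal_michener(a, b, c, d):
    return (a + d) / (a + b + c + d)


@_register("rogers_tanimoto", "Rogers and Tanimoto", 22, "cooccurrence_with_d", True, (0, 1))
def _rogers_tanimoto(a, b, c, d):
    n = a + b + c + d
    return (a + d) / (n + b + c)


@_register("sokal_sneath_ii", "Sokal and Sneath II", 23, "cooccurrence_with_d", True, (0, 1))
def _sokal_sneath_ii(a, b, c, d):
    n = a + b + c + d
    return 2 * (a + d) / (n + a + d)


@_register("sokal_sneath_iii", "Sokal and Sneath III", 24, "cooccurrence_with_d", True, (0, np.inf))
def _sokal_sneath_iii(a, b, c, d):
    return (a + d) / (b + c)


@_register("faith", "Faith", 25, "cooccurrence_with_d", True, (0, 1))
def _faith(a, b, c, d):
    return (a + d / 2) / (a + b + c + d)


@_register("gower_legendre", "Gower and Legendre", 26, "cooccurrence_with_d", True, (0, 1))
def _gower_legendre(a, b, c, d):
    return (a + d) / (a + d + (b + c) / 2)


@_register("gower", "Gower", 27, "cooccurrence_with_d", True)
def _gower(a, b, c, d):
    return (a + d) / np.sqrt((a + b) * (a + c) * (b + d) * (c + d))


@_register("austin_colwell", "Austin and Colwell", 28, "cooccurrence_with_d", True, (0, 1))
def _austin_colwell(a, b, c, d):
    n = a + b + c + d
    return 2 / np.pi * np.arcsin(np.sqrt((a + d) / n))


@_register("ct1", "Consonni and Todeschini I", 29, "cooccurrence_with_d", True, (0, 1))
def _ct1(a, b, c, d):
    return np.log1p(a + d) / np.log1p(a + b + c + d)


@_register("hamann", "Hamann", 30, "cooccurrence_with_d", True, (-1, 1))
def _hamann(a, b, c, d):
    return (a + d - b - c) / (a + b + c + d)


# --- association coefficients with ad - bc numerators (A.31-A.46) ---

@_register("peirce_i", "Peirce I", 31, "association", True, (-1, 1))
def _peirce_i(a, b, c, d):
    return (a * d - b * c) / ((a + b) * (c + d))


@_register("peirce_ii", "Peirce II", 32, "association", True, (-1, 1))
def _peirce_ii(a, b, c, d):
    return (a * d - b * c) / ((a + c) * (b + d))


@_register("yule_q", "Yule's Q", 33, "association", True, (-1, 1))
def _yule_q(a, b, c, d):
    return (a * d - b * c) / (a * d + b * c)


@_register("yule_w", "Yule's W", 34, "association", True, (-1, 1))
def _yule_w(a, b, c, d):
    sad, sbc = np.sqrt(a * d), np.sqrt(b * c)
    return (sad - sbc) / (sad + sbc)


@_register("pearson_i", "Pearson I", 35, "chi_square_type", True, (0, np.inf))
def _pearson_i(a, b, c, d):
    return _chi2(a, b, c, d)


@_register("pearson_ii", "Pearson II", 36, "chi_square_type", True, (0, 1))
def _pearson_ii(a, b, c, d):
    chi2 = _chi2(a, b, c, d)
    n = a + b + c + d
    return np.sqrt(chi2 / (n + chi2))


@_register("phi", "Phi", 37, "association", True, (-1, 1))
def _phi(a, b, c, d):
    return (a * d - b * c) / np.sqrt((a + b) * (a + c) * (b + d) * (c + d))


@_register("michael", "Michael", 38, "association", True, (-1, 1))
def _michael(a, b, c, d):
    return 4 * (a * d - b * c) / ((a + d) ** 2 + (b + c) ** 2)


@_register("cole_i", "Cole I", 39, "association", True)
def _cole_i(a, b, c, d):
    return (a * d - b * c) / ((a + c) * (c + d))


@_register("cole_ii", "Cole II", 40, "association", True)
def _cole_ii(a, b, c, d):
    return (a * d - b * c) / ((a + b) * (b + d))


@_register("cohen", "Cohen", 41, "association", True, (-1, 1))
def _cohen(a, b, c, d):
    return 2 * (a * d - b * c) / ((a + b) * (b + d) + (a + c) * (c + d))


@_register("maxwell_pilliner", "Maxwell and Pilliner", 42, "association", True, (-1, 1))
def _maxwell_pilliner(a, b, c, d):
    return 2 * (a * d - b * c) / ((a + b) * (c + d) + (a + c) * (b + d))


@_register("dennis", "Dennis", 43, "association", True)
def _dennis(a, b, c, d):
    n = a + b + c + d
    return (a * d - b * c) / np.sqrt(n * (a + b) * (a + c))


@_register("dispersion", "Dispersion", 44, "association", True, (-0.25, 0.25))
def _dispersion(a, b, c, d):
    n = a + b + c + d
    return (a * d - b * c) / n**2


@_register("ct5", "Consonni and Todeschini V", 45, "association", True, (-1, 1))
def _ct5(a, b, c, d):
    n = a + b + c + d
    return (np.log1p(a * d) - np.log1p(b * c)) / np.log1p(n**2 / 4)


@_register("stiles", "Stiles", 46, "chi_square_type", True)
def _stiles(a, b, c, d):
    n = a + b + c + d
    num = n * (np.abs(a * d - b * c) - n / 2) ** 2
    return np.log10(num / ((a + b) * (a + c) * (b + d) * (c + d)))


# --- further association measures on ad and bc products (A.47-A.49) ---

@_register("scott", "Scott", 47, "association", True, (-1, 1))
def _scott(a, b, c, d):
    return (4 * a * d - (b + c) ** 2) / ((2 * a + b + c) * (2 * d + b + c))


@_register("tetrachoric", "Tetrachoric", 48, "association", True, (-1, 1))
def _tetrachoric(a, b, c, d):
    # cos(180 deg / (1 + sqrt(ad/bc))); the bc -> 0 limit is +1.
    return np.cos(np.pi / (1 + np.sqrt(a * d / (b * c))))


@_register("odds_ratio", "Odds Ratio", 49, "association", True, (0, np.inf))
def _odds_ratio(a, b, c, d):
    return a * d / (b * c)


# --- pair-counting coefficients (A.50-A.51) ---

def _pair_counts(a, b, c, d):
    n = a + b + c + d
    N = n * (n - 1) / 2
    B = a * b + c * d
    C = a * c + b * d
    D = a * d + b * c
    A = N - B - C - D
    return N, A, B, C, D


@_register("rand", "Rand", 50, "pair_counting", True, (0, 1))
def _rand(a, b, c, d):
    # Proportion of observation pairs on which the two attributes agree
    # (co-clustered by both, or separated by both).
    N, A, B, C, D = _pair_counts(a, b, c, d)
    return (A + D) / N


@_register("ari", "ARI", 51, "pair_counting", True)
def _ari(a, b, c, d):
    N, A, B, C, D = _pair_counts(a, b, c, d)
    expected = (A + B) * (A + C) + (C + D) * (B + D)
    return (N * (A + D) - expected) / (N**2 - expected)


# --- Loevinger's H (A.52) ---

def loevinger_h_values(a, b, c, d, base_rates=None, variant="printed"):
    """Loevinger's H for arrays of quadruples.

    ``variant="printed"`` is ``1 - e / (n * pi1 * pi2)`` where ``pi1 <= pi2``
    are the base rates and ``e`` is the count of observations on which the
    lower-rate attribute is 1 and the other 0.  ``variant="mokken"`` is the
    scaling-theory form ``1 - e / (n * pi1 * (1 - pi2))`` (observed over
    expected Guttman errors), which is ~0 for independent attributes.

    When ``base_rates`` (a sorted pair of population rates, first attribute
    carrying the smaller) is given, the error cell is ``b`` and the supplied
    rates are used; otherwise the sample margins stand in and the error cell
    follows the smaller margin.
    """
    n = a + b + c + d
    if base_rates is not None:
        pi1, pi2 = base_rates
        if pi1 > pi2:
            raise ValueError("base_rates must be sorted (pi1 <= pi2)")
        err = b
    else:
        r1 = (a + b) / n
        r2 = (a + c) / n
        pi1 = np.minimum(r1, r2)
        pi2 = np.maximum(r1, r2)
        err = np.where(r1 <= r2, b, c)
    if variant == "printed":
        return 1 - err / (n * pi1 * pi2)
    if variant == "mokken":
        return 1 - err / (n * pi1 * (1 - pi2))
    raise ValueError(f"unknown Loevinger variant {variant!r}")


@_register("loevinger_h", "Loevinger's H", 52, "other", True, needs_rates=True)
def _loevinger_h(a, b, c, d, base_rates=None):
    return loevinger_h_values(a, b, c, d, base_rates=base_rates)


# --- assorted co-occurrence measures (A.53-A.71) ---

@_register("sokal_sneath_iv", "Sokal and Sneath IV", 53, "other", True, (0, 1))
def _sokal_sneath_iv(a, b, c, d):
    return 0.25 * (a / (a + b) + a / (a + c) + d / (b + d) + d / (c + d))


@_register("sokal_sneath_v", "Sokal and Sneath V", 54, "other", True, (0, 1))
def _sokal_sneath_v(a, b, c, d):
    return a * d / np.sqrt((a + b) * (a + c) * (b + d) * (c + d))


@_register("rogot_goldberg", "Rogot and Goldberg", 55, "other", True, (0, 1))
def _rogot_goldberg(a, b, c, d):
    return a / (2 * a + b + c) + d / (2 * d + b + c)


@_register("baroni_urbani_buser_i", "Baroni-Urbani and Buser I", 56, "other", True, (0, 1))
def _baroni_urbani_buser_i(a, b, c, d):
    sad = np.sqrt(a * d)
    return (sad + a) / (sad + a + b + c)


@_register("peirce_iii", "Peirce III", 57, "other", True)
def _peirce_iii(a, b, c, d):
    return (a * b + b * c) / (a * b + 2 * b * c + c * d)


@_register("hawkins_dotson", "Hawkins and Dotson", 58, "other", True, (0, 1))
def _hawkins_dotson(a, b, c, d):
    return 0.5 * (a / (a + b + c) + d / (b + c + d))


@_register("tarantula", "Tarantula", 59, "other", True, (0, np.inf))
def _tarantula(a, b, c, d):
    return a * (c + d) / (c * (a + b))


@_register("harris_lahey", "Harris and Lahey", 60, "other", True)
def _harris_lahey(a, b, c, d):
    return (a * (2 * d + b + c) / (2 * (a + b + c))
            + d * (2 * a + b + c) / (2 * (b + c + d)))


@_register("forbes_i", "Forbes I", 61, "other", True, (0, np.inf))
def _forbes_i(a, b, c, d):
    n = a + b + c + d
    return n * a / ((a + b) * (a + c))


@_register("baroni_urbani_buser_ii", "Baroni-Urbani and Buser II", 62, "other", True, (-1, 1))
def _baroni_urbani_buser_ii(a, b, c, d):
    sad = np.sqrt(a * d)
    return (sad + a - b - c) / (sad + a + b + c)


@_register("fossum", "Fossum", 63, "other", True, (0, np.inf))
def _fossum(a, b, c, d):
    n = a + b + c + d
    return n * (a - 0.5) ** 2 / ((a + b) * (a + c))


@_register("forbes_ii", "Forbes II", 64, "other", True)
def _forbes_ii(a, b, c, d):
    n = a + b + c + d
    return (n * a - (a + b) * (a + c)) / (n * np.minimum(a + b, a + c) - (a + b) * (a + c))


@_register("eyraud", "Eyraud", 65, "other", True)
def _eyraud(a, b, c, d):
    n = a + b + c + d
    return n**2 * (n * a - (a + b) * (a + c)) / ((a + b) * (a + c) * (b + d) * (c + d))


@_register("tarwid", "Tarwid", 66, "other", True, (-1, 1))
def _tarwid(a, b, c, d):
    n = a + b + c + d
    return (n * a - (a + b) * (a + c)) / (n * a + (a + b) * (a + c))


def _taus(a, b, c, d):
    tau1 = (np.maximum(a, b) + np.maximum(c, d)
            + np.maximum(a, c) + np.maximum(b, d))
    tau2 = np.maximum(a + c, b + d) + np.maximum(a + b, c + d)
    return tau1, tau2


@_register("goodman_kruskal_i", "Goodman and Kruskal I", 67, "other", True, (0, 1))
def _goodman_kruskal_i(a, b, c, d):
    n = a + b + c + d
    tau1, tau2 = _taus(a, b, c, d)
    return (tau1 - tau2) / (2 * n - tau2)


@_register("anderberg", "Anderberg", 68, "other", True, (0, 1))
def _anderberg(a, b, c, d):
    n = a + b + c + d
    tau1, tau2 = _taus(a, b, c, d)
    return (tau1 - tau2) / (2 * n)


@_register("goodman_kruskal_ii", "Goodman and Kruskal II", 69, "other", True, (-1, 1))
def _goodman_kruskal_ii(a, b, c, d):
    m = np.minimum(a, d)
    return (2 * m - b - c) / (2 * m + b + c)


@_register("gilbert_wells", "Gilbert and Wells", 70, "other", True)
def _gilbert_wells(a, b, c, d):
    n = a + b + c + d
    return np.log(a) - np.log(n) - np.log((a + b) / n) - np.log((a + c) / n)


@_register("ct2", "Consonni and Todeschini II", 71, "other", True, (0, 1))
def _ct2(a, b, c, d):
    n = a + b + c + d
    return (np.log1p(n) - np.log1p(b + c)) / np.log1p(n)


assert len(_REGISTRY) == 71, f"registry has {len(_REGISTRY)} entries, expected 71"
assert len({cd.appendix_id for cd in _REGISTRY.values()}) == 71


def registry() -> Dict[str, CoefficientDefinition]:
    """The full registry, keyed by coefficient key, in appendix order."""
    return dict(_REGISTRY)


def coefficient_metadata() -> List[CoefficientDefinition]:
    """All 71 coefficient definitions in appendix order."""
    return list(_REGISTRY.values())


def keys() -> List[str]:
    return list(_REGISTRY)


def labels() -> Dict[str, str]:
    return {k: cd.label for k, cd in _REGISTRY.items()}


def _as_float_cells(q) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(q, ContingencyQuadruple):
        arr = q.as_array().astype(float)
        return arr[0], arr[1], arr[2], arr[3]
    arr = np.asarray(q, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.shape[-1] != 4:
        raise ValueError("quadruple array must have 4 columns (a, b, c, d)")
    return arr[..., 0], arr[..., 1], arr[..., 2], arr[..., 3]


def _clean(values) -> np.ndarray:
    out = np.array(values, dtype=float, copy=True)
    out[~np.isfinite(out)] = np.nan
    return out


def evaluate(key: str, q, base_rates=None) -> float:
    """Evaluate one coefficient on a quadruple; NaN where undefined.

    Raises
    ------
    KeyError
        For an unknown coefficient key.
    """
    if key not in _REGISTRY:
        raise KeyError(f"unknown coefficient key {key!r}")
    a, b, c, d = _as_float_cells(q)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        v = _REGISTRY[key].func(a, b, c, d, base_rates=base_rates)
    v = _clean(np.broadcast_to(np.asarray(v, float), np.shape(a)))
    return float(v) if v.ndim == 0 else v


def evaluate_all(q: ContingencyQuadruple, base_rates=None) -> pd.Series:
    """All 71 coefficients of one quadruple, in registry order."""
    return pd.Series(
        {k: evaluate(k, q, base_rates=base_rates) for k in _REGISTRY},
        dtype=float,
        name="value",
    )


def evaluate_trials(quads, base_rates=None, keys: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Evaluate coefficients for a ``(trials, 4)`` array of quadruples.

    Returns a trials-by-coefficients DataFrame with NaN marking undefined
    values.  ``base_rates`` (the known population rates, if any) only
    affects Loevinger's H.
    """
    arr = np.asarray(quads, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 4:
        raise ValueError("quads must be a (trials, 4) array")
    a, b, c, d = arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3]
    use = list(_REGISTRY) if keys is None else list(keys)
    out = {}
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        for k in use:
            if k not in _REGISTRY:
                raise KeyError(f"unknown coefficient key {k!r}")
            v = _REGISTRY[k].func(a, b, c, d, base_rates=base_rates)
            out[k] = _clean(np.broadcast_to(np.asarray(v, float), a.shape))
    return pd.DataFrame(out, columns=use)


def odds_ratio_values(a, b, c, d, haldane=False):
    """Odds ratio ``ad/bc``; ``haldane=True`` adds 0.5 to every cell."""
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    if haldane:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    with np.errstate(divide="ignore", invalid="ignore"):
        return _clean(a * d / (b * c))


def attribute_similarity(X, key: str, base_rates=None) -> pd.DataFrame:
    """Attribute-by-attribute similarity matrix of a binary data matrix.

    ``X`` is an observations-by-attributes 0/1 matrix (array or DataFrame);
    the result is the p-by-p matrix of the chosen coefficient over all
    attribute pairs, labelled by column names when available.
    """
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        M = X.to_numpy()
    else:
        M = np.asarray(X)
        names = [f"attr{i}" for i in range(M.shape[1])]
    if M.ndim != 2:
        raise ValueError("X must be a 2-d observations-by-attributes matrix")
    if not np.isin(M, (0, 1)).all():
        raise ValueError("X must contain only 0 and 1")
    M = M.astype(np.int64)
    n = M.shape[0]
    A = M.T @ M
    rb = np.diag(A)
    B = rb[:, None] - A
    C = rb[None, :] - A
    D = n - A - B - C
    quads = np.stack([A, B, C, D], axis=-1).reshape(-1, 4)
    vals = evaluate(key, quads, base_rates=base_rates).reshape(A.shape)
    return pd.DataFrame(vals, index=names, columns=names)
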