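"""Contingency quadruples for pairs of binary attributes.

Two binary attributes measured on the same ``n`` observations reduce to four
counts: ``a`` observations where both are 1 (positive matches), ``b`` where
the first is 1 and the second 0, ``c`` where the first is 0 and the second 1,
and ``d`` where both are 0 (negative matches).  Every binary similarity
coefficient in :mod:`binsim.coefficients` is a function of this quadruple.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ContingencyQuadruple",
    "DerivedQuantities",
    "count_quadruple",
    "derived_quantities",
]


@dataclass(frozen=True)
class ContingencyQuadruple:
    """The counts ``(a, b, c, d)`` for one pair of binary attributes.

    Parameters
    ----------
    a : int
        Number of positive matches (both attributes 1).
    b : int
        Number of mismatches with the first attribute 1, the second 0.
    c : int
        Number of mismatches with the first attribute 0, the second 1.
    d : int
        Number of negative matches (both attributes 0).
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
            object.__setattr__(self, name, int(v))
        if self.n <= 0:
            raise ValueError("a + b + c + d must be positive")

    @property
    def n(self) -> int:
        """Total number of observations ``a + b + c + d``."""
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.d], dtype=np.int64)

    def swapped(self) -> "ContingencyQuadruple":
        """The quadruple with the two attributes' roles exchanged (b <-> c)."""
        return ContingencyQuadruple(self.a, self.c, self.b, self.d)


def count_quadruple(x1, x2) -> ContingencyQuadruple:
    """Count the contingency quadruple of two equal-length 0/1 vectors.

    Raises
    ------
    ValueError
        If the vectors differ in length, are empty, or contain entries other
        than 0 and 1.
    """
    x1 = np.asarray(x1)
    x2 = np.asarray(x2)
    if x1.ndim != 1 or x2.ndim != 1 or x1.shape != x2.shape:
        raise ValueError("x1 and x2 must be one-dimensional vectors of equal length")
    if x1.size == 0:
        raise ValueError("vectors must have length >= 1")
    for x in (x1, x2):
        if not np.isin(x, (0, 1)).all():
            raise ValueError("vectors must contain only 0 and 1")
    x1 = x1.astype(np.int64)
    x2 = x2.astype(np.int64)
    a = int((x1 * x2).sum())
    b = int((x1 * (1 - x2)).sum())
    c = int(((1 - x1) * x2).sum())
    d = int(((1 - x1) * (1 - x2)).sum())
    return ContingencyQuadruple(a, b, c, d)


@dataclass(frozen=True)
class DerivedQuantities:
    """Shared intermediate quantities used across coefficient formulas.

    ``tau1``/``tau2`` are the Goodman–Kruskal prediction sums; ``N`` is the
    number of observation pairs and ``A, B, C, D`` partition those pairs by
    co-clustering agreement between the two attributes (``A`` together in
    both, ``B`` together only in the first, ``C`` together only in the
    second, ``D`` apart in both); ``pi1 <= pi2`` are the sorted sample base
    rates; ``chi2`` is the Pearson chi-square of the 2x2 table.
    """

    n: int
    tau1: int
    tau2: int
    N: int
    A: int
    B: int
    C: int
    D: int
    pi1: float
    pi2: float
    chi2: float


def derived_quantities(q: ContingencyQuadruple) -> DerivedQuantities:
    a, b, c, d = q.a, q.b, q.c, q.d
    n = q.n
    tau1 = max(a, b) + max(c, d) + max(a, c) + max(b, d)
    tau2 = max(a + c, b + d) + max(a + b, c + d)
    N = n * (n - 1) // 2
    B = a * b + c * d
    C = a * c + b * d
    D = a * d + b * c
    A = N - B - C - D
    r1 = (a + b) / n
    r2 = (a + c) / n
    denom = (a + b) * (a + c) * (b + d) * (c + d)
    chi2 = n * (a * d - b * c) ** 2 / denom if denom > 0 else float("nan")
    return DerivedQuantities(
        n=n, tau1=tau1, tau2=tau2, N=N, A=A, B=B, C=C, D=D,
        pi1=min(r1, r2), pi2=max(r1, r2), chi2=chi2,
    )
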