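"""K-median (p-median / PAM-style) partitioning of a similarity matrix.

Given a p-by-p similarity matrix S, the model selects K exemplar items
(medoids) Q and assigns every item to its most similar exemplar, maximising

    Z = sum_i max_{j in Q} s_ij.

Each diagonal entry must be maximal in its row (ties allowed), so an
exemplar is always assigned to itself.  Solutions come from a multistart
fast-interchange local search: random initial exemplars, then repeated
exemplar/non-exemplar swaps accepted whenever they strictly increase Z,
until 1-interchange local optimality; the best of many restarts is kept.
An exhaustive solver is provided for small instances.

The module follows a model/results split: build a :class:`KMedian` from a
similarity matrix, call :meth:`KMedian.fit`, and read the partition off the
returned :class:`KMedianResults`.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "SimilarityMatrix",
    "Partition",
    "KMedian",
    "KMedianResults",
    "objective",
    "fast_interchange",
    "multistart_kmedian",
    "brute_force_kmedian",
]

# Minimum absolute gain for a swap to be accepted; guards against cycling on
# floating-point ties (exactly tied columns occur with perfectly correlated
# coefficients).
SWAP_TOLERANCE = 1e-12

_DIAG_TOLERANCE = 1e-9
_BRUTE_FORCE_LIMIT = 10**6


class SimilarityMatrix:
    """A labelled square similarity matrix with row-maximal diagonal.

    Raises ``ValueError`` if the matrix is not square, has non-finite
    entries, or some off-diagonal entry strictly exceeds its row's diagonal
    (ties are permitted).
    """

    def __init__(self, values, labels: Optional[Sequence[str]] = None):
        if isinstance(values, pd.DataFrame):
            if labels is None:
                labels = [str(c) for c in values.columns]
            values = values.to_numpy()
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("similarity matrix must be square")
        if not np.isfinite(values).all():
            raise ValueError("similarity matrix must have finite entries")
        p = values.shape[0]
        if labels is None:
            labels = [f"item{i}" for i in range(p)]
        labels = [str(x) for x in labels]
        if len(labels) != p:
            raise ValueError("labels length must match matrix size")
        diag = np.diag(values)
        if (values.max(axis=1) > diag + _DIAG_TOLERANCE).any():
            bad = np.flatnonzero(values.max(axis=1) > diag + _DIAG_TOLERANCE)
            raise ValueError(
                f"diagonal must be maximal in each row; violated at rows {bad.tolist()}"
            )
        self.values = values
        self.labels = labels

    @property
    def p(self) -> int:
        return self.values.shape[0]

    @classmethod
    def read_csv(cls, path) -> "SimilarityMatrix":
        return cls(pd.read_csv(path, index_col=0))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)


@dataclass(frozen=True)
class Partition:
    """A K-median solution: exemplars, per-item assignment, objective."""

    labels: Tuple[str, ...]
    exemplars: Tuple[int, ...]          # sorted item indices of the K exemplars
    assignment: Tuple[int, ...]         # per item, the index of its exemplar
    objective: float

    @property
    def k(self) -> int:
        return len(self.exemplars)

    @property
    def cluster_ids(self) -> np.ndarray:
        """Per-item cluster id in 0..K-1 (position of the exemplar)."""
        pos = {e: i for i, e in enumerate(self.exemplars)}
        return np.array([pos[e] for e in self.assignment], dtype=np.int64)

    @property
    def exemplar_labels(self) -> Tuple[str, ...]:
        return tuple(self.labels[e] for e in self.exemplars)

    def members(self) -> Dict[str, List[str]]:
        """Cluster members keyed by exemplar label."""
        out: Dict[str, List[str]] = {self.labels[e]: [] for e in self.exemplars}
        for i, e in enumerate(self.assignment):
            out[self.labels[e]].append(self.labels[i])
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"item": self.labels, "cluster": self.cluster_ids,
             "exemplar": [self.labels[e] for e in self.assignment]}
        )


def _as_similarity(S) -> SimilarityMatrix:
    return S if isinstance(S, SimilarityMatrix) else SimilarityMatrix(S)


def _assign(values: np.ndarray, Q: Sequence[int]) -> Tuple[np.ndarray, float]:
    """Assignment to the most similar exemplar; ties go to the lowest index."""
    Q = np.asarray(sorted(Q), dtype=np.int64)
    sub = values[:, Q]
    pos = np.argmax(sub, axis=1)          # argmax takes the first (lowest) tie
    z = float(sub[np.arange(values.shape[0]), pos].sum())
    return Q[pos], z


def objective(S, Q: Sequence[int]) -> float:
    """Z = sum over items of the row maximum over the exemplar set Q."""
    S = _as_similarity(S)
    Q = list(Q)
    if len(Q) == 0:
        raise ValueError("exemplar set Q must be nonempty")
    if not all(0 <= int(q) < S.p for q in Q):
        raise ValueError("exemplar indices out of range")
    return float(S.values[:, sorted(set(int(q) for q in Q))].max(axis=1).sum())


def _partition_from(S: SimilarityMatrix, Q: Sequence[int]) -> Partition:
    assignment, z = _assign(S.values, Q)
    return Partition(
        labels=tuple(S.labels),
        exemplars=tuple(sorted(int(q) for q in Q)),
        assignment=tuple(int(x) for x in assignment),
        objective=z,
    )


def fast_interchange(
    S,
    k: int,
    rng: np.random.Generator,
    improvement: str = "first",
    tol: float = SWAP_TOLERANCE,
) -> Partition:
    """One run of the fast-interchange heuristic from a random start.

    Swaps an exemplar for a non-exemplar whenever it increases Z by more
    than ``tol``.  ``improvement="first"`` accepts the first improving swap
    found (scanning exemplars, then candidates, by index) and restarts the
    scan; ``"best"`` accepts the best swap of a full scan.  Either way the
    result is 1-interchange locally optimal.
    """
    S = _as_similarity(S)
    p = S.p
    if not (1 <= k <= p):
        raise ValueError(f"k must lie in 1..{p}")
    if improvement not in ("first", "best"):
        raise ValueError("improvement must be 'first' or 'best'")
    V = S.values
    Q = sorted(int(x) for x in rng.choice(p, size=k, replace=False))
    _, z = _assign(V, Q)
    in_Q = np.zeros(p, dtype=bool)
    in_Q[Q] = True

    improved = True
    while improved:
        improved = False
        best_gain, best_swap = tol, None
        for j in list(Q):
            rest = [q for q in Q if q != j]
            if rest:
                partial = V[:, rest].max(axis=1)
            else:
                partial = np.full(p, -np.inf)
            # Z for exemplar sets rest + {m}, all candidates m at once.
            cand_z = np.maximum(partial[:, None], V).sum(axis=0)
            cand_z[in_Q] = -np.inf
            if improvement == "first":
                better = np.flatnonzero(cand_z > z + tol)
                if better.size:
                    m = int(better[0])
                    in_Q[j] = False
                    in_Q[m] = True
                    Q = sorted(np.flatnonzero(in_Q).tolist())
                    z = float(cand_z[m])
                    improved = True
                    break
            else:
                m = int(np.argmax(cand_z))
                gain = float(cand_z[m]) - z
                if gain > best_gain:
                    best_gain, best_swap = gain, (j, m)
        if improvement == "best" and best_swap is not None:
            j, m = best_swap
            in_Q[j] = False
            in_Q[m] = True
            Q = sorted(np.flatnonzero(in_Q).tolist())
            z += best_gain
            improved = True
    return _partition_from(S, Q)


def multistart_kmedian(
    S,
    k: int,
    restarts: int = 2000,
    seed: Optional[int] = None,
    improvement: str = "first",
) -> Partition:
    """Best partition over ``restarts`` independent fast-interchange runs.

    Deterministic given ``seed``; ties in Z keep the first-found solution.
    """
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    S = _as_similarity(S)
    children = np.random.SeedSequence(seed).spawn(restarts)
    best: Optional[Partition] = None
    for child in children:
        part = fast_interchange(S, k, np.random.default_rng(child), improvement=improvement)
        if best is None or part.objective > best.objective:
            best = part
    return best


def brute_force_kmedian(S, k: int) -> Partition:
    """Global optimum by exhaustive enumeration of all C(p, k) exemplar sets.

    Refuses instances with more than one million subsets.
    """
    S = _as_similarity(S)
    p = S.p
    if not (1 <= k <= p):
        raise ValueError(f"k must lie in 1..{p}")
    if math.comb(p, k) > _BRUTE_FORCE_LIMIT:
        raise ValueError(f"C({p}, {k}) exceeds the enumeration guard")
    V = S.values
    best_Q, best_z = None, -np.inf
    for Q in itertools.combinations(range(p), k):
        z = V[:, Q].max(axis=1).sum()
        if z > best_z:
            best_Q, best_z = Q, z
    return _partition_from(S, best_Q)


class KMedian:
    """K-median partitioning model over a similarity matrix.

    Parameters
    ----------
    similarity : SimilarityMatrix, DataFrame or square array
        Item-by-item similarities with row-maximal diagonal.
    k : int
        Number of clusters (exemplars).

    Examples
    --------
    >>> model = KMedian(sim_df, k=2)
    >>> res = model.fit(restarts=200, seed=7)
    >>> res.partition.exemplar_labels
    """

    def __init__(self, similarity, k: int = 2, labels: Optional[Sequence[str]] = None):
        if isinstance(similarity, SimilarityMatrix):
            self.similarity = similarity
        else:
            self.similarity = SimilarityMatrix(similarity, labels=labels)
        if not (1 <= int(k) <= self.similarity.p):
            raise ValueError(f"k must lie in 1..{self.similarity.p}")
        self.k = int(k)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, k: int = 2) -> "KMedian":
        return cls(SimilarityMatrix(df), k=k)

    def objective(self, Q: Sequence[int]) -> float:
        return objective(self.similarity, Q)

    def fit(
        self,
        restarts: int = 2000,
        seed: Optional[int] = None,
        improvement: str = "first",
    ) -> "KMedianResults":
        part = multistart_kmedian(
            self.similarity, self.k, restarts=restarts, seed=seed,
            improvement=improvement,
        )
        return KMedianResults(self, part, method="multistart",
                              restarts=restarts, seed=seed)

    def fit_exact(self) -> "KMedianResults":
        part = brute_force_kmedian(self.similarity, self.k)
        return KMedianResults(self, part, method="brute_force", restarts=None, seed=None)


@dataclass
class KMedianResults:
    """Fitted K-median partition with its provenance."""

    model: KMedian
    partition: Partition
    method: str
    restarts: Optional[int]
    seed: Optional[int]

    @property
    def objective(self) -> float:
        return self.partition.objective

    @property
    def exemplars(self) -> Tuple[str, ...]:
        return self.partition.exemplar_labels

    def is_locally_optimal(self, tol: float = SWAP_TOLERANCE) -> bool:
        """Re-scan every exemplar/non-exemplar swap for an improvement."""
        V = self.model.similarity.values
        p = V.shape[0]
        Q = set(self.partition.exemplars)
        z = self.partition.objective
        for j in Q:
            rest = [q for q in Q if q != j]
            partial = V[:, rest].max(axis=1) if rest else np.full(p, -np.inf)
            cand_z = np.maximum(partial[:, None], V).sum(axis=0)
            cand_z[list(Q)] = -np.inf
            if (cand_z > z + tol).any():
                return False
        return True

    def summary(self) -> str:
        part = self.partition
        lines = [
            "K-median partition",
            "=" * 52,
            f"items:      {len(part.labels)}",
            f"clusters:   {part.k}",
            f"objective:  {part.objective:.6f}",
            f"method:     {self.method}"
            + (f" ({self.restarts} restarts, seed={self.seed})"
               if self.method == "multistart" else ""),
            "-" * 52,
        ]
        for exemplar, members in part.members().items():
            lines.append(f"exemplar {exemplar} ({len(members)} members):")
            lines.append("  " + ", ".join(members))
        return "\n".join(lines)

    def save(self, csv_path, json_path=None) -> None:
        """Write the assignment as CSV and a JSON sidecar with metadata."""
        import json
        from pathlib import Path

        self.partition.to_frame().to_csv(csv_path, index=False)
        if json_path is None:
            json_path = Path(csv_path).with_suffix(".json")
        payload = {
            "exemplars": list(self.exemplars),
            "objective": self.objective,
            "k": self.partition.k,
            "method": self.method,
            "restarts": self.restarts,
            "seed": self.seed,
        }
        Path(json_path).write_text(json.dumps(payload, indent=2))
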