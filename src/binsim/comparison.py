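"""Inter-coefficient correlation, partition agreement, and stability.

This module turns per-trial coefficient values into the study's comparison
artifacts: Pearson correlation matrices between coefficients (with a
documented rule for dropping degenerate coefficients), Hubert–Arabie
adjusted Rand agreement between cluster partitions, and co-membership
stability of coefficients across a family of partitions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .kmedian import Partition

__all__ = [
    "CorrelationResult",
    "StabilityReport",
    "correlation_matrix",
    "partition_ari",
    "ari_matrix",
    "co_membership_stability",
    "exemplar_correlation_table",
]

#: A coefficient is dropped from a correlation matrix when more than this
#: fraction of its trial values is undefined.  The level must tolerate the
#: Stiles coefficient, whose continuity correction (|ad-bc| - n/2)^2 lands
#: exactly on zero (hence log10(0), undefined) on roughly 0.1% of trials at
#: n = 2000 because ad - bc = n*a - (a+b)(a+c) lives on a coarse lattice;
#: those trials are handled pairwise complete-case instead.
MAX_UNDEFINED_FRACTION = 1e-2


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlations between retained coefficients for one trial set."""

    matrix: pd.DataFrame                       # k x k, symmetric, unit diagonal
    kept_keys: Tuple[str, ...]
    dropped: Tuple[Tuple[str, str], ...]       # (key, reason)

    def restrict(self, keep: Sequence[str]) -> "CorrelationResult":
        """Restrict to a subset of retained keys (order preserved)."""
        keep = [k for k in keep if k in self.matrix.columns]
        return CorrelationResult(
            matrix=self.matrix.loc[keep, keep],
            kept_keys=tuple(keep),
            dropped=self.dropped,
        )


def correlation_matrix(
    values: pd.DataFrame,
    max_undefined_fraction: float = MAX_UNDEFINED_FRACTION,
) -> CorrelationResult:
    """Pairwise Pearson correlations across trials, with the drop rule.

    A column is dropped when its defined values have zero variance (a
    constant coefficient has no correlation with anything) or when more than
    ``max_undefined_fraction`` of its values is undefined.  The surviving
    rare undefined values are handled pairwise complete-case.

    Raises
    ------
    ValueError
        With fewer than 3 trials, or if fewer than 2 columns survive.
    """
    if values.shape[0] < 3:
        raise ValueError("at least 3 trials are required for correlations")
    arr = values.to_numpy(dtype=float)
    cols = list(values.columns)
    finite = np.isfinite(arr)
    dropped: List[Tuple[str, str]] = []
    kept_idx: List[int] = []
    for j, key in enumerate(cols):
        col = arr[:, j]
        ok = finite[:, j]
        undef_frac = 1.0 - ok.mean()
        if undef_frac > max_undefined_fraction or ok.sum() < 3:
            dropped.append((key, "undefined_values"))
            continue
        defined = col[ok]
        if defined.min() == defined.max():
            dropped.append((key, "zero_variance"))
            continue
        kept_idx.append(j)
    if len(kept_idx) < 2:
        raise ValueError("fewer than 2 coefficients survive the drop rule")

    kept_keys = [cols[j] for j in kept_idx]
    sub = arr[:, kept_idx]
    sub_finite = finite[:, kept_idx]
    k = len(kept_idx)
    corr = np.empty((k, k), dtype=float)

    complete_cols = np.flatnonzero(sub_finite.all(axis=0))
    nan_cols = np.flatnonzero(~sub_finite.all(axis=0))
    if complete_cols.size >= 2:
        corr[np.ix_(complete_cols, complete_cols)] = np.corrcoef(
            sub[:, complete_cols], rowvar=False
        )
    elif complete_cols.size == 1:
        corr[complete_cols[0], complete_cols[0]] = 1.0
    # Pairwise complete-case for the (rare) columns carrying undefined values.
    for j in nan_cols:
        for i in range(k):
            mask = sub_finite[:, i] & sub_finite[:, j]
            if mask.sum() < 3:
                raise ValueError(
                    f"fewer than 3 complete trials for pair "
                    f"({kept_keys[i]}, {kept_keys[j]})"
                )
            r = np.corrcoef(sub[mask, i], sub[mask, j])[0, 1]
            corr[i, j] = corr[j, i] = r

    corr = np.clip(corr, -1.0, 1.0)
    corr = (corr + corr.T) / 2
    np.fill_diagonal(corr, 1.0)
    return CorrelationResult(
        matrix=pd.DataFrame(corr, index=kept_keys, columns=kept_keys),
        kept_keys=tuple(kept_keys),
        dropped=tuple(dropped),
    )


def _cluster_ids(p) -> Tuple[Tuple[str, ...], np.ndarray]:
    if isinstance(p, Partition):
        return tuple(p.labels), p.cluster_ids
    if isinstance(p, pd.Series):
        return tuple(str(i) for i in p.index), np.asarray(p.to_numpy())
    arr = np.asarray(p)
    return tuple(str(i) for i in range(arr.size)), arr


def partition_ari(p1, p2) -> float:
    """Hubert–Arabie adjusted Rand index between two partitions.

    Accepts :class:`~binsim.kmedian.Partition` objects (which must share a
    label set; items are matched by label) or plain cluster-id sequences of
    equal length.  Returns 1.0 for identical partitions up to relabelling
    and has expectation ~0 under chance agreement.
    """
    labels1, ids1 = _cluster_ids(p1)
    labels2, ids2 = _cluster_ids(p2)
    if set(labels1) != set(labels2):
        raise ValueError("partitions must be over the same label set")
    if labels1 != labels2:
        order = {lab: i for i, lab in enumerate(labels2)}
        ids2 = np.asarray([ids2[order[lab]] for lab in labels1])
    n = len(ids1)
    _, u1 = np.unique(ids1, return_inverse=True)
    _, u2 = np.unique(ids2, return_inverse=True)
    k1, k2 = u1.max() + 1, u2.max() + 1
    table = np.zeros((k1, k2), dtype=np.int64)
    np.add.at(table, (u1, u2), 1)

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_cells = comb2(table).sum()
    sum_rows = comb2(table.sum(axis=1)).sum()
    sum_cols = comb2(table.sum(axis=0)).sum()
    total = comb2(n)
    expected = sum_rows * sum_cols / total
    max_index = (sum_rows + sum_cols) / 2.0
    if max_index == expected:
        # Both partitions are trivial (e.g. all singletons or one cluster).
        return 1.0 if sum_cells == max_index else 0.0
    return float((sum_cells - expected) / (max_index - expected))


def ari_matrix(partitions: Mapping[object, Partition]) -> pd.DataFrame:
    """Symmetric matrix of pairwise partition ARIs, in mapping order."""
    names = list(partitions)
    if len(names) < 2:
        raise ValueError("at least 2 partitions are required")
    m = len(names)
    out = np.ones((m, m), dtype=float)
    for i in range(m):
        for j in range(i + 1, m):
            out[i, j] = out[j, i] = partition_ari(
                partitions[names[i]], partitions[names[j]]
            )
    idx = [str(x) for x in names]
    return pd.DataFrame(out, index=idx, columns=idx)


@dataclass(frozen=True)
class StabilityReport:
    """Co-membership of coefficient pairs across a family of partitions."""

    co_membership_counts: pd.DataFrame     # k x k integer matrix
    subsets: Tuple[Tuple[str, ...], ...]   # maximal co-clustered groups, size >= 2
    threshold: int
    n_partitions: int

    @property
    def ungrouped(self) -> Tuple[str, ...]:
        grouped = {x for s in self.subsets for x in s}
        return tuple(x for x in self.co_membership_counts.index if x not in grouped)

    def subset_containing(self, key: str) -> Tuple[str, ...]:
        """The stable subset containing ``key`` (the singleton if ungrouped)."""
        for s in self.subsets:
            if key in s:
                return s
        if key not in self.co_membership_counts.index:
            raise KeyError(f"unknown coefficient {key!r}")
        return (key,)


def co_membership_stability(
    partitions: Mapping[object, Partition],
    threshold: Optional[int] = None,
) -> StabilityReport:
    """Count per-pair co-clustering across partitions and extract subsets.

    ``threshold`` is the minimum number of partitions (default: all) in
    which every internal pair of a subset must co-cluster.  At the full
    threshold, co-membership in every partition is an equivalence relation,
    so the connected components of the co-membership graph are cliques (this
    is verified, not assumed); below it, maximal cliques are extracted.
    """
    parts = list(partitions.values())
    if not parts:
        raise ValueError("at least one partition is required")
    labels = parts[0].labels
    for p in parts[1:]:
        if set(p.labels) != set(labels):
            raise ValueError("partitions must share a label set")
    m = len(parts)
    if threshold is None:
        threshold = m
    if not (1 <= threshold <= m):
        raise ValueError("threshold must lie in 1..n_partitions")

    k = len(labels)
    counts = np.zeros((k, k), dtype=np.int64)
    for p in parts:
        order = {lab: i for i, lab in enumerate(p.labels)}
        ids = p.cluster_ids[[order[lab] for lab in labels]]
        counts += (ids[:, None] == ids[None, :]).astype(np.int64)

    adj = counts >= threshold
    np.fill_diagonal(adj, False)
    if threshold == m:
        subsets = _connected_components(adj, labels, require_clique=True)
    else:
        import networkx as nx

        g = nx.from_numpy_array(adj)
        subsets = sorted(
            (tuple(labels[i] for i in sorted(clique))
             for clique in nx.find_cliques(g) if len(clique) >= 2),
            key=lambda s: (-len(s), s),
        )
    counts_df = pd.DataFrame(counts, index=list(labels), columns=list(labels))
    return StabilityReport(
        co_membership_counts=counts_df,
        subsets=tuple(subsets),
        threshold=threshold,
        n_partitions=m,
    )


def _connected_components(adj, labels, require_clique):
    k = adj.shape[0]
    seen = np.zeros(k, dtype=bool)
    comps = []
    for start in range(k):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for w in np.flatnonzero(adj[v]):
                if not seen[w]:
                    seen[w] = True
                    stack.append(int(w))
        if len(comp) >= 2:
            comp = sorted(comp)
            if require_clique:
                block = adj[np.ix_(comp, comp)]
                np.fill_diagonal(block, True)
                if not block.all():
                    raise AssertionError(
                        "co-membership component at the full threshold is not "
                        "a clique; this contradicts the equivalence-relation "
                        "argument and indicates an implementation error"
                    )
            comps.append(tuple(labels[i] for i in comp))
    return sorted(comps, key=lambda s: (-len(s), s))


def exemplar_correlation_table(
    results: Mapping[object, CorrelationResult],
    pairs: Sequence[Tuple[str, str]],
) -> pd.DataFrame:
    """One row per trial condition, one column per coefficient pair.

    Raises
    ------
    KeyError
        Naming the offending coefficient if a requested key was dropped
        from any condition's correlation matrix.
    """
    rows = {}
    col_names = [f"{k1}~{k2}" for (k1, k2) in pairs]
    for cond, res in results.items():
        row = []
        for (k1, k2) in pairs:
            for key in (k1, k2):
                if key not in res.matrix.columns:
                    raise KeyError(
                        f"coefficient {key!r} is not retained for condition {cond}"
                    )
            row.append(res.matrix.loc[k1, k2])
        rows[str(cond)] = row
    return pd.DataFrame.from_dict(rows, orient="index", columns=col_names)
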