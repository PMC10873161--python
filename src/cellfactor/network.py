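"""Directed cell- and type-level communication networks from the signed W.

The sign rule reads W[i, j] >= 0 as a signal from cell i to cell j and
W[i, j] < 0 as the reverse, so the communication from i to j is witnessed
twice: by the positive part of W[i, j] and by the negative part of
W[j, i].  The default combination adds the two witnesses; type-level
strengths are means over ordered cell pairs, and a type pair is called
significant when its strength strictly exceeds the mean of the whole
k x k matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import CellLabelMap
from .decomposition import CommunicationMatrix
from .errors import AggregationError, ComparisonError, CoverageError, ParameterError

__all__ = [
    "DirectedCellNetwork",
    "TypeCommMatrix",
    "ComparisonResult",
    "resolve_directions",
    "aggregate_to_types",
    "top_k_edges",
    "compare_conditions",
]


@dataclass
class DirectedCellNetwork:
    """Non-negative directed strengths between individual cells.

    ``strengths[i, i]`` is the autoregulation (self-loop) of cell i.
    """

    cell_ids: list[str]
    strengths: np.ndarray

    def edges(self) -> list[tuple[str, str, float]]:
        rows, cols = np.nonzero(self.strengths)
        return [
            (self.cell_ids[i], self.cell_ids[j], float(self.strengths[i, j]))
            for i, j in zip(rows, cols)
        ]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(self.strengths))


@dataclass
class TypeCommMatrix:
    """k x k aggregated cell-type communication strengths with significance."""

    type_labels: list[str]
    strengths: np.ndarray
    threshold: float
    significant: np.ndarray

    def pair_strength(self, source: str, target: str) -> float:
        i, j = self.type_labels.index(source), self.type_labels.index(target)
        return float(self.strengths[i, j])

    def is_significant(self, source: str, target: str) -> bool:
        i, j = self.type_labels.index(source), self.type_labels.index(target)
        return bool(self.significant[i, j])

    def significant_pairs(self) -> list[tuple[str, str]]:
        rows, cols = np.nonzero(self.significant)
        return [(self.type_labels[i], self.type_labels[j]) for i, j in zip(rows, cols)]

    def reordered(self, labels: list[str]) -> "TypeCommMatrix":
        if set(labels) != set(self.type_labels):
            raise ComparisonError("label sets differ")
        idx = [self.type_labels.index(t) for t in labels]
        block = np.ix_(idx, idx)
        return TypeCommMatrix(
            list(labels), self.strengths[block], self.threshold, self.significant[block]
        )


@dataclass
class ComparisonResult:
    """Per ordered type pair: 'both', 'condition1_only', 'condition2_only' or 'neither'."""

    categories: dict[tuple[str, str], str]

    def pairs_in(self, category: str) -> list[tuple[str, str]]:
        return sorted(p for p, c in self.categories.items() if c == category)


def resolve_directions(
    w: CommunicationMatrix, combine: str = "add"
) -> DirectedCellNetwork:
    """Apply the sign rule to W and combine the two directional witnesses.

    D[i, j] = max(W[i, j], 0) + max(-W[j, i], 0) for i != j (``combine=
    "mean"`` halves the sum); D[i, i] = max(W[i, i], 0).
    """
    W = w.w_values
    D = np.maximum(W, 0.0) + np.maximum(-W.T, 0.0)
    if combine == "mean":
        D = D / 2.0
    elif combine != "add":
        raise ParameterError(f"unknown combine rule {combine!r}")
    np.fill_diagonal(D, np.maximum(np.diag(W), 0.0))
    return DirectedCellNetwork(list(w.cell_ids), D)


def aggregate_to_types(
    net: DirectedCellNetwork, labels: CellLabelMap
) -> TypeCommMatrix:
    """Mean directed strength over ordered cell pairs, per ordered type pair.

    The within-type entry averages over all ordered pairs of the type's
    cells including self-loops (autocrine signalling).  The significance
    threshold is the mean of the full k x k matrix; strictly greater wins.
    """
    missing = [c for c in net.cell_ids if c not in labels.mapping]
    if missing:
        raise CoverageError(f"{len(missing)} cells unlabeled (e.g. {missing[:3]})")
    idx = labels.type_indices(net.cell_ids)
    k = labels.n_types
    for t in labels.type_labels:
        if idx[t].size == 0:
            raise AggregationError(f"cell type {t!r} has no cells")
    strengths = np.empty((k, k))
    for a, ta in enumerate(labels.type_labels):
        for b, tb in enumerate(labels.type_labels):
            strengths[a, b] = net.strengths[np.ix_(idx[ta], idx[tb])].mean()
    threshold = float(strengths.mean())
    return TypeCommMatrix(
        list(labels.type_labels), strengths, threshold, strengths > threshold
    )


def top_k_edges(t: TypeCommMatrix, k: int) -> list[tuple[str, str, float]]:
    """The k strongest nonzero ordered type pairs (ties by source, then target)."""
    if k < 1:
        raise ParameterError("k must be at least 1")
    edges = [
        (t.type_labels[i], t.type_labels[j], float(t.strengths[i, j]))
        for i in range(len(t.type_labels))
        for j in range(len(t.type_labels))
        if t.strengths[i, j] > 0
    ]
    edges.sort(key=lambda e: (-e[2], e[0], e[1]))
    return edges[:k]


def compare_conditions(t1: TypeCommMatrix, t2: TypeCommMatrix) -> ComparisonResult:
    """Classify every ordered type pair by its significance in two conditions."""
    if set(t1.type_labels) != set(t2.type_labels):
        raise ComparisonError(
            f"label sets differ: {sorted(t1.type_labels)} vs {sorted(t2.type_labels)}"
        )
    t2 = t2.reordered(list(t1.type_labels))
    categories: dict[tuple[str, str], str] = {}
    for i, a in enumerate(t1.type_labels):
        for j, b in enumerate(t1.type_labels):
            s1, s2 = bool(t1.significant[i, j]), bool(t2.significant[i, j])
            if s1 and s2:
                cat = "both"
            elif s1:
                cat = "condition1_only"
            elif s2:
                cat = "condition2_only"
            else:
                cat = "neither"
            categories[(a, b)] = cat
    return ComparisonResult(categories)
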