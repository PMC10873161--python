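"""Benchmarking utilities: mean-threshold binarization, ROC/AUC, spatial
neighbor ground truth and the global L-R coexpression correlation check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats
from scipy.spatial import cKDTree
from sklearn.metrics import roc_curve

from .data_io import (
    CellLabelMap,
    GeneExpressionMatrix,
    GroundTruthTable,
    LRDatabaseTable,
    _sniff_delimiter,
)
from .errors import DegenerateTruthError, ParameterError, ValidationError
from .lr import collapse_complex
from .network import TypeCommMatrix

__all__ = [
    "ROCResult",
    "SpotTable",
    "read_spots",
    "binarize_mean",
    "roc_auc",
    "spatial_truth",
    "lr_global_correlation",
]


@dataclass
class ROCResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class SpotTable:
    """Spatial capture spots with planar coordinates and a type label each."""

    spot_ids: list[str]
    xy: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        if len(set(self.spot_ids)) != len(self.spot_ids):
            raise ValidationError("duplicate spot IDs")
        if self.xy.shape != (len(self.spot_ids), 2) or not np.all(np.isfinite(self.xy)):
            raise ValidationError("spot coordinates must be finite n x 2")


def read_spots(path: str | Path) -> SpotTable:
    """Read a TSV with columns spot_id, x, y, type_label."""
    df = pd.read_csv(path, sep=_sniff_delimiter(Path(path)))
    if df.shape[1] < 4:
        raise ValidationError("spot table needs columns: spot_id, x, y, type_label")
    c = df.columns
    return SpotTable(
        [str(s) for s in df[c[0]]],
        df[[c[1], c[2]]].to_numpy(dtype=float),
        [str(t) for t in df[c[3]]],
    )


def binarize_mean(t: TypeCommMatrix) -> np.ndarray:
    """1 where a type-pair strength strictly exceeds the matrix mean, else 0."""
    return (t.strengths > t.strengths.mean()).astype(int)


def roc_auc(
    scores: dict[tuple[str, str], float], truth: GroundTruthTable
) -> ROCResult:
    """ROC curve and AUC of type-pair scores against a ground-truth table.

    The curve sweeps the score threshold over all distinct values; the AUC
    is additionally checked against the midrank Mann-Whitney statistic
    (the two agree to 1e-9 by construction).
    """
    pairs = sorted(scores)
    missing = [p for p in pairs if p not in truth.records]
    if missing:
        raise ValidationError(f"pairs missing from ground truth: {missing[:5]}")
    y = np.array([truth.records[p] for p in pairs], dtype=int)
    s = np.array([scores[p] for p in pairs], dtype=float)
    if y.all() or not y.any():
        raise DegenerateTruthError("ROC needs at least one positive and one negative")
    fpr, tpr, thr = roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    # independent rank-sum (Mann-Whitney with midranks) formulation
    ranks = scipy.stats.rankdata(s)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    auc_mw = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    if abs(auc - auc_mw) > 1e-9:  # pragma: no cover - internal consistency
        raise RuntimeError(f"ROC integral {auc} disagrees with rank-sum AUC {auc_mw}")
    return ROCResult(thr, fpr, tpr, auc)


def spatial_truth(spots: SpotTable, neighbor_factor: float = 1.5) -> GroundTruthTable:
    """Ground truth from spatial adjacency.

    Two spots are neighbors when their Euclidean distance is at most
    ``neighbor_factor`` times the median nearest-neighbor distance; an
    ordered type pair is supported when any neighboring spot pair carries
    those labels in either orientation.
    """
    if len(spots.spot_ids) < 2:
        raise ParameterError("need at least 2 spots")
    label_set = sorted(set(spots.labels))
    if len(label_set) < 2:
        raise DegenerateTruthError("need at least 2 distinct spot labels")
    tree = cKDTree(spots.xy)
    nn_dist, _ = tree.query(spots.xy, k=2)
    radius = neighbor_factor * float(np.median(nn_dist[:, 1]))
    supported: set[tuple[str, str]] = set()
    for i, j in tree.query_pairs(r=radius):
        a, b = spots.labels[i], spots.labels[j]
        supported.add((a, b))
        supported.add((b, a))
    records = {
        (a, b): (a, b) in supported for a in label_set for b in label_set
    }
    return GroundTruthTable(records)


def lr_global_correlation(
    t: TypeCommMatrix,
    expr: GeneExpressionMatrix,
    labels: CellLabelMap,
    lrdb: LRDatabaseTable,
) -> tuple[float, float]:
    """Correlate type-pair communication strengths with L-R coexpression.

    Each ordered type pair gets a coexpression score: the mean over
    database pairs of (mean ligand expression in the source type) x (mean
    receptor expression in the target type), complexes collapsed by
    subunit minimum.  Returns the Pearson (r, p) between the flattened
    strengths and these scores; a constant score vector is degenerate and
    yields (0.0, 1.0).
    """
    usable = [
        rec
        for rec in lrdb.deduplicated().records
        if all(s in set(expr.gene_ids) for s in rec.ligand_subunits + rec.receptor_subunits)
    ]
    if not usable:
        raise ValidationError("no database pair is measurable in the expression matrix")
    k = len(t.type_labels)
    if k * k < 3:
        raise ParameterError("need at least 3 ordered type pairs")
    idx = labels.type_indices(expr.cell_ids)
    lig_means = np.array(
        [
            [collapse_complex(expr, rec.ligand_subunits)[idx[a]].mean() for a in t.type_labels]
            for rec in usable
        ]
    )
    rec_means = np.array(
        [
            [collapse_complex(expr, rec.receptor_subunits)[idx[b]].mean() for b in t.type_labels]
            for rec in usable
        ]
    )
    # scores[a, b] = mean over pairs of lig_mean[pair, a] * rec_mean[pair, b]
    scores = np.einsum("pa,pb->ab", lig_means, rec_means) / len(usable)
    flat_s, flat_c = t.strengths.ravel(), scores.ravel()
    if np.ptp(flat_c) == 0 or np.ptp(flat_s) == 0:
        warnings.warn("constant score vector; correlation undefined", stacklevel=2)
        return 0.0, 1.0
    res = scipy.stats.pearsonr(flat_s, flat_c)
    return float(res.statistic), float(res.pvalue)
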