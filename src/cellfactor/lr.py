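"""Ligand-receptor pair nomination for an inferred type-level communication.

Candidate genes are the intersection of the expression matrix's genes (G1)
with the L-R database's genes (G2); universally expressed genes — those
expressed in more than half of the cell types — are removed (G3 -> G4).
For a communication from type A (m1 cells) to type B (m2 cells):

1. genes zero in more than 70% of a type's cells are dropped for that type;
2. ligand expression over A's cells and receptor expression over B's cells
   are each sorted in descending order;
3. the two sorted profiles, truncated to min(m1, m2), are compared by
   Pearson correlation with an exact t-transform p-value;
4. p-values are Bonferroni-corrected over the pairs tested for this
   ordered type pair; corrected p < 0.01 is called significant.

Multi-subunit complexes are collapsed to their per-cell subunit minimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.stats

from .data_io import CellLabelMap, GeneExpressionMatrix, LRDatabaseTable
from .errors import IdentifierError, ParameterError, ValidationError

__all__ = [
    "CandidateGeneSets",
    "LRTestResult",
    "collapse_complex",
    "specificity_filter",
    "zero_fraction_filter",
    "sorted_pearson_test",
    "bonferroni_adjust",
    "identify_lr_pairs",
]

DEFAULT_ALPHA = 0.01
DEFAULT_EXPRESSED_FRAC = 0.3
DEFAULT_ZERO_FRAC = 0.7


@dataclass
class CandidateGeneSets:
    """The nested candidate sets g1 ⊇ g3 ⊇ g4 of the filtering cascade."""

    g1: set[str]
    g2: set[str]
    g3: set[str]
    g4: set[str]


@dataclass
class LRTestResult:
    ligand: str
    receptor: str
    m1: int
    m2: int
    r: float
    p: float
    p_adj: float
    significant: bool
    degenerate: bool = False


def collapse_complex(
    expr: GeneExpressionMatrix, subunits: Sequence[str]
) -> np.ndarray:
    """Per-cell value of a (possibly multi-subunit) complex: subunit minimum."""
    if not subunits:
        raise ValidationError("empty subunit list")
    rows = [expr.gene_index(s) for s in subunits]
    return expr.values[rows].min(axis=0)


def specificity_filter(
    expr: GeneExpressionMatrix,
    labels: CellLabelMap,
    g3: set[str],
    expressed_frac: float = DEFAULT_EXPRESSED_FRAC,
) -> set[str]:
    """Drop universally expressed genes.

    A gene counts as expressed in a type when its nonzero fraction among
    that type's cells is at least ``expressed_frac``; genes expressed in
    strictly more than half of the k types are removed.
    """
    k = labels.n_types
    if k < 2:
        raise ParameterError("specificity filter needs at least 2 cell types")
    idx = labels.type_indices(expr.cell_ids)
    kept = set()
    for gene in g3:
        gi = expr.gene_index(gene)
        n_expressed = sum(
            1
            for t in labels.type_labels
            if np.count_nonzero(expr.values[gi, idx[t]]) >= expressed_frac * idx[t].size
        )
        if not n_expressed > k / 2:
            kept.add(gene)
    return kept


def zero_fraction_filter(
    expr: GeneExpressionMatrix,
    labels: CellLabelMap,
    type_label: str,
    genes: set[str],
    zero_frac: float = DEFAULT_ZERO_FRAC,
) -> set[str]:
    """Keep genes whose zero fraction within the type is at most ``zero_frac``."""
    idx = labels.type_indices(expr.cell_ids).get(type_label)
    if idx is None or idx.size == 0:
        raise ParameterError(f"type {type_label!r} has no cells")
    kept = set()
    for gene in genes:
        vals = expr.values[expr.gene_index(gene), idx]
        if np.count_nonzero(vals == 0) <= zero_frac * idx.size:
            kept.add(gene)
    return kept


def sorted_pearson_test(
    ligand_vals: np.ndarray, receptor_vals: np.ndarray
) -> tuple[float, float, bool]:
    """Descending-sort both profiles, truncate to the common length, correlate.

    Returns ``(r, p, degenerate)``; a constant truncated profile makes the
    correlation undefined and yields ``(0.0, 1.0, True)``.  The p-value is
    the two-sided exact t-transform with min(m1, m2) - 2 degrees of freedom.
    """
    lig = np.sort(np.asarray(ligand_vals, dtype=float))[::-1]
    rec = np.sort(np.asarray(receptor_vals, dtype=float))[::-1]
    t = min(lig.size, rec.size)
    if t < 3:
        raise ParameterError("need at least 3 cells on each side")
    lig, rec = lig[:t], rec[:t]
    if np.ptp(lig) == 0 or np.ptp(rec) == 0:
        return 0.0, 1.0, True
    res = scipy.stats.pearsonr(lig, rec)
    return float(res.statistic), float(res.pvalue), False


def bonferroni_adjust(p_values: Sequence[float]) -> list[float]:
    """p_adj = min(1, p * M) with M the number of tests in the family."""
    ps = np.asarray(list(p_values), dtype=float)
    if ps.size and (np.any(ps < 0) or np.any(ps > 1) or not np.all(np.isfinite(ps))):
        raise ValidationError("p-values must lie in [0, 1]")
    return [float(min(1.0, p * ps.size)) for p in ps]


def candidate_gene_sets(
    expr: GeneExpressionMatrix,
    labels: CellLabelMap,
    lrdb: LRDatabaseTable,
    expressed_frac: float = DEFAULT_EXPRESSED_FRAC,
) -> CandidateGeneSets:
    g1 = set(expr.gene_ids)
    g2 = lrdb.gene_symbols()
    g3 = g1 & g2
    g4 = specificity_filter(expr, labels, g3, expressed_frac=expressed_frac)
    return CandidateGeneSets(g1, g2, g3, g4)


def identify_lr_pairs(
    expr: GeneExpressionMatrix,
    labels: CellLabelMap,
    lrdb: LRDatabaseTable,
    source_type: str,
    target_type: str,
    alpha: float = DEFAULT_ALPHA,
    expressed_frac: float = DEFAULT_EXPRESSED_FRAC,
    zero_frac: float = DEFAULT_ZERO_FRAC,
) -> list[LRTestResult]:
    """Nominate L-R pairs behind a source_type -> target_type communication.

    Runs the full filtering cascade, tests every surviving database pair
    with the descending-sort Pearson statistic, Bonferroni-corrects over
    the tested pairs and returns results sorted by adjusted p-value.
    """
    for t in (source_type, target_type):
        if t not in labels.type_labels:
            raise ParameterError(f"unknown cell type {t!r}")
    idx = labels.type_indices(expr.cell_ids)
    m1, m2 = idx[source_type].size, idx[target_type].size
    if m1 < 3 or m2 < 3:
        raise ParameterError("both cell types need at least 3 cells")

    sets = candidate_gene_sets(expr, labels, lrdb, expressed_frac=expressed_frac)
    lig_ok = zero_fraction_filter(expr, labels, source_type, sets.g4, zero_frac)
    rec_ok = zero_fraction_filter(expr, labels, target_type, sets.g4, zero_frac)

    tested = []
    for rec in lrdb.deduplicated().records:
        all_subunits = rec.ligand_subunits + rec.receptor_subunits
        missing = [s for s in all_subunits if s not in sets.g1]
        if missing:
            warnings.warn(
                f"skipping {rec.ligand_name}-{rec.receptor_name}: subunits "
                f"{missing} absent from the expression matrix",
                stacklevel=2,
            )
            continue
        if not all(s in lig_ok for s in rec.ligand_subunits):
            continue
        if not all(s in rec_ok for s in rec.receptor_subunits):
            continue
        lig_vals = collapse_complex(expr, rec.ligand_subunits)[idx[source_type]]
        rec_vals = collapse_complex(expr, rec.receptor_subunits)[idx[target_type]]
        r, p, degenerate = sorted_pearson_test(lig_vals, rec_vals)
        tested.append((rec, r, p, degenerate))

    p_adj = bonferroni_adjust([p for _, _, p, _ in tested])
    results = [
        LRTestResult(
            ligand=rec.ligand_name,
            receptor=rec.receptor_name,
            m1=m1,
            m2=m2,
            r=r,
            p=p,
            p_adj=pa,
            significant=pa < alpha,
            degenerate=degenerate,
        )
        for (rec, r, p, degenerate), pa in zip(tested, p_adj)
    ]
    results.sort(key=lambda x: (x.p_adj, x.p, x.ligand, x.receptor))
    return results
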