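"""Readers and writers for expression matrices, labels, L-R tables and networks.

All on-disk formats are plain text: dense TSV/CSV tables, Matrix Market
coordinate files with gene/barcode sidecars, and headered TSV tables for
labels, ligand-receptor databases, ground truth and edge lists.  Identifier
order is preserved end-to-end; every downstream matrix indexes against the
gene and cell orders established here.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import (
    AlignmentWarning,
    CoverageError,
    IdentifierError,
    ShapeError,
    ValidationError,
)

__all__ = [
    "GeneExpressionMatrix",
    "CellLabelMap",
    "LRRecord",
    "LRDatabaseTable",
    "GroundTruthTable",
    "read_expression",
    "read_labels",
    "read_lr_database",
    "read_ground_truth",
    "write_network",
    "write_matrix",
    "read_matrix",
    "normalize_expression",
]


def _check_unique(ids: Sequence[str], kind: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise IdentifierError(f"duplicate {kind} identifiers: {sorted(set(dups))[:5]}")
    return ids


@dataclass
class GeneExpressionMatrix:
    """A genes x cells expression matrix with ordered identifiers.

    Values are non-negative finite reals (normalized expression; log scale
    recommended).  Rows follow ``gene_ids``, columns follow ``cell_ids``.
    """

    gene_ids: list[str]
    cell_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.cell_ids = _check_unique(self.cell_ids, "cell")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ShapeError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ShapeError(
                f"expression matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression matrix contains non-finite entries")
        if np.any(self.values < 0):
            raise ValidationError("expression matrix contains negative entries")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise IdentifierError(f"unknown gene {gene!r}") from None

    def gene_values(self, gene: str) -> np.ndarray:
        return self.values[self.gene_index(gene)]

    def subset_genes(self, genes: Sequence[str]) -> "GeneExpressionMatrix":
        idx = [self.gene_index(g) for g in genes]
        return GeneExpressionMatrix(list(genes), list(self.cell_ids), self.values[idx])

    def subset_cells(self, indices: Sequence[int]) -> "GeneExpressionMatrix":
        indices = list(indices)
        return GeneExpressionMatrix(
            list(self.gene_ids),
            [self.cell_ids[i] for i in indices],
            self.values[:, indices],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


@dataclass
class CellLabelMap:
    """cell_id -> cell-type label; type order is first-appearance order."""

    mapping: dict[str, str]
    type_labels: list[str]

    @property
    def n_types(self) -> int:
        return len(self.type_labels)

    def labels_for(self, cell_ids: Sequence[str]) -> list[str]:
        return [self.mapping[c] for c in cell_ids]

    def type_indices(self, cell_ids: Sequence[str]) -> dict[str, np.ndarray]:
        """Column indices of each type, in type_labels order."""
        labels = np.asarray(self.labels_for(cell_ids))
        return {t: np.flatnonzero(labels == t) for t in self.type_labels}

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "CellLabelMap":
        mapping: dict[str, str] = {}
        order: list[str] = []
        for cell, lab in pairs:
            mapping[str(cell)] = str(lab)
            if lab not in order:
                order.append(str(lab))
        return cls(mapping, order)


@dataclass(frozen=True)
class LRRecord:
    """One ligand-receptor pair; either side may be a multi-subunit complex."""

    ligand_subunits: tuple[str, ...]
    receptor_subunits: tuple[str, ...]
    pathway: str | None = None

    def __post_init__(self) -> None:
        if not self.ligand_subunits or not self.receptor_subunits:
            raise ValidationError("L-R record with empty subunit list")
        if any(not s for s in self.ligand_subunits + self.receptor_subunits):
            raise ValidationError("L-R record with empty gene symbol")

    @property
    def ligand_name(self) -> str:
        return "+".join(self.ligand_subunits)

    @property
    def receptor_name(self) -> str:
        return "+".join(self.receptor_subunits)


@dataclass
class LRDatabaseTable:
    records: list[LRRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def deduplicated(self) -> "LRDatabaseTable":
        seen: set[tuple[tuple[str, ...], tuple[str, ...]]] = set()
        out = []
        for r in self.records:
            key = (r.ligand_subunits, r.receptor_subunits)
            if key not in seen:
                seen.add(key)
                out.append(r)
        return LRDatabaseTable(out)

    def gene_symbols(self) -> set[str]:
        genes: set[str] = set()
        for r in self.records:
            genes.update(r.ligand_subunits)
            genes.update(r.receptor_subunits)
        return genes


@dataclass
class GroundTruthTable:
    """Ordered (source_type, target_type) pairs with a supported flag."""

    records: dict[tuple[str, str], bool]

    def __post_init__(self) -> None:
        if not isinstance(self.records, dict):
            rec = {}
            for s, t, flag in self.records:
                if (s, t) in rec:
                    raise ValidationError(f"duplicate ground-truth pair ({s}, {t})")
                rec[(s, t)] = bool(flag)
            self.records = rec

    @property
    def n_positive(self) -> int:
        return sum(self.records.values())

    @property
    def n_negative(self) -> int:
        return len(self.records) - self.n_positive


# ---------------------------------------------------------------------------
# expression readers


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def _read_dense_expression(path: Path) -> GeneExpressionMatrix:
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    genes = _check_unique([str(g) for g in df.index], "gene")
    cells = _check_unique([str(c) for c in df.columns], "cell")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric entry in expression table: {exc}") from None
    return GeneExpressionMatrix(genes, cells, values)


def _read_mtx_expression(path: Path) -> GeneExpressionMatrix:
    path = Path(path)
    if path.is_dir():
        mtx = path / "matrix.mtx"
        genes_file, cells_file = path / "genes.tsv", path / "barcodes.tsv"
    else:
        mtx = path
        genes_file = path.with_name("genes.tsv")
        cells_file = path.with_name("barcodes.tsv")
    mat = scipy.io.mmread(mtx)
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    genes = [ln.split("\t")[0].strip() for ln in genes_file.read_text().splitlines() if ln.strip()]
    cells = [ln.split("\t")[0].strip() for ln in cells_file.read_text().splitlines() if ln.strip()]
    if mat.shape != (len(genes), len(cells)):
        raise ShapeError(
            f"matrix declares shape {mat.shape} but sidecars list "
            f"{len(genes)} genes and {len(cells)} cells"
        )
    return GeneExpressionMatrix(genes, cells, np.asarray(mat, dtype=float))


def read_expression(path: str | Path, format_hint: str | None = None) -> GeneExpressionMatrix:
    """Read a genes x cells expression matrix.

    Parameters
    ----------
    path
        Dense TSV/CSV table (genes as rows, first column gene IDs, header
        row cell IDs) or a Matrix Market ``.mtx`` file / directory with
        ``genes.tsv`` and ``barcodes.tsv`` sidecars.
    format_hint
        ``"dense"`` or ``"mtx"``; inferred from the path when ``None``.
    """
    path = Path(path)
    if format_hint is None:
        format_hint = "mtx" if (path.suffix == ".mtx" or path.is_dir()) else "dense"
    if format_hint == "mtx":
        return _read_mtx_expression(path)
    if format_hint == "dense":
        return _read_dense_expression(path)
    raise ValidationError(f"unknown format hint {format_hint!r}")


def normalize_expression(
    expr: GeneExpressionMatrix, scale: float = 1e4
) -> GeneExpressionMatrix:
    """Optional preprocessing: library-size scaling to ``scale`` then log1p.

    Off by default throughout the package: input values are otherwise used
    exactly as provided.
    """
    totals = expr.values.sum(axis=0)
    totals = np.where(totals > 0, totals, 1.0)
    scaled = np.log1p(expr.values / totals * scale)
    return GeneExpressionMatrix(list(expr.gene_ids), list(expr.cell_ids), scaled)


def read_labels(path: str | Path, expr: GeneExpressionMatrix) -> CellLabelMap:
    """Read a two-column (cell_id, type_label) table and validate coverage.

    Label rows for cells absent from ``expr`` are dropped with a warning;
    an expression cell with no label raises :class:`CoverageError`.
    """
    df = pd.read_csv(path, sep=_sniff_delimiter(Path(path)))
    if df.shape[1] < 2:
        raise ValidationError("label table needs two columns: cell_id, type_label")
    cell_col, type_col = df.columns[:2]
    known = set(expr.cell_ids)
    extra = [str(c) for c in df[cell_col] if str(c) not in known]
    if extra:
        warnings.warn(
            f"dropping {len(extra)} label rows for unknown cells (e.g. {extra[:3]})",
            AlignmentWarning,
            stacklevel=2,
        )
    pairs = [
        (str(c), str(t))
        for c, t in zip(df[cell_col], df[type_col])
        if str(c) in known
    ]
    labels = CellLabelMap.from_pairs(pairs)
    missing = [c for c in expr.cell_ids if c not in labels.mapping]
    if missing:
        raise CoverageError(f"{len(missing)} cells unlabeled (e.g. {missing[:3]})")
    return labels


# ---------------------------------------------------------------------------
# L-R database

_COMPLEX_RE = re.compile(r"^\(?([^()]+)\)?$")


def parse_complex(text: str) -> tuple[str, ...]:
    """Parse a subunit spec like ``"ITGAM+ITGB2"`` or ``"(ITGAM+ITGB2)"``."""
    m = _COMPLEX_RE.match(text.strip())
    if not m:
        raise ValidationError(f"cannot parse complex spec {text!r}")
    subunits = tuple(s.strip() for s in m.group(1).split("+"))
    if any(not s for s in subunits):
        raise ValidationError(f"empty subunit in complex spec {text!r}")
    return subunits


def parse_interaction(text: str) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Parse a one-string pair like ``"C3-(ITGAM+ITGB2)"`` or ``"L_(R1+R2)"``.

    The ligand and receptor parts are separated by the first ``-`` or ``_``
    that is outside parentheses.
    """
    depth = 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        elif ch in "-_" and depth == 0:
            return parse_complex(text[:i]), parse_complex(text[i + 1 :])
    raise ValidationError(f"cannot split interaction spec {text!r}")


def read_lr_database(path: str | Path) -> LRDatabaseTable:
    """Read an L-R table.

    Accepted dialects: ``ligand``/``receptor`` columns whose entries may be
    ``+``-joined (optionally parenthesized) complexes, or a single
    ``interaction`` column of ``"LIG_(R1+R2)"``-style strings.  An optional
    ``pathway`` column is carried through.
    """
    df = pd.read_csv(path, sep=_sniff_delimiter(Path(path)))
    cols = {c.lower(): c for c in df.columns}
    records = []
    if "ligand" in cols and "receptor" in cols:
        for _, row in df.iterrows():
            records.append(
                LRRecord(
                    parse_complex(str(row[cols["ligand"]])),
                    parse_complex(str(row[cols["receptor"]])),
                    str(row[cols["pathway"]]) if "pathway" in cols else None,
                )
            )
    elif "interaction" in cols:
        for _, row in df.iterrows():
            lig, rec = parse_interaction(str(row[cols["interaction"]]))
            records.append(
                LRRecord(lig, rec, str(row[cols["pathway"]]) if "pathway" in cols else None)
            )
    else:
        raise ValidationError(
            "L-R table needs 'ligand'+'receptor' columns or an 'interaction' column"
        )
    return LRDatabaseTable(records)


def read_ground_truth(path: str | Path) -> GroundTruthTable:
    df = pd.read_csv(path, sep=_sniff_delimiter(Path(path)))
    if df.shape[1] < 3:
        raise ValidationError("ground truth needs columns: source_type, target_type, supported")
    s_col, t_col, f_col = df.columns[:3]
    records: dict[tuple[str, str], bool] = {}
    for _, row in df.iterrows():
        key = (str(row[s_col]), str(row[t_col]))
        if key in records:
            raise ValidationError(f"duplicate ground-truth pair {key}")
        flag = row[f_col]
        if isinstance(flag, str):
            flag = flag.strip().lower() in {"1", "true", "yes"}
        records[key] = bool(flag)
    return GroundTruthTable(records)


# ---------------------------------------------------------------------------
# writers


def write_network(
    net: Iterable[tuple[str, str, float]], path: str | Path
) -> None:
    """Write an edge list as a three-column TSV.

    Rows are ordered by descending strength, ties broken by source then
    target label, so output is deterministic.
    """
    edges = [(str(s), str(t), float(w)) for s, t, w in net]
    if any(not np.isfinite(w) for _, _, w in edges):
        raise ValidationError("non-finite edge strength")
    edges.sort(key=lambda e: (-e[2], e[0], e[1]))
    df = pd.DataFrame(edges, columns=["source", "target", "strength"])
    df.to_csv(path, sep="\t", index=False)


def write_matrix(
    values: np.ndarray, row_ids: Sequence[str], col_ids: Sequence[str], path: str | Path
) -> None:
    pd.DataFrame(values, index=list(row_ids), columns=list(col_ids)).to_csv(path, sep="\t")


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    df = pd.read_csv(path, sep=_sniff_delimiter(Path(path)), index_col=0)
    return df.to_numpy(dtype=float), [str(i) for i in df.index], [str(c) for c in df.columns]
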