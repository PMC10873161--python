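"""Gene regulatory network inference via projection and lagged regression.

The left factor R of the decomposition is a weighted directed gene-gene
adjacency.  It can be inferred here from expression alone in three stages
per putative regulator u:

1. project u's expression onto the span of all other genes with an
   L1-penalized (LASSO) regression — a denoised version of u;
2. order the cells by the projected value, producing a monotone pseudotime
   series;
3. for every candidate target v, fit the lag-1 regression
   ``v_t = a*v_{t-1} + b*u_{t-1} + c`` along that order; the edge strength
   is the absolute t-statistic of b, kept when its p-value clears
   ``edge_alpha``.

For each unordered gene pair only the stronger of the two directed
strengths is retained, so at most one of R[u, v], R[v, u] is nonzero.
Any external GRN tool can substitute for this stage via
:func:`load_user_grn`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold

from .data_io import GeneExpressionMatrix, _sniff_delimiter
from .errors import AlignmentWarning, IdentifierError, ParameterError, ShapeError

__all__ = [
    "GRNMatrix",
    "MonotonePseudoSeries",
    "default_edge_alpha",
    "lasso_project",
    "monotone_order",
    "lagged_regression_edge",
    "infer_grn",
    "load_user_grn",
]

#: cross-validation grid used when no LASSO penalty is supplied
PENALTY_GRID = (0.01, 0.03, 0.1, 0.3, 1.0)
DEFAULT_MAX_GENES = 2000
#: family-wise null-network level: with the default edge threshold the
#: inferred network on pure-noise data is empty with probability ~ 1 - this
NULL_NETWORK_LEVEL = 1e-4


def default_edge_alpha(m: int) -> float:
    """Per-test edge p-value threshold for an m-gene inference.

    All m(m-1) ordered pairs are tested, so the per-test level is set to
    ``NULL_NETWORK_LEVEL / (m (m-1))``: a single false edge corrupts a
    whole column of the downstream communication operator, so the default
    keeps the expected number of false edges far below one.
    """
    return NULL_NETWORK_LEVEL / (m * (m - 1))


@dataclass
class GRNMatrix:
    """Weighted directed gene-gene adjacency aligned to an expression matrix.

    ``weights[i, j]`` is the regulatory strength of gene i -> gene j; the
    diagonal is identically zero.
    """

    gene_ids: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        m = len(self.gene_ids)
        if self.weights.shape != (m, m):
            raise ShapeError(f"GRN must be {m}x{m}, got {self.weights.shape}")
        if not np.all(np.isfinite(self.weights)):
            raise ShapeError("GRN contains non-finite weights")

    def edges(self) -> list[tuple[str, str, float]]:
        rows, cols = np.nonzero(self.weights)
        return [
            (self.gene_ids[i], self.gene_ids[j], float(self.weights[i, j]))
            for i, j in zip(rows, cols)
        ]


@dataclass
class MonotonePseudoSeries:
    """A permutation of cells along which projected values are non-decreasing."""

    cell_order: np.ndarray
    projected_values: np.ndarray


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd


def _project(
    y: np.ndarray, X: np.ndarray, penalty: float | None, seed: int | None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Fit the L1 projection of y on standardized X.

    Returns (prediction, coefficients, penalty used).
    """
    if penalty == 0:
        design = np.column_stack([np.ones(len(y)), X])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        return design @ coef, coef[1:], 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # benign convergence chatter on noise genes
        if penalty is None:
            # shuffled folds: cells are often stored grouped by type, and
            # contiguous folds would starve training of whole cell states
            folds = KFold(n_splits=3, shuffle=True, random_state=0 if seed is None else seed)
            cv = LassoCV(
                alphas=list(PENALTY_GRID), cv=folds, max_iter=50_000, tol=1e-8,
            )
            cv.fit(X, y)
            mean_mse = cv.mse_path_.mean(axis=1)
            best = int(np.argmin(mean_mse))
            # null-model guard: the projection is only trusted when its CV
            # error beats the intercept-only model by more than one SE of
            # the null; otherwise the projection is the gene's mean and the
            # cell order falls back to the stable original order
            null_errs = [
                np.mean((y[test] - y[train].mean()) ** 2)
                for train, test in folds.split(y)
            ]
            null_mean = float(np.mean(null_errs))
            null_se = float(np.std(null_errs, ddof=1) / np.sqrt(len(null_errs)))
            if mean_mse[best] > null_mean - null_se:
                return np.full_like(y, y.mean()), np.zeros(X.shape[1]), float(
                    max(PENALTY_GRID)
                )
            alpha = float(cv.alphas_[best])
        else:
            alpha = float(penalty)
        model = Lasso(alpha=alpha, max_iter=200_000, tol=1e-12)
        model.fit(X, y)
    return model.predict(X), model.coef_, alpha


def lasso_project(
    expr: GeneExpressionMatrix,
    gene: str,
    penalty: float | None = None,
    seed: int | None = None,
    exclude: str | None = None,
) -> np.ndarray:
    """L1-penalized linear prediction of one gene from all others.

    Predictors are standardized; ``penalty`` is the LASSO alpha in
    scikit-learn's parameterization (``penalty=0`` reduces to ordinary
    least squares; as penalty grows the projection shrinks to the gene's
    mean).  When ``penalty`` is None a 3-fold cross-validation over
    :data:`PENALTY_GRID` picks it.  ``exclude`` removes one further gene
    from the predictor set (used for the leave-one-out pseudotime when
    testing a directed edge onto that gene).
    """
    if expr.n_genes < 2:
        raise ParameterError("projection needs at least 2 genes")
    gi = expr.gene_index(gene)
    y = expr.values[gi]
    drop = [gi]
    if exclude is not None and exclude != gene:
        drop.append(expr.gene_index(exclude))
    X = _standardize(np.delete(expr.values, drop, axis=0).T)
    if X.shape[1] == 0:
        return np.full_like(y, y.mean())
    if penalty is not None and penalty < 0:
        raise ParameterError("penalty must be non-negative")
    pred, _, _ = _project(y, X, penalty, seed)
    return pred


def _series_values(series: MonotonePseudoSeries, raw: np.ndarray) -> np.ndarray:
    """The lagged-regression driver along a pseudotime order.

    The denoised projection is the regressor; when the projection carries
    no information (constant — the null-model guard fired) the raw values
    in the resulting stable order are used instead.
    """
    if np.ptp(series.projected_values) == 0:
        return raw[series.cell_order]
    return series.projected_values


def monotone_order(projected: np.ndarray) -> MonotonePseudoSeries:
    """Sort cells by projected value ascending; ties stable by cell index."""
    projected = np.asarray(projected, dtype=float)
    if projected.size < 3:
        raise ParameterError("need at least 3 cells")
    order = np.argsort(projected, kind="stable")
    return MonotonePseudoSeries(order, projected[order])


def lagged_regression_edge(
    u_series: np.ndarray, v_series: np.ndarray
) -> tuple[float, float]:
    """Lag-1 regression of v on u along a shared cell order.

    Fits ``v_t = a*v_{t-1} + b*u_{t-1} + c`` over t = 2..n and returns
    ``(|t-statistic of b|, two-sided p-value)``.  Degenerate designs
    (constant regressor, collinearity) yield ``(0.0, 1.0)``.
    """
    u = np.asarray(u_series, dtype=float)
    v = np.asarray(v_series, dtype=float)
    if u.shape != v.shape:
        raise ShapeError("series must share length")
    if u.size < 10:
        raise ParameterError("need at least 10 points for the lagged fit")
    strengths, ps = _lagged_tstats(u[:-1], v[np.newaxis, :])
    return float(strengths[0]), float(ps[0])


def _lagged_tstats(x: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized lag-1 fits of every row of V on a common lagged driver x.

    x has length n-1 (already lagged); V is (g, n).  For each row v the
    model is v[1:] ~ [1, v[:-1], x].  Returns |t| of the x coefficient and
    its two-sided p-value, with (0, 1) for singular designs.
    """
    g, n = V.shape
    np_ = n - 1
    Y = V[:, 1:]
    L = V[:, :-1]
    dof = np_ - 3
    if dof < 1 or np.ptp(x) == 0:
        return np.zeros(g), np.ones(g)

    Sx, Sxx = x.sum(), x @ x
    Sl = L.sum(axis=1)
    Sll = np.einsum("ij,ij->i", L, L)
    Slx = L @ x
    Sy = Y.sum(axis=1)
    Sly = np.einsum("ij,ij->i", L, Y)
    Sxy = Y @ x
    Syy = np.einsum("ij,ij->i", Y, Y)

    G = np.empty((g, 3, 3))
    G[:, 0, 0] = np_
    G[:, 0, 1] = G[:, 1, 0] = Sl
    G[:, 0, 2] = G[:, 2, 0] = Sx
    G[:, 1, 1] = Sll
    G[:, 1, 2] = G[:, 2, 1] = Slx
    G[:, 2, 2] = Sxx
    b = np.stack([Sy, Sly, Sxy], axis=1)

    # scale-aware singularity guard on the Gram determinant
    scale = np.maximum(np.abs(G).max(axis=(1, 2)), 1e-300) ** 3
    ok = np.abs(np.linalg.det(G)) > 1e-12 * scale
    strengths = np.zeros(g)
    ps = np.ones(g)
    if not np.any(ok):
        return strengths, ps

    Gi = np.linalg.inv(G[ok])
    coef = np.einsum("gij,gj->gi", Gi, b[ok])
    rss = Syy[ok] - np.einsum("gi,gi->g", coef, b[ok])
    rss = np.maximum(rss, 0.0)
    sigma2 = rss / dof
    var_b = sigma2 * Gi[:, 2, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(var_b > 0, coef[:, 2] / np.sqrt(var_b), 0.0)
    t = np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)
    strengths[ok] = np.abs(t)
    ps[ok] = 2.0 * scipy.stats.t.sf(np.abs(t), dof)
    return strengths, ps


def infer_grn(
    expr: GeneExpressionMatrix,
    penalty: float | None = None,
    max_genes: int = DEFAULT_MAX_GENES,
    edge_alpha: float | None = None,
    seed: int | None = None,
) -> GRNMatrix:
    """Infer the full directed GRN over (at most) the most variable genes.

    ``edge_alpha`` is the per-test p-value threshold for keeping an edge;
    the default is the multiplicity-aware :func:`default_edge_alpha`.
    When the matrix has more than ``max_genes`` genes it is restricted to
    the ``max_genes`` of largest variance; the returned ``gene_ids`` then
    name that subset and the caller should subset the expression matrix
    accordingly before the decomposition.
    """
    if expr.n_genes < 2:
        raise ParameterError("GRN inference needs at least 2 genes")
    if expr.n_genes > max_genes:
        variances = expr.values.var(axis=1)
        keep = np.sort(np.argsort(variances, kind="stable")[::-1][:max_genes])
        expr = expr.subset_genes([expr.gene_ids[i] for i in keep])
    m = expr.n_genes
    if edge_alpha is None:
        edge_alpha = default_edge_alpha(m)
    R = np.zeros((m, m))
    all_idx = np.arange(m)
    for ui in range(m):
        y = expr.values[ui]
        others = np.delete(all_idx, ui)
        proj, coef, alpha = _project(
            y, _standardize(expr.values[others].T), penalty, seed
        )
        series = monotone_order(proj)
        u_lagged = _series_values(series, y)[:-1]
        V = expr.values[:, series.cell_order]
        strengths, ps = _lagged_tstats(u_lagged, V)
        row = np.where(ps < edge_alpha, strengths, 0.0)
        row[ui] = 0.0
        # leave-one-out pseudotime: a target that informed u's projection
        # would otherwise dictate its own cell order (circularity), erasing
        # the lag asymmetry that decides the direction of regulation
        for vi in others[np.flatnonzero(coef)]:
            keep = others[others != vi]
            if keep.size == 0:  # two-gene case: no predictors left
                proj2 = np.full_like(y, y.mean())
            else:
                proj2, _, _ = _project(
                    y, _standardize(expr.values[keep].T), penalty, seed
                )
            series2 = monotone_order(proj2)
            st2, p2 = _lagged_tstats(
                _series_values(series2, y)[:-1],
                expr.values[vi : vi + 1, series2.cell_order],
            )
            row[vi] = st2[0] if p2[0] < edge_alpha else 0.0
        R[ui] = row
    # direction resolution: keep the stronger of each reciprocal pair;
    # exact ties go to the lower-index regulator
    upper = np.triu_indices(m, k=1)
    fwd, bwd = R[upper], R.T[upper]
    R[upper] = np.where(fwd >= bwd, fwd, 0.0)
    R.T[upper] = np.where(bwd > fwd, bwd, 0.0)
    return GRNMatrix(list(expr.gene_ids), R)


def load_user_grn(path: str | Path, expr: GeneExpressionMatrix) -> GRNMatrix:
    """Load a user-supplied GRN and align it to the expression gene order.

    Accepts a dense square table (gene IDs as header and first column) or a
    3-column edge list (regulator, target, weight).  Genes of the GRN must
    all exist in the expression matrix; expression genes absent from the
    GRN get zero rows/columns and are reported in a warning.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_delimiter(path))
    m = expr.n_genes
    weights = np.zeros((m, m))
    index = {g: i for i, g in enumerate(expr.gene_ids)}

    first_col = str(df.columns[0]).lower()
    is_edge_list = df.shape[1] == 3 and first_col in {"source", "regulator", "from"}
    if is_edge_list:
        covered = set()
        for src, tgt, w in df.itertuples(index=False):
            src, tgt = str(src), str(tgt)
            for g in (src, tgt):
                if g not in index:
                    raise IdentifierError(f"GRN gene {g!r} not in expression matrix")
                covered.add(g)
            weights[index[src], index[tgt]] = float(w)
    else:
        dense = pd.read_csv(path, sep=_sniff_delimiter(path), index_col=0)
        genes = [str(g) for g in dense.index]
        if list(dense.columns.astype(str)) != genes and set(dense.columns.astype(str)) != set(genes):
            raise ShapeError("dense GRN must be square with matching row/column genes")
        for g in genes:
            if g not in index:
                raise IdentifierError(f"GRN gene {g!r} not in expression matrix")
        sub = dense.loc[genes, genes].to_numpy(dtype=float)
        ids = [index[g] for g in genes]
        weights[np.ix_(ids, ids)] = sub
        covered = set(genes)

    missing = [g for g in expr.gene_ids if g not in covered]
    if missing:
        warnings.warn(
            f"{len(missing)} expression genes absent from the GRN get zero "
            f"rows/columns (e.g. {missing[:3]})",
            AlignmentWarning,
            stacklevel=2,
        )
    np.fill_diagonal(weights, 0.0)
    return GRNMatrix(list(expr.gene_ids), weights)
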