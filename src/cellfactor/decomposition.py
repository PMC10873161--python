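"""The algebraic core: A = R Sigma W solved by Moore-Penrose pseudoinverse.

A genes x cells matrix A is factorized into a gene regulatory adjacency R
(m x m), the singular matrix Sigma of A (m x n) and a cell-cell
communication matrix W (n x n):

    A = R Sigma W        =>        W = (R Sigma)^+ A

W is the minimum-Frobenius-norm least-squares solution; its sign encodes
direction (W[i, j] >= 0: cell i signals cell j; negative: the reverse) and
its magnitude the strength, with the diagonal read as autoregulation.

When there are more cells than genes (n > m) the system is underdetermined
column-rank-wise; :func:`compute_W_sampled` then repeatedly solves the
decomposition on random cell subsets of at most m cells and averages the
entries over the rounds in which both cells of a pair appear.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_io import GeneExpressionMatrix
from .errors import (
    DegenerateOperatorError,
    IdentifierError,
    ParameterError,
    RankDeficiencyWarning,
    ShapeError,
    ValidationError,
)
from .grn import GRNMatrix

__all__ = [
    "SingularSpectrum",
    "CommunicationMatrix",
    "compute_sigma",
    "compute_W",
    "compute_W_sampled",
    "reconstruct",
    "reconstruction_mse",
    "default_rcond",
]


@dataclass
class SingularSpectrum:
    """The singular matrix of A, stored as its diagonal plus shape.

    ``sigma_values`` are non-increasing and non-negative; ``u_matrix``
    (m x r) and ``v_matrix`` (n x r) are the singular vectors, retained for
    diagnostics, with A = U diag(sigma) V^T.
    """

    sigma_values: np.ndarray
    shape: tuple[int, int]
    u_matrix: np.ndarray
    v_matrix: np.ndarray

    def materialize(self) -> np.ndarray:
        """The dense m x n singular matrix."""
        m, n = self.shape
        S = np.zeros((m, n))
        r = len(self.sigma_values)
        S[:r, :r] = np.diag(self.sigma_values)
        return S


@dataclass
class CommunicationMatrix:
    """The solved right factor W over the expression matrix's cells."""

    cell_ids: list[str]
    w_values: np.ndarray

    def __post_init__(self) -> None:
        self.w_values = np.asarray(self.w_values, dtype=float)
        n = len(self.cell_ids)
        if self.w_values.shape != (n, n):
            raise ShapeError(f"W must be {n}x{n}, got {self.w_values.shape}")
        if not np.all(np.isfinite(self.w_values)):
            raise ValidationError("W contains non-finite entries")


def compute_sigma(expr: GeneExpressionMatrix) -> SingularSpectrum:
    """Singular value decomposition of the expression matrix."""
    A = expr.values
    if not np.all(np.isfinite(A)):
        raise ValidationError("expression matrix contains non-finite entries")
    u, s, vh = np.linalg.svd(A, full_matrices=False)
    return SingularSpectrum(s, A.shape, u, vh.T)


def default_rcond(shape: tuple[int, int]) -> float:
    """Standard pseudoinverse cutoff: max(m, n) * machine epsilon."""
    return max(shape) * np.finfo(float).eps


def _r_sigma(grn: GRNMatrix, sigma: SingularSpectrum) -> np.ndarray:
    """R Sigma computed by column-scaling R (identical to the dense product)."""
    m, n = sigma.shape
    r = len(sigma.sigma_values)
    RS = np.zeros((m, n))
    RS[:, :r] = grn.weights[:, :r] * sigma.sigma_values[np.newaxis, :]
    return RS


def compute_W(
    expr: GeneExpressionMatrix,
    grn: GRNMatrix,
    sigma: SingularSpectrum | None = None,
    rcond: float | None = None,
    ridge: float | None = None,
) -> CommunicationMatrix:
    """Solve W = (R Sigma)^+ A.

    Singular values of R Sigma below ``rcond * sigma_max`` are treated as
    zero; the result is the minimum-norm least-squares solution of
    (R Sigma) W ~= A.  A rank of R Sigma below n leaves part of W
    undetermined and triggers a :class:`RankDeficiencyWarning`.

    ``ridge`` switches the exact pseudoinverse to a Tikhonov-filtered one:
    the inverse filter 1/s becomes s / (s^2 + lambda) with
    ``lambda = (ridge * s_max)^2``.  The pseudoinverse amplifies the
    operator's weakest resolved directions by s_max / s_min, which on
    noisy expression data lets measurement noise dominate W; the ridge
    filter caps the amplification at 1 / (2 * ridge * s_max) with no hard
    cliff.  ``None`` (the default) keeps the exact algebraic solution.
    """
    if grn.gene_ids != expr.gene_ids:
        raise IdentifierError("GRN gene order does not match the expression matrix")
    if sigma is None:
        sigma = compute_sigma(expr)
    if sigma.shape != expr.shape:
        raise ShapeError("singular spectrum was not computed from this matrix")
    RS = _r_sigma(grn, sigma)
    if not np.any(RS):
        raise DegenerateOperatorError("R Sigma is identically zero; no communication inferable")
    if rcond is None:
        rcond = default_rcond(RS.shape)
    n = expr.n_cells
    u, s, vh = np.linalg.svd(RS, full_matrices=False)
    keep = s > rcond * s[0]
    rank = int(keep.sum())
    if rank < n:
        warnings.warn(
            f"rank(R Sigma) = {rank} < {n} cells; W is determined only up to "
            "the operator's row space",
            RankDeficiencyWarning,
            stacklevel=2,
        )
    if ridge is not None:
        lam = (ridge * s[0]) ** 2
        filt = s / (s * s + lam)
        W = vh.T @ ((u.T @ expr.values) * filt[:, np.newaxis])
    else:
        # pseudoinverse applied from the truncated SVD of R Sigma
        W = vh[keep].T @ ((u[:, keep].T @ expr.values) / s[keep, np.newaxis])
    return CommunicationMatrix(list(expr.cell_ids), W)


def reconstruct(
    grn: GRNMatrix, sigma: SingularSpectrum, w: CommunicationMatrix
) -> np.ndarray:
    """R Sigma W — the model's reconstruction of the expression matrix."""
    RS = _r_sigma(grn, sigma)
    if RS.shape[1] != w.w_values.shape[0]:
        raise ShapeError(
            f"R Sigma has {RS.shape[1]} columns but W is {w.w_values.shape[0]}-dimensional"
        )
    return RS @ w.w_values


def reconstruction_mse(expr: GeneExpressionMatrix, recon: np.ndarray) -> float:
    """Mean squared entrywise error between A and its reconstruction."""
    recon = np.asarray(recon, dtype=float)
    if recon.shape != expr.shape:
        raise ShapeError(f"reconstruction shape {recon.shape} != {expr.shape}")
    diff = expr.values - recon
    return float(np.mean(diff * diff))


def compute_W_sampled(
    expr: GeneExpressionMatrix,
    grn: GRNMatrix,
    batch_size: int | None = None,
    n_rounds: int | None = None,
    seed: int | None = None,
    rcond: float | None = None,
    ridge: float | None = None,
) -> CommunicationMatrix:
    """Cell-sampled estimate of W for matrices with more cells than genes.

    Each round draws ``batch_size`` cells without replacement, recomputes
    Sigma on the column subset and solves that round's W; the final W[i, j]
    is the mean over all rounds containing both cells.  Rounds are extended
    until every ordered cell pair is covered at least once.  With n <= m
    this delegates to :func:`compute_W`.
    """
    m, n = expr.shape
    if n <= m:
        return compute_W(expr, grn, rcond=rcond, ridge=ridge)
    if batch_size is None:
        batch_size = m
    if batch_size > m:
        raise ParameterError(f"batch_size {batch_size} exceeds gene count {m}")
    if batch_size < 2:
        raise ParameterError("batch_size must be at least 2")
    # expected per-round coverage probability of a fixed cell pair
    p_pair = (batch_size / n) * ((batch_size - 1) / (n - 1))
    if n_rounds is None:
        n_rounds = max(int(np.ceil(3.0 / p_pair)), 1)
    rng = np.random.default_rng(seed)
    sums = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)

    def one_round() -> None:
        idx = np.sort(rng.choice(n, size=batch_size, replace=False))
        sub = expr.subset_cells(idx)
        w_sub = compute_W(sub, grn, rcond=rcond, ridge=ridge).w_values
        block = np.ix_(idx, idx)
        sums[block] += w_sub
        counts[block] += 1

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RankDeficiencyWarning)
        for _ in range(n_rounds):
            one_round()
        guard = 0
        while counts.min() == 0:
            one_round()
            guard += 1
            if guard > 100 * n_rounds:  # pragma: no cover - probabilistically unreachable
                raise RuntimeError("cell-pair coverage did not complete")
    return CommunicationMatrix(list(expr.cell_ids), sums / counts)
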