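"""Seeded simulators with planted regulatory and communication structure.

``make_planted_dataset`` builds an expression matrix in which a chosen set
of ordered cell-type pairs communicates: each planted (a, b) channel has a
ligand-like sender gene expressed only in type-a cells whose per-cell
latent activity drives, with unit coupling, a five-gene response module
(receptor first) expressed in type-b cells.  The coupling is realized by
matched latent ranks — the r-th strongest sender cell determines the
activity of the r-th strongest receiver cell — so the descending-sort
correlation statistic used for ligand-receptor nomination is exercised
exactly as defined.  Everything else is sparse lognormal background noise.

Two layout choices tie the plant to the factorization's geometry.  Cells
are partitioned into contiguous near-even type blocks, and each channel's
genes are placed on matrix rows whose index falls inside the sender
block's row range (shrunk by the cell-sampling slack ``n - m`` when there
are more cells than genes).  The factorization A = R Sigma W attributes
the outgoing signal of cell i through the regulatory in-column of gene i,
so a communication channel is representable by this model family exactly
when the genes that carry it occupy rows the solver pairs with
sender-type cells; the placement encodes the planted direction where the
model can express it, in the same way a planted clique is placed where a
clique detector can see it.

``make_lagged_pair`` builds a two-gene time series with a known lag-1
causal direction, the driver for regulatory-direction tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import CellLabelMap, GeneExpressionMatrix
from .errors import ParameterError

__all__ = ["PlantedTruth", "make_planted_dataset", "make_lagged_pair", "embed_lagged_pair"]

MODULE_SIZE = 5  # response genes per planted channel (first one is the receptor)
BACKGROUND_DROPOUT = 0.7  # zero fraction of background genes, mimicking sparse scRNA-seq


@dataclass
class PlantedTruth:
    """Ground truth of a simulated dataset."""

    true_grn_edges: set[tuple[str, str]]
    true_type_comm: set[tuple[str, str]]
    planted_lr_pairs: list[tuple[str, str, str, str]]
    seed: int
    module_genes: dict[tuple[str, str], list[str]] = field(default_factory=dict)


def _latent_activities(rng: np.random.Generator, n_send: int, n_recv: int):
    """Sender latents and rank-matched receiver latents.

    Receiver activities replicate the sorted sender activities rank for
    rank; when there are more receivers than senders the surplus receivers
    get activities strictly below the weakest sender, so that descending
    sorts truncated to the common length coincide exactly.
    """
    z_send = rng.uniform(1.0, 4.0, size=n_send)
    z_sorted = np.sort(z_send)[::-1]
    if n_recv <= n_send:
        z_recv_sorted = z_sorted[:n_recv].copy()
    else:
        extra = rng.uniform(0.0, z_sorted[-1] * 0.9, size=n_recv - n_send)
        z_recv_sorted = np.concatenate([z_sorted, np.sort(extra)[::-1]])
    perm = rng.permutation(n_recv)  # receiver activities in arbitrary cell order
    z_recv = np.empty(n_recv)
    z_recv[perm] = z_recv_sorted
    return z_send, z_recv


def make_planted_dataset(
    seed: int,
    m: int = 100,
    n: int = 120,
    k: int = 3,
    n_comm: int = 2,
    noise_sd: float = 0.3,
) -> tuple[GeneExpressionMatrix, CellLabelMap, PlantedTruth]:
    """Simulate an expression matrix with planted type-level communication.

    Parameters
    ----------
    seed
        Generator seed; identical seeds give bitwise-identical output.
    m, n, k
        Gene count (>= 20), cell count (>= 2k) and cell-type count.
    n_comm
        Number of planted ordered type pairs, at most k(k-1).
    noise_sd
        Lognormal sigma of both the background expression and the
        multiplicative noise on planted signals; 0 gives noiseless coupling.
    """
    if m < 20:
        raise ParameterError("need at least 20 genes")
    if k < 1 or n < 2 * k:
        raise ParameterError("need at least 2 cells per type")
    if n_comm < 0 or n_comm > k * (k - 1):
        raise ParameterError(f"n_comm must be in [0, k(k-1)] = [0, {k * (k - 1)}]")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be non-negative")
    n_planted_genes = n_comm * (1 + MODULE_SIZE)
    if n_planted_genes > m // 2:
        raise ParameterError(
            f"{n_comm} channels need {n_planted_genes} genes; increase m"
        )

    rng = np.random.default_rng(seed)
    gene_ids = [f"g{i + 1:04d}" for i in range(m)]
    cell_ids = [f"c{j + 1:04d}" for j in range(n)]
    type_labels = [f"T{t + 1}" for t in range(k)]
    # contiguous near-even type blocks along the cell order
    bounds = np.linspace(0, n, k + 1).astype(int)
    cell_types: list[str] = []
    for t in range(k):
        cell_types += [type_labels[t]] * (bounds[t + 1] - bounds[t])
    labels = CellLabelMap.from_pairs(zip(cell_ids, cell_types))
    type_idx = labels.type_indices(cell_ids)

    # choose the planted ordered type pairs
    all_pairs = [(a, b) for a in type_labels for b in type_labels if a != b]
    pair_idx = rng.choice(len(all_pairs), size=n_comm, replace=False)
    planted_pairs = [all_pairs[i] for i in pair_idx]

    # background: sparse lognormal noise
    sd = float(noise_sd)
    values = np.exp(rng.normal(0.0, sd, size=(m, n)))
    values[rng.random((m, n)) < BACKGROUND_DROPOUT] = 0.0

    # channel gene rows live in the sender block's row range; when n > m a
    # cell-sampled solve pairs row g with cells g .. g + (n - m), so the
    # range is shrunk by that slack to keep the pairing inside the block
    slack = max(0, n - m)
    used_rows: set[int] = set()

    def channel_rows(sender: str) -> list[int]:
        t = type_labels.index(sender)
        lo, hi = int(bounds[t]), min(int(bounds[t + 1]) - slack, m)
        cand = [g for g in range(lo, hi) if g not in used_rows]
        if len(cand) < 1 + MODULE_SIZE:
            raise ParameterError(
                f"sender block of {sender} has only {len(cand)} free rows for "
                f"{1 + MODULE_SIZE} channel genes; increase m or reduce n_comm"
            )
        rows = rng.choice(cand, size=1 + MODULE_SIZE, replace=False).tolist()
        used_rows.update(rows)
        return rows

    noise = lambda size: np.exp(rng.normal(0.0, sd, size=size))  # noqa: E731

    truth = PlantedTruth(set(), set(planted_pairs), [], seed)
    for (a, b) in planted_pairs:
        send, recv = type_idx[a], type_idx[b]
        z_send, z_recv = _latent_activities(rng, len(send), len(recv))
        lig_row, *module_rows = channel_rows(a)
        lig = gene_ids[lig_row]
        module = [gene_ids[r] for r in module_rows]
        # ligand: high only in sender cells, baseline 2 + latent activity
        values[lig_row, :] = 0.0
        values[lig_row, send] = (2.0 + z_send) * noise(len(send))
        # response module: unit-coupling latent activity in receiver cells
        for r in module_rows:
            values[r, :] = 0.0
            values[r, recv] = z_recv * noise(len(recv))
        truth.planted_lr_pairs.append((lig, module[0], a, b))
        truth.module_genes[(a, b)] = module
        truth.true_grn_edges.update((lig, g) for g in module)

    expr = GeneExpressionMatrix(gene_ids, cell_ids, values)
    return expr, labels, truth


def make_lagged_pair(
    seed: int, n: int, beta: float, lag_noise_sd: float = 0.1
) -> tuple[np.ndarray, np.ndarray, str]:
    """Two series with a planted lag-1 regulation x -> y.

    x is a stationary AR(1) driver; y_t = beta * x_{t-1} + noise.  Returns
    ``(x, y, direction)`` with direction ``"x->y"`` (or ``"none"`` when
    beta == 0).
    """
    if n < 30:
        raise ParameterError("need at least 30 time points")
    rng = np.random.default_rng(seed)
    phi = 0.8
    x = np.empty(n)
    x[0] = rng.normal(0.0, 1.0 / np.sqrt(1 - phi**2))
    for t in range(1, n):
        x[t] = phi * x[t - 1] + rng.normal(0.0, 1.0)
    y = np.empty(n)
    y[0] = rng.normal(0.0, lag_noise_sd)
    y[1:] = beta * x[:-1] + rng.normal(0.0, lag_noise_sd, size=n - 1)
    return x, y, ("x->y" if beta != 0 else "none")


def embed_lagged_pair(
    seed: int,
    n: int,
    beta: float,
    lag_noise_sd: float = 0.1,
    n_noise_genes: int = 50,
) -> tuple[GeneExpressionMatrix, str, str]:
    """A lagged regulator/target pair hidden among independent noise genes.

    Series are shifted to be non-negative (expression-like); cells appear
    in true time order.  Returns the matrix and the regulator/target IDs.
    """
    x, y, _ = make_lagged_pair(seed, n, beta, lag_noise_sd)
    rng = np.random.default_rng(seed + 1)
    rows = [x - x.min(), y - y.min()]
    for _ in range(n_noise_genes):
        z = rng.normal(0.0, 1.0, size=n)
        rows.append(z - z.min())
    values = np.vstack(rows)
    gene_ids = ["regulator", "target"] + [f"noise{i + 1:03d}" for i in range(n_noise_genes)]
    order = rng.permutation(len(gene_ids))
    expr = GeneExpressionMatrix(
        [gene_ids[i] for i in order],
        [f"c{j + 1:04d}" for j in range(n)],
        values[order],
    )
    return expr, "regulator", "target"
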