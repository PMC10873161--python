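"""One-call orchestration: expression + labels -> GRN -> W -> type network.

:func:`analyze` is the in-memory pipeline used by the CLI, the test
harness and downstream scripts; :func:`run_pipeline` adds file I/O, a
validated configuration and a JSON run manifest.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .data_io import (
    CellLabelMap,
    GeneExpressionMatrix,
    normalize_expression,
    read_expression,
    read_labels,
    read_lr_database,
    write_matrix,
    write_network,
)
from .decomposition import (
    CommunicationMatrix,
    compute_sigma,
    compute_W,
    compute_W_sampled,
    reconstruct,
    reconstruction_mse,
)
from .errors import CellFactorError, ConfigError, RankDeficiencyWarning
from .grn import GRNMatrix, infer_grn, load_user_grn
from .lr import identify_lr_pairs
from .network import TypeCommMatrix, aggregate_to_types, resolve_directions, top_k_edges

__all__ = ["PipelineConfig", "PipelineResult", "analyze", "run_pipeline", "DEFAULT_RIDGE"]

#: relative Tikhonov damping scale of the pipeline's solve; see compute_W.
#: The exact pseudoinverse remains available via ridge=None.
DEFAULT_RIDGE = 0.1


@dataclass
class PipelineResult:
    """All stage outputs of one in-memory pipeline run."""

    expr: GeneExpressionMatrix
    grn: GRNMatrix
    w: CommunicationMatrix
    type_comm: TypeCommMatrix
    reconstruction_mse: float
    rank_r_sigma: int
    sampled: bool


def analyze(
    expr: GeneExpressionMatrix,
    labels: CellLabelMap,
    grn: GRNMatrix | None = None,
    penalty: float | None = None,
    edge_alpha: float | None = None,
    max_genes: int = 2000,
    rcond: float | None = None,
    ridge: float | None = DEFAULT_RIDGE,
    sampling: str = "auto",
    combine: str = "add",
    seed: int | None = None,
) -> PipelineResult:
    """Run GRN inference (unless supplied), the decomposition and aggregation.

    ``sampling`` is ``"auto"`` (cell-sampled solve when n > m), ``"on"`` or
    ``"off"``.  The solve is Tikhonov-filtered by default (``ridge``);
    pass ``ridge=None`` for the exact pseudoinverse.  The single ``seed``
    governs LASSO cross-validation folds and the cell sampling rounds.
    """
    if grn is None:
        grn = infer_grn(
            expr, penalty=penalty, max_genes=max_genes, edge_alpha=edge_alpha, seed=seed
        )
        if grn.gene_ids != expr.gene_ids:  # most-variable-gene restriction applied
            expr = expr.subset_genes(grn.gene_ids)
    m, n = expr.shape
    use_sampling = sampling == "on" or (sampling == "auto" and n > m)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RankDeficiencyWarning)
        if use_sampling and n > m:
            w = compute_W_sampled(expr, grn, seed=seed, rcond=rcond, ridge=ridge)
            sampled = True
        else:
            w = compute_W(expr, grn, rcond=rcond, ridge=ridge)
            sampled = False
    sigma = compute_sigma(expr)
    from .decomposition import _r_sigma, default_rcond  # local import to keep surface small

    RS = _r_sigma(grn, sigma)
    s_rs = np.linalg.svd(RS, compute_uv=False)
    cut = (rcond if rcond is not None else default_rcond(RS.shape)) * (s_rs[0] if s_rs.size else 0)
    rank = int((s_rs > cut).sum())
    mse = reconstruction_mse(expr, reconstruct(grn, sigma, w))
    net = resolve_directions(w, combine=combine)
    type_comm = aggregate_to_types(net, labels)
    return PipelineResult(expr, grn, w, type_comm, mse, rank, sampled)


# ---------------------------------------------------------------------------
# configuration


_SCHEMA: dict[str, dict[str, type | tuple]] = {
    "inputs": {"expression": str, "labels": str, "grn": str, "lrdb": str, "normalize": bool},
    "grn": {"mode": str, "penalty": (int, float), "edge_alpha": (int, float), "max_genes": int},
    "decomposition": {"rcond": (int, float), "sampling": str, "ridge": (int, float)},
    "network": {"combine": str, "top_k": int},
    "lr": {"enabled": bool, "alpha": (int, float), "expressed_frac": (int, float),
           "zero_frac": (int, float)},
    "output_dir": str,
    "seed": int,
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (plain YAML key-value file)."""

    expression: str
    labels: str
    output_dir: str
    grn_path: str | None = None
    lrdb: str | None = None
    normalize: bool = False
    grn_mode: str = "infer"
    penalty: float | None = None
    edge_alpha: float | None = None
    max_genes: int = 2000
    rcond: float | None = None
    ridge: float | None = DEFAULT_RIDGE
    sampling: str = "auto"
    combine: str = "add"
    top_k: int = 10
    lr_enabled: bool = False
    lr_alpha: float = 0.01
    expressed_frac: float = 0.3
    zero_frac: float = 0.7
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        def check_keys(d: dict, schema: dict, prefix: str = "") -> None:
            for key, val in d.items():
                if key not in schema:
                    raise ConfigError(
                        f"unknown config key {prefix + key!r}; known: {sorted(schema)}"
                    )
                if isinstance(schema[key], dict):
                    if not isinstance(val, dict):
                        raise ConfigError(f"{prefix + key!r} must be a mapping")
                    check_keys(val, schema[key], prefix=f"{key}.")
                elif val is not None and not isinstance(val, schema[key]):
                    raise ConfigError(f"{prefix + key!r} has wrong type {type(val).__name__}")

        check_keys(raw, _SCHEMA)
        inputs = raw.get("inputs", {})
        if "expression" not in inputs or "labels" not in inputs:
            raise ConfigError("config needs inputs.expression and inputs.labels")
        if "output_dir" not in raw:
            raise ConfigError("config needs output_dir")
        grn_cfg = raw.get("grn", {})
        dec = raw.get("decomposition", {})
        net = raw.get("network", {})
        lr_cfg = raw.get("lr", {})
        cfg = cls(
            expression=inputs["expression"],
            labels=inputs["labels"],
            output_dir=raw["output_dir"],
            grn_path=inputs.get("grn"),
            lrdb=inputs.get("lrdb"),
            normalize=inputs.get("normalize", False),
            grn_mode=grn_cfg.get("mode", "infer"),
            penalty=grn_cfg.get("penalty"),
            edge_alpha=grn_cfg.get("edge_alpha"),
            max_genes=grn_cfg.get("max_genes", 2000),
            rcond=dec.get("rcond"),
            ridge=dec.get("ridge", DEFAULT_RIDGE),
            sampling=dec.get("sampling", "auto"),
            combine=net.get("combine", "add"),
            top_k=net.get("top_k", 10),
            lr_enabled=lr_cfg.get("enabled", False),
            lr_alpha=lr_cfg.get("alpha", 0.01),
            expressed_frac=lr_cfg.get("expressed_frac", 0.3),
            zero_frac=lr_cfg.get("zero_frac", 0.7),
            seed=raw.get("seed", 0),
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError("config file must hold a YAML mapping")
        return cls.from_dict(raw)

    def validate(self) -> None:
        for name, p in [("expression", self.expression), ("labels", self.labels)]:
            if not Path(p).exists():
                raise ConfigError(f"inputs.{name} path does not exist: {p}")
        for name, p in [("grn", self.grn_path), ("lrdb", self.lrdb)]:
            if p is not None and not Path(p).exists():
                raise ConfigError(f"inputs.{name} path does not exist: {p}")
        if self.grn_mode not in {"infer", "load"}:
            raise ConfigError("grn.mode must be 'infer' or 'load'")
        if self.grn_mode == "load" and self.grn_path is None:
            raise ConfigError("grn.mode 'load' needs inputs.grn")
        if self.sampling not in {"auto", "on", "off"}:
            raise ConfigError("decomposition.sampling must be auto/on/off")
        if self.combine not in {"add", "mean"}:
            raise ConfigError("network.combine must be 'add' or 'mean'")
        if self.lr_enabled and self.lrdb is None:
            raise ConfigError("lr.enabled needs inputs.lrdb")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages, write every stage output and return the manifest."""
    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def stage(name: str):
        class _Timer:
            def __enter__(self):
                self.t = time.time()

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.time() - self.t, 3)
                if exc is not None and isinstance(exc, CellFactorError):
                    raise CellFactorError(f"stage {name!r}: {exc}") from exc

        return _Timer()

    with stage("load"):
        expr = read_expression(config.expression)
        if config.normalize:
            expr = normalize_expression(expr)
        labels = read_labels(config.labels, expr)

    with stage("grn"):
        grn = (
            load_user_grn(config.grn_path, expr)
            if config.grn_mode == "load"
            else None
        )

    with stage("decomposition"):
        result = analyze(
            expr,
            labels,
            grn=grn,
            penalty=config.penalty,
            edge_alpha=config.edge_alpha,
            max_genes=config.max_genes,
            rcond=config.rcond,
            ridge=config.ridge,
            sampling=config.sampling,
            combine=config.combine,
            seed=config.seed,
        )

    with stage("write"):
        write_matrix(result.grn.weights, result.grn.gene_ids, result.grn.gene_ids,
                     out / "grn.tsv")
        write_matrix(result.w.w_values, result.w.cell_ids, result.w.cell_ids,
                     out / "w.tsv")
        write_matrix(result.type_comm.strengths, result.type_comm.type_labels,
                     result.type_comm.type_labels, out / "type_comm.tsv")
        write_network(top_k_edges(result.type_comm, config.top_k), out / "top_edges.tsv")
        write_network(
            [(a, b, result.type_comm.pair_strength(a, b))
             for a, b in result.type_comm.significant_pairs()],
            out / "significant_pairs.tsv",
        )

    lr_summary = None
    if config.lr_enabled:
        with stage("lr"):
            lrdb = read_lr_database(config.lrdb)
            rows = []
            for a, b in result.type_comm.significant_pairs():
                for res in identify_lr_pairs(
                    result.expr, labels, lrdb, a, b,
                    alpha=config.lr_alpha,
                    expressed_frac=config.expressed_frac,
                    zero_frac=config.zero_frac,
                ):
                    rows.append(
                        {"source": a, "target": b, "ligand": res.ligand,
                         "receptor": res.receptor, "r": res.r, "p": res.p,
                         "p_adj": res.p_adj, "significant": res.significant}
                    )
            import pandas as pd

            pd.DataFrame(
                rows,
                columns=["source", "target", "ligand", "receptor", "r", "p",
                         "p_adj", "significant"],
            ).to_csv(out / "lr_pairs.tsv", sep="\t", index=False)
            lr_summary = {
                "n_tested": len(rows),
                "n_significant": sum(r["significant"] for r in rows),
            }

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "outputs": {
            "grn": str(out / "grn.tsv"),
            "w": str(out / "w.tsv"),
            "type_comm": str(out / "type_comm.tsv"),
            "top_edges": str(out / "top_edges.tsv"),
            "significant_pairs": str(out / "significant_pairs.tsv"),
        },
        "n_genes": result.expr.n_genes,
        "n_cells": result.expr.n_cells,
        "k_types": result.type_comm.strengths.shape[0],
        "reconstruction_mse": result.reconstruction_mse,
        "rank_r_sigma": result.rank_r_sigma,
        "sampled": result.sampled,
        "threshold": result.type_comm.threshold,
        "n_significant_pairs": len(result.type_comm.significant_pairs()),
        "significant_pairs": sorted(result.type_comm.significant_pairs()),
        "lr": lr_summary,
    }
    # timings go to the log, not the manifest, so identical runs are bitwise equal
    logging.getLogger(__name__).info(
        "pipeline finished in %.2fs (stages: %s)", time.time() - t0, timings
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
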