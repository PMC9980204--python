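"""Cell-type composition tables and gene-set module scoring.

Module scores follow the binned-control scheme: on log-normalized
expression, genes are ranked by mean expression into equal-size bins;
each gene-set member is paired with control genes drawn from its bin,
and the score is the per-cell mean over set genes minus the mean over
the pooled control genes.  A "stemness" score is this statistic applied
to a stem-program gene list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CellMetadataTable, SparseCountMatrix


def composition_table(meta: CellMetadataTable) -> pd.DataFrame:
    """Per-sample cell-type proportions (rows sum to 1)."""
    df = meta.frame
    counts = pd.crosstab(df["sample_id"], df["cell_type"])
    if (counts.sum(axis=1) == 0).any():
        raise ValueError("sample with zero cells")
    return counts.div(counts.sum(axis=1), axis=0)


def group_proportions(meta: CellMetadataTable, column: str = "tumor_type") -> pd.Series:
    """Fraction of all cells in each level of a metadata column."""
    return meta.frame[column].value_counts(normalize=True).sort_index()


def log_normalize(expr: SparseCountMatrix, scale: float = 1e4) -> np.ndarray:
    """ln(1 + scale * count / cell_total); zero-total cells stay zero."""
    x = expr.dense().astype(float)
    totals = x.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(totals > 0, x / np.maximum(totals, 1e-300) * scale, 0.0)
    return np.log1p(norm)


@dataclass
class ModuleScoreResult:
    scores: pd.Series  # indexed by barcode
    gene_set: list[str]
    control_sets: dict[str, list[str]]  # set gene -> its control draw


def module_score(
    expr: SparseCountMatrix,
    gene_set: list[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> ModuleScoreResult:
    """Binned-control module score per cell.

    Genes are binned by mean log-normalized expression into ``n_bins``
    equal-size (rank-based) bins.  For each set gene, ``n_ctrl`` control
    genes are drawn without replacement from its bin, excluding the set
    itself (the whole bin complement is used when it is smaller).  The
    score is mean(set genes) − mean(pooled controls), per cell, on the
    log-normalized matrix.  Genes absent from the matrix are dropped
    with a warning.
    """
    present = [g for g in gene_set if g in expr.features]
    missing = sorted(set(gene_set) - set(present))
    if missing:
        warnings.warn(f"{len(missing)} gene-set genes absent from matrix", stacklevel=2)
    if not present:
        raise ValueError("gene set empty after intersecting with matrix features")

    lognorm = log_normalize(expr)
    mean_expr = lognorm.mean(axis=0)
    order = np.argsort(mean_expr, kind="stable")
    bins = np.empty(expr.n_features, dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        bins[chunk] = b

    rng = np.random.default_rng(seed)
    feat_idx = {f: i for i, f in enumerate(expr.features)}
    set_idx = np.array([feat_idx[g] for g in present])
    set_mask = np.zeros(expr.n_features, dtype=bool)
    set_mask[set_idx] = True

    control_sets: dict[str, list[str]] = {}
    control_union: set[int] = set()
    for g in present:
        b = bins[feat_idx[g]]
        pool = np.where((bins == b) & ~set_mask)[0]
        if len(pool) == 0:
            control_sets[g] = []
            continue
        take = min(n_ctrl, len(pool))
        draw = rng.choice(pool, size=take, replace=False)
        control_sets[g] = [expr.features[i] for i in draw]
        control_union.update(int(i) for i in draw)

    if not control_union:
        raise ValueError("no control genes available; reduce n_bins or the set size")
    ctrl_idx = np.fromiter(control_union, dtype=int)
    scores = lognorm[:, set_idx].mean(axis=1) - lognorm[:, ctrl_idx].mean(axis=1)
    return ModuleScoreResult(
        scores=pd.Series(scores, index=expr.barcodes, name="module_score"),
        gene_set=present,
        control_sets=control_sets,
    )


def per_sample_median_score(
    scores: pd.Series, meta: CellMetadataTable
) -> pd.Series:
    """Median score per sample (midpoint convention for even counts)."""
    df = meta.frame
    missing = set(df["barcode"]) - set(scores.index)
    if missing:
        raise ValueError(f"{len(missing)} metadata barcodes lack scores")
    aligned = scores.loc[df["barcode"]].to_numpy()
    return (
        pd.DataFrame({"sample_id": df["sample_id"].to_numpy(), "score": aligned})
        .groupby("sample_id")["score"]
        .median()
    )
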