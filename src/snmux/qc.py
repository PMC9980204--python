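"""Nucleus-level quality filtering.

A nucleus is kept iff it has more than ``min_features`` and fewer than
``max_features`` detected genes and less than ``max_mito_fraction`` of
its reads mapping to mitochondrial genes — all strict inequalities, so
boundary values are excluded.  Mitochondrial genes are identified by an
explicit ID list; a "MT-" prefix helper is provided but opt-in.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import SparseCountMatrix


def mito_features_by_prefix(features: list[str], prefix: str = "MT-") -> list[str]:
    """Opt-in helper: mitochondrial feature IDs by name prefix."""
    return [f for f in features if f.startswith(prefix)]


def qc_metrics(expr: SparseCountMatrix, mito_feature_ids: list[str]) -> pd.DataFrame:
    """Per-barcode n_features (genes with count > 0) and mito_fraction.

    A zero-total barcode gets mito_fraction 0 by convention (it is
    excluded by the feature rule anyway).
    """
    unknown = set(mito_feature_ids) - set(expr.features)
    if unknown:
        raise ValueError(f"mito features not in matrix: {sorted(unknown)[:5]}")
    counts = expr.counts
    n_features = np.diff(counts.indptr) if counts.format == "csr" else None
    if n_features is None or (counts.data == 0).any():
        n_features = np.asarray((counts > 0).sum(axis=1)).ravel()
    totals = np.asarray(counts.sum(axis=1)).ravel().astype(float)
    mito_cols = [expr.features.index(f) for f in mito_feature_ids]
    if mito_cols:
        mito_totals = np.asarray(counts[:, mito_cols].sum(axis=1)).ravel().astype(float)
    else:
        mito_totals = np.zeros_like(totals)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_fraction = np.where(totals > 0, mito_totals / np.maximum(totals, 1e-300), 0.0)
    return pd.DataFrame(
        {
            "barcode": expr.barcodes,
            "n_features": n_features.astype(int),
            "mito_fraction": mito_fraction,
        }
    )


def qc_filter(
    expr: SparseCountMatrix,
    mito_feature_ids: list[str],
    min_features: int = 200,
    max_features: int = 10_000,
    max_mito_fraction: float = 0.05,
) -> tuple[list[str], pd.DataFrame]:
    """Return (kept barcodes in input order, metrics for all barcodes)."""
    metrics = qc_metrics(expr, mito_feature_ids)
    keep = (
        (metrics["n_features"] > min_features)
        & (metrics["n_features"] < max_features)
        & (metrics["mito_fraction"] < max_mito_fraction)
    )
    metrics["kept"] = keep
    return list(metrics.loc[keep, "barcode"]), metrics
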