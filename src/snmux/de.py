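"""Quasi-Poisson differential expression with cell-type adjustment.

Each tumor type is compared with the non-tumor referent, gene by gene,
with a Poisson log-link GLM whose standard errors are inflated by a
Pearson-residual dispersion estimate (quasi-Poisson).  The *unadjusted*
design contains only an intercept and the tumor-type indicator; the
*adjusted* design adds cell-type indicator columns, removing signal
that is driven purely by differences in cell-type composition between
tumor and referent tissue.  Testing is restricted to the most variable
genes, and Benjamini–Hochberg FDR is applied within each
(tumor type, model) stratum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .io import CellMetadataTable, SparseCountMatrix


@dataclass
class DesignSpec:
    """Contrast definition for the tumor vs non-tumor comparisons."""

    referent_group: str = "non-tumor"
    groups: list[str] | None = None  # None: every non-referent level present
    fdr_alpha: float = 0.05
    n_top_genes: int = 4000
    use_t_reference: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.fdr_alpha < 1:
            raise ValueError("fdr_alpha must be in (0, 1)")


# ---------------------------------------------------------------------------
# Variable-gene selection
# ---------------------------------------------------------------------------

def _local_poly_fit(x: np.ndarray, y: np.ndarray, span: float = 0.3) -> np.ndarray:
    """Tricube-weighted degree-2 local polynomial fit of y on x, evaluated
    at every x (loess-like mean-variance trend)."""
    n = len(x)
    k = max(int(np.ceil(span * n)), 4)
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    fitted_sorted = np.empty(n)
    for i in range(n):
        lo = max(0, min(i - k // 2, n - k))
        window = slice(lo, lo + k)
        xw, yw = xs[window], ys[window]
        d = np.abs(xw - xs[i])
        dmax = d.max()
        w = (1 - (d / dmax) ** 3) ** 3 if dmax > 0 else np.ones_like(d)
        w = np.maximum(w, 1e-12)
        X = np.vander(xw - xs[i], 3)  # quadratic in centered x
        WX = X * w[:, None]
        beta, *_ = np.linalg.lstsq(WX.T @ X, WX.T @ yw, rcond=None)
        fitted_sorted[i] = beta[2]  # value at the centre point
    fitted = np.empty(n)
    fitted[order] = fitted_sorted
    return fitted


def standardized_variance(
    expr: SparseCountMatrix, span: float = 0.3
) -> pd.Series:
    """Variance of counts standardized by the mean-variance trend.

    log10(variance) is regressed on log10(mean) with a degree-2 local
    polynomial (span 0.3); each gene's counts are z-scored by the
    predicted sd and clipped at sqrt(n_cells); the reported statistic is
    the variance of the clipped z-scores.  Genes with zero mean or zero
    variance score 0.
    """
    x = expr.dense().astype(float)
    n = x.shape[0]
    mean = x.mean(axis=0)
    var = x.var(axis=0, ddof=1)
    out = np.zeros(expr.n_features)
    informative = (mean > 0) & (var > 0)
    if informative.sum() < 2:
        raise ValueError("fewer than 2 informative genes")
    lm = np.log10(mean[informative])
    lv = np.log10(var[informative])
    fitted = _local_poly_fit(lm, lv, span)
    sd_pred = np.sqrt(10.0 ** fitted)
    clip = np.sqrt(n)
    z = (x[:, informative] - mean[informative]) / sd_pred
    z = np.clip(z, -clip, clip)
    out[informative] = z.var(axis=0, ddof=1)
    return pd.Series(out, index=expr.features, name="standardized_variance")


def select_variable_genes(
    expr: SparseCountMatrix, n: int = 4000, span: float = 0.3, method: str = "vst"
) -> list[str]:
    """Top-n genes by standardized variance (ties broken by gene id).

    ``method="lognorm_var"`` ranks instead by plain variance of
    log-normalized counts.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if method == "vst":
        stat = standardized_variance(expr, span)
    elif method == "lognorm_var":
        from .scoring import log_normalize

        stat = pd.Series(
            log_normalize(expr).var(axis=0, ddof=1), index=expr.features
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    ranked = stat.sort_values(ascending=False, kind="stable")
    ranked = ranked.loc[sorted(ranked.index)].sort_values(ascending=False, kind="stable")
    informative = ranked[ranked > 0]
    pool = informative if len(informative) else ranked
    return list(pool.index[: min(n, len(pool))])


# ---------------------------------------------------------------------------
# Size factors and the GLM
# ---------------------------------------------------------------------------

def size_factors(expr: SparseCountMatrix) -> pd.Series:
    """Per-cell total counts scaled by their geometric mean.

    The log size factor enters the count model as an offset.  Every cell
    must have a positive total over the modeled genes.
    """
    totals = np.asarray(expr.counts.sum(axis=1)).ravel().astype(float)
    if (totals <= 0).any():
        raise ValueError("cells with zero total count among modeled genes")
    log_t = np.log(totals)
    return pd.Series(
        np.exp(log_t - log_t.mean()), index=expr.barcodes, name="size_factor"
    )


@dataclass
class QuasiPoissonFit:
    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray
    dispersion: float
    converged: bool
    flagged: bool
    flag_reason: str = ""


def fit_quasipoisson(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray | None = None,
    use_t_reference: bool = False,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> QuasiPoissonFit:
    """Poisson log-link GLM with quasi-likelihood standard errors.

    Fitted by IRLS to |Δdeviance| < tol; dispersion φ = Pearson χ²/(n−p)
    floored at 1; se = sqrt(φ)·se_Poisson; two-sided p from the normal
    reference on β/se (t reference optional).  Non-convergence or
    separation (a fitted group mean collapsing to 0, seen as an extreme
    coefficient) is flagged with null p-values.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p_cols = X.shape
    if np.linalg.matrix_rank(X) < p_cols:
        raise ValueError("design matrix is rank deficient")
    model = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(maxiter=max_iter, tol=tol, scale=1.0)
        except Exception as exc:  # noqa: BLE001 - flagged, not fatal
            nan = np.full(p_cols, np.nan)
            return QuasiPoissonFit(nan, nan, nan, np.nan, False, True, str(exc))
    converged = bool(getattr(res, "converged", True))
    phi = max(float(res.pearson_chi2) / max(n - p_cols, 1), 1.0)
    beta = np.asarray(res.params)
    se = np.sqrt(phi) * np.asarray(res.bse)
    separated = bool(np.any(np.abs(beta) > 20))
    flagged = (not converged) or separated or not np.all(np.isfinite(se))
    if flagged:
        p = np.full(p_cols, np.nan)
        reason = "non-convergence" if not converged else "separation"
    else:
        z = beta / se
        if use_t_reference:
            p = 2 * st.t.sf(np.abs(z), df=max(n - p_cols, 1))
        else:
            p = 2 * st.norm.sf(np.abs(z))
        reason = ""
    return QuasiPoissonFit(beta, se, p, phi, converged, flagged, reason)


# ---------------------------------------------------------------------------
# The DE test and model comparison
# ---------------------------------------------------------------------------

def _design(
    meta: pd.DataFrame, group: str, referent: str, adjusted: bool
) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(meta)), (meta["tumor_type"] == group).astype(float).to_numpy()]
    names = ["intercept", f"group[{group}]"]
    if adjusted:
        dummies = pd.get_dummies(meta["cell_type"], drop_first=True, dtype=float)
        for c in dummies.columns:
            col = dummies[c].to_numpy()
            if col.std() > 0:
                cols.append(col)
                names.append(f"cell_type[{c}]")
    return np.column_stack(cols), names


def de_test(
    expr: SparseCountMatrix,
    meta: CellMetadataTable,
    spec: DesignSpec,
    genes: list[str] | None = None,
    models: tuple[str, ...] = ("adjusted", "unadjusted"),
) -> pd.DataFrame:
    """Per-gene quasi-Poisson DE for every tumor type vs the referent.

    Returns one row per gene × group × model with columns estimate / se /
    p / q (BH within each group × model stratum) / significant / flag.
    ``genes`` defaults to the top ``spec.n_top_genes`` variable genes.
    """
    mf = meta.frame.set_index("barcode").loc[expr.barcodes].reset_index()
    levels = list(pd.unique(mf["tumor_type"]))
    if spec.referent_group not in levels:
        raise ValueError(f"referent group {spec.referent_group!r} absent from metadata")
    groups = spec.groups or [g for g in levels if g != spec.referent_group]
    for g in groups:
        if g not in levels:
            raise ValueError(f"group {g!r} absent from metadata")

    if genes is None:
        genes = select_variable_genes(expr, spec.n_top_genes)
    gene_idx = {g: i for i, g in enumerate(expr.features)}
    sub = expr.counts[:, [gene_idx[g] for g in genes]]

    rows = []
    for group in groups:
        in_contrast = mf["tumor_type"].isin([group, spec.referent_group]).to_numpy()
        totals = np.asarray(sub[in_contrast].sum(axis=1)).ravel()
        usable = np.where(in_contrast)[0][totals > 0]
        n_dropped = int((totals == 0).sum())
        if n_dropped:
            warnings.warn(
                f"{n_dropped} zero-total cells dropped from the {group} contrast",
                stacklevel=2,
            )
        sub_meta = mf.iloc[usable]
        counts = np.asarray(sub[usable].todense())
        log_t = np.log(counts.sum(axis=1))
        offset = log_t - log_t.mean()

        for model in models:
            X, names = _design(sub_meta, group, spec.referent_group, model == "adjusted")
            coef_j = names.index(f"group[{group}]")
            for j, gene in enumerate(genes):
                y = counts[:, j]
                if y.sum() == 0:
                    rows.append(
                        dict(gene=gene, group=group, model=model, estimate=np.nan,
                             se=np.nan, p=np.nan, flag="all-zero")
                    )
                    continue
                fit = fit_quasipoisson(
                    y, X, offset=offset, use_t_reference=spec.use_t_reference
                )
                rows.append(
                    dict(
                        gene=gene,
                        group=group,
                        model=model,
                        estimate=fit.beta[coef_j],
                        se=fit.se[coef_j],
                        p=fit.p[coef_j],
                        flag=fit.flag_reason,
                    )
                )

    table = pd.DataFrame(rows)
    table["q"] = np.nan
    for (_, _), idx in table.groupby(["group", "model"]).groups.items():
        stratum = table.loc[idx]
        ok = stratum["p"].notna()
        if ok.any():
            q = multipletests(stratum.loc[ok, "p"], method="fdr_bh")[1]
            table.loc[stratum.index[ok], "q"] = q
    table["significant"] = table["q"] < spec.fdr_alpha
    return table


def compare_models(
    adjusted: pd.DataFrame, unadjusted: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group overlap of significant genes between the two models.

    Returns ``(counts, sign_flips)``: counts has columns only_adjusted /
    only_unadjusted / both per group; sign_flips lists genes significant
    in both models with opposite estimate signs.
    """
    a = adjusted[adjusted["model"] == "adjusted"] if "model" in adjusted else adjusted
    u = (
        unadjusted[unadjusted["model"] == "unadjusted"]
        if "model" in unadjusted
        else unadjusted
    )
    if set(zip(a["gene"], a["group"])) != set(zip(u["gene"], u["group"])):
        raise ValueError("gene x group universes differ between the two tables")
    merged = a.merge(u, on=["gene", "group"], suffixes=("_adj", "_unadj"))
    counts, flips = [], []
    for group, sub in merged.groupby("group"):
        sig_a = sub["significant_adj"].fillna(False)
        sig_u = sub["significant_unadj"].fillna(False)
        counts.append(
            dict(
                group=group,
                only_adjusted=int((sig_a & ~sig_u).sum()),
                only_unadjusted=int((~sig_a & sig_u).sum()),
                both=int((sig_a & sig_u).sum()),
            )
        )
        both = sub[sig_a & sig_u]
        flip = both[np.sign(both["estimate_adj"]) * np.sign(both["estimate_unadj"]) < 0]
        for _, r in flip.iterrows():
            flips.append(
                dict(
                    gene=r["gene"],
                    group=group,
                    estimate_adjusted=r["estimate_adj"],
                    estimate_unadjusted=r["estimate_unadj"],
                )
            )
    return (
        pd.DataFrame(counts),
        pd.DataFrame(flips, columns=["gene", "group", "estimate_adjusted", "estimate_unadjusted"]),
    )
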