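"""Quasi-Poisson GLM, variable genes, and the adjusted-vs-unadjusted contrast."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
import scipy.stats as st

from snmux.de import (
    DesignSpec,
    compare_models,
    de_test,
    fit_quasipoisson,
    select_variable_genes,
    size_factors,
    standardized_variance,
)
from snmux.io import CellMetadataTable, SparseCountMatrix


def matrix_from(counts, genes=None):
    counts = np.asarray(counts, dtype=int)
    genes = genes or [f"g{j}" for j in range(counts.shape[1])]
    return SparseCountMatrix(
        sp.csr_matrix(counts), [f"BC{i}" for i in range(counts.shape[0])], genes
    )


class TestSizeFactors:
    def test_closed_form(self):
        # totals 1, e^2 -> log totals 0, 2; geometric mean e -> factors e^-1, e
        expr = matrix_from([[1, 0], [4, 3]])
        sf = size_factors(expr)
        t = np.array([1.0, 7.0])
        expected = t / np.exp(np.mean(np.log(t)))
        np.testing.assert_allclose(sf.to_numpy(), expected, rtol=1e-12)

    def test_geometric_mean_of_factors_is_one(self):
        rng = np.random.default_rng(0)
        expr = matrix_from(rng.poisson(5, size=(50, 20)) + 1)
        sf = size_factors(expr)
        assert np.exp(np.mean(np.log(sf))) == pytest.approx(1.0, abs=1e-12)

    def test_zero_total_cell_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            size_factors(matrix_from([[0, 0], [1, 2]]))


class TestQuasiPoissonFit:
    def test_intercept_only_is_log_mean(self):
        rng = np.random.default_rng(1)
        y = rng.poisson(7.0, size=300)
        fit = fit_quasipoisson(y, np.ones((300, 1)))
        assert fit.beta[0] == pytest.approx(np.log(y.mean()), abs=1e-8)

    def test_two_group_closed_form(self):
        # saturated two-group model: coefficients are the group log means
        y = np.array([2, 4, 6, 10, 14, 12], dtype=float)
        X = np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1]])
        fit = fit_quasipoisson(y, X)
        assert fit.beta[0] == pytest.approx(np.log(4.0), abs=1e-8)
        assert fit.beta[1] == pytest.approx(np.log(12.0) - np.log(4.0), abs=1e-8)

    def test_planted_log2_effect_recovered(self):
        rng = np.random.default_rng(2)
        n = 2000
        y = np.concatenate([rng.poisson(5.0, n), rng.poisson(10.0, n)])
        X = np.column_stack([np.ones(2 * n), np.repeat([0.0, 1.0], n)])
        fit = fit_quasipoisson(y, X)
        assert abs(fit.beta[1] - np.log(2)) < 3 * fit.se[1]
        assert fit.p[1] < 1e-10

    def test_matches_naive_irls_oracle(self):
        rng = np.random.default_rng(3)
        n = 150
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n), rng.normal(size=n)])
        y = rng.poisson(np.exp(0.5 + 0.8 * X[:, 1] + 0.3 * X[:, 2]))
        offset = rng.normal(scale=0.1, size=n)

        beta = np.zeros(3)
        for _ in range(200):
            eta = X @ beta + offset
            mu = np.exp(eta)
            W = mu
            z = eta - offset + (y - mu) / mu
            beta_new = np.linalg.solve(X.T @ (W[:, None] * X), X.T @ (W * z))
            if np.max(np.abs(beta_new - beta)) < 1e-12:
                beta = beta_new
                break
            beta = beta_new

        fit = fit_quasipoisson(y, X, offset=offset)
        np.testing.assert_allclose(fit.beta, beta, atol=1e-6)

    def test_dispersion_near_one_for_poisson_data(self):
        rng = np.random.default_rng(4)
        y = rng.poisson(8.0, size=2000)
        fit = fit_quasipoisson(y, np.ones((2000, 1)))
        assert 1.0 <= fit.dispersion < 1.15

    def test_dispersion_recovers_planted_overdispersion(self):
        # gamma-Poisson with mean mu, shape r: Pearson dispersion -> 1 + mu/r
        rng = np.random.default_rng(5)
        mu, r = 10.0, 2.5
        lam = mu * rng.gamma(r, 1 / r, size=4000)
        y = rng.poisson(lam)
        fit = fit_quasipoisson(y, np.ones((4000, 1)))
        assert fit.dispersion == pytest.approx(1 + mu / r, rel=0.15)

    def test_overdispersion_inflates_se_by_sqrt_phi(self):
        rng = np.random.default_rng(6)
        lam = 10.0 * rng.gamma(2.0, 0.5, size=1000)
        y = rng.poisson(lam)
        X = np.ones((1000, 1))
        fit = fit_quasipoisson(y, X)
        # Poisson se for the intercept is 1/sqrt(sum mu) = 1/sqrt(sum y)
        se_pois = 1.0 / np.sqrt(y.sum())
        assert fit.se[0] == pytest.approx(np.sqrt(fit.dispersion) * se_pois, rel=1e-6)

    def test_doubling_counts_leaves_group_effect_unchanged(self):
        rng = np.random.default_rng(7)
        n = 400
        X = np.column_stack([np.ones(n), np.repeat([0.0, 1.0], n // 2)])
        y = rng.poisson(np.exp(1.0 + 0.6 * X[:, 1]))
        a = fit_quasipoisson(y, X)
        b = fit_quasipoisson(2 * y, X)
        assert b.beta[1] == pytest.approx(a.beta[1], abs=1e-6)
        assert b.beta[0] == pytest.approx(a.beta[0] + np.log(2), abs=1e-6)

    def test_offset_shift_moves_only_the_intercept(self):
        rng = np.random.default_rng(8)
        n = 300
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n).astype(float)])
        y = rng.poisson(5.0, size=n)
        a = fit_quasipoisson(y, X, offset=np.zeros(n))
        b = fit_quasipoisson(y, X, offset=np.full(n, 0.7))
        assert b.beta[0] == pytest.approx(a.beta[0] - 0.7, abs=1e-8)
        assert b.beta[1] == pytest.approx(a.beta[1], abs=1e-8)

    def test_separation_is_flagged_not_fatal(self):
        y = np.array([0, 0, 0, 0, 9, 11, 10, 8], dtype=float)
        X = np.column_stack([np.ones(8), np.repeat([0.0, 1.0], 4)])
        fit = fit_quasipoisson(y, X)
        assert fit.flagged and np.isnan(fit.p).all()

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(ValueError, match="rank"):
            fit_quasipoisson(np.ones(10), X)


class TestVariableGenes:
    def test_constant_gene_never_selected(self):
        rng = np.random.default_rng(9)
        counts = rng.poisson(5, size=(100, 20))
        counts[:, 3] = 7  # zero variance
        genes = select_variable_genes(matrix_from(counts), n=20)
        assert "g3" not in genes

    def test_overdispersed_gene_ranks_first(self):
        rng = np.random.default_rng(10)
        counts = rng.poisson(5.0, size=(200, 40))
        # same mean, far heavier tail than the Poisson trend predicts
        lam = 5.0 * rng.gamma(0.2, 5.0, size=200)
        counts[:, 7] = rng.poisson(lam)
        genes = select_variable_genes(matrix_from(counts), n=5)
        assert genes[0] == "g7"

    def test_deterministic_and_tie_broken_by_gene_id(self):
        counts = np.tile([[1], [5], [2], [9]], (1, 6))  # all genes identical
        got = select_variable_genes(matrix_from(counts), n=3)
        assert got == ["g0", "g1", "g2"]

    def test_standardized_variance_clipped_scale(self):
        rng = np.random.default_rng(11)
        expr = matrix_from(rng.poisson(4, size=(80, 30)))
        sv = standardized_variance(expr)
        assert (sv >= 0).all()
        assert sv.max() <= 80  # bounded by the clip at sqrt(n) squared


def confounded_dataset(seed=12, n_per_group=400):
    """Two groups, two cell types, composition flipped between groups.

    Genes 0-4: cell-type driven only (Simpson-style marginal signal).
    Genes 5-9: true within-type group effect (2x).
    Gene 10:   within-type decrease but marginal increase (sign flip).
    Gene 11:   balance gene keeping every cell's expected total equal, so
               the total-count offset cannot leak group signal into nulls.
    Genes 12-30: flat fillers.
    """
    rng = np.random.default_rng(seed)
    group = np.repeat(["non-tumor", "tumor_A"], n_per_group)
    p_typeB = np.where(group == "tumor_A", 0.8, 0.2)
    ctype = np.where(rng.random(2 * n_per_group) < p_typeB, "B", "A")
    n_genes = 31
    rate = np.full((2 * n_per_group, n_genes), 20.0)
    isB = ctype == "B"
    isT = group == "tumor_A"
    rate[:, 0:5] = np.where(isB[:, None], 40.0, 5.0)
    rate[:, 5:10] = np.where(isT[:, None], 16.0, 8.0)
    rate[:, 10] = np.where(isB, 60.0, 4.0) * np.where(isT, 0.55, 1.0)
    rate[:, 11] = 0.0
    rate[:, 11] = 800.0 - rate.sum(axis=1)
    counts = rng.poisson(rate)
    expr = matrix_from(counts)
    meta = CellMetadataTable(
        pd.DataFrame(
            {
                "barcode": expr.barcodes,
                "sample_id": np.where(isT, "s_tumor", "s_ctrl"),
                "tumor_type": group,
                "cell_type": ctype,
            }
        )
    )
    return expr, meta


@pytest.fixture(scope="module")
def confounded():
    expr, meta = confounded_dataset()
    spec = DesignSpec(n_top_genes=31)
    return de_test(expr, meta, spec, genes=list(expr.features))


class TestDeTest:

    def test_table_schema_and_strata(self, confounded):
        assert set(confounded["model"]) == {"adjusted", "unadjusted"}
        assert len(confounded) == 31 * 2
        assert ((confounded["q"] >= confounded["p"]) | confounded["p"].isna()).all()

    def test_composition_driven_genes_vanish_under_adjustment(self, confounded):
        piv = confounded.pivot(index="gene", columns="model", values="significant")
        conf_genes = [f"g{j}" for j in range(5)]
        assert piv.loc[conf_genes, "unadjusted"].all()
        # truly null under adjustment; BH tolerates at most one stray hit
        assert piv.loc[conf_genes, "adjusted"].sum() <= 1
        est = confounded.pivot(index="gene", columns="model", values="estimate")
        assert est.loc[conf_genes, "unadjusted"].abs().min() > 0.8
        assert est.loc[conf_genes, "adjusted"].abs().max() < 0.1

    def test_true_effects_survive_adjustment(self, confounded):
        piv = confounded.pivot(index="gene", columns="model", values="significant")
        true_genes = [f"g{j}" for j in range(5, 10)]
        assert piv.loc[true_genes, "adjusted"].all()

    def test_simpson_gene_flips_sign(self, confounded):
        est = confounded.pivot(index="gene", columns="model", values="estimate")
        assert est.loc["g10", "unadjusted"] > 0
        assert est.loc["g10", "adjusted"] < 0

    def test_compare_models_counts(self, confounded):
        counts, flips = compare_models(
            confounded[confounded["model"] == "adjusted"],
            confounded[confounded["model"] == "unadjusted"],
        )
        row = counts.set_index("group").loc["tumor_A"]
        assert row["only_unadjusted"] >= 5  # the composition-driven genes
        assert row["both"] >= 5  # the true effects
        piv = confounded.pivot(index="gene", columns="model", values="significant")
        if piv.loc["g10"].all():
            assert "g10" in set(flips["gene"])

    def test_bh_matches_manual_oracle(self, confounded):
        sub = confounded[
            (confounded["model"] == "adjusted") & confounded["p"].notna()
        ].sort_values("p")
        p = sub["p"].to_numpy()
        m = len(p)
        q_manual = np.minimum.accumulate((p * m / np.arange(1, m + 1))[::-1])[::-1]
        np.testing.assert_allclose(sub["q"].to_numpy(), np.minimum(q_manual, 1),
                                   rtol=1e-10)

    def test_missing_referent_rejected(self):
        expr, meta = confounded_dataset()
        with pytest.raises(ValueError, match="referent"):
            de_test(expr, meta, DesignSpec(referent_group="nope"),
                    genes=["g0"])


class TestNullBehaviour:
    def test_null_genes_yield_uniform_p_and_no_discoveries(self):
        rng = np.random.default_rng(13)
        n, n_genes = 200, 300
        counts = rng.poisson(8.0, size=(n, n_genes))
        expr = matrix_from(counts)
        meta = CellMetadataTable(
            pd.DataFrame(
                {
                    "barcode": expr.barcodes,
                    "sample_id": "s",
                    "tumor_type": np.repeat(["non-tumor", "tumor_A"], n // 2),
                    "cell_type": "A",
                }
            )
        )
        table = de_test(expr, meta, DesignSpec(), genes=list(expr.features),
                        models=("unadjusted",))
        p = table["p"].dropna().to_numpy()
        assert st.kstest(p, "uniform").pvalue > 1e-3
        assert table["significant"].mean() <= 0.01
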