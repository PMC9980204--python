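"""Generator correctness: genotype law, pool structure, expression design."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from snmux.simulate import (
    SimulationConfig,
    default_metadata_design,
    generate_donor_genotypes,
    generate_expression,
    generate_pool,
)


class TestDonorGenotypes:
    def test_hardy_weinberg_at_half(self):
        geno, _ = generate_donor_genotypes(200, 300, maf_range=(0.5, 0.5), seed=0)
        freqs = np.bincount(geno.genotypes.ravel(), minlength=3) / geno.genotypes.size
        np.testing.assert_allclose(freqs, [0.25, 0.5, 0.25], atol=0.01)

    def test_same_seed_is_deterministic(self):
        a, sa = generate_donor_genotypes(6, 100, seed=9)
        b, sb = generate_donor_genotypes(6, 100, seed=9)
        np.testing.assert_array_equal(a.genotypes, b.genotypes)
        assert sa.to_frame().equals(sb.to_frame())

    def test_fewer_than_two_donors_rejected(self):
        with pytest.raises(ValueError):
            generate_donor_genotypes(1, 10)

    def test_distinct_genotype_fraction_matches_analytic_expectation(self):
        # brute-force/analytic oracle: for two donors with genotype law
        # Bin(2, maf), P(distinct) = 1 - sum_g P(g)^2, averaged over the
        # uniform MAF distribution by numerical integration
        lo, hi = 0.2, 0.4
        mafs = np.linspace(lo, hi, 2001)
        pg = np.stack([st.binom.pmf(g, 2, mafs) for g in (0, 1, 2)])
        expected = np.trapezoid(1 - (pg**2).sum(axis=0), mafs) / (hi - lo)
        geno, _ = generate_donor_genotypes(2, 5000, maf_range=(lo, hi), seed=1)
        observed = (geno.genotypes[0] != geno.genotypes[1]).mean()
        assert abs(observed - expected) < 0.025  # ~3.5 sigma Monte-Carlo slack


class TestPool:
    def test_extreme_snr_argmax_recovers_donor(self):
        cfg = SimulationConfig(
            n_donors=4, n_sites=50, nuclei_per_donor=100, untagged_rate=0.0,
            doublet_rate=0.0, hto_signal_mean=500, hto_ambient_mean=1, seed=5,
        )
        geno, _ = generate_donor_genotypes(4, 50, seed=5)
        hto, _, _, truth = generate_pool(geno, cfg)
        argmax_tag = np.asarray(hto.counts.argmax(axis=1)).ravel()
        expected = [geno.donors.index(d) for d in truth.frame["true_donor"]]
        np.testing.assert_array_equal(argmax_tag, expected)

    def test_zero_read_depth_gives_empty_allele_counts(self):
        cfg = SimulationConfig(
            n_donors=2, n_sites=20, nuclei_per_donor=30, reads_per_cell_mean=0.0, seed=2
        )
        geno, _ = generate_donor_genotypes(2, 20, seed=2)
        _, alt, dp, _ = generate_pool(geno, cfg)
        assert dp.nnz == 0 and alt.nnz == 0

    def test_alt_never_exceeds_dp(self, extreme_pool):
        diff = extreme_pool["dp"] - extreme_pool["alt"]
        assert diff.nnz == 0 or diff.data.min() >= 0

    def test_doublet_fraction_within_binomial_ci(self):
        cfg = SimulationConfig(n_donors=8, n_sites=10, nuclei_per_donor=500,
                               doublet_rate=0.05, seed=11)
        geno, _ = generate_donor_genotypes(8, 10, seed=11)
        _, _, _, truth = generate_pool(geno, cfg)
        n = len(truth.frame)
        lo, hi = st.binom.ppf([0.005, 0.995], n, 0.05) / n
        assert lo <= truth.frame["is_doublet"].mean() <= hi

    def test_doublets_are_cross_donor(self, extreme_pool):
        dbl = extreme_pool["truth"].frame.query("is_doublet")
        assert (dbl["true_donor"] != dbl["donor_b"]).all()

    def test_fixed_seed_reproduces_pool_exactly(self):
        cfg = SimulationConfig(n_donors=3, n_sites=30, nuclei_per_donor=40, seed=8)
        geno, _ = generate_donor_genotypes(3, 30, seed=8)
        out1 = generate_pool(geno, cfg)
        out2 = generate_pool(geno, cfg)
        assert (out1[0].counts != out2[0].counts).nnz == 0
        assert (out1[1] != out2[1]).nnz == 0
        assert out1[3].frame.equals(out2[3].frame)


def _small_truth(n_cells, donors, seed=0):
    rng = np.random.default_rng(seed)
    from snmux.simulate import TruthTable

    return TruthTable(
        pd.DataFrame(
            {
                "barcode": [f"BC{i}" for i in range(n_cells)],
                "true_donor": rng.choice(donors, size=n_cells),
                "donor_b": [None] * n_cells,
                "is_doublet": [False] * n_cells,
                "is_tagged": [True] * n_cells,
            }
        )
    )


class TestExpression:
    def _design(self, donors, groups):
        return pd.DataFrame(
            {
                "donor": donors,
                "sample_id": [f"s_{d}" for d in donors],
                "tumor_type": groups,
            }
        )

    def test_null_case_group_means_equal(self):
        donors = ["d1", "d2"]
        truth = _small_truth(3000, donors, seed=1)
        cfg = SimulationConfig(n_genes=30, cell_type_levels=["A", "B"],
                               composition_by_group={"non-tumor": [0.5, 0.5],
                                                     "tumor": [0.5, 0.5]}, seed=1)
        expr, meta = generate_expression(truth, self._design(donors, ["non-tumor", "tumor"]), cfg)
        x = expr.dense()
        g = meta.frame["tumor_type"].to_numpy()
        m0, m1 = x[g == "non-tumor"].mean(), x[g == "tumor"].mean()
        assert abs(m0 - m1) / m0 < 0.05

    def test_composition_confounding_moves_marginal_not_stratified_means(self):
        # oracle: direct computation of stratified means
        donors = ["d1", "d2"]
        truth = _small_truth(6000, donors, seed=2)
        eff = pd.DataFrame(0.0, index=["gene00000"], columns=["tumor"])
        cfg = SimulationConfig(
            n_genes=20, cell_type_levels=["A", "B"],
            composition_by_group={"non-tumor": [0.8, 0.2], "tumor": [0.2, 0.8]},
            effect_table=eff, seed=2,
        )
        expr, meta = generate_expression(truth, self._design(donors, ["non-tumor", "tumor"]), cfg)
        x = expr.dense()[:, 0]
        grp = meta.frame["tumor_type"].to_numpy()
        ct = meta.frame["cell_type"].to_numpy()
        marginal = {g: x[grp == g].mean() for g in ("non-tumor", "tumor")}
        # stratified means agree within each cell type
        for c in ("A", "B"):
            a = x[(grp == "non-tumor") & (ct == c)].mean()
            b = x[(grp == "tumor") & (ct == c)].mean()
            assert abs(a - b) < 0.35 * max(a, b, 0.2)
        # but the marginal means differ whenever the gene is cell-type biased
        lam_bias = abs(
            x[ct == "A"].mean() - x[ct == "B"].mean()
        )
        if lam_bias > 0.3:
            assert abs(marginal["tumor"] - marginal["non-tumor"]) > 0.1

    def test_planted_log2_effect_doubles_stratified_means(self):
        donors = ["d1", "d2"]
        truth = _small_truth(8000, donors, seed=3)
        eff = pd.DataFrame(np.log(2.0), index=["gene00000"], columns=["tumor"])
        cfg = SimulationConfig(
            n_genes=10, cell_type_levels=["A", "B"],
            composition_by_group={"non-tumor": [0.5, 0.5], "tumor": [0.5, 0.5]},
            effect_table=eff, seed=3,
        )
        expr, meta = generate_expression(truth, self._design(donors, ["non-tumor", "tumor"]), cfg)
        x = expr.dense()[:, 0]
        grp = meta.frame["tumor_type"].to_numpy()
        ct = meta.frame["cell_type"].to_numpy()
        ratios = []
        for c in ("A", "B"):
            ratios.append(
                x[(grp == "tumor") & (ct == c)].mean()
                / x[(grp == "non-tumor") & (ct == c)].mean()
            )
        np.testing.assert_allclose(ratios, 2.0, rtol=0.25)

    def test_unknown_effect_gene_rejected(self):
        donors = ["d1", "d2"]
        truth = _small_truth(10, donors)
        eff = pd.DataFrame(1.0, index=["nope"], columns=["tumor"])
        cfg = SimulationConfig(n_genes=5, effect_table=eff)
        with pytest.raises(ValueError, match="unknown"):
            generate_expression(truth, self._design(donors, ["non-tumor", "tumor"]), cfg)
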