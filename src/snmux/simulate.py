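"""Synthetic pooled snRNA-seq experiments with known ground truth.

The generator emulates a hashtag-multiplexed pool of nuclei from K donors:

* donor diploid genotypes at M biallelic SNV sites (per-site minor allele
  frequency drawn uniformly, genotype ~ Binomial(2, MAF));
* per-nucleus hashtag (HTO) counts: Poisson ambient background on every
  tag plus a Poisson signal on the nucleus's own tag, except for an
  "untagged" fraction that carries background only;
* per-nucleus ALT/DP allele counts at the SNV sites: total reads Poisson
  with the depth spread uniformly over sites, ALT reads binomial with
  success probability ε, 0.5 or 1−ε for genotypes 0, 1, 2;
* cross-donor doublets (rate configurable) that carry signal on both tags
  and 50/50-mixed allele counts;
* cell-type-structured gene expression in which the cell-type composition
  of each tumor type differs, so that naive group comparisons are
  confounded by composition while group effects act within cell types.

Every output is a deterministic function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import (
    CellMetadataTable,
    DonorGenotypeMatrix,
    SiteTable,
    SparseCountMatrix,
)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic pooled experiment.

    Defaults describe a realistic multiplexed pool: 8 donors tagged with
    one hashtag each, ~500 nuclei per donor, 5% cross-donor doublets, a
    20% untagged fraction (hashtag staining of frozen nuclei is lossy),
    strong hashtag signal over ambient (200 vs 2 mean counts), 50 reads
    per nucleus over 500 genomic sites, and 1% base-call error.
    """

    n_donors: int = 8
    n_sites: int = 500
    maf_range: tuple[float, float] = (0.05, 0.5)
    nuclei_per_donor: int | list[int] = 500
    doublet_rate: float = 0.05
    untagged_rate: float = 0.2
    hto_signal_mean: float = 200.0
    hto_ambient_mean: float = 2.0
    reads_per_cell_mean: float = 50.0
    base_error_rate: float = 0.01
    n_genes: int = 2000
    cell_type_levels: list[str] = field(
        default_factory=lambda: ["neuron", "astrocyte", "progenitor"]
    )
    composition_by_group: dict[str, list[float]] | None = None
    effect_table: pd.DataFrame | None = None  # genes x groups, log-fold effects
    seed: int = 0

    def validate(self) -> None:
        for name in ("doublet_rate", "untagged_rate", "base_error_rate"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name}={v} outside [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range {self.maf_range} outside (0, 0.5]")
        if self.composition_by_group is not None:
            for g, p in self.composition_by_group.items():
                if len(p) != len(self.cell_type_levels):
                    raise ValueError(f"composition for {g} has wrong length")
                if abs(sum(p) - 1.0) > 1e-9:
                    raise ValueError(f"composition for {g} does not sum to 1")


@dataclass
class TruthTable:
    """Ground truth per synthetic barcode."""

    frame: pd.DataFrame  # barcode, true_donor, donor_b, is_doublet, is_tagged

    def __post_init__(self) -> None:
        if self.frame["barcode"].duplicated().any():
            raise ValueError("duplicate barcodes in truth table")
        pair = self.frame["donor_b"].notna()
        if not (pair == self.frame["is_doublet"]).all():
            raise ValueError("is_doublet inconsistent with donor pair")


def generate_donor_genotypes(
    n_donors: int,
    n_sites: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
) -> tuple[DonorGenotypeMatrix, SiteTable]:
    """Draw diploid genotypes: per-site MAF ~ U(maf_range), G ~ Bin(2, MAF)."""
    if n_donors < 2:
        raise ValueError("need at least 2 donors for demultiplexing")
    if n_sites < 1:
        raise ValueError("need at least 1 site")
    rng = np.random.default_rng(seed)
    maf = rng.uniform(maf_range[0], maf_range[1], size=n_sites)
    geno = rng.binomial(2, maf, size=(n_donors, n_sites))
    donors = [f"donor{d:02d}" for d in range(n_donors)]
    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
    sites = SiteTable(
        chrom=["chr1"] * n_sites,
        pos=list(range(1, n_sites + 1)),
        ref=list(bases[ref_idx]),
        alt=list(bases[alt_idx]),
    )
    return DonorGenotypeMatrix(donors, geno), sites


def _alt_prob(genotype: np.ndarray, eps: float) -> np.ndarray:
    """P(ALT read | genotype) for genotypes 0/1/2: ε, 0.5, 1−ε."""
    return np.choose(genotype, [eps, 0.5, 1.0 - eps])


def generate_pool(
    genotypes: DonorGenotypeMatrix, config: SimulationConfig
) -> tuple[SparseCountMatrix, sp.csr_matrix, sp.csr_matrix, TruthTable]:
    """Simulate a hashtag-multiplexed pool of nuclei.

    Returns the HTO count matrix (one tag per donor), the per-cell
    ALT and DP allele-count matrices (cells × sites), and the truth table.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    K, S = genotypes.n_donors, genotypes.n_sites
    per = config.nuclei_per_donor
    per_donor = [per] * K if np.isscalar(per) else list(per)
    if len(per_donor) != K:
        raise ValueError("nuclei_per_donor list must have one entry per donor")
    n_cells = int(sum(per_donor))

    donor_a = np.repeat(np.arange(K), per_donor)
    is_doublet = rng.random(n_cells) < config.doublet_rate
    # second donor of a doublet: uniform over the other K-1 donors
    shift = rng.integers(1, K, size=n_cells)
    donor_b = np.where(is_doublet, (donor_a + shift) % K, -1)
    is_tagged = rng.random(n_cells) >= config.untagged_rate

    barcodes = [f"BC{i:06d}" for i in range(n_cells)]
    tags = [f"tag-{d}" for d in genotypes.donors]

    # HTO counts: ambient Poisson everywhere, signal on own tag(s) if tagged
    hto = rng.poisson(config.hto_ambient_mean, size=(n_cells, K))
    signal = rng.poisson(config.hto_signal_mean, size=(n_cells, 2))
    tagged_idx = np.where(is_tagged)[0]
    hto[tagged_idx, donor_a[tagged_idx]] += signal[tagged_idx, 0]
    dbl_tagged = np.where(is_tagged & is_doublet)[0]
    hto[dbl_tagged, donor_b[dbl_tagged]] += signal[dbl_tagged, 1]
    hto_mat = SparseCountMatrix(sp.csr_matrix(hto), barcodes, tags)

    # Allele counts: reads Poisson, spread uniformly over sites
    total_reads = rng.poisson(config.reads_per_cell_mean, size=n_cells)
    eps = config.base_error_rate
    p_by_donor = _alt_prob(genotypes.genotypes, eps)  # (K, S)
    indptr = [0]
    cols_all, dp_all, alt_all = [], [], []
    for c in range(n_cells):
        n = total_reads[c]
        if n == 0:
            indptr.append(indptr[-1])
            continue
        counts = rng.multinomial(n, np.full(S, 1.0 / S))
        covered = np.nonzero(counts)[0]
        dp = counts[covered]
        p = p_by_donor[donor_a[c], covered]
        if is_doublet[c]:
            p = 0.5 * (p + p_by_donor[donor_b[c], covered])
        alt = rng.binomial(dp, p)
        cols_all.append(covered)
        dp_all.append(dp)
        alt_all.append(alt)
        indptr.append(indptr[-1] + len(covered))
    if cols_all:
        cols = np.concatenate(cols_all)
        dp_data = np.concatenate(dp_all)
        alt_data = np.concatenate(alt_all)
    else:
        cols = np.array([], dtype=int)
        dp_data = alt_data = np.array([], dtype=int)
    dp_mat = sp.csr_matrix((dp_data, cols, indptr), shape=(n_cells, S))
    alt_mat = sp.csr_matrix((alt_data, cols.copy(), list(indptr)), shape=(n_cells, S))
    alt_mat.eliminate_zeros()

    truth = TruthTable(
        pd.DataFrame(
            {
                "barcode": barcodes,
                "true_donor": [genotypes.donors[d] for d in donor_a],
                "donor_b": [
                    genotypes.donors[d] if d >= 0 else None for d in donor_b
                ],
                "is_doublet": is_doublet,
                "is_tagged": is_tagged,
            }
        )
    )
    return hto_mat, alt_mat, dp_mat, truth


def generate_expression(
    truth: TruthTable,
    metadata_design: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[SparseCountMatrix, CellMetadataTable]:
    """Simulate cell-type-structured gene counts with group effects.

    ``metadata_design`` maps each donor to a sample_id and tumor_type
    (columns: donor, sample_id, tumor_type).  Each cell's type is drawn
    from its tumor type's composition; counts are Poisson with rate
    ``s_c * lambda[gene, cell_type] * exp(effect_table[gene, group])``
    where ``s_c`` is a LogNormal per-cell size factor.  Doublet cells are
    assigned by their first donor (expression doublet artifacts are not
    modeled).
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    levels = list(config.cell_type_levels)
    groups = list(dict.fromkeys(metadata_design["tumor_type"]))
    comp = config.composition_by_group
    if comp is None:
        comp = {g: [1.0 / len(levels)] * len(levels) for g in groups}
    for g in groups:
        if g not in comp:
            raise ValueError(f"no composition for group {g!r}")

    genes = [f"gene{j:05d}" for j in range(config.n_genes)]
    effect = config.effect_table
    if effect is not None:
        unknown_genes = set(effect.index) - set(genes)
        unknown_groups = set(effect.columns) - set(groups)
        if unknown_genes or unknown_groups:
            raise ValueError(
                f"effect_table references unknown genes {sorted(unknown_genes)[:3]} "
                f"or groups {sorted(unknown_groups)}"
            )

    donor_map = metadata_design.set_index("donor")
    frame = truth.frame
    sample_id = donor_map.loc[frame["true_donor"], "sample_id"].to_numpy()
    tumor_type = donor_map.loc[frame["true_donor"], "tumor_type"].to_numpy()
    n_cells = len(frame)

    cell_type = np.empty(n_cells, dtype=object)
    for g in groups:
        mask = tumor_type == g
        cell_type[mask] = rng.choice(levels, size=mask.sum(), p=comp[g])

    # baseline lambda: gene x cell type, LogNormal means around 0.5
    base = rng.lognormal(mean=np.log(0.5), sigma=0.5, size=config.n_genes)
    type_mult = rng.lognormal(mean=0.0, sigma=0.6, size=(config.n_genes, len(levels)))
    lam = base[:, None] * type_mult  # (G, n_types)

    log_eff = np.zeros((config.n_genes, len(groups)))
    if effect is not None:
        gidx = {g: i for i, g in enumerate(genes)}
        cidx = {g: i for i, g in enumerate(groups)}
        for gene, row in effect.iterrows():
            for grp, val in row.items():
                if not np.isnan(val):
                    log_eff[gidx[gene], cidx[grp]] = val

    size_factor = rng.lognormal(mean=0.0, sigma=0.3, size=n_cells)
    type_idx = np.array([levels.index(t) for t in cell_type])
    group_idx = np.array([groups.index(g) for g in tumor_type])

    rows, cols, data = [], [], []
    for t in range(len(levels)):
        for g in range(len(groups)):
            mask = np.where((type_idx == t) & (group_idx == g))[0]
            if mask.size == 0:
                continue
            rate = np.outer(size_factor[mask], lam[:, t] * np.exp(log_eff[:, g]))
            counts = rng.poisson(rate)
            r, c = np.nonzero(counts)
            rows.append(mask[r])
            cols.append(c)
            data.append(counts[r, c])
    if rows:
        mat = sp.csr_matrix(
            (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n_cells, config.n_genes),
        )
    else:
        mat = sp.csr_matrix((n_cells, config.n_genes), dtype=int)

    expr = SparseCountMatrix(mat, list(frame["barcode"]), genes)
    meta = CellMetadataTable(
        pd.DataFrame(
            {
                "barcode": frame["barcode"],
                "sample_id": sample_id,
                "tumor_type": tumor_type,
                "cell_type": cell_type,
            }
        )
    )
    return expr, meta


def default_metadata_design(
    donors: list[str], groups: list[str] | None = None
) -> pd.DataFrame:
    """Assign donors round-robin to tumor types (last group gets the rest).

    By default the first two donors are non-tumor and the remainder are
    split between two tumor types, mimicking a pool that mixes tumor and
    referent tissue.
    """
    if groups is None:
        groups = ["non-tumor", "tumor_A", "tumor_B"]
    n = len(donors)
    assignment = [groups[min(i * len(groups) // n, len(groups) - 1)] for i in range(n)]
    return pd.DataFrame(
        {
            "donor": donors,
            "sample_id": [f"sample_{d}" for d in donors],
            "tumor_type": assignment,
        }
    )
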