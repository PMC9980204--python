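import numpy as np
import pytest
import scipy.sparse as sp

from snmux.genotype import CellAlleleCounts
from snmux.io import SparseCountMatrix
from snmux.simulate import (
    SimulationConfig,
    generate_donor_genotypes,
    generate_pool,
)


@pytest.fixture(scope="session")
def extreme_pool():
    """Strong-signal multiplexed pool: 8 donors x 500 nuclei, 500 sites,
    HTO signal 200 vs ambient 2, 20% untagged, 5% doublets, 50 reads/cell."""
    cfg = SimulationConfig(seed=42)
    geno, sites = generate_donor_genotypes(
        cfg.n_donors, cfg.n_sites, cfg.maf_range, cfg.seed
    )
    hto, alt, dp, truth = generate_pool(geno, cfg)
    return dict(cfg=cfg, geno=geno, sites=sites, hto=hto, alt=alt, dp=dp, truth=truth)


@pytest.fixture(scope="session")
def extreme_hto_calls(extreme_pool):
    from snmux.hto import classify_hto

    return classify_hto(extreme_pool["hto"], seed=0)


@pytest.fixture(scope="session")
def extreme_geno_calls(extreme_pool):
    from snmux.genotype import demux_genotype

    cells = CellAlleleCounts(
        extreme_pool["alt"],
        extreme_pool["dp"],
        list(extreme_pool["truth"].frame["barcode"]),
    )
    return demux_genotype(cells, extreme_pool["geno"])


def random_count_matrix(rng, n_cells=20, n_features=10, density=0.3, max_count=50):
    mat = sp.random(
        n_cells,
        n_features,
        density=density,
        random_state=np.random.RandomState(rng.integers(2**31)),
        data_rvs=lambda k: rng.integers(1, max_count, size=k),
    )
    return SparseCountMatrix(
        sp.csr_matrix(mat.astype(int)),
        [f"BC{i}" for i in range(n_cells)],
        [f"G{j}" for j in range(n_features)],
    )
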