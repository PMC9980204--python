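"""Donor assignment from per-cell allele counts at known genotypes.

Each cell's ALT/DP read counts at bulk-derived SNV sites are scored
under every donor (and, optionally, every unordered cross-donor pair as
a doublet hypothesis) with a per-site binomial read model:

    P(ALT reads | genotype g) = Binomial(DP, p_g),
    p_0 = eps, p_1 = 0.5, p_2 = 1 - eps,

with the doublet success probability the mean of the two donors'.  A
posterior over hypotheses (uniform singlet prior, a configurable total
doublet prior mass split over pairs) yields singlet / doublet /
unassigned calls at a posterior threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import scipy.sparse as sp
from scipy.special import gammaln, logsumexp

from .io import DonorGenotypeMatrix


@dataclass
class CellAlleleCounts:
    """Per-cell ALT and DP sparse count matrices (cells × sites)."""

    alt: sp.csr_matrix
    dp: sp.csr_matrix
    barcodes: list[str]

    def __post_init__(self) -> None:
        self.alt = sp.csr_matrix(self.alt)
        self.dp = sp.csr_matrix(self.dp)
        if self.alt.shape != self.dp.shape:
            raise ValueError("alt and dp shapes differ")
        if self.alt.shape[0] != len(self.barcodes):
            raise ValueError("barcode count does not match matrix rows")
        if (self.alt.data < 0).any() or (self.dp.data < 0).any():
            raise ValueError("negative allele counts")
        if ((self.dp - self.alt) < 0).nnz:
            raise ValueError("alt exceeds dp")


@dataclass
class GenotypeCall:
    barcode: str
    call: str  # singlet | doublet | unassigned
    assigned_donor: str | None
    posterior: float
    n_informative_sites: int


def _geno_probs(G: np.ndarray, eps: float) -> np.ndarray:
    return np.choose(G, [eps, 0.5, 1.0 - eps])


def cell_donor_loglik(
    cells: CellAlleleCounts,
    G: DonorGenotypeMatrix,
    error_rate: float = 0.01,
    doublet_pairs: bool = True,
) -> tuple[np.ndarray, list]:
    """Log-likelihood of each cell under each donor / donor-pair hypothesis.

    Returns ``(loglik, hypotheses)`` where ``loglik`` is cells × hypotheses
    and ``hypotheses`` lists donor ids (singlets) followed by unordered
    ``(donor_a, donor_b)`` tuples when ``doublet_pairs``.  Sites with
    DP = 0 contribute nothing; the binomial coefficient term (constant
    across hypotheses) is included.
    """
    if not 0 < error_rate < 0.5:
        raise ValueError(f"error_rate {error_rate} outside (0, 0.5)")
    if cells.alt.shape[1] != G.n_sites:
        raise ValueError("site dimension mismatch between cells and genotypes")

    p_singlet = _geno_probs(G.genotypes, error_rate)  # (K, S)
    hypotheses: list = list(G.donors)
    p_rows = [p_singlet]
    if doublet_pairs:
        pairs = list(combinations(range(G.n_donors), 2))
        hypotheses += [(G.donors[a], G.donors[b]) for a, b in pairs]
        p_rows.append(
            np.stack([0.5 * (p_singlet[a] + p_singlet[b]) for a, b in pairs])
        )
    P = np.vstack(p_rows)  # (H, S)

    A = cells.alt.astype(float)
    D = cells.dp.astype(float)
    R = D - A  # REF reads, sparse
    # per-cell constant: sum of log C(dp, alt) over covered sites,
    # computed on the dp sparsity pattern (alt's pattern is a subset)
    Dcsr = D.tocsr()
    alt_on_dp = np.asarray(A[Dcsr.nonzero()]).ravel()
    dp_vals = Dcsr.data
    const = np.zeros(A.shape[0])
    cell_idx = np.repeat(np.arange(A.shape[0]), np.diff(Dcsr.indptr))
    term = (
        gammaln(dp_vals + 1)
        - gammaln(alt_on_dp + 1)
        - gammaln(dp_vals - alt_on_dp + 1)
    )
    np.add.at(const, cell_idx, term)

    loglik = A @ np.log(P).T + R @ np.log1p(-P).T
    loglik = np.asarray(loglik) + const[:, None]
    return loglik, hypotheses


def n_informative_sites(cells: CellAlleleCounts) -> np.ndarray:
    """Number of sites with DP > 0 per cell."""
    return np.asarray((cells.dp > 0).sum(axis=1)).ravel()


def assign_genotype(
    logliks: np.ndarray,
    hypotheses: list,
    barcodes: list[str],
    n_informative: np.ndarray,
    posterior_threshold: float = 0.9,
    doublet_prior: float = 0.05,
) -> list[GenotypeCall]:
    """Posterior donor assignment from hypothesis log-likelihoods.

    Prior: total singlet mass ``1 - doublet_prior`` split uniformly over
    donors, total doublet mass ``doublet_prior`` split uniformly over
    pairs (all mass on singlets when there are no pair hypotheses).
    A cell with no informative site is unassigned with posterior
    ``1 / n_donors``.
    """
    if len(hypotheses) == 0:
        raise ValueError("empty hypothesis set")
    is_pair = np.array([isinstance(h, tuple) for h in hypotheses])
    n_singlet = int((~is_pair).sum())
    n_pair = int(is_pair.sum())
    log_prior = np.empty(len(hypotheses))
    if n_pair:
        log_prior[~is_pair] = np.log((1 - doublet_prior) / n_singlet)
        log_prior[is_pair] = np.log(doublet_prior / n_pair)
    else:
        log_prior[:] = -np.log(n_singlet)

    calls: list[GenotypeCall] = []
    for c, bc in enumerate(barcodes):
        n_inf = int(n_informative[c])
        if n_inf == 0:
            calls.append(
                GenotypeCall(bc, "unassigned", None, 1.0 / n_singlet, 0)
            )
            continue
        logpost = logliks[c] + log_prior
        logpost -= logsumexp(logpost)
        post = np.exp(logpost)
        top = int(np.argmax(post))
        if not is_pair[top]:
            p = float(post[top])
            if p >= posterior_threshold:
                calls.append(GenotypeCall(bc, "singlet", hypotheses[top], p, n_inf))
            else:
                calls.append(GenotypeCall(bc, "unassigned", None, p, n_inf))
        else:
            pair_mass = float(post[is_pair].sum())
            if pair_mass >= posterior_threshold:
                calls.append(GenotypeCall(bc, "doublet", None, pair_mass, n_inf))
            else:
                calls.append(GenotypeCall(bc, "unassigned", None, float(post[top]), n_inf))
    return calls


def demux_genotype(
    cells: CellAlleleCounts,
    G: DonorGenotypeMatrix,
    error_rate: float = 0.01,
    doublet_pairs: bool = True,
    posterior_threshold: float = 0.9,
    doublet_prior: float = 0.05,
) -> list[GenotypeCall]:
    """End-to-end genotype demultiplexing of a pool."""
    loglik, hyps = cell_donor_loglik(cells, G, error_rate, doublet_pairs)
    return assign_genotype(
        loglik,
        hyps,
        cells.barcodes,
        n_informative_sites(cells),
        posterior_threshold,
        doublet_prior,
    )


def geno_calls_to_frame(calls: list[GenotypeCall]):
    import pandas as pd

    return pd.DataFrame(
        {
            "barcode": [c.barcode for c in calls],
            "call": [c.call for c in calls],
            "assigned_donor": [c.assigned_donor for c in calls],
            "posterior": [c.posterior for c in calls],
            "n_informative_sites": [c.n_informative_sites for c in calls],
        }
    )
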