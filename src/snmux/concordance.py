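"""Cross-tumor-type sharing and direction-concordance of DE genes.

For T tumor types each compared with the same referent, a gene
significant in all T contrasts is *concordant* when its effect sign is
identical in every contrast.  Under a null where each contrast's sign is
an independent fair coin, the expected concordant fraction is
2/2^T (the 2 all-same vectors out of the 2^T equiprobable sign
vectors); the observed fraction is compared to it with a one-sample
proportion test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.stats.proportion import proportions_chisquare


def sharing_counts(
    de_tables: dict[str, pd.DataFrame], alpha: float = 0.05
) -> pd.DataFrame:
    """Per-gene count of tumor types with q < alpha, plus effect signs.

    ``de_tables`` maps tumor type → DE table (columns gene, estimate, q).
    All tables must cover the same gene universe.  Returns one row per
    gene with ``n_types_significant`` and a ``sign_<type>`` column per
    tumor type (−1/0/+1; 0 where not significant or estimate is 0).
    """
    if len(de_tables) < 2:
        raise ValueError("need at least 2 tumor types")
    types = list(de_tables)
    universe = None
    cols = {}
    for t, table in de_tables.items():
        tab = table.set_index("gene")
        genes = set(tab.index)
        if universe is None:
            universe = sorted(genes)
        elif set(universe) != genes:
            raise ValueError(f"gene universe of {t!r} differs from the others")
        sig = (tab["q"] < alpha).reindex(universe).fillna(False)
        sign = np.sign(tab["estimate"].reindex(universe).fillna(0.0))
        cols[t] = np.where(sig, sign, 0).astype(int)
    out = pd.DataFrame({f"sign_{t}": cols[t] for t in types}, index=pd.Index(universe, name="gene"))
    out.insert(0, "n_types_significant", (out != 0).sum(axis=1))
    return out


@dataclass
class ConcordanceResult:
    n_shared: int
    n_concordant: int
    observed_prop: float
    expected_prop: float | None = None
    p_value: float | None = None


def direction_concordance(sharing: pd.DataFrame, k: int) -> ConcordanceResult:
    """Concordance among genes significant in exactly k tumor types.

    A gene is concordant when all k of its non-zero signs are identical;
    a zero sign (estimate exactly 0) counts as discordant.
    """
    sign_cols = [c for c in sharing.columns if c.startswith("sign_")]
    T = len(sign_cols)
    if k > T:
        raise ValueError(f"k={k} exceeds the {T} tumor types present")
    shared = sharing[sharing["n_types_significant"] == k]
    if len(shared) == 0:
        raise ValueError(f"no genes significant in exactly {k} tumor types")
    signs = shared[sign_cols].to_numpy()
    n_pos = (signs > 0).sum(axis=1)
    n_neg = (signs < 0).sum(axis=1)
    concordant = (n_pos == k) | (n_neg == k)
    return ConcordanceResult(
        n_shared=int(len(shared)),
        n_concordant=int(concordant.sum()),
        observed_prop=float(concordant.mean()),
    )


def expected_concordance(T: int) -> float:
    """Null concordant fraction: 2 all-same vectors of the 2^T sign vectors."""
    if T < 1:
        raise ValueError("need at least 1 tumor type")
    return 2.0 / 2**T


def one_sample_proportion_test(
    k: int, n: int, p0: float, exact: bool = False
) -> float:
    """Two-sided one-sample proportion test of k/n against p0.

    Default is the χ² proportion test without continuity correction;
    ``exact`` switches to the exact binomial test.
    """
    if n == 0:
        raise ValueError("n must be positive")
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    if not 0 <= k <= n:
        raise ValueError("k must be in [0, n]")
    if exact:
        return float(st.binomtest(k, n, p0).pvalue)
    _, p, _ = proportions_chisquare(k, n, value=p0)
    return float(p)


def concordance_test(sharing: pd.DataFrame, k: int | None = None) -> ConcordanceResult:
    """Full concordance analysis: observed vs the 2/2^T null at k = T."""
    sign_cols = [c for c in sharing.columns if c.startswith("sign_")]
    T = len(sign_cols)
    if k is None:
        k = T
    res = direction_concordance(sharing, k)
    res.expected_prop = expected_concordance(T)
    res.p_value = one_sample_proportion_test(res.n_concordant, res.n_shared, res.expected_prop)
    return res
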