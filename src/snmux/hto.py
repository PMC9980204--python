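"""Hashtag-oligonucleotide (HTO) demultiplexing.

Classifies each nucleus as singlet (one hashtag clearly above its
background), doublet (two or more), or negative (none) from the raw HTO
counts, using the standard background-model scheme: CLR-normalize, find
a background population per tag by k-means clustering, fit a negative
binomial to that tag's raw background counts, and call a tag "positive"
for a cell when its raw count exceeds a high quantile of the fitted
background distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats as st
from sklearn.cluster import KMeans

from .io import SparseCountMatrix


@dataclass
class HTOCall:
    barcode: str
    call: str  # singlet | doublet | negative
    assigned_tag: str | None
    positive_tags: frozenset[str]
    margin: float


def clr_normalize(hto: SparseCountMatrix | np.ndarray) -> np.ndarray:
    """Centered log transform per tag: ln(x+1) minus its across-cell mean."""
    x = hto.dense() if isinstance(hto, SparseCountMatrix) else np.asarray(hto, float)
    if x.size == 0:
        raise ValueError("empty HTO matrix")
    logx = np.log1p(x)
    return logx - logx.mean(axis=0, keepdims=True)


def _background_threshold(raw: np.ndarray, q: float) -> float:
    """Quantile of an NB fitted by moments to background counts.

    Falls back to Poisson when the sample variance does not exceed the
    mean (the NB moment estimator is undefined there).
    """
    m = raw.mean()
    v = raw.var(ddof=1) if raw.size > 1 else 0.0
    if m <= 0:
        return 0.0
    if v <= m:
        return float(st.poisson.ppf(q, m))
    r = m * m / (v - m)
    p = r / (r + m)
    return float(st.nbinom.ppf(q, r, p))


def classify_hto(
    hto: SparseCountMatrix,
    positive_quantile: float = 0.99,
    seed: int = 0,
) -> list[HTOCall]:
    """Singlet/doublet/negative calls from hashtag counts.

    Algorithm: (1) CLR-normalize; (2) k-means with k = n_tags + 1 on the
    CLR profiles (seeded, n_init=10, centroid order canonicalized by
    lexicographic sort so cell order cannot relabel clusters); (3) per
    tag, background cells = the cluster with the lowest mean CLR for that
    tag; (4) negative binomial fitted by moments to the tag's raw counts
    over background cells (Poisson fallback when variance <= mean);
    (5) positive iff raw count > the ``positive_quantile`` quantile of
    the background fit; (6) singlet/doublet/negative by the number of
    positive tags, with the assigned tag the CLR argmax among positives.
    """
    n_cells, n_tags = hto.n_cells, hto.n_features
    if n_tags < 2:
        raise ValueError("need at least 2 hashtags")
    k = n_tags + 1
    if n_cells < k:
        raise ValueError(f"need at least {k} cells for k-means with k={k}")

    raw = hto.dense().astype(float)
    clr = clr_normalize(raw)

    # Deterministic, cell-order-invariant initialization: one centre per
    # tag from that tag's strongly-positive cells (argmax == tag, top
    # quartile within them) and one negative centre from low-max cells.
    # Plain k-means++ seeding would depend on row order.
    centers0 = np.empty((k, n_tags))
    argmax = clr.argmax(axis=1)
    for t in range(n_tags):
        own = clr[argmax == t]
        if len(own) == 0:
            own = clr[np.argsort(clr[:, t])[-max(n_cells // 20, 2):]]
        cut = np.quantile(own[:, t], 0.75)
        strong = own[own[:, t] >= cut]
        centers0[t] = strong.mean(axis=0)
    maxes = clr.max(axis=1)
    low = clr[maxes <= np.quantile(maxes, 0.25)]
    centers0[n_tags] = low.mean(axis=0) if len(low) else clr.mean(axis=0)

    km = KMeans(n_clusters=k, init=centers0, n_init=1, random_state=seed)
    labels = km.fit_predict(clr)
    # canonicalize: relabel clusters by lexicographic order of centroids
    order = np.lexsort(km.cluster_centers_.T[::-1])
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    labels = relabel[labels]
    centers = km.cluster_centers_[order]

    thresholds = np.empty(n_tags)
    for t in range(n_tags):
        bg_cluster = int(np.argmin(centers[:, t]))
        bg_cells = labels == bg_cluster
        if not bg_cells.any():
            raise ValueError(
                f"background cluster for tag {hto.features[t]!r} is empty; "
                "use a larger pool or a smaller k"
            )
        thresholds[t] = _background_threshold(raw[bg_cells, t], positive_quantile)

    positive = raw > thresholds[None, :]
    calls: list[HTOCall] = []
    for c in range(n_cells):
        pos = np.nonzero(positive[c])[0]
        clr_sorted = np.sort(clr[c])[::-1]
        margin = float(clr_sorted[0] - clr_sorted[1])
        if len(pos) == 0:
            call, tag = "negative", None
        elif len(pos) == 1:
            call, tag = "singlet", hto.features[pos[0]]
        else:
            call = "doublet"
            tag = None
        calls.append(
            HTOCall(
                barcode=hto.barcodes[c],
                call=call,
                assigned_tag=tag,
                positive_tags=frozenset(hto.features[i] for i in pos),
                margin=margin,
            )
        )
    return calls


def calls_to_frame(calls: list[HTOCall]):
    import pandas as pd

    return pd.DataFrame(
        {
            "barcode": [c.barcode for c in calls],
            "call": [c.call for c in calls],
            "assigned_tag": [c.assigned_tag for c in calls],
            "positive_tags": [",".join(sorted(c.positive_tags)) for c in calls],
            "margin": [c.margin for c in calls],
        }
    )
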