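"""Interpretation of fitted factors.

Assigns each sample its predominant signature, hierarchically clusters
samples by their signature-weight make-up (loading columns are first
normalized to proportions, so only the relative composition matters),
scores cluster-group agreement, and extracts each signature's top-weighted
metabolite list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, fcluster, linkage
from scipy.spatial.distance import pdist

from .exceptions import (
    DegenerateProfileError,
    UndefinedDominanceError,
    ValidationError,
)
from .matrix import SampleWeights, SignatureSet

__all__ = ["ClusterAssignment", "dominant_signature", "cluster_samples",
           "top_metabolites"]


def _loadings_frame(loadings) -> pd.DataFrame:
    if isinstance(loadings, SampleWeights):
        return loadings.loadings
    if isinstance(loadings, pd.DataFrame):
        return loadings
    arr = np.asarray(loadings, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"P{i + 1}" for i in range(arr.shape[0])],
        columns=[f"S{j + 1}" for j in range(arr.shape[1])],
    )


@dataclass
class ClusterAssignment:
    """Average-linkage hierarchy over samples plus a flat cut.

    ``merge_tree`` is a scipy linkage matrix (rows: node, node, height,
    size); ``flat_labels`` maps sample id -> cluster index at the requested
    cut; ``purity_by_group`` is the fraction of each group's samples that
    fall in the group's majority cluster (only when groups are supplied).
    """

    merge_tree: np.ndarray
    flat_labels: pd.Series
    cut_k: int
    sample_ids: list[str]
    purity_by_group: dict[str, float] = field(default_factory=dict)
    # cophenetic correlation of this direct clustering of the profiles
    # (NaN when the pairwise distances have no variance); reported for
    # comparison with the consensus-based coefficient
    cophenetic: float = float("nan")


def dominant_signature(loadings) -> pd.DataFrame:
    """Per-sample predominant signature (maximum loading).

    Ties are broken toward the lowest signature index and flagged in the
    ``tie`` column.  A sample with all-zero loadings has no defined
    dominant signature and raises :class:`UndefinedDominanceError`.
    """
    L = _loadings_frame(loadings)
    H = L.to_numpy()
    zero = np.flatnonzero(H.sum(axis=0) == 0)
    if zero.size:
        raise UndefinedDominanceError(
            f"sample(s) {[L.columns[j] for j in zero]} have all-zero loadings"
        )
    idx = np.argmax(H, axis=0)  # argmax takes the first (lowest) on ties
    ties = (H == H.max(axis=0)).sum(axis=0) > 1
    return pd.DataFrame(
        {
            "sample": list(L.columns),
            "signature": [L.index[i] for i in idx],
            "tie": ties,
        }
    ).set_index("sample")


def cluster_samples(
    loadings,
    distance: str = "correlation",
    cut_k: int = 2,
    groups: pd.Series | dict | None = None,
    linkage_method: str = "average",
) -> ClusterAssignment:
    """Hierarchically cluster samples by their signature proportions.

    Loading columns are normalized to proportions before the distance
    computation, so the clustering is invariant to per-sample rescaling.
    ``distance`` is "correlation" (default; relative signature make-up) or
    "euclidean".
    """
    L = _loadings_frame(loadings)
    n = L.shape[1]
    if n < 2:
        raise ValidationError("clustering needs >= 2 samples")
    if not (1 <= cut_k <= n):
        raise ValidationError(f"cut_k={cut_k} outside [1, {n}]")
    if distance not in ("correlation", "euclidean"):
        raise ValidationError(f"unknown distance {distance!r}")
    H = L.to_numpy()
    totals = H.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise UndefinedDominanceError(
            f"sample(s) {[L.columns[j] for j in zero]} have all-zero loadings"
        )
    profiles = (H / totals).T  # samples x k proportions
    if distance == "correlation":
        flat = np.flatnonzero(profiles.std(axis=1) == 0)
        if flat.size:
            raise DegenerateProfileError(
                f"sample(s) {[L.columns[j] for j in flat]} have a constant "
                "loading profile; correlation distance is undefined"
            )
    d = pdist(profiles, metric=distance)
    Z = linkage(d, method=linkage_method)
    if n >= 3 and np.ptp(d) > 1e-15:
        coph = float(cophenet(Z, d)[0])
    else:
        coph = float("nan")
    labels = fcluster(Z, t=cut_k, criterion="maxclust")
    flat = pd.Series(labels, index=list(L.columns), name="cluster")

    purity: dict[str, float] = {}
    if groups is not None:
        g = pd.Series(groups)
        for grp in sorted(g.unique()):
            members = g.index[g == grp]
            counts = flat.loc[members].value_counts()
            purity[grp] = float(counts.iloc[0] / len(members))
    return ClusterAssignment(
        merge_tree=Z,
        flat_labels=flat,
        cut_k=cut_k,
        sample_ids=list(L.columns),
        purity_by_group=purity,
        cophenetic=coph,
    )


def top_metabolites(
    signatures,
    signature: str,
    q: float | None = None,
    floor: float | None = None,
) -> pd.DataFrame:
    """Top-weighted metabolites of one signature.

    Exactly one rule applies: ``q`` (cumulative-mass, default 0.5) keeps
    the smallest descending-weight prefix whose weights sum to at least
    ``q``; ``floor`` keeps every metabolite with weight strictly above the
    floor.  Ordering is by descending weight, ties broken by metabolite
    identifier, so the result is deterministic.
    """
    W = signatures.weights if isinstance(signatures, SignatureSet) else signatures
    if signature not in W.columns:
        raise KeyError(
            f"unknown signature {signature!r}; have {list(W.columns)}"
        )
    if q is not None and floor is not None:
        raise ValidationError("give either q (cumulative mass) or floor, not both")
    if q is None and floor is None:
        q = 0.5
    col = W[signature]
    order = sorted(col.index, key=lambda m: (-col[m], m))
    weights = col.loc[order]
    cum = weights.cumsum()
    if q is not None:
        if not (0 < q <= 1):
            raise ValidationError("q must lie in (0, 1]")
        # smallest prefix reaching q (tolerate rounding at q == 1)
        n_keep = int(np.searchsorted(cum.to_numpy(), q - 1e-12) + 1)
        n_keep = min(n_keep, len(cum))
        keep = order[:n_keep]
    else:
        if floor < 0:
            raise ValidationError("floor must be >= 0")
        keep = [m for m in order if col[m] > floor]
    return pd.DataFrame(
        {"weight": weights.loc[keep], "cumulative_weight": cum.loc[keep]},
        index=pd.Index(keep, name="metabolite"),
    )
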