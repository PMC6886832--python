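"""Consensus clustering across NMF restarts and cophenetic rank selection.

For a candidate rank ``k`` the factorization is repeated from ``n_runs``
random initializations; each run assigns every sample to its
maximum-loading signature, giving a binary connectivity matrix, and the
consensus matrix is the mean connectivity across runs.  A stable rank
yields a near-binary consensus whose distance structure ``1 - C`` is close
to ultrametric; this is quantified by the cophenetic correlation
coefficient of an average-linkage dendrogram built on ``1 - C``.  The rank
maximizing the coefficient (smallest rank on ties) is selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator

from .exceptions import DegenerateDendrogramError, PipelineStageError, ValidationError
from .matrix import MetaboliteMatrix
from .nmf import SignatureNMF

__all__ = [
    "ConsensusResult",
    "RankSelectionResult",
    "ConsensusRankSelector",
    "consensus_matrix",
    "cophenetic_coefficient",
    "select_rank",
]


@dataclass
class ConsensusResult:
    """Consensus matrix at one rank with its cophenetic coefficient.

    ``cophenetic`` is NaN when the consensus distances are all equal and
    the coefficient is undefined (degenerate dendrogram).
    """

    k: int
    consensus: pd.DataFrame  # samples x samples, entries in [0, 1]
    cophenetic: float
    n_runs: int
    seeds: list[int] = field(default_factory=list)


@dataclass
class RankSelectionResult:
    k_candidates: list[int]
    cophenetic_by_k: dict[int, float]
    chosen_k: int
    consensus_by_k: dict[int, ConsensusResult] = field(default_factory=dict)


def cophenetic_coefficient(consensus, linkage_method: str = "average") -> float:
    """Cophenetic correlation of the dendrogram built on ``1 - consensus``.

    Builds an average-linkage (configurable) hierarchy on the distance
    matrix ``1 - C`` and returns the Pearson correlation between the
    original and the dendrogram-implied (cophenetic) pairwise distances.
    """
    C = np.asarray(
        consensus.to_numpy() if isinstance(consensus, pd.DataFrame) else consensus,
        dtype=float,
    )
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValidationError("consensus must be a square matrix")
    n = C.shape[0]
    if n < 3:
        raise ValidationError("cophenetic correlation needs >= 3 samples")
    if not np.allclose(C, C.T, atol=1e-12):
        raise ValidationError("consensus matrix must be symmetric")
    if not np.allclose(np.diag(C), 1.0, atol=1e-12):
        raise ValidationError("consensus diagonal must be 1")
    if C.min() < -1e-12 or C.max() > 1 + 1e-12:
        raise ValidationError("consensus entries must lie in [0, 1]")
    D = 1.0 - np.clip(C, 0.0, 1.0)
    np.fill_diagonal(D, 0.0)
    dvec = squareform(D, checks=False)
    if np.ptp(dvec) < 1e-15:
        raise DegenerateDendrogramError(
            "all pairwise consensus distances are equal; "
            "the cophenetic correlation is undefined"
        )
    Z = linkage(dvec, method=linkage_method)
    coeff, _ = cophenet(Z, dvec)
    return float(coeff)


def consensus_matrix(
    X: MetaboliteMatrix,
    k: int,
    n_runs: int = 50,
    base_seed: int = 0,
    objective: str = "frobenius",
    max_iter: int = 2000,
    rel_tol: float = 1e-6,
    linkage_method: str = "average",
) -> ConsensusResult:
    """Mean co-clustering matrix over ``n_runs`` NMF restarts at rank ``k``.

    Run ``r`` uses seed ``base_seed + r``.  Each sample is assigned to its
    maximum-loading signature; two samples co-cluster when they share an
    assignment.
    """
    if n_runs < 1:
        raise ValidationError("n_runs must be >= 1")
    _, sample_ids = (X.values, X.sample_ids) if isinstance(X, MetaboliteMatrix) else (
        np.asarray(X), [f"S{j+1}" for j in range(np.asarray(X).shape[1])]
    )
    n = len(sample_ids)
    acc = np.zeros((n, n))
    seeds = [base_seed + r for r in range(n_runs)]
    for r, seed in enumerate(seeds):
        try:
            est = SignatureNMF(
                n_signatures=k,
                objective=objective,
                max_iter=max_iter,
                rel_tol=rel_tol,
                random_state=seed,
            ).fit(X)
        except Exception as exc:  # annotate with the failing run
            raise PipelineStageError(
                f"factorization failed in consensus run {r} (seed {seed}): {exc}"
            ) from exc
        assign = np.argmax(est.loadings_.to_numpy(), axis=0)
        acc += (assign[:, None] == assign[None, :]).astype(float)
    consensus = acc / n_runs
    np.fill_diagonal(consensus, 1.0)
    try:
        coeff = cophenetic_coefficient(consensus, linkage_method)
    except DegenerateDendrogramError:
        coeff = float("nan")
    return ConsensusResult(
        k=k,
        consensus=pd.DataFrame(consensus, index=sample_ids, columns=sample_ids),
        cophenetic=coeff,
        n_runs=n_runs,
        seeds=seeds,
    )


class ConsensusRankSelector(BaseEstimator):
    """Select the number of signatures by restart-consensus stability.

    Parameters mirror :func:`consensus_matrix`; ``k_candidates`` must all
    be >= 2 (the coefficient is degenerate at rank 1) and <= n_samples.

    Attributes
    ----------
    cophenetic_by_k_ : dict rank -> coefficient (NaN when degenerate)
    best_k_ : selected rank (max coefficient, smallest on ties)
    consensus_by_k_ : dict rank -> :class:`ConsensusResult`
    """

    def __init__(
        self,
        k_candidates=(2, 3, 4, 5, 6, 7),
        n_runs: int = 50,
        base_seed: int = 0,
        objective: str = "frobenius",
        max_iter: int = 2000,
        rel_tol: float = 1e-6,
        linkage_method: str = "average",
    ):
        self.k_candidates = k_candidates
        self.n_runs = n_runs
        self.base_seed = base_seed
        self.objective = objective
        self.max_iter = max_iter
        self.rel_tol = rel_tol
        self.linkage_method = linkage_method

    def fit(self, X, y=None) -> "ConsensusRankSelector":
        candidates = sorted(set(int(k) for k in self.k_candidates))
        if not candidates:
            raise ValidationError("k_candidates must be non-empty")
        n_samples = X.n_samples if isinstance(X, MetaboliteMatrix) else X.shape[1]
        for k in candidates:
            if k < 2:
                raise ValidationError("candidate ranks must be >= 2")
            if k > n_samples:
                raise ValidationError(
                    f"candidate rank {k} exceeds n_samples={n_samples}"
                )
        self.consensus_by_k_ = {}
        self.cophenetic_by_k_ = {}
        for k in candidates:
            res = consensus_matrix(
                X,
                k,
                n_runs=self.n_runs,
                base_seed=self.base_seed,
                objective=self.objective,
                max_iter=self.max_iter,
                rel_tol=self.rel_tol,
                linkage_method=self.linkage_method,
            )
            self.consensus_by_k_[k] = res
            self.cophenetic_by_k_[k] = res.cophenetic
        coeffs = np.array([self.cophenetic_by_k_[k] for k in candidates])
        if np.all(np.isnan(coeffs)):
            raise DegenerateDendrogramError(
                "cophenetic coefficient degenerate at every candidate rank"
            )
        best = np.nanmax(coeffs)
        # smallest rank attaining the maximum (exact-tie rule)
        self.best_k_ = next(
            k for k, c in zip(candidates, coeffs) if not np.isnan(c) and c == best
        )
        return self


def select_rank(
    X: MetaboliteMatrix,
    k_candidates,
    n_runs: int = 50,
    base_seed: int = 0,
    **kwargs,
) -> RankSelectionResult:
    """Functional wrapper around :class:`ConsensusRankSelector`."""
    sel = ConsensusRankSelector(
        k_candidates=k_candidates, n_runs=n_runs, base_seed=base_seed, **kwargs
    ).fit(X)
    return RankSelectionResult(
        k_candidates=sorted(set(int(k) for k in k_candidates)),
        cophenetic_by_k=dict(sel.cophenetic_by_k_),
        chosen_k=sel.best_k_,
        consensus_by_k=dict(sel.consensus_by_k_),
    )
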