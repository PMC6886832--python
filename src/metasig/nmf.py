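"""Multiplicative-update nonnegative matrix factorization.

Factorizes a metabolite x sample abundance matrix ``X`` as ``X ~ W H`` with
``W >= 0`` (metabolite weight profiles, one column per signature) and
``H >= 0`` (per-sample signature loadings), using the classical
multiplicative update rules for either the Frobenius or the generalized
Kullback-Leibler objective.  Both rules are monotone: the objective never
increases across iterations (up to tiny floating-point slack from the
epsilon guarding denominators).

After convergence the factors are normalized so every signature column of
``W`` sums to 1, with the scale moved into ``H`` (the product is
preserved exactly), and columns are put in a canonical order of descending
total loading so repeated runs are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .exceptions import DegenerateSignatureError, ValidationError
from .matrix import MetaboliteMatrix, SampleWeights, SignatureSet

__all__ = [
    "SignatureNMF",
    "FactorizationResult",
    "factorize",
    "normalize_signatures",
    "reconstruction_error",
]

_EPS = 1e-12  # guards denominators only; data are never perturbed
_CHECK_EVERY = 10  # convergence test cadence (iterations)


def _as_array(X) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(X, MetaboliteMatrix):
        return X.values, X.metabolite_ids, X.sample_ids
    A = np.asarray(X, dtype=float)
    if A.ndim != 2:
        raise ValidationError("X must be a two-dimensional matrix")
    if not np.all(np.isfinite(A)):
        raise ValidationError("X contains non-finite entries")
    if np.any(A < 0):
        i, j = np.argwhere(A < 0)[0]
        raise ValidationError(f"X contains a negative entry at ({i}, {j})")
    rows = [f"M{i + 1:04d}" for i in range(A.shape[0])]
    cols = [f"S{j + 1}" for j in range(A.shape[1])]
    return A, rows, cols


def _objective(X: np.ndarray, W: np.ndarray, H: np.ndarray, kind: str) -> float:
    WH = W @ H
    if kind == "frobenius":
        return 0.5 * float(np.sum((X - WH) ** 2))
    # generalized KL divergence, with the 0 log 0 = 0 convention
    pos = X > 0
    val = float(np.sum(X[pos] * np.log(X[pos] / (WH[pos] + _EPS))))
    return val - float(X.sum()) + float(WH.sum())


class SignatureNMF(BaseEstimator):
    """Signature extraction by multiplicative-update NMF.

    Follows the metabolomics/mutational-signature convention: the input is
    metabolites x samples, and ``fit`` learns both the signature profiles
    and the loadings of the fitted samples.  ``transform`` projects new
    samples onto the fitted signatures with ``W`` held fixed.

    Parameters
    ----------
    n_signatures : int, default 4
        Rank ``k`` of the factorization.
    objective : {"frobenius", "kl"}, default "frobenius"
        Divergence minimized by the multiplicative updates.
    max_iter : int, default 2000
    rel_tol : float, default 1e-6
        Stop when the relative objective decrease over a 10-iteration
        sweep falls below this value.
    random_state : int, default 0
        Seed for the strictly positive uniform initialization.

    Attributes
    ----------
    signatures_ : DataFrame (n_metabolites x k)
        Normalized signature profiles; every column sums to 1.
    loadings_ : DataFrame (k x n_samples)
        Nonnegative loadings on the abundance scale.
    objective_trace_ : ndarray
        Objective value at initialization and after every iteration.
    n_iter_ : int
    converged_ : bool
    """

    def __init__(
        self,
        n_signatures: int = 4,
        objective: str = "frobenius",
        max_iter: int = 2000,
        rel_tol: float = 1e-6,
        random_state: int = 0,
    ):
        self.n_signatures = n_signatures
        self.objective = objective
        self.max_iter = max_iter
        self.rel_tol = rel_tol
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _validate_params(self, n_m: int, n_s: int) -> None:
        if self.objective not in ("frobenius", "kl"):
            raise ValueError(f"unknown objective {self.objective!r}")
        if not (1 <= self.n_signatures <= min(n_m, n_s)):
            raise ValueError(
                f"n_signatures={self.n_signatures} outside [1, {min(n_m, n_s)}]"
            )
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not (self.rel_tol > 0):
            raise ValueError("rel_tol must be > 0")

    def _init_factors(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        rng = np.random.default_rng(self.random_state)
        k = self.n_signatures
        # strictly positive uniform entries, scaled so W H matches mean(X)
        scale = np.sqrt(max(X.mean(), _EPS) / k)
        W = (1.0 - rng.random((X.shape[0], k))) * scale
        H = (1.0 - rng.random((k, X.shape[1]))) * scale
        return W, H

    @staticmethod
    def _update_frobenius(X, W, H):
        H *= (W.T @ X) / (W.T @ W @ H + _EPS)
        W *= (X @ H.T) / (W @ (H @ H.T) + _EPS)
        return W, H

    @staticmethod
    def _update_kl(X, W, H):
        H *= (W.T @ (X / (W @ H + _EPS))) / (W.sum(axis=0)[:, None] + _EPS)
        W *= ((X / (W @ H + _EPS)) @ H.T) / (H.sum(axis=1)[None, :] + _EPS)
        return W, H

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y=None) -> "SignatureNMF":
        A, met_ids, sample_ids = _as_array(X)
        self._validate_params(*A.shape)
        W, H = self._init_factors(A)
        update = (
            self._update_frobenius
            if self.objective == "frobenius"
            else self._update_kl
        )
        trace = [_objective(A, W, H, self.objective)]
        converged = False
        last_checked = trace[0]
        n_iter = 0
        for it in range(1, self.max_iter + 1):
            W, H = update(A, W, H)
            trace.append(_objective(A, W, H, self.objective))
            n_iter = it
            if it % _CHECK_EVERY == 0:
                cur = trace[-1]
                denom = max(abs(last_checked), _EPS)
                if (last_checked - cur) / denom < self.rel_tol:
                    converged = True
                    break
                last_checked = cur

        # degenerate (all-zero) components can arise at over-large ranks on
        # tiny matrices; give them a vanishing uniform profile so
        # normalization stays defined while their loading stays ~0
        dead = W.sum(axis=0) <= 0
        if np.any(dead):
            W[:, dead] = _EPS

        sig, load = normalize_signatures(W, H)
        order = np.argsort(-load.sum(axis=1), kind="stable")
        W_n = sig[:, order]
        H_n = load[order, :]
        names = [f"P{i + 1}" for i in range(self.n_signatures)]

        self.signatures_ = pd.DataFrame(W_n, index=met_ids, columns=names)
        self.loadings_ = pd.DataFrame(H_n, index=names, columns=sample_ids)
        self.objective_trace_ = np.asarray(trace)
        self.n_iter_ = n_iter
        self.converged_ = converged
        return self

    def transform(self, X) -> pd.DataFrame:
        """Loadings of (possibly new) samples on the fitted signatures."""
        if not hasattr(self, "signatures_"):
            raise ValidationError("estimator is not fitted")
        A, _, sample_ids = _as_array(X)
        W = self.signatures_.to_numpy()
        if A.shape[0] != W.shape[0]:
            raise ValidationError(
                f"X has {A.shape[0]} metabolites, fitted model has {W.shape[0]}"
            )
        rng = np.random.default_rng(self.random_state)
        H = (1.0 - rng.random((W.shape[1], A.shape[1]))) * np.sqrt(
            max(A.mean(), _EPS) / W.shape[1]
        )
        for _ in range(self.max_iter):
            H_new = H * (W.T @ A) / (W.T @ W @ H + _EPS)
            if np.max(np.abs(H_new - H)) <= self.rel_tol * (np.max(H) + _EPS):
                H = H_new
                break
            H = H_new
        return pd.DataFrame(H, index=self.signatures_.columns, columns=sample_ids)

    def fit_transform(self, X, y=None) -> pd.DataFrame:
        return self.fit(X).loadings_

    def reconstruct(self) -> np.ndarray:
        return self.signatures_.to_numpy() @ self.loadings_.to_numpy()


@dataclass
class FactorizationResult:
    """One NMF fit: normalized factors plus convergence diagnostics."""

    signatures: SignatureSet
    loadings: SampleWeights
    objective_trace: np.ndarray
    n_iter: int
    converged: bool
    seed: int
    objective_kind: str


def factorize(
    X,
    k: int,
    objective: str = "frobenius",
    seed: int = 0,
    max_iter: int = 2000,
    rel_tol: float = 1e-6,
) -> FactorizationResult:
    """Functional wrapper around :class:`SignatureNMF`."""
    est = SignatureNMF(
        n_signatures=k,
        objective=objective,
        max_iter=max_iter,
        rel_tol=rel_tol,
        random_state=seed,
    ).fit(X)
    return FactorizationResult(
        signatures=SignatureSet(weights=est.signatures_),
        loadings=SampleWeights(loadings=est.loadings_),
        objective_trace=est.objective_trace_,
        n_iter=est.n_iter_,
        converged=est.converged_,
        seed=seed,
        objective_kind=objective,
    )


def normalize_signatures(W, H) -> tuple[np.ndarray, np.ndarray]:
    """Rescale so each signature column of W sums to 1; W H is unchanged.

    Accepts and returns plain arrays: ``W`` (metabolites x k) and ``H``
    (k x samples).  A zero column is a degenerate signature and raises.
    """
    W = np.asarray(W, dtype=float)
    H = np.asarray(H, dtype=float)
    if W.ndim != 2 or H.ndim != 2 or W.shape[1] != H.shape[0]:
        raise ValidationError("W and H must be 2-d with matching inner dimension")
    if np.any(W < 0) or np.any(H < 0):
        raise ValidationError("factors must be nonnegative")
    sums = W.sum(axis=0)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        raise DegenerateSignatureError(
            f"signature column(s) {zero.tolist()} sum to zero"
        )
    return W / sums, H * sums[:, None]


def reconstruction_error(X, result, kind: str = "frobenius_rel") -> float:
    """Reconstruction error of a factorization against the data.

    ``frobenius_rel`` is ``||X - WH||_F / ||X||_F``; ``kl`` is the
    generalized KL divergence.  Zero iff the product equals ``X`` exactly.
    """
    A, _, _ = _as_array(X)
    if isinstance(result, FactorizationResult):
        W = result.signatures.weights.to_numpy()
        H = result.loadings.loadings.to_numpy()
    else:  # (W, H) pair
        W, H = (np.asarray(m, dtype=float) for m in result)
    if W.shape[0] != A.shape[0] or H.shape[1] != A.shape[1]:
        raise ValidationError(
            f"factor shapes {W.shape} x {H.shape} do not match data {A.shape}"
        )
    if kind == "frobenius_rel":
        denom = np.linalg.norm(A)
        if denom == 0:
            return 0.0 if np.allclose(W @ H, 0) else float("inf")
        return float(np.linalg.norm(A - W @ H) / denom)
    if kind == "kl":
        return _objective(A, W, H, "kl")
    raise ValueError(f"unknown error kind {kind!r}")
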