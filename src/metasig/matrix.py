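"""Core data containers.

The central object is :class:`MetaboliteMatrix`: a nonnegative abundance
table with metabolites as rows and samples as columns (relative units, as
produced by LC-MS/MS peak integration after upstream normalization).  The
two NMF factors are carried by :class:`SignatureSet` (per-signature
metabolite weight profiles, each column summing to 1) and
:class:`SampleWeights` (per-sample signature loadings on the abundance
scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = ["MetaboliteMatrix", "SignatureSet", "SampleWeights"]


def _check_unique(ids, what: str) -> list[str]:
    ids = [str(i) for i in ids]
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)
    return ids


@dataclass
class MetaboliteMatrix:
    """Nonnegative metabolite x sample abundance matrix.

    Parameters
    ----------
    values : ndarray of shape (n_metabolites, n_samples)
        Nonnegative, finite abundances.
    metabolite_ids, sample_ids : sequences of unique names.
    group_labels : optional mapping sample id -> group label.
    """

    values: np.ndarray
    metabolite_ids: list[str]
    sample_ids: list[str]
    group_labels: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("matrix values must be two-dimensional")
        self.metabolite_ids = _check_unique(self.metabolite_ids, "metabolite")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        n_m, n_s = self.values.shape
        if len(self.metabolite_ids) != n_m:
            raise ValidationError(
                f"{len(self.metabolite_ids)} metabolite ids for {n_m} rows"
            )
        if len(self.sample_ids) != n_s:
            raise ValidationError(f"{len(self.sample_ids)} sample ids for {n_s} columns")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite abundance at metabolite {self.metabolite_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative abundance at metabolite {self.metabolite_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        if self.group_labels is not None:
            unknown = set(self.group_labels) - set(self.sample_ids)
            if unknown:
                raise ValidationError(
                    f"group labels for unknown samples: {sorted(unknown)}"
                )

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def groups(self) -> pd.Series:
        """Per-sample group labels as a Series indexed by sample id."""
        if self.group_labels is None:
            raise ValidationError("matrix carries no group labels")
        missing = [s for s in self.sample_ids if s not in self.group_labels]
        if missing:
            raise ValidationError(f"samples without a group label: {missing}")
        return pd.Series(
            [self.group_labels[s] for s in self.sample_ids],
            index=self.sample_ids,
            name="group",
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.metabolite_ids, columns=self.sample_ids
        )

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, group_labels: dict[str, str] | None = None
    ) -> "MetaboliteMatrix":
        return cls(
            values=frame.to_numpy(dtype=float),
            metabolite_ids=list(frame.index),
            sample_ids=list(frame.columns),
            group_labels=group_labels,
        )


@dataclass
class SignatureSet:
    """Per-signature metabolite weight profiles; each column sums to 1."""

    weights: pd.DataFrame  # n_metabolites x k, columns are signature names

    def __post_init__(self) -> None:
        w = self.weights.to_numpy(dtype=float)
        if np.any(w < 0) or not np.all(np.isfinite(w)):
            raise ValidationError("signature weights must be nonnegative and finite")
        sums = w.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            bad = self.weights.columns[np.argmax(np.abs(sums - 1.0))]
            raise ValidationError(
                f"signature column {bad!r} does not sum to 1 (got {sums.max():.6g})"
            )

    @property
    def signature_names(self) -> list[str]:
        return list(self.weights.columns)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.weights.index)


@dataclass
class SampleWeights:
    """Per-sample signature loadings (abundance-scale units)."""

    loadings: pd.DataFrame  # k x n_samples, index = signature names

    def __post_init__(self) -> None:
        h = self.loadings.to_numpy(dtype=float)
        if np.any(h < 0) or not np.all(np.isfinite(h)):
            raise ValidationError("loadings must be nonnegative and finite")

    @property
    def signature_names(self) -> list[str]:
        return list(self.loadings.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.loadings.columns)
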