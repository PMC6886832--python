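"""Synthetic study generator.

Emulates a two-group cardiac metabolomics design: a nonnegative abundance
matrix built from a small number of planted signatures (sparse nonnegative
metabolite profiles, columns summing to 1) mixed by per-sample loadings in
which each group's samples are dominated by one group-specific signature,
with the remaining loading mass spread over shared background signatures.
Measurement error is multiplicative log-normal (median 1) with a configured
coefficient of variation, matching the roughly proportional error of
relative-abundance LC-MS/MS data.  Per-metabolite group fold changes can be
planted on top of the factor structure; the planted ratio is made
identifiable by folding the row's baseline group imbalance into the
group-A multiplier (see ``docs/methods.md``).

The defaults reproduce the reference study design: 280 metabolites across
12 samples in two groups of 6, four signatures of which one per group is
dominant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError
from .matrix import MetaboliteMatrix

__all__ = ["StudyConfig", "StudyTruth", "PathwayLibrary", "generate_study",
           "generate_pathway_library"]

# Fraction of each signature's weight mass carried by its sparse support;
# the remainder is a dense low-level baseline so every metabolite is
# present in every sample, as in a matrix restricted to ubiquitously
# detected metabolites.
_SUPPORT_MASS = 0.95
# Dirichlet concentration for weights: moderately flat, so the support is
# a recoverable set of comparably weighted metabolites.
_DIRICHLET_ALPHA = 5.0
# Mean total loading per sample (arbitrary relative-abundance units).
_BASE_ABUNDANCE = 100.0
# Dirichlet concentration for the split of each sample's non-dominant
# loading mass over the remaining signatures: 2.0 gives individual
# variation in secondary signature usage of roughly 25-30% CV, in line
# with between-animal variability of tissue metabolite levels.
_BACKGROUND_ALPHA = 2.0


@dataclass
class StudyConfig:
    """Parameters of the synthetic two-group study.

    Attributes
    ----------
    n_metabolites : number of metabolite rows (default 280).
    n_per_group : samples per group as ``{"A": 6, "B": 6}``.
    n_signatures : number of planted signatures (default 4).
    group_signature_map : dominant signature index per group; by default
        group A is dominated by the last signature and group B by the
        second, leaving the rest as shared background.
    dominance : fraction in (0.5, 1] of each sample's total loading carried
        by its group's dominant signature (lower bound; the realized share
        is drawn in ``[dominance, dominance + (1 - dominance)/2]``).
    signature_sparsity : fraction of metabolites in each signature's
        strongly weighted support.
    noise_cv : coefficient of variation of the multiplicative log-normal
        measurement noise (0 disables noise).
    sample_scale_cv : optional per-sample total-abundance scale jitter
        (log-normal CV; 0 disables), for testing per-sample normalization
        regimes.
    planted_fold_changes : sequence of ``(metabolite_index, ratio)`` pairs;
        the ratio is the group-A over group-B mean of that metabolite.
    seed : integer random seed.
    """

    n_metabolites: int = 280
    n_per_group: dict[str, int] = field(default_factory=lambda: {"A": 6, "B": 6})
    n_signatures: int = 4
    group_signature_map: dict[str, int] | None = None
    dominance: float = 0.6
    signature_sparsity: float = 0.15
    noise_cv: float = 0.2
    sample_scale_cv: float = 0.0
    planted_fold_changes: tuple[tuple[int, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_metabolites < 1:
            raise ConfigurationError("n_metabolites must be >= 1")
        if self.n_signatures < 1:
            raise ConfigurationError("n_signatures must be >= 1")
        if not self.n_per_group or any(n < 1 for n in self.n_per_group.values()):
            raise ConfigurationError("n_per_group counts must all be >= 1")
        if not (0.5 < self.dominance <= 1.0):
            raise ConfigurationError("dominance must lie in (0.5, 1]")
        if not (0.0 < self.signature_sparsity <= 1.0):
            raise ConfigurationError("signature_sparsity must lie in (0, 1]")
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be >= 0")
        if self.sample_scale_cv < 0:
            raise ConfigurationError("sample_scale_cv must be >= 0")
        if self.group_signature_map is None:
            groups = sorted(self.n_per_group)
            if len(groups) > self.n_signatures:
                raise ConfigurationError(
                    "group_signature_map: more groups than signatures"
                )
            # one distinct dominant signature per group; the first group takes
            # the last signature and the second skips one when possible
            # (a P4/P2-style pairing), the rest fill in descending
            pool = set(range(self.n_signatures))
            picks = {}
            for i, g in enumerate(groups):
                prefer = self.n_signatures - 1 - 2 * i
                picks[g] = prefer if prefer in pool else max(pool)
                pool.discard(picks[g])
            self.group_signature_map = picks
        bad = {
            g: s
            for g, s in self.group_signature_map.items()
            if not (0 <= s < self.n_signatures)
        }
        if bad:
            raise ConfigurationError(
                f"group_signature_map indexes out of range: {bad}"
            )
        if set(self.group_signature_map) != set(self.n_per_group):
            raise ConfigurationError(
                "group_signature_map groups must match n_per_group groups"
            )
        self.planted_fold_changes = tuple(
            (int(m), float(r)) for m, r in self.planted_fold_changes
        )
        for m, r in self.planted_fold_changes:
            if not (0 <= m < self.n_metabolites):
                raise ConfigurationError(
                    f"planted_fold_changes: metabolite index {m} out of range"
                )
            if not (r > 0 and math.isfinite(r)):
                raise ConfigurationError(
                    f"planted_fold_changes: ratio must be finite and > 0, got {r}"
                )

    @property
    def n_samples(self) -> int:
        return sum(self.n_per_group.values())


@dataclass
class StudyTruth:
    """Ground truth behind a generated study.

    ``true_signatures`` is metabolites x signatures with unit column sums;
    ``true_loadings`` is signatures x samples; ``signature_support`` maps
    each signature name to its planted strongly weighted metabolite set.
    """

    true_signatures: "pd.DataFrame"
    true_loadings: "pd.DataFrame"
    group_labels: dict[str, str]
    planted_fold_changes: tuple[tuple[int, float], ...]
    signature_support: dict[str, set[str]]
    seed: int


@dataclass
class PathwayLibrary:
    """Named metabolite sets over a universe of metabolite names."""

    pathways: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        if not self.pathways:
            raise ConfigurationError("pathway library must contain >= 1 pathway")
        for name, members in self.pathways.items():
            if not members:
                raise ConfigurationError(f"pathway {name!r} is empty")
            stray = members - self.universe
            if stray:
                raise ConfigurationError(
                    f"pathway {name!r} has members outside the universe: "
                    f"{sorted(stray)[:5]}"
                )


def _lognormal_factors(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Multiplicative log-normal factors with median 1 and the given CV."""
    if cv == 0:
        return np.ones(shape)
    sigma = math.sqrt(math.log1p(cv * cv))
    return np.exp(rng.normal(0.0, sigma, size=shape))


def generate_study(config: StudyConfig) -> tuple[MetaboliteMatrix, StudyTruth]:
    """Generate one synthetic study.

    Returns the abundance matrix (metabolites x samples, group labels
    attached) and the ground truth used to build it.  Identical config and
    seed reproduce the matrix bit for bit.
    """
    import pandas as pd

    rng = np.random.default_rng(config.seed)
    n_m, k = config.n_metabolites, config.n_signatures
    sig_names = [f"P{i + 1}" for i in range(k)]
    met_ids = [f"M{i + 1:04d}" for i in range(n_m)]

    # --- signatures: sparse support carrying most mass + dense baseline ---
    support_size = max(1, round(config.signature_sparsity * n_m))
    W = np.empty((n_m, k))
    support: dict[str, set[str]] = {}
    for s in range(k):
        idx = rng.choice(n_m, size=support_size, replace=False)
        support[sig_names[s]] = {met_ids[i] for i in idx}
        col = rng.gamma(_DIRICHLET_ALPHA, size=n_m)
        col /= col.sum()
        col *= (1.0 - _SUPPORT_MASS) if support_size < n_m else 0.0
        top = rng.gamma(_DIRICHLET_ALPHA, size=support_size)
        top /= top.sum()
        if support_size < n_m:
            col[idx] += _SUPPORT_MASS * top
        else:
            col = top
        W[:, s] = col / col.sum()

    # --- loadings: group-dominant signature + shared background ---
    sample_ids: list[str] = []
    group_labels: dict[str, str] = {}
    cols = []
    for g in sorted(config.n_per_group):
        dom = config.group_signature_map[g]
        for j in range(config.n_per_group[g]):
            sid = f"{g}{j + 1}"
            sample_ids.append(sid)
            group_labels[sid] = g
            share = rng.uniform(
                config.dominance, config.dominance + 0.5 * (1.0 - config.dominance)
            )
            h = np.zeros(k)
            if k > 1:
                rest = rng.dirichlet(_BACKGROUND_ALPHA * np.ones(k - 1)) * (1.0 - share)
                h[[i for i in range(k) if i != dom]] = rest
            h[dom] = share if k > 1 else 1.0
            total = _BASE_ABUNDANCE * _lognormal_factors(
                rng, config.sample_scale_cv, ()
            )
            cols.append(h * total)
    H = np.column_stack(cols)

    baseline = W @ H

    # --- planted fold changes: equalize the row's baseline group means,
    # then multiply group A so the planted ratio is the noiseless ratio ---
    group_arr = np.array([group_labels[s] for s in sample_ids])
    groups_sorted = sorted(config.n_per_group)
    if config.planted_fold_changes:
        a_mask = group_arr == groups_sorted[0]
        b_mask = ~a_mask
        for m, ratio in config.planted_fold_changes:
            m_a = baseline[m, a_mask].mean()
            m_b = baseline[m, b_mask].mean()
            if m_a <= 0 or m_b <= 0:
                raise ConfigurationError(
                    f"planted_fold_changes: metabolite index {m} has a zero "
                    "baseline group mean"
                )
            baseline[m, a_mask] *= (m_b / m_a) * ratio

    noise = _lognormal_factors(rng, config.noise_cv, baseline.shape)
    values = baseline * noise

    matrix = MetaboliteMatrix(
        values=values,
        metabolite_ids=met_ids,
        sample_ids=sample_ids,
        group_labels=group_labels,
    )
    truth = StudyTruth(
        true_signatures=pd.DataFrame(W, index=met_ids, columns=sig_names),
        true_loadings=pd.DataFrame(H, index=sig_names, columns=sample_ids),
        group_labels=group_labels,
        planted_fold_changes=config.planted_fold_changes,
        signature_support=support,
        seed=config.seed,
    )
    return matrix, truth


def generate_pathway_library(
    n_pathways: int,
    size_range: tuple[int, int],
    truth: StudyTruth,
    planted: list[tuple[int, int]] | None = None,
    seed: int = 0,
) -> PathwayLibrary:
    """Generate a pathway library over the study's metabolites.

    ``planted`` pairs ``(pathway_index, signature_index)`` mark pathways
    that draw at least 80% of their members from the top-weighted
    metabolites of the paired signature; all other pathways draw members
    uniformly from the universe.
    """
    planted = list(planted or [])
    met_ids = list(truth.true_signatures.index)
    n_m = len(met_ids)
    lo, hi = size_range
    if not (1 <= lo <= hi <= n_m):
        raise ConfigurationError(
            f"size_range {size_range} must satisfy 1 <= min <= max <= {n_m}"
        )
    if n_pathways < 1:
        raise ConfigurationError("n_pathways must be >= 1")
    k = truth.true_signatures.shape[1]
    for p_idx, s_idx in planted:
        if not (0 <= p_idx < n_pathways):
            raise ConfigurationError(f"planted pathway index {p_idx} out of range")
        if not (0 <= s_idx < k):
            raise ConfigurationError(f"planted signature index {s_idx} out of range")

    rng = np.random.default_rng(seed)
    planted_map = dict(planted)
    pathways: dict[str, set[str]] = {}
    for p in range(n_pathways):
        size = int(rng.integers(lo, hi + 1))
        name = f"PW{p + 1:03d}"
        if p in planted_map:
            sig = truth.true_signatures.iloc[:, planted_map[p]]
            pool = list(sig.sort_values(ascending=False).index[: max(size, 1)])
            n_top = min(size, max(1, math.ceil(0.8 * size)), len(pool))
            members = set(rng.choice(pool, size=n_top, replace=False))
            rest = [m for m in met_ids if m not in members]
            if size > n_top:
                members |= set(rng.choice(rest, size=size - n_top, replace=False))
        else:
            members = set(rng.choice(met_ids, size=size, replace=False))
        pathways[name] = members
    return PathwayLibrary(pathways=pathways, universe=set(met_ids))
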