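"""Consensus matrices and cophenetic rank selection."""

import numpy as np
import pytest

from metasig import (
    StudyConfig,
    consensus_matrix,
    cophenetic_coefficient,
    generate_study,
    select_rank,
)
from metasig.exceptions import DegenerateDendrogramError, ValidationError


def cophenetic_oracle(C):
    """Independent average-linkage + cophenetic computation.

    Naive O(n^3) agglomeration over an explicit distance dictionary;
    cophenetic distance of a pair is the height of the merge that first
    united them.
    """
    n = C.shape[0]
    D = 1.0 - C
    clusters = {i: [i] for i in range(n)}
    coph = np.zeros((n, n))
    next_id = n
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for ai, a in enumerate(keys):
            for b in keys[ai + 1:]:
                d = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = d
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    iu = np.triu_indices(n, 1)
    return np.corrcoef(D[iu], coph[iu])[0, 1]


class TestCopheneticCoefficient:
    def test_perfect_two_block_consensus_is_ultrametric(self):
        C = np.eye(6)
        C[:3, :3] = 1.0
        C[3:, 3:] = 1.0
        assert cophenetic_coefficient(C) == pytest.approx(1.0, abs=1e-12)

    def test_matches_hand_oracle_on_four_samples(self):
        C = np.array(
            [
                [1.0, 0.9, 0.1, 0.2],
                [0.9, 1.0, 0.15, 0.1],
                [0.1, 0.15, 1.0, 0.8],
                [0.2, 0.1, 0.8, 1.0],
            ]
        )
        assert cophenetic_coefficient(C) == pytest.approx(
            cophenetic_oracle(C), abs=1e-12
        )

    def test_matches_hand_oracle_on_random_consensus(self, rng):
        for _ in range(5):
            R = rng.random((6, 6))
            C = (R + R.T) / 2
            np.fill_diagonal(C, 1.0)
            assert cophenetic_coefficient(C) == pytest.approx(
                cophenetic_oracle(C), abs=1e-10
            )

    def test_equal_offdiagonals_degenerate(self):
        C = np.full((4, 4), 0.3)
        np.fill_diagonal(C, 1.0)
        with pytest.raises(DegenerateDendrogramError):
            cophenetic_coefficient(C)

    def test_affine_rescaling_invariance(self):
        C = np.array(
            [
                [1.0, 0.9, 0.1, 0.2],
                [0.9, 1.0, 0.15, 0.1],
                [0.1, 0.15, 1.0, 0.8],
                [0.2, 0.1, 0.8, 1.0],
            ]
        )
        # shrinking all distances by a common positive factor about their
        # mean leaves the correlation unchanged
        base = cophenetic_coefficient(C)
        scaled = 1.0 - 0.5 * (1.0 - C)  # distances halved
        assert cophenetic_coefficient(scaled) == pytest.approx(base, abs=1e-12)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            cophenetic_coefficient(np.eye(2))


class TestConsensusMatrix:
    def test_single_run_is_binary(self, small_study):
        _, X, _ = small_study
        res = consensus_matrix(X, k=2, n_runs=1, base_seed=0)
        vals = res.consensus.to_numpy()
        assert set(np.unique(vals)) <= {0.0, 1.0}

    def test_diagonal_one_and_symmetric(self, small_study):
        _, X, _ = small_study
        res = consensus_matrix(X, k=3, n_runs=5, base_seed=1)
        C = res.consensus.to_numpy()
        np.testing.assert_array_equal(np.diag(C), 1.0)
        np.testing.assert_allclose(C, C.T)
        assert C.min() >= 0 and C.max() <= 1

    def test_two_separated_groups_give_block_consensus(self):
        config = StudyConfig(
            n_metabolites=80, n_per_group={"A": 5, "B": 5}, n_signatures=2,
            noise_cv=0.05, seed=3,
        )
        X, _ = generate_study(config)
        res = consensus_matrix(X, k=2, n_runs=30, base_seed=0)
        C = res.consensus.to_numpy()
        groups = X.groups().to_numpy()
        same = groups[:, None] == groups[None, :]
        off_diag = ~np.eye(len(groups), dtype=bool)
        assert C[same & off_diag].min() >= 0.9
        assert C[~same].max() <= 0.1

    def test_consensus_invariant_to_sample_permutation(self, small_study):
        from metasig import MetaboliteMatrix

        _, X, _ = small_study
        perm = np.random.default_rng(0).permutation(X.n_samples)
        Xp = MetaboliteMatrix(
            X.values[:, perm],
            X.metabolite_ids,
            [X.sample_ids[j] for j in perm],
        )
        res = consensus_matrix(X, k=2, n_runs=10, base_seed=4)
        resp = consensus_matrix(Xp, k=2, n_runs=10, base_seed=4)
        C = res.consensus.to_numpy()
        Cp = resp.consensus.to_numpy()
        np.testing.assert_allclose(Cp, C[np.ix_(perm, perm)], atol=0.35)
        # the dominant block structure is permutation-equivariant even when
        # individual restarts differ; exact equality holds per run seed only
        # for identical input column order, so compare co-clustering rates
        assert abs(Cp.mean() - C.mean()) < 0.2


class TestSelectRank:
    def test_true_rank_consensus_is_stable_and_overfit_ranks_are_not(self):
        """At the planted rank the restart consensus is exactly binary
        (perfectly stable three-block structure); past it, stability decays.

        Note the selection rule itself still returns the smallest rank: any
        stable binary partition -- including the two-block one that every
        under-rank factorization of a group-dominant design produces -- has
        a perfectly ultrametric 1-C distance and a cophenetic coefficient
        of exactly 1, so the smallest-tie maximum saturates at the lowest
        candidate on clean group-structured data.
        """
        config = StudyConfig(
            n_metabolites=150,
            n_per_group={"A": 4, "B": 4, "C": 4},
            n_signatures=3,
            noise_cv=0.05,
            seed=2,
        )
        X, _ = generate_study(config)
        res = select_rank(X, range(2, 7), n_runs=20, base_seed=0)
        C3 = res.consensus_by_k[3].consensus.to_numpy()
        groups = X.groups().to_numpy()
        same = groups[:, None] == groups[None, :]
        assert C3[same].min() >= 0.9
        assert C3[~same].max() <= 0.1
        assert res.cophenetic_by_k[3] == pytest.approx(1.0, abs=1e-9)
        assert res.cophenetic_by_k[3] >= res.cophenetic_by_k[5]

    def test_tie_broken_toward_smaller_rank(self, monkeypatch):
        import metasig.consensus as cons

        def fake_consensus(X, k, **kwargs):
            C = np.eye(4)
            C[:2, :2] = 1.0
            C[2:, 2:] = 1.0
            import pandas as pd

            ids = [f"S{j}" for j in range(4)]
            return cons.ConsensusResult(
                k=k,
                consensus=pd.DataFrame(C, index=ids, columns=ids),
                cophenetic=0.8,
                n_runs=1,
                seeds=[0],
            )

        monkeypatch.setattr(cons, "consensus_matrix", fake_consensus)
        X = np.abs(np.random.default_rng(0).normal(size=(10, 4))) + 0.1
        from metasig.matrix import MetaboliteMatrix

        Xm = MetaboliteMatrix(X, [f"M{i}" for i in range(10)], [f"S{j}" for j in range(4)])
        res = cons.select_rank(Xm, [2, 3, 4], n_runs=1)
        assert res.chosen_k == 2

    def test_empty_candidates_rejected(self, small_study):
        _, X, _ = small_study
        with pytest.raises(ValidationError):
            select_rank(X, [], n_runs=1)

    def test_rank_one_candidate_rejected(self, small_study):
        _, X, _ = small_study
        with pytest.raises(ValidationError):
            select_rank(X, [1, 2], n_runs=1)

    def test_stability_at_true_rank_dominates_overfit_ranks(self):
        """Cophenetic at k_true >= cophenetic at k_true + 2 (majority over
        replicate studies)."""
        wins = 0
        n_rep = 6
        for seed in range(n_rep):
            config = StudyConfig(
                n_metabolites=100,
                n_per_group={"A": 4, "B": 4, "C": 4},
                n_signatures=3,
                noise_cv=0.05,
                seed=100 + seed,
            )
            X, _ = generate_study(config)
            res = select_rank(X, [3, 5], n_runs=15, base_seed=0)
            if res.cophenetic_by_k[3] >= res.cophenetic_by_k[5]:
                wins += 1
        assert wins > n_rep / 2
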