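import numpy as np
import pandas as pd
import pytest

import pathpair as pp
from pathpair.subtype import metrics_frame


class TestExpTransform:
    def test_indicator_values_map_to_exp(self):
        out = pp.exp_transform(np.array([[-1.0, 1.0], [0.0, 2.0]]))
        np.testing.assert_allclose(
            out, [[np.exp(-1), np.e], [1.0, np.exp(2)]]
        )

    def test_strictly_positive_and_order_preserving(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        y = pp.exp_transform(x)
        assert (y > 0).all()
        assert (np.argsort(x) == np.argsort(y)).all()

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            pp.exp_transform([np.inf, 1.0])


def _planted(k=2, per=8, m=20, seed=0):
    """Nonnegative matrix with k well-separated column blocks."""
    rng = np.random.default_rng(seed)
    blocks = []
    for i in range(k):
        centre = np.zeros(m)
        centre[i * (m // k) : (i + 1) * (m // k)] = 5.0
        blocks.append(centre[:, None] + rng.uniform(0, 0.3, size=(m, per)))
    return np.hstack(blocks) + 0.1, np.repeat(np.arange(k), per)


class TestNmfFactorize:
    def test_factorizable_input_reaches_near_zero_divergence(self):
        rng = np.random.default_rng(1)
        V = rng.uniform(0.5, 2.0, size=(20, 2)) @ rng.uniform(0.5, 2.0, size=(2, 15))
        run = pp.nmf_factorize(V, k=2, seed=0, max_iter=5000, tol=0.0)
        assert run.trace[-1] <= 1e-6 * run.trace[0]

    def test_deterministic_under_seed(self):
        V, _ = _planted(seed=2)
        a = pp.nmf_factorize(V, 2, seed=5)
        b = pp.nmf_factorize(V, 2, seed=5)
        np.testing.assert_array_equal(a.W, b.W)
        np.testing.assert_array_equal(a.H, b.H)

    def test_objective_trace_never_increases(self):
        rng = np.random.default_rng(3)
        V = rng.uniform(0.1, 3.0, size=(15, 12))
        run = pp.nmf_factorize(V, 3, seed=1, max_iter=300, tol=0.0)
        assert (np.diff(run.trace) <= 1e-9 * np.abs(run.trace[:-1])).all()

    def test_objective_matches_sklearn_definition(self):
        # independent formulation of generalized KL divergence
        from sklearn.decomposition._nmf import _beta_divergence

        from pathpair.subtype import _kl_divergence

        rng = np.random.default_rng(4)
        V = rng.uniform(0.1, 2.0, size=(8, 6))
        W = rng.uniform(0.1, 1.0, size=(8, 3))
        H = rng.uniform(0.1, 1.0, size=(3, 6))
        assert _kl_divergence(V, W @ H) == pytest.approx(
            _beta_divergence(V, W, H, "kullback-leibler"), rel=1e-10
        )

    def test_negative_input_rejected_with_exp_hint(self):
        with pytest.raises(ValueError, match="exp_transform"):
            pp.nmf_factorize(np.array([[1.0, -0.5], [0.2, 0.3], [1.0, 2.0]]), 2)

    def test_invalid_rank_rejected(self):
        V = np.ones((4, 4)) + np.eye(4)
        with pytest.raises(ValueError, match="rank"):
            pp.nmf_factorize(V, 4)


class TestConsensus:
    def test_separated_blocks_give_binary_consensus(self):
        V, labels = _planted(seed=5)
        results = pp.consensus_cluster(V, k_range=[2], nrun=4, seed=0)
        consensus = results[2].consensus.to_numpy()
        assert set(np.unique(consensus)) <= {0.0, 1.0}
        assert results[2].dispersion == pytest.approx(1.0)
        # assignments match the planted blocks (up to label naming)
        got = results[2].assignments.to_numpy()
        assert len({tuple(got[labels == i]) for i in range(2)}) == 2

    def test_block_diagonal_consensus_has_cophenetic_one(self):
        consensus = np.kron(np.eye(2), np.ones((2, 2)))
        coph, dispersion, sil, labels = pp.summarize_consensus(consensus, 2)
        assert coph == pytest.approx(1.0, abs=1e-9)
        assert dispersion == pytest.approx(1.0)
        assert sorted(np.bincount(labels)[1:]) == [2, 2]

    def test_permutation_equivariance_on_separated_data(self):
        V, _ = _planted(seed=6)
        base = pp.consensus_cluster(V, k_range=[2], nrun=3, seed=1)[2]
        rng = np.random.default_rng(0)
        perm = rng.permutation(V.shape[1])
        permuted = pp.consensus_cluster(V[:, perm], k_range=[2], nrun=3, seed=1)[2]
        np.testing.assert_allclose(
            permuted.consensus.to_numpy(), base.consensus.to_numpy()[np.ix_(perm, perm)]
        )

    def test_nrun_must_be_at_least_two(self):
        with pytest.raises(ValueError, match="nrun"):
            pp.consensus_cluster(np.ones((5, 5)), k_range=[2], nrun=1)


class TestSelectRank:
    @staticmethod
    def _result(k, coph, disp=0.5, sil=0.5):
        n = 4
        return pp.ConsensusResult(
            k=k,
            consensus=pd.DataFrame(np.eye(n)),
            assignments=pd.Series(np.arange(n) % k + 1),
            cophenetic=coph,
            dispersion=disp,
            silhouette=sil,
        )

    def test_maximum_cophenetic_wins(self):
        results = {
            2: self._result(2, 0.99),
            3: self._result(3, 0.90),
            4: self._result(4, 0.85),
        }
        assert pp.select_rank(results) == 2

    def test_all_equal_returns_smallest_k(self):
        results = {k: self._result(k, 0.9) for k in (2, 3, 4)}
        assert pp.select_rank(results) == 2

    def test_cophenetic_tie_broken_by_dispersion(self):
        results = {
            2: self._result(2, 0.9, disp=0.4),
            3: self._result(3, 0.9, disp=0.8),
        }
        assert pp.select_rank(results) == 3

    def test_metrics_frame_lists_all_ranks(self):
        results = {k: self._result(k, 0.9) for k in (2, 3)}
        frame = metrics_frame(results)
        assert frame.index.tolist() == [2, 3]
        assert set(frame.columns) == {"cophenetic", "dispersion", "silhouette"}
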