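import numpy as np
import pandas as pd
import pytest

import pathpair as pp
from oracles import chi2_bruteforce, holm_bruteforce


def _activity(scores, ids=None):
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    ids = ids or [f"P{i + 1}" for i in range(scores.shape[0])]
    return pp.PathwayActivityMatrix(
        scores=pd.DataFrame(
            scores, index=ids, columns=[f"s{j + 1}" for j in range(scores.shape[1])]
        ),
        alpha=0.25,
        normalized=False,
    )


class TestBuildMpp:
    def test_deltas_and_tie_indicator(self):
        mpp = pp.build_mpp(_activity([[0.2], [0.5], [0.5]]))
        assert mpp.pair_index.tolist() == ["P1-P2", "P1-P3", "P2-P3"]
        np.testing.assert_allclose(mpp.delta["s1"], [-0.3, -0.3, 0.0])
        # ties take +1 by the I(x >= 0) convention
        assert mpp.indicator["s1"].tolist() == [-1, -1, 1]

    @pytest.mark.parametrize("m, expected", [(2, 1), (5, 10), (84, 3486)])
    def test_pair_count_is_m_choose_2(self, m, expected):
        rng = np.random.default_rng(m)
        mpp = pp.build_mpp(_activity(rng.normal(size=(m, 3))))
        assert len(mpp.pair_index) == expected

    def test_single_pathway_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            pp.build_mpp(_activity([[1.0, 2.0]]))

    def test_antisymmetry_under_pathway_swap(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=(4, 6))
        fwd = pp.build_mpp(_activity(scores, ids=["A", "B", "C", "D"]))
        rev = pp.build_mpp(_activity(scores[[1, 0, 2, 3]], ids=["B", "A", "C", "D"]))
        np.testing.assert_allclose(
            rev.delta.loc["B-A"].to_numpy(), -fwd.delta.loc["A-B"].to_numpy()
        )
        ties = fwd.delta.loc["A-B"].to_numpy() == 0
        assert (
            rev.indicator.loc["B-A"].to_numpy()[~ties]
            == -fwd.indicator.loc["A-B"].to_numpy()[~ties]
        ).all()


class TestChiSquare:
    def test_published_gender_counts(self):
        chi2, p = pp.chi_square_2x2(288, 200, 282, 205)
        assert round(p, 3) == 0.725
        assert chi2 == pytest.approx(chi2_bruteforce(288, 200, 282, 205), rel=1e-12)

    def test_identical_rows_give_null(self):
        chi2, p = pp.chi_square_2x2(10, 10, 10, 10)
        assert chi2 == 0.0
        assert p == 1.0

    def test_row_and_column_swap_invariance(self):
        base = pp.chi_square_2x2(12, 30, 25, 8)
        assert pp.chi_square_2x2(25, 8, 12, 30) == pytest.approx(base)
        assert pp.chi_square_2x2(30, 12, 8, 25) == pytest.approx(base)

    @pytest.mark.parametrize("table", [(0, 0, 3, 4), (0, 5, 0, 4), (1, 2, 3, -1)])
    def test_degenerate_or_invalid_tables_rejected(self, table):
        with pytest.raises(ValueError):
            pp.chi_square_2x2(*table)


class TestHolm:
    def test_hand_computed_step_down(self):
        np.testing.assert_allclose(
            pp.holm_adjust([0.01, 0.02, 0.03]), [0.03, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(pp.holm_adjust([0.2]), [0.2])

    def test_matches_bruteforce_rule_and_dominates_raw(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 40))
            adj = pp.holm_adjust(p)
            np.testing.assert_allclose(adj, holm_bruteforce(list(p)), atol=1e-12)
            assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pp.holm_adjust([0.5, 1.5])


class TestDifferentialScreen:
    def test_count_conservation_and_flagging(self, flip_screen):
        mpp, screen, truth = flip_screen
        n_ctrl = 60
        n_case = 70
        for r in screen.results:
            assert r.a + r.b == n_ctrl
            assert r.c + r.d == n_case
        flagged = set(screen.flagged_pair_ids)
        assert truth.truth_pairs <= flagged

    def test_invariant_to_sample_column_order(self, flip_screen):
        mpp, screen, _ = flip_screen
        rng = np.random.default_rng(0)
        perm = rng.permutation(mpp.delta.columns)
        shuffled = pp.MPPMatrix(
            delta=mpp.delta[perm], indicator=mpp.indicator[perm]
        )
        groups = pd.Series(
            ["AD" if s.startswith("A") else "non-AD" for s in perm], index=perm
        )
        screen2 = pp.differential_screen(shuffled, groups, alpha_adj=0.01)
        assert screen2.flagged_pair_ids == screen.flagged_pair_ids
        assert [r.p for r in screen2.results] == [r.p for r in screen.results]

    def test_constant_pair_skipped_as_degenerate(self):
        # pathway P1 always above P2: zero column margin, no test possible
        scores = np.array([[5.0, 5.0, 5.0, 5.0], [1.0, 1.0, 1.0, 1.0],
                           [2.0, 3.0, 1.5, 4.0]])
        mpp = pp.build_mpp(_activity(scores))
        groups = pd.Series(["non-AD", "non-AD", "AD", "AD"],
                           index=["s1", "s2", "s3", "s4"])
        screen = pp.differential_screen(mpp, groups)
        assert "P1-P2" in screen.skipped
        assert "P1-P2" not in [r.pair_id for r in screen.results]

    def test_single_group_rejected(self):
        mpp = pp.build_mpp(_activity(np.random.default_rng(0).normal(size=(3, 4))))
        groups = pd.Series(["AD"] * 4, index=["s1", "s2", "s3", "s4"])
        with pytest.raises(ValueError, match="two group"):
            pp.differential_screen(mpp, groups)
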