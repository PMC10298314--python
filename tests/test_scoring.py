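import numpy as np
import pandas as pd
import pytest

import pathpair as pp

# hand-added sum of the 13 published coefficients
PUBLISHED_COEF_SUM = 6.1875148


@pytest.fixture(scope="module")
def published():
    return pp.load_published_model()


def _unit_frame(pair_ids, hot, value=1.0):
    frame = pd.DataFrame(0.0, index=pd.Index(pair_ids, name="pair"), columns=["s1"])
    frame.loc[hot, "s1"] = value
    return frame


class TestRiskScore:
    def test_unit_vector_returns_each_coefficient(self, published):
        for pair, coef in published.entries:
            score = pp.risk_score(published, _unit_frame(published.pair_ids, pair))
            assert score["s1"] == coef

    def test_zero_vector_scores_intercept(self, published):
        frame = _unit_frame(published.pair_ids, published.pair_ids[0], value=0.0)
        assert pp.risk_score(published, frame)["s1"] == 0.0

    def test_all_ones_sums_the_coefficients(self, published):
        frame = pd.DataFrame(
            1.0, index=pd.Index(published.pair_ids, name="pair"), columns=["s1"]
        )
        assert pp.risk_score(published, frame)["s1"] == pytest.approx(
            PUBLISHED_COEF_SUM, abs=1e-9
        )

    def test_linearity_in_the_signature_values(self, published):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame(
            rng.normal(size=(13, 4)),
            index=pd.Index(published.pair_ids, name="pair"),
            columns=list("abcd"),
        )
        base = pp.risk_score(published, frame)
        scaled = pp.risk_score(published, frame * 2.5)
        np.testing.assert_allclose(scaled.to_numpy(), 2.5 * base.to_numpy())

    def test_reversed_pair_orientation_negates(self, published):
        reversed_ids = ["-".join(reversed(p.split("-"))) for p in published.pair_ids]
        frame = pd.DataFrame(
            -np.ones((13, 1)), index=pd.Index(reversed_ids, name="pair"), columns=["s1"]
        )
        assert pp.risk_score(published, frame)["s1"] == pytest.approx(
            PUBLISHED_COEF_SUM, abs=1e-9
        )

    def test_unresolvable_pair_listed(self, published):
        frame = _unit_frame(published.pair_ids[:-1], published.pair_ids[0])
        with pytest.raises(KeyError, match="hsa00051-hsa00860"):
            pp.risk_score(published, frame)

    def test_discrete_scoring_invariant_to_monotone_activity_rescaling(
        self, toy_expression, toy_catalog
    ):
        activity = pp.ssgsea_matrix(toy_expression, toy_catalog, normalize=False)
        mpp = pp.build_mpp(activity)
        model = pp.MPPSSModel(entries=[("PA-PB", 1.7)], representation="discrete")
        base = pp.risk_score(model, mpp)
        warped = toy_expression.values.copy() * 3 + 10.0
        mpp2 = pp.build_mpp(
            pp.ssgsea_matrix(
                pp.ExpressionMatrix(values=warped, metadata=toy_expression.metadata),
                toy_catalog,
                normalize=False,
            )
        )
        np.testing.assert_allclose(pp.risk_score(model, mpp2), base)


class TestTrainMppss:
    def test_deterministic_under_seed(self, classification_mpp):
        mpp, groups, _ = classification_mpp
        cfg = pp.TrainConfig(n_iter=3, cv_folds=5)
        a = pp.train_mppss(mpp, groups, cfg, seed=11)
        b = pp.train_mppss(mpp, groups, cfg, seed=11)
        pd.testing.assert_series_equal(a.frequencies, b.frequencies)
        assert a.model.entries == b.model.entries
        assert a.metrics == b.metrics

    def test_planted_world_yields_discriminative_model(self, classification_mpp):
        mpp, groups, _ = classification_mpp
        report = pp.train_mppss(mpp, groups, pp.TrainConfig(n_iter=5, cv_folds=5), seed=0)
        assert report.selected
        assert report.metrics["test_auc"] >= 0.9
        # every selected pair must be a real matrix row
        assert set(report.selected) <= set(mpp.pair_index)

    def test_frequencies_are_proportions(self, classification_mpp):
        mpp, groups, _ = classification_mpp
        report = pp.train_mppss(mpp, groups, pp.TrainConfig(n_iter=3, cv_folds=5), seed=2)
        assert ((report.frequencies >= 0) & (report.frequencies <= 1)).all()

    def test_too_few_samples_rejected(self):
        rng = np.random.default_rng(0)
        delta = pd.DataFrame(
            rng.normal(size=(5, 12)),
            index=[f"a{i}-b{i}" for i in range(5)],
            columns=[f"s{i}" for i in range(12)],
        )
        mpp = pp.MPPMatrix(delta=delta, indicator=(delta >= 0) * 2 - 1)
        groups = pd.Series(["AD"] * 6 + ["non-AD"] * 6, index=delta.columns)
        with pytest.raises(ValueError, match="at least 10"):
            pp.train_mppss(mpp, groups, pp.TrainConfig(n_iter=1))
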