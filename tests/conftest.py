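import numpy as np
import pandas as pd
import pytest

import pathpair as pp


@pytest.fixture
def toy_expression() -> pp.ExpressionMatrix:
    """Six genes, four samples, two groups; values on an arbitrary log scale."""
    rng = np.random.default_rng(42)
    genes = [f"g{i}" for i in range(1, 7)]
    samples = ["s1", "s2", "s3", "s4"]
    values = pd.DataFrame(rng.normal(6, 1, size=(6, 4)), index=genes, columns=samples)
    metadata = pd.DataFrame(
        {"group": ["non-AD", "non-AD", "AD", "AD"]}, index=samples
    )
    return pp.ExpressionMatrix(values=values, metadata=metadata)


@pytest.fixture
def toy_catalog() -> pp.GeneSetCatalog:
    return pp.GeneSetCatalog(
        [
            pp.GeneSet("PA", "pathway A", frozenset({"g1", "g2"})),
            pp.GeneSet("PB", "pathway B", frozenset({"g4", "g5", "g6"})),
        ]
    )


@pytest.fixture(scope="session")
def flip_dataset():
    """One cohort from the flipped-pathway world (seed 1)."""
    return pp.generate_dataset(pp.flip_config(1))


@pytest.fixture(scope="session")
def flip_screen(flip_dataset):
    expr, catalog, truth = flip_dataset
    activity = pp.ssgsea_matrix(expr, catalog)
    mpp = pp.build_mpp(activity)
    screen = pp.differential_screen(mpp, expr.groups, alpha_adj=0.01)
    return mpp, screen, truth


@pytest.fixture(scope="session")
def classification_mpp():
    """Pair matrix + labels from the five-shifted-pathway world (seed 1)."""
    expr, catalog, truth = pp.generate_dataset(pp.classification_config(1))
    activity = pp.ssgsea_matrix(expr, catalog)
    return pp.build_mpp(activity), expr.groups, truth
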