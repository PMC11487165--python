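import warnings

import numpy as np
import pandas as pd
import pytest

from esckit.io import ExpressionMatrix, GeneSetCollection, MutationTable
from esckit.simulate import CohortSimConfig


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """Library-internal advisory warnings are part of several contracts and
    asserted explicitly where relevant; keep the rest out of the output."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_config():
    """A miniature cohort used by fast unit tests."""
    return CohortSimConfig(
        n_per_subtype=5,
        n_genes=200,
        n_markers_per_subtype=10,
        n_slides=8,
        tiles_per_slide_raw=20,
        n_tile_features=40,
        seed=11,
    )


@pytest.fixture
def tiny_expr():
    frame = pd.DataFrame(
        {
            "s1": [1.0, 5.0, 0.0],
            "s2": [2.0, 5.0, 0.1],
            "s3": [3.0, 5.0, 4.0],
        },
        index=["gA", "gB", "gC"],
    )
    return ExpressionMatrix(frame)


@pytest.fixture
def tiny_sets():
    return GeneSetCollection.from_dict({"S1": {"gA", "gB"}, "S2": {"gC"}})


def make_mutations(rows):
    """rows: list of (sample, gene, variant_class, ref, alt)."""
    return MutationTable(
        pd.DataFrame(
            rows, columns=["sample", "gene", "variant_class", "ref_count", "alt_count"]
        )
    )


@pytest.fixture
def mutation_factory():
    return make_mutations
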