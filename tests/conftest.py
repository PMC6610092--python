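"""Shared fixtures: toy graphs and a desk-scale synthetic study.

The small study (150 genes, 25-gene module, 20:180 compounds) keeps the
per-test cost low; the full-size reference conditions live in the
acceptance tests.
"""

import numpy as np
import pandas as pd
import pytest

from drugwalk.interactome import ScoredEdgeList, build_graph
from drugwalk.model_selection import PipelineData
from drugwalk.synthetic_data import SyntheticSpec, generate_dataset


def edge_list(rows):
    """ScoredEdgeList from (a, b, score) tuples."""
    return ScoredEdgeList(pd.DataFrame(rows, columns=["node_a", "node_b", "score"]))


@pytest.fixture
def path_graph():
    """A - B - C path, all edges kept."""
    return build_graph(edge_list([("A", "B", 900), ("B", "C", 900)]), 0)


@pytest.fixture(scope="session")
def small_spec():
    return SyntheticSpec(
        n_genes=150,
        module_size=25,
        module_density=0.3,
        background_density=0.02,
        n_positive=20,
        n_negative=180,
        targets_per_compound=(10, 15),
        module_target_fraction=0.7,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return generate_dataset(small_spec, n_foods=6, n_food_compounds=40)


@pytest.fixture(scope="session")
def small_pipeline(small_dataset):
    return PipelineData(small_dataset.edges, small_dataset.compounds)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
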