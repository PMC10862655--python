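"""Shared fixtures: schemas, toy graphs and fitted small-scale models."""

import numpy as np
import pytest

from targetpath.graph import Edge, KnowledgeGraph, Node
from targetpath.model import AssociationModel
from targetpath.quate import QuatEConfig
from targetpath.schema import default_schema
from targetpath.synthetic import SyntheticConfig, generate
from targetpath.training import WarpConfig


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture()
def toy_kg(schema):
    """DI1 -asw- GE1 -ppi- GE2, plus a compound bound to GE2 and a
    transcription factor edge GE1 -pdi-> GE2."""
    nodes = [
        Node("DI1", "DI"), Node("GE1", "GE"), Node("GE2", "GE"),
        Node("GE3", "GE"), Node("CO1", "CO"),
    ]
    edges = [
        Edge("DI1", "asw", "GE1", causal=True),
        Edge("GE1", "ppi", "GE2"),
        Edge("CO1", "bin", "GE2"),
        Edge("GE1", "pdi", "GE2"),
    ]
    return KnowledgeGraph(schema, nodes, edges)


def small_config(seed: int = 3) -> SyntheticConfig:
    cfg = SyntheticConfig(seed=seed)
    cfg.node_counts = dict(cfg.node_counts, DI=8, GE=300, CO=60, PW=40,
                           AN=10, GO=30, SE=15, PC=5)
    cfg.background_edges = {k: max(1, v // 5)
                            for k, v in cfg.background_edges.items()}
    return cfg


@pytest.fixture(scope="session")
def small_synthetic():
    """A small but structurally complete synthetic KG (8 diseases, 300
    genes) with its planted ground truth."""
    return generate(small_config())


@pytest.fixture(scope="session")
def small_fit(small_synthetic):
    """A fitted association model on the small synthetic KG (reduced
    embedding size and epochs; enough for contract tests)."""
    kg, truth = small_synthetic
    model = AssociationModel(
        kg, truth=truth, seed=7,
        quate_config=QuatEConfig(epochs=5, k=8, seed=11),
        warp_config=WarpConfig(epochs=2, seed=12),
        select_max_count=6)
    return model, truth, model.fit()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
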