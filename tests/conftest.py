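"""Shared fixtures: small synthetic studies and random typed networks."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from regloop import GroundTruth, SimConfig, write_fixture
from regloop.regnet import RegNetwork


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig(seed=7)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, default_config):
    """One fully written synthetic study, shared read-only across tests."""
    d = tmp_path_factory.mktemp("fixture")
    manifest = write_fixture(d, default_config)
    return d, manifest


@pytest.fixture(scope="session")
def fixture_truth(fixture_dir) -> GroundTruth:
    _, manifest = fixture_dir
    return GroundTruth.from_json(manifest["ground_truth"].read_text(encoding="utf-8"))


def make_regnet(edges: list[tuple[str, str]], classes: dict[str, str],
                directions: dict[str, str] | None = None) -> RegNetwork:
    """Hand-build a typed network; every node defaults to direction 'up'."""
    g = nx.DiGraph()
    nodes = {n for e in edges for n in e}
    for n in nodes:
        g.add_node(n, node_class=classes[n],
                   direction=(directions or {}).get(n, "up"))
    for u, v in edges:
        g.add_edge(u, v, evidence="experimental")
    return RegNetwork(g)


def random_regnet(rng: np.random.Generator, n_tf: int, n_mi: int, n_gene: int,
                  p: float) -> RegNetwork:
    """Random tripartite directed network with the four regulatory edge kinds."""
    tfs = [f"T{i}" for i in range(n_tf)]
    mis = [f"M{i}" for i in range(n_mi)]
    genes = [f"G{i}" for i in range(n_gene)]
    g = nx.DiGraph()
    for n, cls in [(t, "TF") for t in tfs] + [(m, "miRNA") for m in mis] + [
        (x, "gene") for x in genes
    ]:
        g.add_node(n, node_class=cls, direction="up" if rng.random() < 0.5 else "down")
    for srcs, tgts in [(tfs, genes), (tfs, mis), (mis, genes), (mis, tfs)]:
        for s in srcs:
            for t in tgts:
                if rng.random() < p:
                    g.add_edge(s, t, evidence="experimental")
    return RegNetwork(g)


def brute_force_ffls(net: RegNetwork, allow_tf_as_target: bool = False):
    """Exhaustive (TF, miRNA, target) triple scan, independent of enumerate_ffls.

    Returns a sorted set of (tf, mirna, gene, motif_class) tuples using the
    same three-class typology, classified by direct edge membership checks.
    """
    edge_set = set(net.graph.edges)
    tfs = [n for n in net.graph.nodes if net.node_class(n) == "TF"]
    targets = [n for n in net.graph.nodes if net.node_class(n) == "gene"]
    if allow_tf_as_target:
        targets = targets + tfs
    mis = [n for n in net.graph.nodes if net.node_class(n) == "miRNA"]
    found = set()
    for tf in tfs:
        for mi in mis:
            for g in targets:
                if g == tf or g == mi:
                    continue
                if (tf, g) not in edge_set or (mi, g) not in edge_set:
                    continue
                a, b = (tf, mi) in edge_set, (mi, tf) in edge_set
                if a and b:
                    cls = "composite-FFL"
                elif a:
                    cls = "TF-FFL"
                elif b:
                    cls = "miRNA-FFL"
                else:
                    continue
                found.add((tf, mi, g, cls))
    return found


def de_frame(items: list[tuple[str, str]]) -> pd.DataFrame:
    """(feature_id, direction) pairs as the frame build_network expects."""
    return pd.DataFrame(items, columns=["feature_id", "direction"])
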