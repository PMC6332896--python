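"""Mixed TF-miRNA-gene regulatory network construction and hub analysis.

Nodes carry a class (TF, miRNA or gene) and a differential-expression
direction; the network is built only from differentially expressed
features, keeping exactly the catalog edges whose *both* endpoints were
called differential.  A node id present in the TF list is class TF even
though it is measured on the gene array — TFs are a regulator class, not
a gene subtype.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

__all__ = [
    "RegulatoryEdge",
    "RegNetwork",
    "is_mirna_id",
    "load_edge_catalog",
    "build_network",
    "node_degrees",
    "top_hubs",
    "regulated_fraction",
]

NODE_CLASSES = ("TF", "miRNA", "gene")
EVIDENCE_LEVELS = ("experimental", "predicted")
_CATALOG_COLUMNS = ["source", "target", "source_class", "target_class", "evidence"]


@dataclass(frozen=True)
class RegulatoryEdge:
    """A directed regulatory relation with its evidence label."""

    source: str
    target: str
    source_class: str
    target_class: str
    evidence: str = "experimental"

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError(f"self-edge {self.source}")
        if self.source_class not in ("TF", "miRNA"):
            raise ValueError(f"source class must be TF or miRNA, got {self.source_class}")
        if self.target_class not in NODE_CLASSES:
            raise ValueError(f"bad target class {self.target_class}")
        if self.source_class == "miRNA" and self.target_class == "miRNA":
            raise ValueError(f"miRNA->miRNA edge {self.source}->{self.target} disallowed")
        if self.evidence not in EVIDENCE_LEVELS:
            raise ValueError(f"bad evidence label {self.evidence}")


@dataclass
class RegNetwork:
    """Directed network over differentially expressed TFs, miRNAs and genes.

    Backed by a :class:`networkx.DiGraph` whose nodes carry ``node_class``
    and ``direction`` attributes and whose edges carry ``evidence``.
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def node_class(self, node: str) -> str:
        return self.graph.nodes[node]["node_class"]

    def direction(self, node: str) -> str:
        return self.graph.nodes[node]["direction"]

    def nodes_of_class(self, node_class: str) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d["node_class"] == node_class
        )

    def has_edge(self, source: str, target: str) -> bool:
        return self.graph.has_edge(source, target)

    def edges(self) -> list[RegulatoryEdge]:
        out = []
        for u, v, d in sorted(self.graph.edges(data=True)):
            out.append(
                RegulatoryEdge(
                    u, v, self.node_class(u), self.node_class(v), d["evidence"]
                )
            )
        return out


def is_mirna_id(feature_id: str, mirna_ids: set[str] | None = None) -> bool:
    """miRNA naming convention: declared in a list, or miR-/let- prefixed."""
    if mirna_ids is not None and feature_id in mirna_ids:
        return True
    low = feature_id.lower()
    return low.startswith(("mir-", "let-")) or "-mir-" in low or "-let-" in low


def _classify(feature_id: str, tf_ids: set[str], mirna_ids: set[str] | None) -> str:
    if feature_id in tf_ids:
        if is_mirna_id(feature_id, mirna_ids):
            raise ValueError(f"id {feature_id!r} declared TF but matches miRNA convention")
        return "TF"
    if is_mirna_id(feature_id, mirna_ids):
        return "miRNA"
    return "gene"


def load_edge_catalog(
    paths: list[str | Path] | str | Path,
    tf_ids: set[str] | None = None,
    mirna_ids: set[str] | None = None,
) -> list[RegulatoryEdge]:
    """Read and merge one or more edge-catalog TSV files.

    Each file has columns ``source, target, source_class, target_class,
    evidence``.  Duplicate (source, target) pairs are collapsed; when a pair
    occurs with both evidence labels the ``experimental`` one wins.  When
    ``tf_ids`` is given, node classes are re-derived from it plus the miRNA
    naming convention and checked against the file's class columns; a
    conflicting assignment for any recurring id is an error.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    rows: list[tuple[str, str, str, str, str]] = []
    for path in paths:
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != _CATALOG_COLUMNS:
                raise ValueError(f"{path}: expected header {_CATALOG_COLUMNS}, got {header}")
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 5:
                    raise ValueError(f"{path}:{lineno}: expected 5 columns, got {len(parts)}")
                rows.append(tuple(parts))  # type: ignore[arg-type]

    classes: dict[str, str] = {}
    merged: dict[tuple[str, str], str] = {}
    for src, tgt, scls, tcls, ev in rows:
        if tf_ids is not None:
            scls = _classify(src, tf_ids, mirna_ids)
            tcls = _classify(tgt, tf_ids, mirna_ids)
        for node, cls in ((src, scls), (tgt, tcls)):
            prev = classes.setdefault(node, cls)
            if prev != cls:
                raise ValueError(f"conflicting class for {node!r}: {prev} vs {cls}")
        key = (src, tgt)
        if key in merged:
            if ev == "experimental":
                merged[key] = ev
        else:
            merged[key] = ev

    return [
        RegulatoryEdge(src, tgt, classes[src], classes[tgt], ev)
        for (src, tgt), ev in sorted(merged.items())
    ]


def build_network(
    deg: pd.DataFrame,
    dem: pd.DataFrame,
    catalog: list[RegulatoryEdge],
) -> RegNetwork:
    """Restrict the catalog to edges between differentially expressed features.

    ``deg`` and ``dem`` are ``feature_id, direction`` frames (genes+TFs and
    miRNAs respectively).  An edge is kept iff both endpoints appear in
    either frame; the node set is the endpoints of kept edges, so isolated
    differential features never enter the network.
    """
    direction: dict[str, str] = {}
    for frame in (deg, dem):
        for fid, d in zip(frame["feature_id"], frame["direction"]):
            direction[fid] = d
    g = nx.DiGraph()
    for e in catalog:
        if e.source in direction and e.target in direction:
            g.add_node(e.source, node_class=e.source_class, direction=direction[e.source])
            g.add_node(e.target, node_class=e.target_class, direction=direction[e.target])
            g.add_edge(e.source, e.target, evidence=e.evidence)
    return RegNetwork(g)


def node_degrees(net: RegNetwork) -> pd.DataFrame:
    """In/out/total degree per node, sorted by total degree then id."""
    rows = [
        {
            "node": n,
            "node_class": net.node_class(n),
            "in_degree": net.graph.in_degree(n),
            "out_degree": net.graph.out_degree(n),
            "total_degree": net.graph.in_degree(n) + net.graph.out_degree(n),
        }
        for n in net.nodes
    ]
    df = pd.DataFrame(rows, columns=["node", "node_class", "in_degree", "out_degree", "total_degree"])
    if len(df):
        df = df.sort_values(["total_degree", "node"], ascending=[False, True], kind="stable")
        df = df.reset_index(drop=True)
    return df


def top_hubs(net: RegNetwork, k: int, node_class: str | None = None) -> list[str]:
    """The k highest-total-degree nodes (optionally of one class).

    Ties are broken lexicographically by node id; returns
    ``min(k, available)`` nodes.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    deg = node_degrees(net)
    if node_class is not None:
        deg = deg[deg["node_class"] == node_class]
    return deg["node"].head(k).tolist()


def regulated_fraction(
    net: RegNetwork, regulators: set[str], target_class: str
) -> float:
    """Fraction of ``target_class`` nodes one regulatory step from ``regulators``.

    Returns 0.0 when the network has no node of the requested class.
    """
    unknown = regulators - set(net.graph.nodes)
    if unknown:
        raise ValueError(f"regulators not in network: {sorted(unknown)}")
    pool = set(net.nodes_of_class(target_class))
    if not pool:
        return 0.0
    reached = {
        t for r in regulators for t in net.graph.successors(r) if t in pool
    }
    return len(reached) / len(pool)
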