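"""Three-node TF-miRNA-target feed-forward loop enumeration.

A feed-forward loop (FFL) is a (TF, miRNA, gene) triple in which the TF
and the miRNA both regulate the common target gene and at least one of
them regulates the other.  The standard three-class typology is used:

- ``TF-FFL``:        TF->miRNA, TF->gene, miRNA->gene
- ``miRNA-FFL``:     miRNA->TF, TF->gene, miRNA->gene
- ``composite-FFL``: both TF->miRNA and miRNA->TF, plus both ->gene edges

Each triple is reported once under its most specific class (composite
supersedes the one-way classes).  Regulation sign is not a constraint:
loops may freely mix up- and down-regulated members.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .regnet import RegNetwork

__all__ = ["FFLInstance", "Subnetwork", "enumerate_ffls", "ffl_summary", "extract_subnetwork"]

MOTIF_CLASSES = ("TF-FFL", "miRNA-FFL", "composite-FFL")


@dataclass(frozen=True)
class FFLInstance:
    """One ordered (tf, mirna, gene) loop with its motif class and edges."""

    tf: str
    mirna: str
    gene: str
    motif_class: str
    edges: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if len({self.tf, self.mirna, self.gene}) != 3:
            raise ValueError("FFL nodes must be pairwise distinct")
        if self.motif_class not in MOTIF_CLASSES:
            raise ValueError(f"bad motif class {self.motif_class}")

    @property
    def triple(self) -> tuple[str, str, str]:
        return (self.tf, self.mirna, self.gene)


def classify_triple(
    net: RegNetwork, tf: str, mirna: str, gene: str
) -> FFLInstance | None:
    """Classify one candidate triple, or None when it is not an FFL."""
    if not (net.has_edge(tf, gene) and net.has_edge(mirna, gene)):
        return None
    tf_m = net.has_edge(tf, mirna)
    m_tf = net.has_edge(mirna, tf)
    if tf_m and m_tf:
        cls = "composite-FFL"
        arms = ((tf, mirna), (mirna, tf))
    elif tf_m:
        cls = "TF-FFL"
        arms = ((tf, mirna),)
    elif m_tf:
        cls = "miRNA-FFL"
        arms = ((mirna, tf),)
    else:
        return None
    return FFLInstance(tf, mirna, gene, cls, arms + ((tf, gene), (mirna, gene)))


def enumerate_ffls(net: RegNetwork, allow_tf_as_target: bool = False) -> list[FFLInstance]:
    """All distinct FFLs in the network, sorted by (tf, mirna, gene).

    The gene slot is normally restricted to class-gene nodes; with
    ``allow_tf_as_target`` a TF may fill it when it is itself the target of
    another TF and a miRNA (the regulating TF is never its own target).
    """
    tfs = net.nodes_of_class("TF")
    targets = net.nodes_of_class("gene")
    if allow_tf_as_target:
        targets = sorted(targets + tfs)
    out: list[FFLInstance] = []
    for gene in targets:
        preds = list(net.graph.predecessors(gene))
        tf_preds = [p for p in preds if net.node_class(p) == "TF"]
        mi_preds = [p for p in preds if net.node_class(p) == "miRNA"]
        for tf in tf_preds:
            if tf == gene:
                continue
            for mi in mi_preds:
                inst = classify_triple(net, tf, mi, gene)
                if inst is not None:
                    out.append(inst)
    out.sort(key=lambda f: f.triple)
    return out


def ffl_summary(ffls: list[FFLInstance]) -> tuple[dict[str, int], pd.DataFrame]:
    """Counts per motif class plus a per-node FFL participation table."""
    counts = {cls: 0 for cls in MOTIF_CLASSES}
    participation: dict[str, int] = {}
    for f in ffls:
        counts[f.motif_class] += 1
        for node in f.triple:
            participation[node] = participation.get(node, 0) + 1
    table = pd.DataFrame(
        sorted(participation.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["node", "n_ffls"],
    )
    return counts, table


@dataclass
class Subnetwork:
    """A term-anchored slice of a regulatory network.

    Gene nodes are those annotated to at least one anchor term; every TF
    and miRNA with an edge to a retained gene is added, together with all
    parent edges among the retained nodes and the parent FFLs whose target
    gene survives.
    """

    parent: RegNetwork
    anchor_terms: list[str]
    nodes: list[str]
    edges: list[tuple[str, str]]
    ffls: list[FFLInstance] = field(default_factory=list)
    term_links: list[tuple[str, str]] = field(default_factory=list)


def extract_subnetwork(
    net: RegNetwork,
    annotation: dict[str, set[str]],
    anchor_terms: list[str],
    allow_tf_as_target: bool = False,
) -> Subnetwork:
    """Build the subnetwork of genes annotated to the anchor terms."""
    unknown = [t for t in anchor_terms if t not in annotation]
    if unknown:
        raise ValueError(f"unknown annotation terms: {unknown}")
    anchored = set()
    for term in anchor_terms:
        anchored |= annotation[term]
    genes = [g for g in net.nodes_of_class("gene") if g in anchored]
    gene_set = set(genes)
    keep = set(genes)
    for g in genes:
        for reg in net.graph.predecessors(g):
            if net.node_class(reg) in ("TF", "miRNA"):
                keep.add(reg)
    edges = sorted(
        (u, v) for u, v in net.graph.edges if u in keep and v in keep
    )
    ffls = [f for f in enumerate_ffls(net, allow_tf_as_target) if f.gene in gene_set]
    term_links = sorted(
        (g, term)
        for term in anchor_terms
        for g in annotation[term]
        if g in gene_set
    )
    return Subnetwork(net, list(anchor_terms), sorted(keep), edges, ffls, term_links)
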