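#!/usr/bin/env python
"""Spearman screen of drug IC50 profiles against network-gene expression.

Each drug is correlated with each network gene across the cell-line panel;
pairs with |rho| > 0.4 and p < 1e-4 are significant.  The bipartite
drug-gene graph (edges signed by correlation direction) is exported and
recovery of the planted pairs reported.
"""

import sys
from pathlib import Path

import networkx as nx

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from regloop import DrugResponseMatrix, GroundTruth, drug_gene_pairs, drug_network
from regloop import io as rio
from regloop.regnet import RegNetwork

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    fx = ROOT / "fixture"
    out = ROOT / "drug"
    out.mkdir(parents=True, exist_ok=True)
    truth = GroundTruth.from_json((fx / "ground_truth.json").read_text())
    net = RegNetwork(nx.read_graphml(ROOT / "network" / "network.graphml"))
    expr = rio.read_expression_tsv(fx / "cellline_expression.tsv")
    ic50 = DrugResponseMatrix(rio.read_expression_tsv(fx / "ic50.tsv"))
    genes = {n for n in net.graph.nodes
             if net.node_class(n) in ("gene", "TF")} & set(expr.index)
    pairs = drug_gene_pairs(ic50, expr, genes)
    rio.write_table(pairs, out / "drug_gene_pairs.tsv")
    sig = pairs[pairs["significant"]]
    print(f"{len(sig)} significant of {len(pairs)} tested pairs "
          f"({sig['drug_id'].nunique()} drugs x {sig['gene_id'].nunique()} genes)")
    planted = {(d, g) for d, g, _ in truth.planted_drug_pairs if g in genes}
    found = {(r.drug_id, r.gene_id) for r in sig.itertuples()}
    print(f"planted pairs within the network: {len(planted)}; "
          f"recovered: {len(planted & found)}")
    g = drug_network(pairs, net)
    rio.write_sif(g, out / "drug_network.sif")
    rio.write_graphml(g, out / "drug_network.graphml")


if __name__ == "__main__":
    main()
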