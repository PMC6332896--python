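#!/usr/bin/env python
"""Build the TF-miRNA-gene regulatory network over the differential features.

Catalog edges are kept only when both endpoints were called differential.
Writes SIF/GraphML exports and the degree table under results/network/,
reports the top-5 TF and miRNA hubs and the fraction of network genes the
top-3 TFs reach in one step.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from regloop import build_network, load_edge_catalog, node_degrees, regulated_fraction, top_hubs
from regloop import io as rio

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    fx = ROOT / "fixture"
    out = ROOT / "network"
    out.mkdir(parents=True, exist_ok=True)
    deg = pd.read_csv(ROOT / "de" / "deg_intersection.tsv", sep="\t")
    dem = pd.read_csv(ROOT / "de" / "dem_intersection.tsv", sep="\t")
    catalog = load_edge_catalog(fx / "edge_catalog.tsv", rio.read_tf_list(fx / "tf_list.txt"))
    net = build_network(deg, dem, catalog)
    rio.write_sif(net, out / "network.sif")
    rio.write_graphml(net, out / "network.graphml")
    rio.write_table(node_degrees(net), out / "node_degrees.tsv")
    print(f"network: {len(net.nodes)} nodes "
          f"({len(net.nodes_of_class('TF'))} TFs, "
          f"{len(net.nodes_of_class('miRNA'))} miRNAs, "
          f"{len(net.nodes_of_class('gene'))} genes), {net.n_edges} edges")
    top_tfs = top_hubs(net, 5, "TF")
    print("top-5 TF hubs:   ", ", ".join(top_tfs))
    print("top-5 miRNA hubs:", ", ".join(top_hubs(net, 5, "miRNA")))
    if top_tfs:
        frac = regulated_fraction(net, set(top_tfs[:3]), "gene")
        print(f"top-3 TFs reach {frac:.0%} of network genes in one step")


if __name__ == "__main__":
    main()
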