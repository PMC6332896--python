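#!/usr/bin/env python
"""Term over-representation of the up- and downregulated gene sets.

Hypergeometric upper tail against the GMT annotation with BH correction,
universe = all measured gene-matrix features.  The planted cell-cycle term
should dominate whichever direction holds the planted loop targets.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from regloop import enrich
from regloop import io as rio

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    fx = ROOT / "fixture"
    out = ROOT / "enrichment"
    out.mkdir(parents=True, exist_ok=True)
    universe = set(rio.read_expression_tsv(fx / "gene_expression.tsv").index)
    annotation, names = rio.read_gmt(fx / "annotation.gmt")
    deg = pd.read_csv(ROOT / "de" / "deg_intersection.tsv", sep="\t")
    for direction in ("up", "down"):
        query = set(deg.loc[deg["direction"] == direction, "feature_id"])
        res = enrich(query, universe, annotation, names)
        rio.write_table(res, out / f"enrichment_{direction}.tsv")
        if len(res):
            top = res.iloc[0]
            print(f"{direction}: {len(res)} terms with hits; top {top.term_id} "
                  f"(hits {top.hits}/{top.term_size}, p_adj {top.p_adj:.2e})")
        else:
            print(f"{direction}: no terms hit")


if __name__ == "__main__":
    main()
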