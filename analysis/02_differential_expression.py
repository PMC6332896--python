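#!/usr/bin/env python
"""Differential expression in both comparisons of each modality.

Genes: Welch t on log2 intensity, fold change > 4 and BH-adjusted p < 1e-5.
miRNAs: count filter (> 100 reads in >= 1 sample), Welch t on log2(CPM+0.5),
fold change > 2 and raw p < 0.05, then the expression-consistency filter.
Features must pass both comparisons with the same direction.  Writes the
per-comparison tables and the intersections under results/de/, and scores
them against the planted truth.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from regloop import GENE_POLICY, MIRNA_POLICY, GroundTruth
from regloop import io as rio
from regloop.pipeline import _de_stage

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    fx = ROOT / "fixture"
    out = ROOT / "de"
    out.mkdir(parents=True, exist_ok=True)
    truth = GroundTruth.from_json((fx / "ground_truth.json").read_text())

    gene_values = rio.read_expression_tsv(fx / "gene_expression.tsv")
    _, gene_tables, deg, _ = _de_stage(
        gene_values, rio.read_groups_tsv(fx / "gene_groups.tsv"),
        "intensity", GENE_POLICY)
    for comp, tab in gene_tables.items():
        rio.write_table(tab, out / f"de_genes_{comp}.tsv")
        print(f"gene comparison {comp}: {int(tab['passed'].sum())} differential")
    rio.write_table(deg, out / "deg_intersection.tsv")
    called = set(deg["feature_id"])
    tp = len(called & truth.de_genes)
    print(f"gene overlap: {len(deg)} ({(deg['direction'] == 'up').sum()} up, "
          f"{(deg['direction'] == 'down').sum()} down); "
          f"sensitivity {tp / len(truth.de_genes):.2f}, "
          f"false calls {len(called) - tp}")

    mirna_values = rio.read_expression_tsv(fx / "mirna_expression.tsv", "count")
    _, mirna_tables, dem, _ = _de_stage(
        mirna_values, rio.read_groups_tsv(fx / "mirna_groups.tsv"),
        "count", MIRNA_POLICY, min_fraction=0.8)
    for comp, tab in mirna_tables.items():
        rio.write_table(tab, out / f"de_mirnas_{comp}.tsv")
        print(f"miRNA comparison {comp}: {int(tab['passed'].sum())} differential")
    rio.write_table(dem, out / "dem_intersection.tsv")
    tp = len(set(dem["feature_id"]) & truth.de_mirnas)
    print(f"miRNA overlap after consistency filter: {len(dem)}; "
          f"sensitivity {tp / len(truth.de_mirnas):.2f}")


if __name__ == "__main__":
    main()
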