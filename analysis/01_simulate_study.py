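#!/usr/bin/env python
"""Generate the reference synthetic study under results/fixture/.

Two gene-intensity comparisons and two miRNA-count comparisons (15 case +
15 control samples each), a regulatory edge catalog with 10 planted
feed-forward loops among the planted differential features, a cell-line
expression panel, drug IC50 profiles with 5 planted associations, and the
ground-truth JSON used by the later steps to score recovery.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from regloop import GroundTruth, SimConfig, write_fixture

OUT = Path(__file__).resolve().parents[1] / "results" / "fixture"


def main() -> None:
    config = SimConfig(seed=1)
    manifest = write_fixture(OUT, config)
    truth = GroundTruth.from_json(manifest["ground_truth"].read_text())
    print(f"fixture written to {OUT}")
    for name, path in sorted(manifest.items()):
        print(f"  {name:22s} {path.name}")
    print(f"planted: {len(truth.de_genes)} differential genes/TFs "
          f"({len(truth.de_genes_up)} up, {len(truth.de_genes_down)} down), "
          f"{len(truth.de_mirnas)} differential miRNAs, "
          f"{len(truth.planted_ffls)} feed-forward loops, "
          f"{len(truth.planted_drug_pairs)} drug-gene pairs")


if __name__ == "__main__":
    main()
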