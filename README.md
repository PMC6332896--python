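# regloop

Analysis pipeline for TF–miRNA co-regulatory networks in two-cohort
differential-expression studies, with feed-forward loop (FFL) enumeration,
hub analysis, term enrichment and drug-sensitivity correlation screening.

The motivating setting is transcriptome dysregulation in T-cell acute
lymphoblastic leukemia (T-ALL): genes and miRNAs are each compared between
two disease cohorts and normal controls, the features that change
consistently in both comparisons are kept, and a mixed regulatory network
over transcription factors (TFs), miRNAs and target genes is assembled from
an evidence catalog.  Within that network the pipeline enumerates
three-node feed-forward loops — a TF and a miRNA that both regulate a
common target while one regulates the other — ranks hub regulators by
degree, tests the up/down gene sets for annotation-term over-representation
(hypergeometric upper tail, BH-corrected), and screens network genes
against drug IC50 profiles across cell lines by Spearman correlation.

## Methods in brief

- **Differential expression.** Per feature, a Welch two-sample *t* on log2
  intensities (arrays) or log2(CPM + 0.5) (counts).  Gene cutoffs:
  FC > 4 and BH-adjusted p < 1e-5; miRNA cutoffs: FC > 2, raw p < 0.05 and
  read count > 100 in at least one sample, plus an expression-consistency
  filter for unbalanced designs.  Features must pass **both** comparisons
  with the same direction.
- **FFL typology.** TF-FFL = {TF→miRNA, TF→gene, miRNA→gene};
  miRNA-FFL = {miRNA→TF, TF→gene, miRNA→gene}; composite-FFL = both
  TF↔miRNA arms.  Each triple is reported once, most specific class first.
- **Drug screen.** Spearman rho per (drug, gene) over shared cell lines
  (pairwise-complete); significant iff |rho| > 0.4 and p < 1e-4.

Because the original cohorts live in external repositories, the package
ships a synthetic-study generator (`regloop.synthetic`) that plants every
signal the analysis assumes — differential features with known direction,
complete FFLs among them, an annotated target-gene term, and drug–gene
associations with known rank correlation — together with the ground truth
needed to score recovery.  See `docs/methods.md` for the full model.

## Worked example

The numbered scripts under `analysis/` run the whole study on the
reference synthetic fixture (seed 1) and write their tables under
`results/`:

```sh
python analysis/01_simulate_study.py
python analysis/02_differential_expression.py
python analysis/03_build_network.py
python analysis/04_ffl_enumeration.py
python analysis/05_enrichment.py
python analysis/06_drug_screen.py
```

Output of the run that produced this README:

```
gene overlap: 69 (35 up, 34 down); sensitivity 1.00, false calls 0
miRNA overlap after consistency filter: 9; sensitivity 1.00
network: 37 nodes (9 TFs, 9 miRNAs, 19 genes), 52 edges
top-5 TF hubs:    TF015, TF011, TF012, TF030, TF006
10 FFLs: 5 TF-FFL, 1 miRNA-FFL, 4 composite-FFL
planted-loop recovery: 10/10
CELL_CYCLE_SYN subnetwork: 25 nodes, 39 edges, 10 FFLs
up: 25 terms with hits; top CELL_CYCLE_SYN (hits 7/10, p_adj 2.31e-03)
5 significant of 560 tested pairs (5 drugs x 5 genes)
planted pairs within the network: 5; recovered: 5
```

Read: all 69 planted differential gene-matrix features and all 9 planted
miRNAs were recalled with no false calls; the network restricted to them
contains all 10 planted loops and no loop touching a non-differential
node; the synthetic cell-cycle term tops the enrichment of the
upregulated set; and all 5 planted drug–gene associations pass the screen
cutoffs.

The same pipeline runs on real data from a shell via the CLI
(`regloop run-all --config config.yaml`, or per-stage subcommands
`simulate | de | network | ffl | enrich | drugcorr`); inputs are plain
TSV/GMT files as described in `docs/methods.md`.

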