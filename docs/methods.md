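# Methods

## Study design emulated

The pipeline targets a two-modality, dual-comparison design: gene
expression measured on an intensity platform for two disease cohorts (for
example cell lines and patients) each compared against normal controls,
and miRNA abundance measured by small-RNA sequencing likewise compared
against two control populations.  A feature is accepted as differential
only when it passes the cutoffs in **both** comparisons of its modality
with the same direction of change; features significant in both but with
opposite trends are reported separately and excluded.  Accepted genes and
miRNAs, restricted to the edges of a regulatory evidence catalog whose
endpoints are both differential, form the co-regulatory network on which
all downstream analyses run.

## Differential expression

Both modalities are tested with a per-feature Welch two-sample *t*:

- intensity data are assumed to be on the log2 scale already;
- count data are normalised to counts per million (CPM) per library and
  transformed to log2(CPM + 0.5) before testing.  Before normalisation a
  count filter removes features without more than `min_count` (default
  100) reads in at least `min_samples` (default 1) samples.

The Welch statistic is a deliberate simplification of moderated linear
models and negative-binomial GLMs: it keeps the stage dependency-free and
transparent while preserving two-group location-test semantics.  The
substitution is recorded in the run report.  Its costs — no variance
moderation at small n, and susceptibility of CPM to compositional shifts —
are discussed under *Limitations*.

Thresholds are a `ThresholdPolicy`: linear fold-change floor `fc_min`
(pass iff |log2FC| > log2(fc_min)), p ceiling `p_max`, and a flag choosing
raw or BH-adjusted p.  All comparisons are strict, matching the
conventions FC > x and p < y.  Defaults: genes `fc_min=4, p_max=1e-5`
on adjusted p; miRNAs `fc_min=2, p_max=0.05` on raw p (no adjustment is
conventionally applied at this screening stage).  Benjamini–Hochberg
adjustment is the standard step-up procedure, implemented once in
`diffexpr.bh_adjust` and shared with the enrichment module.

Degenerate inputs: a feature with equal group means and zero variance in
both groups gets p = 1 by convention; when means differ, a variance floor
of 1e-12 prevents division by zero.

### Expression-consistency filter

Published workflows apply a robustness step (e.g. an entropy-based
consistency statistic) when group sizes are very unequal.  This package
substitutes a transparent majority-side rule: a candidate with claimed
direction *up* (*down*) is retained iff at least `min_fraction` (default
0.8) of its case samples lie strictly above (below) the feature's pooled
across-group median on the log2 scale.  The 0.8 default is a design
choice — the published statistic has no portable threshold — and is
exposed as a parameter.  The pipeline applies the rule against both
comparisons' matrices, so a retained miRNA is supported by the bulk of
case samples in each cohort.

## Network construction

Node classes follow the precedence: an id on the user-supplied TF list is
a TF; an id matching the miRNA naming convention (`miR-`/`let-` prefix, or
a declared miRNA list) is a miRNA; anything else is a gene.  A
differentially expressed TF is class TF, not gene — TFs are a regulator
class.  Edge catalogs (TSV: source, target, classes, evidence) from
multiple sources are merged with duplicate (source, target) pairs
collapsed, `experimental` evidence taking precedence over `predicted`.
Evidence labels are carried on edges but do not filter by default (an
`experimental_only` flag restricts them), since merged public catalogs
rarely state a combination rule; the default is the union.

`build_network` keeps exactly the catalog edges with both endpoints
differential; the node set is the endpoints of kept edges, so isolated
differential features are dropped.  Degree is total (in + out); hub
extraction sorts by total degree descending with lexicographic
tie-breaking and returns the top k (default 5) per class.

## Feed-forward loops

The standard three-class typology over ordered (TF, miRNA, gene) triples:

| class         | required edges                              |
|---------------|---------------------------------------------|
| TF-FFL        | TF→miRNA, TF→gene, miRNA→gene               |
| miRNA-FFL     | miRNA→TF, TF→gene, miRNA→gene               |
| composite-FFL | TF→miRNA **and** miRNA→TF, plus both →gene  |

Each triple is reported once under its most specific class (composite
supersedes the one-way classes), in deterministic (tf, mirna, gene) sorted
order.  Regulation sign is not an enumeration constraint: loops may mix
up- and down-regulated members.  The gene slot is restricted to class-gene
nodes by default; `allow_tf_as_target` lets a TF fill it when it is the
target of another TF and a miRNA.  Enumeration walks each candidate
target's TF and miRNA predecessor lists rather than all triples; its
equivalence to exhaustive search is a tested property.

Term-anchored subnetworks keep the network genes annotated to at least
one anchor term, add every TF/miRNA with an edge to a retained gene, keep
all parent edges among retained nodes, and report the parent FFLs whose
target gene survives.

## Enrichment

Over-representation of a query gene set in each annotation term (GMT) is
the hypergeometric upper tail P(X ≥ hits) with BH correction across
tested terms.  The universe defaults to the features actually measured on
the platform, not the genome, because differential sets are
platform-bounded; it is overridable.  Terms with fewer than two universe
genes are skipped as unstable; terms without query hits are omitted.  The
plain tail is used — not the EASE-style (hits − 1) deflation some web
services apply — which makes p-values exactly Fisher one-sided.

## Drug screen

For each (drug, gene) pair the Spearman correlation between the drug's
IC50 profile and the gene's expression over shared cell lines is computed
on average-ranked values, with pairwise-complete deletion of missing
IC50s and at least 3 complete pairs required.  Two-sided p comes from
t = rho·sqrt((n−2)/(1−rho²)) on n−2 df — standard at screen sizes of tens
of cell lines and up; |rho| = 1 returns p = 0 by convention and zero rank
variance returns a flagged (NaN) result.  IC50s enter untransformed
(ranks are transform-invariant).  Significance is the strict double
cutoff |rho| > 0.4 and p < 1e-4.  Significant pairs whose gene lies in
the regulatory network form a bipartite drug–gene graph with edges
labelled by correlation sign.

## Synthetic-data generator

`SimConfig` defaults define the reference study: 30 TFs + 200 genes and
30 miRNAs, two comparisons per modality with 15 case + 15 control samples
each, 30% of features differential at |log2FC| = 3, Gaussian intensity
noise sd 0.5, negative-binomial counts (variance µ + 0.3µ²) at expected
depth 1e6, background edge probability 0.02, 10 planted FFLs, 60 cell
lines × 20 drugs with 5 planted drug–gene pairs at population Spearman
0.8.  The 15+15 arms mirror cohort sizes typical of the motivating
studies; effect size and noise are calibration choices giving the
per-feature test high power at the stated cutoffs, as a planted-truth
benchmark requires.

Construction order: differential features and directions are drawn first;
FFL triples are sampled from the differential TFs × miRNAs × genes
(distinct triples, loop targets spread over distinct genes first), their
3–4 edges injected with `experimental` evidence; background edges are
added kind-by-kind (TF→gene, TF→miRNA, miRNA→gene, miRNA→TF — never
miRNA→miRNA or self-edges) with independent probability and random
evidence.  Requesting more FFLs than there are distinct differential
triples is an error.

Gene intensities are baseline Uniform(6, 12) log2 units plus the planted
±log2FC shift for case samples of **both** comparisons (same sign — the
trend-consistent intersection assumes it) plus N(0, noise_sd) per sample.
miRNA counts are negative binomial with the case mean scaled by
2^(±log2FC).  Background miRNA abundances span ~12 log2 units so some
features genuinely sit below the count filter; differential miRNAs are
drawn from a mid-abundance band — high enough that the downshifted arm
stays above the filter floor, low enough that the shifted species hold a
small share of the library.  Under total-count normalisation a
composition-dominating shift would bleed into every other feature's
apparent fold change; real sequencing has this pathology too, and the
generator deliberately stays in the regime where CPM is trustworthy (see
*Limitations*).

Drug profiles: planted (drug, gene, sign) pairs get
IC50 = sign·r·standardised-expression + sqrt(1−r²)·noise with
r = 2·sin(π·ρ_s/6), which for jointly Gaussian variables yields population
Spearman exactly ρ_s; the noise term vanishes as ρ_s → 1.  Non-planted
drugs are independent noise (zero population correlation with every
gene).  Planted pair genes prefer planted-loop targets so the screen has
in-network signal.

All randomness flows from `SimConfig.seed` through fixed per-stage child
streams; identical (config, seed) reproduce byte-identical fixture files.

## File formats and determinism

TSV throughout (UTF-8, no quoting, `NA` for missing): expression and IC50
matrices (first column feature id, header sample/cell-line ids), sample
group maps (sample_id, group, comparison), edge catalogs, result tables;
GMT for annotations; SIF and GraphML for networks (SIF relation labels:
`activates_tf` for TF-source edges, `targets_mirna` for miRNA-source,
`regulates` otherwise).  Writers sort their lines and fix float formats —
data matrices at 12 significant digits (so write/read round trips are
faithful), derived tables at 6 — making every artifact byte-reproducible.

## Validation strategy and problem sizes

The test suite checks each stage against an independent oracle: Welch p
against the hand-evaluated textbook formula, BH against the reference
implementation in statsmodels, Spearman against rank-then-Pearson and
scipy, the hypergeometric tail against direct mass summation and Fisher's
exact test (exhaustively for universes ≤ 30), FFL enumeration against
brute-force triple scans (200 random networks up to 300 nodes, densities
0.01–0.3), and the end-to-end pipeline against planted ground truth (20
seeds of the reference study; ≥ 9/10 loops recovered with no loop
touching a non-differential node).  Null calibration is verified on the
generator's own null (raw p < 0.05 fraction inside the 99% binomial band
at 2000 features; drug screen passes at p < 1e-4 within the 99.9%
binomial bound over 1000 null pairs).  These sizes keep the whole suite
under a minute of compute while leaving the binomial bands tight enough
to be informative.

Passing these tests shows the machinery is correct and calibrated on data
matching its assumptions; it does not show that real cohorts satisfy
those assumptions (see next section).

## Limitations

- The Welch-on-log2 substitute lacks the variance moderation of limma and
  the dispersion shrinkage of DESeq2; on real small-n cohorts it is less
  powerful and its null behaviour on strongly non-Gaussian intensities is
  approximate.
- CPM normalisation is compositional: a few dominant changing miRNAs
  shift every other feature's apparent level.  The generator avoids this
  regime by design; real libraries may not.
- The generator plants equal effect sizes and homoscedastic noise, no
  batch effects, probe structure, correlated features, or
  isoform/arm-specific miRNA counting.
- The consistency filter's 0.8 threshold is a design default, not an
  estimate; on heavily unbalanced real designs it should be examined.
- Enrichment ignores term–term dependence (no GO-graph propagation or
  redundancy trimming); p-values across overlapping terms are correlated.
- The drug screen's t-approximation is inaccurate in the extreme tail for
  very small panels; an exact approach should replace it below ~10 cell
  lines.
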