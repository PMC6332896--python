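"""Synthetic study generator with planted, recoverable signal.

Emulates the statistical structure of a two-modality differential
expression study feeding a TF-miRNA-target network analysis:

- two case-vs-control comparisons on a log2-intensity gene matrix
  (microarray-like Gaussian noise) sharing one set of planted
  differential features with a common direction of change,
- two comparisons on a miRNA count matrix (sequencing-like
  negative-binomial counts) likewise,
- a regulatory edge catalog containing a known number of planted
  feed-forward loops among the differential features plus random
  background edges,
- a cell-line expression matrix and drug IC50 profiles in which selected
  (drug, gene) pairs carry a planted monotone association of known
  population Spearman correlation,
- a GMT annotation placing the planted loop target genes in one synthetic
  term among random decoy terms.

Every random draw flows from ``SimConfig.seed`` through per-stage child
streams, so identical (config, seed) reproduce identical outputs
byte-for-byte.  The ground truth needed to score recovery is returned
alongside the data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .diffexpr import ExpressionMatrix
from .regnet import RegulatoryEdge

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_regulome",
    "simulate_expression",
    "simulate_cellline_expression",
    "simulate_drug_response",
    "write_fixture",
]

COMPARISONS = ("A", "B")  # two independent case cohorts vs control
PLANTED_TERM = "CELL_CYCLE_SYN"


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic study.

    Defaults describe the reference conditions the pipeline is validated
    under: 15+15 samples per comparison, |log2FC| = 3 planted on 30% of
    features over Gaussian noise of sd 0.5 (intensity) or negative-binomial
    counts (dispersion 0.3), 10 planted feed-forward loops, and 5 planted
    drug-gene pairs at population Spearman 0.8 across 60 cell lines.
    """

    n_tfs: int = 30
    n_mirnas: int = 30
    n_genes: int = 200
    n_samples_per_group: int = 15
    frac_de: float = 0.3
    planted_log2fc: float = 3.0
    noise_sd: float = 0.5
    count_depth: float = 1e6
    count_dispersion: float = 0.3
    edge_prob: float = 0.02
    n_planted_ffls: int = 10
    n_cell_lines: int = 60
    n_drugs: int = 20
    n_planted_drug_pairs: int = 5
    planted_rho: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_tfs", "n_mirnas", "n_genes", "n_samples_per_group",
                     "n_planted_ffls", "n_cell_lines", "n_drugs",
                     "n_planted_drug_pairs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 <= self.frac_de <= 1):
            raise ValueError("frac_de must be in [0, 1]")
        if not (-1 < self.planted_rho < 1):
            raise ValueError("planted_rho must be in (-1, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not (0 <= self.edge_prob <= 1):
            raise ValueError("edge_prob must be in [0, 1]")

    @property
    def tf_ids(self) -> list[str]:
        return [f"TF{i:03d}" for i in range(1, self.n_tfs + 1)]

    @property
    def mirna_ids(self) -> list[str]:
        return [f"miR-{i:03d}" for i in range(1, self.n_mirnas + 1)]

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(1, self.n_genes + 1)]

    @property
    def drug_ids(self) -> list[str]:
        return [f"DRUG{i:03d}" for i in range(1, self.n_drugs + 1)]

    def rng(self, stage: int) -> np.random.Generator:
        """Independent deterministic stream for one simulation stage."""
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stage]))


@dataclass
class GroundTruth:
    """What was planted, for scoring recovery downstream.

    Directions apply to both comparisons of a modality (planted features
    shift the same way in both, which is what the trend-consistent
    intersection step assumes).  ``de_genes_*`` include differential TFs:
    TFs are measured on the gene matrix.
    """

    de_genes_up: set[str] = field(default_factory=set)
    de_genes_down: set[str] = field(default_factory=set)
    de_mirnas_up: set[str] = field(default_factory=set)
    de_mirnas_down: set[str] = field(default_factory=set)
    planted_edges: list[tuple[str, str]] = field(default_factory=list)
    planted_ffls: list[tuple[str, str, str, str]] = field(default_factory=list)
    planted_drug_pairs: list[tuple[str, str, int]] = field(default_factory=list)

    @property
    def de_genes(self) -> set[str]:
        return self.de_genes_up | self.de_genes_down

    @property
    def de_mirnas(self) -> set[str]:
        return self.de_mirnas_up | self.de_mirnas_down

    @property
    def de_features(self) -> set[str]:
        return self.de_genes | self.de_mirnas

    def gene_direction(self, fid: str) -> str:
        return "up" if fid in self.de_genes_up else "down"

    def to_json(self) -> str:
        payload = {
            "de_genes_up": sorted(self.de_genes_up),
            "de_genes_down": sorted(self.de_genes_down),
            "de_mirnas_up": sorted(self.de_mirnas_up),
            "de_mirnas_down": sorted(self.de_mirnas_down),
            "planted_edges": [list(e) for e in self.planted_edges],
            "planted_ffls": [list(f) for f in self.planted_ffls],
            "planted_drug_pairs": [list(p) for p in self.planted_drug_pairs],
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            de_genes_up=set(d["de_genes_up"]),
            de_genes_down=set(d["de_genes_down"]),
            de_mirnas_up=set(d["de_mirnas_up"]),
            de_mirnas_down=set(d["de_mirnas_down"]),
            planted_edges=[tuple(e) for e in d["planted_edges"]],
            planted_ffls=[tuple(f) for f in d["planted_ffls"]],
            planted_drug_pairs=[tuple(p) for p in d["planted_drug_pairs"]],
        )


def _pick_de(rng: np.random.Generator, ids: list[str], frac: float) -> tuple[set[str], set[str]]:
    n_de = int(round(frac * len(ids)))
    chosen = rng.choice(len(ids), size=n_de, replace=False) if n_de else np.array([], dtype=int)
    up, down = set(), set()
    for idx in sorted(chosen):
        (up if rng.random() < 0.5 else down).add(ids[idx])
    return up, down


_FFL_ARMS = {
    "TF-FFL": lambda tf, mi, g: [(tf, mi), (tf, g), (mi, g)],
    "miRNA-FFL": lambda tf, mi, g: [(mi, tf), (tf, g), (mi, g)],
    "composite-FFL": lambda tf, mi, g: [(tf, mi), (mi, tf), (tf, g), (mi, g)],
}


def simulate_regulome(config: SimConfig) -> tuple[list[RegulatoryEdge], GroundTruth]:
    """Random tripartite edge catalog with planted differential FFLs.

    Edges come in four kinds (TF->gene, TF->miRNA, miRNA->gene, miRNA->TF),
    each background pair included independently with ``edge_prob`` and a
    random evidence label.  Exactly ``n_planted_ffls`` complete loops
    (random motif class) are injected among features that are also planted
    differential, with evidence ``experimental``, so they survive the
    differential-expression restriction downstream.  Planted drug-gene
    pairs are drawn here too, preferring planted loop target genes so the
    drug screen has in-network signal.
    """
    rng = config.rng(0)
    truth = GroundTruth()
    truth.de_genes_up, truth.de_genes_down = _pick_de(rng, config.gene_ids, config.frac_de)
    tf_up, tf_down = _pick_de(rng, config.tf_ids, config.frac_de)
    truth.de_genes_up |= tf_up
    truth.de_genes_down |= tf_down
    truth.de_mirnas_up, truth.de_mirnas_down = _pick_de(rng, config.mirna_ids, config.frac_de)

    de_tfs = sorted((tf_up | tf_down))
    de_mirnas = sorted(truth.de_mirnas)
    de_genes = sorted(truth.de_genes - set(config.tf_ids))
    feasible = len(de_tfs) * len(de_mirnas) * len(de_genes)
    if config.n_planted_ffls > feasible:
        raise ValueError(
            f"cannot plant {config.n_planted_ffls} FFLs: only {feasible} distinct "
            f"(TF, miRNA, gene) triples among differential features"
        )

    edges: dict[tuple[str, str], str] = {}
    classes = list(_FFL_ARMS)
    seen_triples: set[tuple[str, str, str]] = set()
    gene_cycle: list[str] = []
    while config.n_planted_ffls and len(seen_triples) < config.n_planted_ffls:
        if not gene_cycle:  # spread loop targets over distinct genes first
            gene_cycle = list(rng.permutation(de_genes))
        g = gene_cycle.pop()
        tf = de_tfs[rng.integers(len(de_tfs))]
        mi = de_mirnas[rng.integers(len(de_mirnas))]
        if (tf, mi, g) in seen_triples:
            continue
        seen_triples.add((tf, mi, g))
        cls = classes[rng.integers(len(classes))]
        for src, tgt in _FFL_ARMS[cls](tf, mi, g):
            edges[(src, tgt)] = "experimental"
            truth.planted_edges.append((src, tgt))
        truth.planted_ffls.append((tf, mi, g, cls))
    truth.planted_ffls.sort()
    truth.planted_edges = sorted(set(truth.planted_edges))

    # background edges, kind by kind in fixed order
    kinds = [
        (config.tf_ids, config.gene_ids),
        (config.tf_ids, config.mirna_ids),
        (config.mirna_ids, config.gene_ids),
        (config.mirna_ids, config.tf_ids),
    ]
    for sources, targets in kinds:
        if not sources or not targets:
            continue
        mask = rng.random((len(sources), len(targets))) < config.edge_prob
        ev_draw = rng.random((len(sources), len(targets))) < 0.5
        for i, j in zip(*np.nonzero(mask)):
            key = (sources[i], targets[j])
            if key not in edges:
                edges[key] = "experimental" if ev_draw[i, j] else "predicted"

    classmap = {fid: "TF" for fid in config.tf_ids}
    classmap.update({fid: "miRNA" for fid in config.mirna_ids})
    classmap.update({fid: "gene" for fid in config.gene_ids})
    catalog = [
        RegulatoryEdge(s, t, classmap[s], classmap[t], ev)
        for (s, t), ev in sorted(edges.items())
    ]

    # planted drug-gene pairs, preferring loop target genes (in-network)
    if config.n_planted_drug_pairs:
        if config.n_planted_drug_pairs > config.n_drugs:
            raise ValueError("more planted drug pairs than drugs")
        pool = sorted({f[2] for f in truth.planted_ffls}) or de_genes or config.gene_ids
        if config.n_planted_drug_pairs > len(pool):
            pool = sorted(set(pool) | set(de_genes) | set(config.gene_ids))
        drugs = [config.drug_ids[i] for i in sorted(
            rng.choice(config.n_drugs, size=config.n_planted_drug_pairs, replace=False))]
        genes = [pool[i] for i in sorted(
            rng.choice(len(pool), size=config.n_planted_drug_pairs, replace=False))]
        for d, g in zip(drugs, genes):
            sign = 1 if rng.random() < 0.5 else -1
            truth.planted_drug_pairs.append((d, g, sign))
    return catalog, truth


def _gene_matrices(
    config: SimConfig, truth: GroundTruth, rng: np.random.Generator
) -> dict[str, ExpressionMatrix]:
    features = config.tf_ids + config.gene_ids
    base = rng.uniform(6.0, 12.0, size=len(features))
    shift = np.array(
        [
            config.planted_log2fc if f in truth.de_genes_up
            else -config.planted_log2fc if f in truth.de_genes_down
            else 0.0
            for f in features
        ]
    )
    out = {}
    n = config.n_samples_per_group
    for comp in COMPARISONS:
        case = base[:, None] + shift[:, None] + rng.normal(0, config.noise_sd, (len(features), n))
        ctrl = base[:, None] + rng.normal(0, config.noise_sd, (len(features), n))
        cols = [f"{comp}_case_{i:02d}" for i in range(1, n + 1)] + [
            f"{comp}_ctrl_{i:02d}" for i in range(1, n + 1)
        ]
        values = pd.DataFrame(np.hstack([case, ctrl]), index=features, columns=cols)
        groups = {c: ("case" if "_case_" in c else "control") for c in cols}
        out[comp] = ExpressionMatrix(values, groups, "intensity")
    return out


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu^2 (Poisson at 0)."""
    if dispersion <= 0:
        return rng.poisson(mu)
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def _mirna_matrices(
    config: SimConfig, truth: GroundTruth, rng: np.random.Generator
) -> dict[str, ExpressionMatrix]:
    features = config.mirna_ids
    # background abundances span ~12 log2 units so some miRNAs sit near the
    # count-filter floor; differential miRNAs are drawn from a mid-abundance
    # band: high enough that a 2^-lfc downshift stays above the floor, low
    # enough that the shifted species hold a small share of the library --
    # under total-count (CPM) normalisation a composition-dominating shift
    # would bleed into every other feature's apparent fold change
    de = np.array([f in truth.de_mirnas for f in features])
    lo = np.where(de, 4.0, 2.0)
    hi = np.where(de, 6.5, 14.0)
    w = np.exp2(rng.uniform(lo, hi))
    mu0 = config.count_depth * w / w.sum()
    fold = np.array(
        [
            2.0**config.planted_log2fc if f in truth.de_mirnas_up
            else 2.0**-config.planted_log2fc if f in truth.de_mirnas_down
            else 1.0
            for f in features
        ]
    )
    out = {}
    n = config.n_samples_per_group
    for comp in COMPARISONS:
        case = _nb_draw(rng, np.tile((mu0 * fold)[:, None], (1, n)), config.count_dispersion)
        ctrl = _nb_draw(rng, np.tile(mu0[:, None], (1, n)), config.count_dispersion)
        cols = [f"{comp}_case_{i:02d}" for i in range(1, n + 1)] + [
            f"{comp}_ctrl_{i:02d}" for i in range(1, n + 1)
        ]
        values = pd.DataFrame(np.hstack([case, ctrl]), index=features, columns=cols)
        groups = {c: ("case" if "_case_" in c else "control") for c in cols}
        out[comp] = ExpressionMatrix(values, groups, "count")
    return out


def simulate_expression(
    config: SimConfig, truth: GroundTruth
) -> tuple[dict[str, ExpressionMatrix], dict[str, ExpressionMatrix]]:
    """Two gene-intensity and two miRNA-count comparisons.

    Gene intensities are log2-scale Gaussian around a per-feature baseline,
    with the planted mean shift applied to the case group of *both*
    comparisons with the same sign; miRNA counts are negative binomial with
    the case mean scaled by 2**(+-planted_log2fc).  Non-planted features
    have expected log2 fold change zero.
    """
    known = set(config.tf_ids) | set(config.gene_ids) | set(config.mirna_ids)
    stray = truth.de_features - known
    if stray:
        raise ValueError(f"ground truth references unknown features: {sorted(stray)}")
    rng = config.rng(1)
    return _gene_matrices(config, truth, rng), _mirna_matrices(config, truth, rng)


def simulate_cellline_expression(config: SimConfig) -> pd.DataFrame:
    """Gene log2 expression across a panel of cell lines (no group design)."""
    rng = config.rng(2)
    features = config.tf_ids + config.gene_ids
    base = rng.uniform(6.0, 12.0, size=len(features))
    vals = base[:, None] + rng.normal(0, 1.0, (len(features), config.n_cell_lines))
    cols = [f"CL{i:03d}" for i in range(1, config.n_cell_lines + 1)]
    return pd.DataFrame(vals, index=features, columns=cols)


def simulate_drug_response(
    config: SimConfig,
    expr: pd.DataFrame,
    truth: GroundTruth,
    missing_rate: float = 0.0,
) -> pd.DataFrame:
    """Drug x cell-line IC50 profiles with planted rank correlations.

    For a planted (drug, gene, sign) pair the IC50 vector is a Gaussian
    mixture of the standardised gene profile and independent noise with
    Pearson weight r = 2*sin(pi*planted_rho/6), which for jointly Gaussian
    data yields population Spearman correlation exactly ``planted_rho``
    (times the sign); the noise amplitude sqrt(1 - r^2) vanishes as
    planted_rho -> 1.  Non-planted drugs are pure independent noise, so
    their correlation with every gene is zero in population.
    """
    if expr.shape[1] != config.n_cell_lines:
        raise ValueError(
            f"expression matrix has {expr.shape[1]} cell lines, config says {config.n_cell_lines}"
        )
    absent = [g for _, g, _ in truth.planted_drug_pairs if g not in expr.index]
    if absent:
        raise ValueError(f"planted drug pairs reference absent genes: {absent}")
    rng = config.rng(3)
    planted = {d: (g, s) for d, g, s in truth.planted_drug_pairs}
    r = 2.0 * np.sin(np.pi * config.planted_rho / 6.0)
    rows = []
    for drug in config.drug_ids:
        z = rng.normal(size=config.n_cell_lines)
        if drug in planted:
            g, sign = planted[drug]
            gv = expr.loc[g].to_numpy(dtype=float)
            gstd = (gv - gv.mean()) / gv.std()
            rows.append(sign * r * gstd + np.sqrt(1.0 - r**2) * z)
        else:
            rows.append(z)
    ic50 = pd.DataFrame(rows, index=config.drug_ids, columns=expr.columns)
    if missing_rate > 0:
        mask = rng.random(ic50.shape) < missing_rate
        ic50 = ic50.mask(mask)
    return ic50


def _annotation(config: SimConfig, truth: GroundTruth, n_decoys: int = 25) -> dict[str, set[str]]:
    """Planted term over loop target genes plus random decoy terms."""
    rng = config.rng(4)
    universe = config.gene_ids
    ann: dict[str, set[str]] = {}
    planted_genes = sorted({f[2] for f in truth.planted_ffls})
    if planted_genes:
        ann[PLANTED_TERM] = set(planted_genes)
    for i in range(1, n_decoys + 1):
        size = int(rng.integers(10, 31))
        idx = rng.choice(len(universe), size=min(size, len(universe)), replace=False)
        ann[f"SYN_TERM_{i:02d}"] = {universe[j] for j in idx}
    return ann


def write_fixture(output_dir: str | Path, config: SimConfig) -> dict[str, Path]:
    """Simulate everything and write the full fixture to ``output_dir``.

    Returns a manifest of written paths.  Formats match the pipeline's
    readers: expression/IC50 TSVs, a sample-group TSV per modality, the
    edge-catalog TSV, a TF id list, a GMT annotation and the ground-truth
    JSON.
    """
    from . import io as rio

    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    catalog, truth = simulate_regulome(config)
    gene_mats, mirna_mats = simulate_expression(config, truth)
    cl_expr = simulate_cellline_expression(config)
    ic50 = simulate_drug_response(config, cl_expr, truth)
    ann = _annotation(config, truth)

    manifest: dict[str, Path] = {}

    def combined(mats: dict[str, ExpressionMatrix]) -> tuple[pd.DataFrame, pd.DataFrame]:
        values = pd.concat([mats[c].values for c in COMPARISONS], axis=1)
        rows = [
            {"sample_id": s, "group": mats[c].groups[s], "comparison": c}
            for c in COMPARISONS
            for s in mats[c].sample_ids
        ]
        return values, pd.DataFrame(rows)

    gene_values, gene_groups = combined(gene_mats)
    mirna_values, mirna_groups = combined(mirna_mats)

    manifest["gene_expression"] = rio.write_expression_tsv(gene_values, out / "gene_expression.tsv")
    manifest["gene_groups"] = rio.write_table(gene_groups, out / "gene_groups.tsv")
    manifest["mirna_expression"] = rio.write_expression_tsv(
        mirna_values, out / "mirna_expression.tsv", integer=True
    )
    manifest["mirna_groups"] = rio.write_table(mirna_groups, out / "mirna_groups.tsv")
    manifest["edge_catalog"] = rio.write_edge_catalog(catalog, out / "edge_catalog.tsv")
    manifest["tf_list"] = out / "tf_list.txt"
    manifest["tf_list"].write_text("".join(f"{t}\n" for t in config.tf_ids), encoding="utf-8")
    manifest["annotation"] = rio.write_gmt(ann, out / "annotation.gmt")
    manifest["cellline_expression"] = rio.write_expression_tsv(
        cl_expr, out / "cellline_expression.tsv"
    )
    manifest["ic50"] = rio.write_expression_tsv(ic50, out / "ic50.tsv", allow_na=True)
    manifest["ground_truth"] = out / "ground_truth.json"
    manifest["ground_truth"].write_text(truth.to_json() + "\n", encoding="utf-8")
    manifest["config"] = out / "sim_config.json"
    manifest["config"].write_text(
        json.dumps(asdict(config), indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
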