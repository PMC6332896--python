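"""Drug-sensitivity correlation screen.

For every (drug, gene) pair, the Spearman rank correlation between the
drug's IC50 profile and the gene's expression across shared cell lines is
computed; a pair is significant at the screen's strict double cutoff
|rho| > rho_min and p < p_max (defaults 0.4 and 1e-4).  A negative rho
means higher expression tracks lower IC50, i.e. greater sensitivity.

The p-value uses the t approximation
t = rho * sqrt((n - 2) / (1 - rho^2)) with n - 2 degrees of freedom,
standard for screens of this size; |rho| = 1 yields p = 0 by convention.
Missing IC50 values are handled by pairwise-complete deletion.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .regnet import RegNetwork

__all__ = ["DrugResponseMatrix", "spearman", "drug_gene_pairs", "drug_network"]


@dataclass
class DrugResponseMatrix:
    """Drugs x cell lines IC50 grid; NaN marks missing measurements."""

    values: pd.DataFrame  # index: drug ids, columns: cell-line ids

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("duplicate drug or cell-line ids")

    @property
    def drug_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_line_ids(self) -> list[str]:
        return list(self.values.columns)


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho and two-sided p for paired vectors.

    Pairs with a missing value in either vector are dropped; at least 3
    complete pairs are required.  Returns ``(nan, nan)`` when either
    vector has zero rank variance (all values tied).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    rx = stats.rankdata(x)  # average ranks for ties
    ry = stats.rankdata(y)
    sx = rx - rx.mean()
    sy = ry - ry.mean()
    denom = np.sqrt((sx**2).sum() * (sy**2).sum())
    if denom == 0:
        return float("nan"), float("nan")
    rho = float((sx * sy).sum() / denom)
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) >= 1.0 - 1e-13:
        return (1.0 if rho > 0 else -1.0), 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return rho, p


def drug_gene_pairs(
    ic50: DrugResponseMatrix,
    expr: pd.DataFrame,
    genes: set[str] | None = None,
    rho_min: float = 0.4,
    p_max: float = 1e-4,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Screen every drug against every requested gene.

    ``expr`` is a genes x cell-lines frame; only cell lines shared with the
    IC50 matrix are used, with pairwise-complete deletion per pair.  Output
    columns: ``drug_id, gene_id, n_used, rho, p, significant``, sorted by
    |rho| descending (ties by drug then gene).  Pairs with fewer than
    ``min_pairs`` complete observations or undefined rank variance are
    dropped.
    """
    shared = [c for c in ic50.values.columns if c in expr.columns]
    if len(shared) < min_pairs:
        raise ValueError(f"only {len(shared)} shared cell lines; need >= {min_pairs}")
    gene_ids = sorted(genes) if genes is not None else list(expr.index)
    missing = [g for g in gene_ids if g not in expr.index]
    if missing:
        raise ValueError(f"genes absent from expression matrix: {missing}")
    ic = ic50.values[shared]
    ex = expr.loc[gene_ids, shared]
    rows = []
    for drug in ic50.drug_ids:
        dvec = ic.loc[drug].to_numpy(dtype=float)
        for gene in gene_ids:
            gvec = ex.loc[gene].to_numpy(dtype=float)
            n_used = int((~(np.isnan(dvec) | np.isnan(gvec))).sum())
            if n_used < min_pairs:
                continue
            rho, p = spearman(dvec, gvec)
            if np.isnan(rho):
                continue
            rows.append(
                {
                    "drug_id": drug,
                    "gene_id": gene,
                    "n_used": n_used,
                    "rho": rho,
                    "p": p,
                    "significant": bool(abs(rho) > rho_min and p < p_max),
                }
            )
    df = pd.DataFrame(rows, columns=["drug_id", "gene_id", "n_used", "rho", "p", "significant"])
    if len(df):
        df = df.reindex(
            df.assign(_a=df["rho"].abs())
            .sort_values(["_a", "drug_id", "gene_id"], ascending=[False, True, True], kind="stable")
            .index
        ).reset_index(drop=True)
    return df


def drug_network(pairs: pd.DataFrame, net: RegNetwork) -> nx.Graph:
    """Bipartite drug-gene graph of significant pairs within the network.

    Genes absent from the regulatory network are excluded; edges carry the
    correlation sign (``positive``/``negative``) and rho, genes keep their
    differential-expression direction.
    """
    g = nx.Graph()
    net_nodes = set(net.graph.nodes)
    sig = pairs[pairs["significant"]]
    for row in sig.itertuples():
        if row.gene_id not in net_nodes:
            continue
        g.add_node(row.drug_id, node_class="drug")
        g.add_node(
            row.gene_id,
            node_class=net.node_class(row.gene_id),
            direction=net.direction(row.gene_id),
        )
        g.add_edge(
            row.drug_id,
            row.gene_id,
            rho=float(row.rho),
            sign="positive" if row.rho > 0 else "negative",
        )
    return g
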