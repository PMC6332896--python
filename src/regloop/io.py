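"""Plain-text file formats: expression/IC50 TSV, group maps, GMT, SIF, GraphML.

All writers are deterministic (sorted line order, fixed float formats) so
identical inputs give byte-identical files.  Data matrices are written at
12 significant digits to make write/read round trips faithful; derived
result tables use 6 significant digits.  Missing values are the literal
token ``NA``.
"""

from __future__ import annotations

import math
from pathlib import Path

import networkx as nx
import pandas as pd

from .diffexpr import ExpressionMatrix
from .regnet import RegNetwork, RegulatoryEdge

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_groups_tsv",
    "read_tf_list",
    "read_gmt",
    "write_gmt",
    "write_edge_catalog",
    "write_table",
    "write_sif",
    "write_graphml",
    "sif_relation",
]

NA = "NA"


def _fmt(x: float, digits: int = 12) -> str:
    if isinstance(x, float) and math.isnan(x):
        return NA
    return f"{x:.{digits}g}"


def read_expression_tsv(path: str | Path, modality: str = "intensity") -> pd.DataFrame:
    """Parse a feature x sample TSV (first column feature id, header samples).

    Count modality enforces non-negative integer cells.  Ragged rows,
    duplicate ids and non-numeric cells raise with the offending location.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ValueError(f"{path}:1: need a feature-id column plus >= 1 sample")
        samples = header[1:]
        if len(set(samples)) != len(samples):
            dups = sorted({s for s in samples if samples.count(s) > 1})
            raise ValueError(f"{path}:1: duplicate sample ids {dups}")
        features: list[str] = []
        rows: list[list[float]] = []
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} columns, got {len(parts)}"
                )
            fid = parts[0]
            if fid in seen:
                raise ValueError(f"{path}:{lineno}: duplicate feature id {fid!r}")
            seen.add(fid)
            vals = []
            for col, cell in zip(samples, parts[1:]):
                if cell == NA:
                    vals.append(float("nan"))
                    continue
                try:
                    v = float(cell)
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: non-numeric value {cell!r} in column {col}"
                    ) from None
                if modality == "count":
                    if v < 0 or v != int(v):
                        raise ValueError(
                            f"{path}:{lineno}: count modality requires non-negative "
                            f"integers, got {cell!r} in column {col}"
                        )
                vals.append(v)
            features.append(fid)
            rows.append(vals)
    df = pd.DataFrame(rows, index=features, columns=samples)
    if modality == "count":
        df = df.astype(int) if not df.isna().any().any() else df
    return df


def write_expression_tsv(
    values: pd.DataFrame,
    path: str | Path,
    integer: bool = False,
    allow_na: bool = False,
) -> Path:
    """Write a feature x sample matrix; feature order is preserved."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("feature_id\t" + "\t".join(str(c) for c in values.columns) + "\n")
        for fid, row in zip(values.index, values.to_numpy()):
            if integer:
                cells = [str(int(v)) for v in row]
            else:
                cells = [_fmt(float(v)) for v in row]
            if not allow_na and NA in cells:
                raise ValueError(f"missing value for feature {fid!r} but allow_na=False")
            fh.write(str(fid) + "\t" + "\t".join(cells) + "\n")
    return path


def read_groups_tsv(path: str | Path) -> dict[str, dict[str, str]]:
    """Sample-group map: columns sample_id, group, comparison.

    Returns ``{comparison: {sample_id: group}}``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group", "comparison"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}, got {list(df.columns)}")
    out: dict[str, dict[str, str]] = {}
    for row in df.itertuples():
        out.setdefault(row.comparison, {})[row.sample_id] = row.group
    return out


def split_comparisons(
    values: pd.DataFrame, groups: dict[str, dict[str, str]], modality: str
) -> dict[str, ExpressionMatrix]:
    """One ExpressionMatrix per comparison from a combined matrix + group map."""
    out = {}
    for comp in sorted(groups):
        samples = [s for s in values.columns if s in groups[comp]]
        out[comp] = ExpressionMatrix(values[samples], dict(groups[comp]), modality)
    return out


def read_tf_list(path: str | Path) -> set[str]:
    return {
        line.strip()
        for line in Path(path).read_text(encoding="utf-8").splitlines()
        if line.strip()
    }


def read_gmt(path: str | Path) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Parse a GMT file into (term -> gene set, term -> description)."""
    terms: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: GMT rows need term, description, >=1 gene")
        term, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
        if not genes:
            raise ValueError(f"{path}:{lineno}: term {term!r} has no genes")
        terms[term] = set(genes)
        names[term] = desc
    return terms, names


def write_gmt(annotation: dict[str, set[str]], path: str | Path,
              names: dict[str, str] | None = None) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for term in sorted(annotation):
            desc = (names or {}).get(term, term)
            fh.write("\t".join([term, desc] + sorted(annotation[term])) + "\n")
    return path


def write_edge_catalog(edges: list[RegulatoryEdge], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\tsource_class\ttarget_class\tevidence\n")
        for e in sorted(edges, key=lambda e: (e.source, e.target)):
            fh.write(f"{e.source}\t{e.target}\t{e.source_class}\t{e.target_class}\t{e.evidence}\n")
    return path


def write_table(df: pd.DataFrame, path: str | Path, digits: int = 6) -> Path:
    """Generic result-table TSV with fixed float formatting."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(str(c) for c in df.columns) + "\n")
        for row in df.itertuples(index=False):
            cells = [
                _fmt(v, digits) if isinstance(v, float) else str(v) for v in row
            ]
            fh.write("\t".join(cells) + "\n")
    return path


def sif_relation(source_class: str) -> str:
    if source_class == "TF":
        return "activates_tf"
    if source_class == "miRNA":
        return "targets_mirna"
    return "regulates"


def _as_digraph(graph: RegNetwork | nx.Graph | nx.DiGraph) -> nx.Graph | nx.DiGraph:
    return graph.graph if isinstance(graph, RegNetwork) else graph


def write_sif(graph: RegNetwork | nx.Graph | nx.DiGraph, path: str | Path) -> Path:
    """SIF export: one ``source<TAB>relation<TAB>target`` line per edge, sorted."""
    g = _as_digraph(graph)
    path = Path(path)
    lines = []
    for u, v in g.edges:
        cls = g.nodes[u].get("node_class", "gene")
        lines.append(f"{u}\t{sif_relation(cls)}\t{v}\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.writelines(sorted(lines))
    return path


def write_graphml(graph: RegNetwork | nx.Graph | nx.DiGraph, path: str | Path) -> Path:
    """GraphML export with node class/direction/degree and edge attributes.

    Nodes and edges are inserted in sorted order so output is deterministic.
    """
    g = _as_digraph(graph)
    out = nx.DiGraph() if g.is_directed() else nx.Graph()
    for n in sorted(g.nodes):
        attrs = {k: v for k, v in g.nodes[n].items() if v is not None}
        attrs.setdefault("degree", g.degree(n))
        out.add_node(n, **attrs)
    for u, v in sorted(g.edges):
        out.add_edge(u, v, **g.edges[u, v])
    path = Path(path)
    nx.write_graphml(out, path, named_key_ids=True)
    return path
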