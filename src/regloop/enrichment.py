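"""Hypergeometric over-representation analysis of gene sets.

A self-contained replacement for web-service enrichment tools: each
annotation term is tested with the upper-tail hypergeometric probability
P(X >= hits) of drawing the observed number of query genes from the term,
given the universe, followed by Benjamini-Hochberg correction across the
tested terms.  The plain tail is used, not the EASE-modified (hits - 1)
variant.  The universe defaults to the features actually measured (the
platform), not the genome.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

__all__ = ["hypergeom_test", "enrich"]


def hypergeom_test(hits: int, query_size: int, term_size: int, universe_size: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= hits).

    X ~ Hypergeometric(universe_size, term_size, query_size): the number of
    term genes in a uniform draw of ``query_size`` genes from the universe.
    """
    if not (0 <= hits <= min(query_size, term_size)):
        raise ValueError(f"hits={hits} inconsistent with query={query_size}, term={term_size}")
    if term_size > universe_size or query_size > universe_size:
        raise ValueError("term and query cannot exceed the universe")
    if hits == 0:
        return 1.0
    return float(stats.hypergeom.sf(hits - 1, universe_size, term_size, query_size))


def enrich(
    query: set[str],
    universe: set[str],
    annotation: dict[str, set[str]],
    term_names: dict[str, str] | None = None,
    min_term_size: int = 2,
) -> pd.DataFrame:
    """Over-representation of ``query`` in each annotation term.

    Annotation genes outside the universe are ignored; terms with fewer
    than ``min_term_size`` universe genes are skipped as unstable.  One row
    is returned per term with at least one query hit, BH-corrected across
    the tested terms and sorted by raw p then term id.
    """
    stray = query - universe
    if stray:
        raise ValueError(f"query genes outside universe: {sorted(stray)}")
    rows = []
    for term_id in sorted(annotation):
        term_genes = annotation[term_id] & universe
        if len(term_genes) < min_term_size:
            continue
        hits = len(query & term_genes)
        if hits == 0:
            continue
        p = hypergeom_test(hits, len(query), len(term_genes), len(universe))
        fold = (hits / len(query)) / (len(term_genes) / len(universe))
        rows.append(
            {
                "term_id": term_id,
                "name": (term_names or {}).get(term_id, term_id),
                "hits": hits,
                "query_size": len(query),
                "term_size": len(term_genes),
                "universe_size": len(universe),
                "fold_enrichment": fold,
                "p_raw": p,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["term_id", "name", "hits", "query_size", "term_size",
                 "universe_size", "fold_enrichment", "p_raw"],
    )
    if len(df):
        df["p_adj"] = bh_adjust(df["p_raw"].to_numpy())
        df = df.sort_values(["p_raw", "term_id"], kind="stable").reset_index(drop=True)
    else:
        df["p_adj"] = pd.Series(dtype=float)
    return df
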