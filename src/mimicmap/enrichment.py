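"""Gene-set over-representation analysis (hypergeometric / EASE).

For a query of n genes drawn from a universe of N, and a term covering K
universe genes of which k are in the query, the enrichment P value is the
hypergeometric upper tail P[X >= k].  EASE mode (the conservative variant
popularized by DAVID) removes one gene from the overlap before taking the
tail, penalizing single-gene overlaps.  BH FDR is applied within each
annotation category (pathway / MF / CC / BP), matching per-chart reporting.

The universe should be the set of genes actually measured in the
contributing datasets, not the whole genome.
"""

from __future__ import annotations

import logging
from typing import Iterable

import pandas as pd
from scipy.stats import hypergeom

from .diffexpr import bh_adjust
from .io_formats import GO_CATEGORIES, GeneSetCollection, normalize_symbol

__all__ = ["hypergeom_enrich", "select_top_terms", "ENRICHMENT_COLUMNS"]

logger = logging.getLogger(__name__)

ENRICHMENT_COLUMNS = ["term_id", "name", "category", "k", "K", "n", "N", "p", "fdr"]


def _normalize(genes: Iterable[str]) -> set[str]:
    return {normalize_symbol(g) for g in genes if str(g).strip()}


def hypergeom_enrich(query: Iterable[str], collection: GeneSetCollection,
                     universe: Iterable[str], mode: str = "ease") -> pd.DataFrame:
    """Score every term in the collection against the query.

    Query genes outside the universe are dropped (logged).  Returns one row
    per term with columns term_id, name, category, k, K, n, N, p, fdr —
    sorted by (category, p, -k, term_id).  ``mode="ease"`` computes the tail
    at max(k - 1, 0); ``mode="standard"`` at k.
    """
    if mode not in ("standard", "ease"):
        raise ValueError(f"mode must be standard|ease, got {mode!r}")
    universe_set = _normalize(universe)
    if not universe_set:
        raise ValueError("empty universe")
    query_set = _normalize(query)
    if not query_set:
        raise ValueError("empty query")
    outside = query_set - universe_set
    if outside:
        logger.info("enrichment: dropped %d query gene(s) outside the universe",
                    len(outside))
        query_set &= universe_set
    if not query_set:
        raise ValueError("no query genes inside the universe")
    N, n = len(universe_set), len(query_set)
    records = []
    for term_id in sorted(collection.sets):
        gs = collection.sets[term_id]
        members = gs.genes & universe_set
        K = len(members)
        k = len(members & query_set)
        k_eff = max(k - 1, 0) if mode == "ease" else k
        # upper tail P[X >= k_eff]; sf(k_eff - 1) == 1 when k_eff == 0
        p = float(hypergeom.sf(k_eff - 1, N, K, n))
        records.append((term_id, gs.name, gs.category, k, K, n, N, min(max(p, 0.0), 1.0)))
    out = pd.DataFrame(records, columns=ENRICHMENT_COLUMNS[:-1])
    out["fdr"] = 1.0
    for cat in GO_CATEGORIES:
        mask = out["category"] == cat
        if mask.any():
            out.loc[mask, "fdr"] = bh_adjust(out.loc[mask, "p"].to_numpy())
    out = out.sort_values(["category", "p", "k", "term_id"],
                          ascending=[True, True, False, True],
                          kind="mergesort").reset_index(drop=True)
    return out


def select_top_terms(rows: pd.DataFrame, p_max: float = 1e-4,
                     fdr_max: float = 0.25, n_pathway: int = 10,
                     n_go: int = 5) -> pd.DataFrame:
    """Apply the reporting thresholds: keep terms with p < p_max and
    fdr < fdr_max, then the top ``n_pathway`` pathways and top ``n_go`` terms
    per GO category by ascending p (ties: larger k, then term id).  An empty
    result is not an error."""
    passing = rows[(rows["p"] < p_max) & (rows["fdr"] < fdr_max)].copy()
    passing = passing.sort_values(["p", "k", "term_id"],
                                  ascending=[True, False, True], kind="mergesort")
    parts = []
    for cat in GO_CATEGORIES:
        limit = n_pathway if cat == "pathway" else n_go
        parts.append(passing[passing["category"] == cat].head(limit))
    return pd.concat(parts, ignore_index=True) if parts else passing
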