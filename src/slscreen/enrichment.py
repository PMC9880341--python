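"""Hypergeometric over-representation analysis of predicted partner sets.

Given a query gene set (e.g. the partners a screen nominated), each gene
set in a GMT collection is scored with the upper hypergeometric tail
against a stated universe, then Benjamini-Hochberg corrected across sets.
The universe should be the candidate space the screen actually tested, not
the whole genome — that is the sampling frame the null refers to.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .dataio import DataValidationError, GeneSetCollection
from .stats import bh_fdr, hypergeom_tail

logger = logging.getLogger("slscreen.enrichment")


@dataclass
class EnrichmentRow:
    set_name: str
    overlap: int  # k
    set_size: int  # K, restricted to the universe
    query_size: int  # n
    universe_size: int  # N
    p_value: float
    q_value: float = float("nan")
    overlapping_genes: tuple[str, ...] = ()
    shared_flag: bool = False  # significant for >= 2 query sets (multi mode)


def enrich(
    query_genes,
    collection: GeneSetCollection,
    universe,
) -> list[EnrichmentRow]:
    """Score every set; rows sorted by ascending q then p.

    Query genes outside the universe are dropped with a logged count; an
    empty query after restriction is an error.
    """
    universe = set(universe)
    if not universe:
        raise DataValidationError("empty universe")
    query = set(query_genes)
    dropped = len(query - universe)
    if dropped:
        logger.info("enrich: dropped %d query genes outside the universe",
                    dropped)
    query &= universe
    if not query:
        raise DataValidationError("no query genes inside the universe")

    rows = []
    for gs in collection:
        members = set(gs.genes) & universe
        overlap = sorted(query & members)
        p = hypergeom_tail(len(universe), len(members), len(query),
                           len(overlap))
        rows.append(EnrichmentRow(
            set_name=gs.name,
            overlap=len(overlap),
            set_size=len(members),
            query_size=len(query),
            universe_size=len(universe),
            p_value=p,
            overlapping_genes=tuple(overlap),
        ))
    q_vals = bh_fdr([r.p_value for r in rows])
    for r, qv in zip(rows, q_vals):
        r.q_value = float(qv)
    rows.sort(key=lambda r: (r.q_value, r.p_value, r.set_name))
    return rows


def enrich_multi(
    query_sets: dict[str, set],
    collection: GeneSetCollection,
    universe,
    alpha: float = 0.05,
) -> dict[str, list[EnrichmentRow]]:
    """Enrich several prediction approaches' query sets against one universe.

    Sets with p <= alpha in at least two query sets get ``shared_flag`` —
    the reporting convention for terms supported by multiple prediction
    approaches.
    """
    results = {name: enrich(genes, collection, universe)
               for name, genes in query_sets.items()}
    hits: dict[str, int] = {}
    for rows in results.values():
        for r in rows:
            if r.p_value <= alpha:
                hits[r.set_name] = hits.get(r.set_name, 0) + 1
    for rows in results.values():
        for r in rows:
            r.shared_flag = hits.get(r.set_name, 0) >= 2
    return results


def rows_to_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "set_name": r.set_name,
            "overlap": r.overlap,
            "set_size": r.set_size,
            "query_size": r.query_size,
            "universe_size": r.universe_size,
            "p_value": r.p_value,
            "q_value": r.q_value,
            "shared_flag": r.shared_flag,
            "overlapping_genes": ",".join(r.overlapping_genes),
        }
        for r in rows
    ])
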