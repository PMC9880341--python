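"""Conserved genetic interaction (CGI) workflow.

Negative genetic interactions — yeast double mutants whose fitness falls
below the multiplicative expectation of the single mutants (epsilon below a
negative cutoff, at a p-value cutoff) — are called from a pairwise SGA
table and transferred to human candidate synthetic-lethal pairs through a
yeast-to-human ortholog map.  One-to-many orthology expands as a
cross-product: the workflow is a candidate generator and downstream
evidence is expected to filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .dataio import (
    DataValidationError,
    OrthologMap,
    YeastInteractionTable,
    strip_strain_suffix,
)

logger = logging.getLogger("slscreen.cgi")

DEFAULT_EPS_MAX = -0.12
DEFAULT_P_MAX = 0.05


@dataclass(frozen=True)
class SourcePair:
    """Provenance: the yeast record(s) behind a human candidate pair."""

    query_gene: str
    array_gene: str
    epsilon: float
    p_value: float


@dataclass
class HumanSLPair:
    """Unordered human pair, canonicalized gene_a < gene_b."""

    gene_a: str
    gene_b: str
    source_pairs: list[SourcePair] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError("self-pair is not a synthetic-lethal candidate")
        if self.gene_a > self.gene_b:
            self.gene_a, self.gene_b = self.gene_b, self.gene_a

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


def filter_negative_interactions(
    table: YeastInteractionTable,
    eps_max: float = DEFAULT_EPS_MAX,
    p_max: float = DEFAULT_P_MAX,
) -> YeastInteractionTable:
    """Keep records with epsilon <= eps_max and p <= p_max.

    Duplicate records of an unordered yeast pair collapse to the one with
    the most negative epsilon.  ``eps_max`` must be negative: a non-negative
    cutoff contradicts the definition of a negative interaction.
    """
    if not eps_max < 0:
        raise DataValidationError(
            f"eps_max must be negative for negative interactions, got {eps_max}"
        )
    rec = table.records
    kept = rec[(rec["epsilon"] <= eps_max) & (rec["p_value"] <= p_max)].copy()
    a = kept["query_gene"].map(strip_strain_suffix)
    b = kept["array_gene"].map(strip_strain_suffix)
    kept["_pair"] = [tuple(sorted(t)) for t in zip(a, b)]
    kept = (
        kept.sort_values(["_pair", "epsilon"], kind="stable")
        .drop_duplicates("_pair", keep="first")
        .drop(columns="_pair")
        .reset_index(drop=True)
    )
    return YeastInteractionTable(kept)


def map_to_human(
    pairs: YeastInteractionTable,
    orthologs: OrthologMap,
    counts: dict | None = None,
) -> list[HumanSLPair]:
    """Expand each yeast pair to the cross-product of its members' orthologs.

    Yeast identifiers are stripped of strain/allele suffixes before lookup.
    Pairs with an unmapped member are dropped (counted), as are self-pairs
    arising after mapping.  Output pairs are unordered-deduplicated with
    merged provenance, sorted canonically.
    """
    stats = {"unmapped": 0, "self_pairs": 0}
    merged: dict[tuple[str, str], list[SourcePair]] = {}
    for row in pairs.records.itertuples(index=False):
        qy = strip_strain_suffix(row.query_gene)
        ay = strip_strain_suffix(row.array_gene)
        src = SourcePair(row.query_gene, row.array_gene,
                         float(row.epsilon), float(row.p_value))
        qh = orthologs.mapping.get(qy)
        ah = orthologs.mapping.get(ay)
        if not qh or not ah:
            stats["unmapped"] += 1
            continue
        for h1 in qh:
            for h2 in ah:
                if h1 == h2:
                    stats["self_pairs"] += 1
                    continue
                merged.setdefault(tuple(sorted((h1, h2))), []).append(src)
    if stats["unmapped"]:
        logger.info("map_to_human: %d yeast pairs had an unmapped member",
                    stats["unmapped"])
    if counts is not None:
        counts.update(stats)
    out = [
        HumanSLPair(a, b, source_pairs=list(dict.fromkeys(srcs)))
        for (a, b), srcs in sorted(merged.items())
    ]
    return out


def cgi_predict(
    table: YeastInteractionTable,
    orthologs: OrthologMap,
    eps_max: float = DEFAULT_EPS_MAX,
    p_max: float = DEFAULT_P_MAX,
    counts: dict | None = None,
) -> list[HumanSLPair]:
    """Filter negative interactions, then map to human candidate pairs."""
    surviving = filter_negative_interactions(table, eps_max=eps_max, p_max=p_max)
    return map_to_human(surviving, orthologs, counts=counts)


def pairs_to_frame(pairs: list[HumanSLPair]) -> pd.DataFrame:
    """Tabulate candidate pairs with provenance summary columns."""
    rows = []
    for p in pairs:
        eps = [s.epsilon for s in p.source_pairs]
        rows.append({
            "gene_a": p.gene_a,
            "gene_b": p.gene_b,
            "n_source_pairs": len(p.source_pairs),
            "min_epsilon": min(eps),
            "source_pairs": ";".join(
                f"{s.query_gene}|{s.array_gene}|{s.epsilon:g}|{s.p_value:g}"
                for s in p.source_pairs
            ),
        })
    return pd.DataFrame(
        rows,
        columns=["gene_a", "gene_b", "n_source_pairs", "min_epsilon",
                 "source_pairs"],
    )
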