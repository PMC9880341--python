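"""Binary molecular-state calls that condition the screening tests.

Three masks are derived from the omics layers: functional mutation (a
damaging variant class observed for the sample/gene), inactivation
(functional mutation OR jointly low expression and copy number), and
overactivation (jointly high expression and copy number).  Each mask
carries provenance sufficient to recompute it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import DataValidationError, MutationCatalog, OmicsMatrix

logger = logging.getLogger("slscreen.states")

#: MAF variant classes treated as altering protein expression or structure.
#: Silent, UTR, intronic and intergenic classes are deliberately excluded.
DEFAULT_DAMAGING_CLASSES = frozenset({
    "Nonsense_Mutation",
    "Missense_Mutation",
    "Frame_Shift_Del",
    "Frame_Shift_Ins",
    "Splice_Site",
    "Nonstop_Mutation",
    "Start_Codon_SNP",
    "Start_Codon_Del",
    "Start_Codon_Ins",
    "De_novo_Start_OutOfFrame",
})


@dataclass
class StateMatrix:
    """Boolean sample x gene matrix of molecular-state calls."""

    data: pd.DataFrame  # bool, index=samples, columns=genes
    state_kind: str  # functional_mutation | inactive | overactive
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.state_kind not in ("functional_mutation", "inactive", "overactive"):
            raise ValueError(f"unknown state_kind {self.state_kind!r}")
        self.data = self.data.astype(bool)

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def genes(self) -> list[str]:
        return list(self.data.columns)

    def column(self, gene: str) -> pd.Series:
        return self.data[gene]


def functional_mutation_mask(
    catalog: MutationCatalog,
    samples,
    genes,
    damaging_classes=DEFAULT_DAMAGING_CLASSES,
) -> StateMatrix:
    """True where a sample carries >= 1 damaging-class record for a gene.

    Records outside the (samples, genes) universe are ignored with a logged
    count; duplicate records collapse to a single event.
    """
    damaging = frozenset(damaging_classes)
    if not damaging:
        raise DataValidationError("damaging_classes must be non-empty")
    samples = list(samples)
    genes = list(genes)
    mask = pd.DataFrame(False, index=samples, columns=genes)
    rec = catalog.records
    functional = rec[rec["variant_classification"].isin(damaging)]
    in_universe = functional["sample"].isin(mask.index) & functional["gene"].isin(
        mask.columns
    )
    ignored = int((~in_universe).sum())
    if ignored:
        logger.info(
            "functional_mutation_mask: %d records outside the cohort universe",
            ignored,
        )
    hits = functional[in_universe]
    if len(hits):
        mask.values[
            mask.index.get_indexer(hits["sample"]),
            mask.columns.get_indexer(hits["gene"]),
        ] = True
    return StateMatrix(
        mask,
        "functional_mutation",
        provenance={"damaging_classes": sorted(damaging)},
    )


def _aligned(expr: OmicsMatrix, cn: OmicsMatrix, extra_samples=None):
    samples = expr.data.index.intersection(cn.data.index)
    if extra_samples is not None:
        samples = samples.intersection(pd.Index(extra_samples))
    genes = expr.data.columns.intersection(cn.data.columns)
    if len(samples) == 0:
        raise DataValidationError("no samples shared across the state inputs")
    if len(genes) == 0:
        raise DataValidationError("no genes shared across the state inputs")
    dropped = max(len(expr.data.index), len(cn.data.index)) - len(samples)
    if dropped:
        logger.info("state mask: intersection dropped up to %d samples", dropped)
    return samples, genes


def _percentile_cutoffs(values: np.ndarray, percentile: float) -> np.ndarray:
    # per-gene linear-interpolation percentile over non-missing entries;
    # all-missing columns get a NaN cutoff, which no comparison satisfies
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanpercentile(values, percentile, axis=0)


def inactivation_mask(
    expr: OmicsMatrix,
    cn: OmicsMatrix,
    mut: StateMatrix | None,
    expr_percentile: float = 10.0,
    cn_max: float = -0.3,
) -> StateMatrix:
    """Call a gene inactive in a sample.

    A cell is inactive iff the sample has a functional mutation of the gene,
    OR its expression is strictly below the gene's ``expr_percentile``
    percentile (computed across the analyzed samples) AND its copy-number
    ratio is below ``cn_max``.  Missing omics values never satisfy a clause.
    """
    samples, genes = _aligned(expr, cn)
    e = expr.data.loc[samples, genes].to_numpy()
    c = cn.data.loc[samples, genes].to_numpy()
    cutoffs = _percentile_cutoffs(e, expr_percentile)
    with np.errstate(invalid="ignore"):
        low = (e < cutoffs) & (c < cn_max)
    mask = pd.DataFrame(low, index=samples, columns=genes)
    if mut is not None:
        m = mut.data.reindex(index=samples, columns=genes, fill_value=False)
        mask |= m
    return StateMatrix(
        mask,
        "inactive",
        provenance={
            "expr_percentile": expr_percentile,
            "cn_max": cn_max,
            "with_mutations": mut is not None,
        },
    )


def overactivation_mask(
    expr: OmicsMatrix,
    cn: OmicsMatrix,
    expr_percentile: float = 10.0,
    cn_min: float = 0.3,
) -> StateMatrix:
    """Call a gene overactive: expression strictly above the
    (100 - expr_percentile) percentile AND copy number above ``cn_min``."""
    samples, genes = _aligned(expr, cn)
    e = expr.data.loc[samples, genes].to_numpy()
    c = cn.data.loc[samples, genes].to_numpy()
    cutoffs = _percentile_cutoffs(e, 100.0 - expr_percentile)
    with np.errstate(invalid="ignore"):
        high = (e > cutoffs) & (c > cn_min)
    return StateMatrix(
        pd.DataFrame(high, index=samples, columns=genes),
        "overactive",
        provenance={"expr_percentile": expr_percentile, "cn_min": cn_min},
    )
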