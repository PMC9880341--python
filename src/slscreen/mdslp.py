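"""Mutation-dependent synthetic lethality prediction (MDSLP).

For a mutated query gene, a candidate partner supports a synthetic-lethal
interaction when knocking it out (CRISPR) or knocking it down (shRNA) is
significantly more damaging in query-mutant cell lines than in wild-type
lines.  Each (query, partner, context, dataset) combination is a two-sided
Welch t-test on the partner's gene-effect scores stratified by functional
mutation status of the query; negative delta (mutant mean minus wild-type
mean) supports synthetic lethality.  Benjamini-Hochberg correction runs
within each (context, dataset) family.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .dataio import (
    DataValidationError,
    MutationCatalog,
    OmicsMatrix,
    PredictionRecord,
    SampleAnnotation,
)
from .states import DEFAULT_DAMAGING_CLASSES, StateMatrix, functional_mutation_mask
from .stats import welch_t_test

logger = logging.getLogger("slscreen.mdslp")

PAN_CANCER = "pan-cancer"


@dataclass
class MdslpResult:
    """One mutation-stratified differential-dependency test."""

    mutated_gene: str
    partner_gene: str
    context: str
    dataset_label: str
    t_statistic: float = math.nan
    delta: float = math.nan  # mean effect(mutant) - mean effect(wild-type)
    p_value: float = math.nan
    q_value: float = math.nan
    n_mutant: int = 0
    n_wildtype: int = 0
    testable: bool = True
    significant: bool = False
    reason: str = ""


def _untestable(mut_gene, partner, context, label, reason, n_mut=0, n_wt=0):
    return MdslpResult(mut_gene, partner, context, label, n_mutant=n_mut,
                       n_wildtype=n_wt, testable=False, reason=reason)


def mdslp_test(
    mut_gene: str,
    partner: str,
    mut_mask: StateMatrix,
    effect: OmicsMatrix,
    context: str | None = None,
    annotation: SampleAnnotation | None = None,
    min_mut: int = 3,
    min_wt: int = 3,
    dataset_label: str = "",
) -> MdslpResult:
    """Welch t-test of partner gene effect, mutant vs wild-type for the query.

    ``context`` (a cancer-type label) restricts the cohort via ``annotation``
    before stratification; ``None`` or "pan-cancer" uses all lines.
    """
    ctx = context if context not in (None, PAN_CANCER) else PAN_CANCER
    if mut_gene not in mut_mask.data.columns:
        return _untestable(mut_gene, partner, ctx, dataset_label,
                           "query absent from mutation mask")
    if partner not in effect.data.columns:
        return _untestable(mut_gene, partner, ctx, dataset_label,
                           "partner absent from gene-effect matrix")
    samples = mut_mask.data.index.intersection(effect.data.index)
    if ctx != PAN_CANCER:
        if annotation is None:
            raise DataValidationError("context filtering requires an annotation")
        samples = samples.intersection(annotation.samples_for(ctx))
    flags = mut_mask.data.loc[samples, mut_gene].to_numpy()
    values = effect.data.loc[samples, partner].to_numpy()
    ok = np.isfinite(values)
    flags, values = flags[ok], values[ok]
    mut_vals = values[flags]
    wt_vals = values[~flags]
    if mut_vals.size < min_mut or wt_vals.size < min_wt:
        return _untestable(
            mut_gene, partner, ctx, dataset_label,
            f"group sizes {mut_vals.size}/{wt_vals.size} below "
            f"{min_mut}/{min_wt}",
            n_mut=int(mut_vals.size), n_wt=int(wt_vals.size),
        )
    res = welch_t_test(mut_vals, wt_vals, alternative="two_sided")
    return MdslpResult(
        mutated_gene=mut_gene,
        partner_gene=partner,
        context=ctx,
        dataset_label=dataset_label,
        t_statistic=res.statistic,
        delta=float(np.mean(mut_vals) - np.mean(wt_vals)),
        p_value=res.p_value,
        n_mutant=int(mut_vals.size),
        n_wildtype=int(wt_vals.size),
    )


def mdslp_screen(
    mut_genes,
    partners,
    mutations: MutationCatalog | StateMatrix,
    effects: dict[str, OmicsMatrix],
    annotation: SampleAnnotation | None = None,
    contexts=None,
    q_threshold: float = 0.05,
    min_mut: int = 3,
    min_wt: int = 3,
    damaging_classes=DEFAULT_DAMAGING_CLASSES,
) -> list[MdslpResult]:
    """Screen all (query, partner, context, dataset) combinations.

    ``mutations`` may be a raw catalog (a functional-mutation mask is built
    per dataset universe) or a precomputed mask.  ``contexts`` defaults to
    the pan-cancer analysis only.  BH-FDR runs within each (context,
    dataset) family over testable results, and ``significant`` flags
    q <= q_threshold.
    """
    from .stats import bh_fdr  # local import keeps module load cheap

    queries = sorted(dict.fromkeys(mut_genes))
    cands = sorted(dict.fromkeys(partners))
    ctxs = list(contexts) if contexts else [PAN_CANCER]
    if annotation is not None:
        known = set(annotation.mapping.unique()) | {PAN_CANCER}
        unknown = [c for c in ctxs if c not in known]
        if unknown:
            raise DataValidationError(
                f"unknown contexts {unknown}; known: {sorted(known)}"
            )
    elif any(c != PAN_CANCER for c in ctxs):
        raise DataValidationError("named contexts require a sample annotation")

    results: list[MdslpResult] = []
    for label, effect in effects.items():
        if isinstance(mutations, StateMatrix):
            mask = mutations
        else:
            mask = functional_mutation_mask(
                mutations, effect.data.index, queries,
                damaging_classes=damaging_classes,
            )
        for ctx in ctxs:
            for q in queries:
                for p in cands:
                    if p == q:
                        continue
                    results.append(mdslp_test(
                        q, p, mask, effect, context=ctx,
                        annotation=annotation, min_mut=min_mut,
                        min_wt=min_wt, dataset_label=label,
                    ))

    by_family: dict = {}
    for i, r in enumerate(results):
        if r.testable:
            by_family.setdefault((r.context, r.dataset_label), []).append(i)
    for idx in by_family.values():
        q_vals = bh_fdr([results[i].p_value for i in idx])
        for i, qv in zip(idx, q_vals):
            results[i].q_value = float(qv)
            results[i].significant = bool(qv <= q_threshold)
    return results


def result_records(results) -> list[PredictionRecord]:
    """Flatten screen results to the shared prediction-table schema."""
    return [
        PredictionRecord(
            query_gene=r.mutated_gene,
            partner_gene=r.partner_gene,
            workflow="mdslp",
            module="welch_t",
            dataset_label=r.dataset_label,
            context=r.context,
            statistic=r.t_statistic,
            effect_size=r.delta,
            p_value=r.p_value,
            q_value=r.q_value,
            n_query_group=r.n_mutant,
            n_other_group=r.n_wildtype,
            passed=r.significant,
        )
        for r in results
    ]
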