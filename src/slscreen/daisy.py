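"""The DAISY screen: three inference procedures and their intersection.

DAISY nominates a synthetic-lethal (SL) pair when all three of its modules
agree, each on at least one dataset:

* survival of the fittest (``sof``): partner copy number is tested higher in
  samples where the query is inactivated — surviving tumors tolerate losing
  one member of an SL pair, not both, so co-loss is depleted;
* functional examination (``funex``): partner gene-effect scores are tested
  lower (more essential) in cell lines where the query is inactivated;
* pairwise co-expression: the pair must be significantly positively
  correlated.

Synthetic dosage lethality (SDL) mode conditions SoF and FunEx on
overactivation of the query instead and flips the SoF alternative (extra
partner dosage, not depleted loss, is then the expected footprint);
co-expression is unchanged.  Screens run pan-cancer or restricted to one
cancer type, and correct for multiple testing per (module, dataset) family.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .dataio import Cohort, DataValidationError, OmicsMatrix, PredictionRecord
from .states import (
    DEFAULT_DAMAGING_CLASSES,
    StateMatrix,
    functional_mutation_mask,
    inactivation_mask,
    overactivation_mask,
)
from .stats import TestResult, bh_fdr, rank_sum_test, spearman_test

logger = logging.getLogger("slscreen.daisy")

MODULES = ("sof", "funex", "coexpression")


@dataclass
class ModuleEvidence:
    """One module's test of one pair on one dataset."""

    query_gene: str
    partner_gene: str
    module: str  # sof | funex | coexpression
    dataset_label: str
    result: TestResult | None
    effect_size: float = math.nan  # rho (coexpression) or rank-biserial r
    q_value: float = math.nan
    n_query_group: int = 0
    n_other_group: int = 0
    testable: bool = True
    reason: str = ""

    @property
    def p_value(self) -> float:
        return self.result.p_value if self.result is not None else math.nan


@dataclass
class DaisyPrediction:
    """Per-pair verdict: module pass flags and the all-module intersection."""

    query_gene: str
    partner_gene: str
    mode: str  # SL | SDL
    evidence: list[ModuleEvidence] = field(default_factory=list)
    pass_flags: dict = field(default_factory=dict)  # module -> bool
    testable_flags: dict = field(default_factory=dict)  # module -> bool
    combined: bool = False
    lenient: bool = False


def _untestable(query, partner, module, label, reason) -> ModuleEvidence:
    return ModuleEvidence(query, partner, module, label, result=None,
                          testable=False, reason=reason)


def _rank_biserial(result: TestResult) -> float:
    # r = 2U/(n_a n_b) - 1 from the rank-sum statistic of group a
    n_a, n_b = result.n_a, result.n_b
    u = result.statistic - n_a * (n_a + 1) / 2.0
    return 2.0 * u / (n_a * n_b) - 1.0


def _conditioned_rank_sum(
    query: str,
    partner: str,
    state: StateMatrix,
    matrix: OmicsMatrix,
    module: str,
    dataset_label: str,
    alternative: str,
    min_group: int,
) -> ModuleEvidence:
    if query not in state.data.columns:
        return _untestable(query, partner, module, dataset_label,
                           "query absent from state matrix")
    if partner not in matrix.data.columns:
        return _untestable(query, partner, module, dataset_label,
                           f"partner absent from {matrix.role.value} matrix")
    samples = state.data.index.intersection(matrix.data.index)
    flags = state.data.loc[samples, query].to_numpy()
    values = matrix.data.loc[samples, partner].to_numpy()
    ok = np.isfinite(values)
    flags, values = flags[ok], values[ok]
    in_state = values[flags]
    out_state = values[~flags]
    if in_state.size < min_group or out_state.size < min_group:
        return _untestable(
            query, partner, module, dataset_label,
            f"group sizes {in_state.size}/{out_state.size} below {min_group}",
        )
    res = rank_sum_test(in_state, out_state, alternative=alternative)
    return ModuleEvidence(
        query, partner, module, dataset_label, result=res,
        effect_size=_rank_biserial(res),
        n_query_group=in_state.size, n_other_group=out_state.size,
    )


def sof_test(
    query: str,
    partner: str,
    state: StateMatrix,
    cn: OmicsMatrix,
    alternative: str = "greater",
    min_group: int = 3,
    dataset_label: str = "",
) -> ModuleEvidence:
    """Survival-of-the-fittest: partner copy number conditioned on query state.

    SL: one-sided "greater" — partner copy number is higher where the query
    is inactive, i.e. co-loss is depleted in the surviving population.
    """
    return _conditioned_rank_sum(query, partner, state, cn, "sof",
                                 dataset_label, alternative, min_group)


def funex_test(
    query: str,
    partner: str,
    state: StateMatrix,
    effect: OmicsMatrix,
    alternative: str = "less",
    min_group: int = 3,
    dataset_label: str = "",
) -> ModuleEvidence:
    """Functional examination: partner gene effect conditioned on query state.

    One-sided "less": lower effect score means more essential, so SL partners
    drop when the query is inactive (SL) or overactive (SDL).
    """
    return _conditioned_rank_sum(query, partner, state, effect, "funex",
                                 dataset_label, alternative, min_group)


def coexpression_test(
    query: str,
    partner: str,
    expr: OmicsMatrix,
    min_pairs: int = 10,
    dataset_label: str = "",
) -> ModuleEvidence:
    """Pairwise co-expression: one-sided Spearman for positive correlation."""
    for g in (query, partner):
        if g not in expr.data.columns:
            return _untestable(query, partner, "coexpression", dataset_label,
                               f"{g} absent from expression matrix")
    x = expr.data[query].to_numpy()
    y = expr.data[partner].to_numpy()
    complete = int((np.isfinite(x) & np.isfinite(y)).sum())
    if complete < min_pairs:
        return _untestable(query, partner, "coexpression", dataset_label,
                           f"{complete} complete pairs below {min_pairs}")
    res = spearman_test(x, y, alternative="greater")
    return ModuleEvidence(
        query, partner, "coexpression", dataset_label, result=res,
        effect_size=res.statistic, n_query_group=complete,
        n_other_group=complete,
    )


def _normalize_thresholds(thresholds) -> dict:
    if thresholds is None:
        thresholds = 0.05
    if isinstance(thresholds, (int, float)):
        return {m: float(thresholds) for m in MODULES}
    out = {m: 0.05 for m in MODULES}
    for m, v in dict(thresholds).items():
        if m not in MODULES:
            raise ValueError(f"unknown DAISY module {m!r}")
        out[m] = float(v)
    return out


def _condition_state(cohort: Cohort, mode: str, expr_percentile, cn_max, cn_min,
                     damaging_classes) -> StateMatrix | None:
    if cohort.expression is None or cohort.copy_number is None:
        return None
    if mode == "SDL":
        return overactivation_mask(cohort.expression, cohort.copy_number,
                                   expr_percentile=expr_percentile,
                                   cn_min=cn_min)
    mut = None
    if cohort.mutations is not None:
        samples = cohort.expression.data.index.intersection(
            cohort.copy_number.data.index
        )
        genes = cohort.expression.data.columns.intersection(
            cohort.copy_number.data.columns
        )
        mut = functional_mutation_mask(cohort.mutations, samples, genes,
                                       damaging_classes)
    return inactivation_mask(cohort.expression, cohort.copy_number, mut,
                             expr_percentile=expr_percentile, cn_max=cn_max)


def daisy_screen(
    query_genes,
    candidate_partners,
    cohorts,
    mode: str = "SL",
    thresholds=None,
    context: str | None = None,
    min_group: int = 3,
    min_pairs: int = 10,
    strict: bool = True,
    expr_percentile: float = 10.0,
    cn_max: float = -0.3,
    cn_min: float = 0.3,
    damaging_classes=DEFAULT_DAMAGING_CLASSES,
) -> list[DaisyPrediction]:
    """Run the three DAISY modules over every query/partner pair.

    Each cohort contributes whichever modules its layers support (SoF needs
    expression+copy number [+ mutations], FunEx additionally a gene-effect
    matrix, co-expression only expression).  BH-FDR is applied within each
    (module, dataset) family; a module passes for a pair when any dataset's
    q-value is at or below that module's cutoff; ``combined`` requires all
    three modules.  In strict mode a module with no testable dataset fails
    the combination; in lenient mode it is skipped and the prediction
    flagged.
    """
    if mode not in ("SL", "SDL"):
        raise ValueError(f"mode must be SL or SDL, got {mode!r}")
    cutoffs = _normalize_thresholds(thresholds)
    queries = sorted(dict.fromkeys(query_genes))
    partners = sorted(dict.fromkeys(candidate_partners))
    if isinstance(cohorts, Cohort):
        cohorts = [cohorts]

    evidence: list[ModuleEvidence] = []
    for cohort in cohorts:
        if context is not None:
            if cohort.annotation is None:
                raise DataValidationError(
                    f"cohort {cohort.label!r} has no annotation for context filtering"
                )
            cohort = cohort.restrict_samples(cohort.annotation.samples_for(context))
        state = _condition_state(cohort, mode, expr_percentile, cn_max, cn_min,
                                 damaging_classes)
        sof_alt = "greater" if mode == "SL" else "less"
        for q in queries:
            for p in partners:
                if p == q:
                    continue
                if state is not None and cohort.copy_number is not None:
                    evidence.append(sof_test(q, p, state, cohort.copy_number,
                                             alternative=sof_alt,
                                             min_group=min_group,
                                             dataset_label=cohort.label))
                if state is not None and cohort.gene_effect is not None:
                    evidence.append(funex_test(q, p, state, cohort.gene_effect,
                                               min_group=min_group,
                                               dataset_label=cohort.label))
                if cohort.expression is not None:
                    evidence.append(coexpression_test(q, p, cohort.expression,
                                                      min_pairs=min_pairs,
                                                      dataset_label=cohort.label))

    # BH within each (module, dataset) family, over testable evidence only
    by_family: dict = {}
    for i, ev in enumerate(evidence):
        if ev.testable:
            by_family.setdefault((ev.module, ev.dataset_label), []).append(i)
    for idx in by_family.values():
        q_vals = bh_fdr([evidence[i].p_value for i in idx])
        for i, qv in zip(idx, q_vals):
            evidence[i].q_value = float(qv)

    predictions: list[DaisyPrediction] = []
    testable_any = sum(ev.testable for ev in evidence)
    if testable_any == 0:
        logger.warning("daisy_screen: no testable pair in any cohort")
    grouped: dict = {}
    for ev in evidence:
        grouped.setdefault((ev.query_gene, ev.partner_gene), []).append(ev)
    for q in queries:
        for p in partners:
            if p == q:
                continue
            evs = grouped.get((q, p), [])
            pass_flags, testable_flags = {}, {}
            for m in MODULES:
                mod_evs = [e for e in evs if e.module == m and e.testable]
                testable_flags[m] = bool(mod_evs)
                pass_flags[m] = any(e.q_value <= cutoffs[m] for e in mod_evs)
            if strict:
                combined = all(pass_flags[m] for m in MODULES)
                lenient_used = False
            else:
                applicable = [m for m in MODULES if testable_flags[m]]
                combined = bool(applicable) and all(
                    pass_flags[m] for m in applicable
                )
                lenient_used = len(applicable) < len(MODULES)
            predictions.append(DaisyPrediction(
                query_gene=q, partner_gene=p, mode=mode, evidence=evs,
                pass_flags=pass_flags, testable_flags=testable_flags,
                combined=combined, lenient=lenient_used,
            ))
    return predictions


def evidence_records(predictions, context: str | None = None) -> list[PredictionRecord]:
    """Flatten screen evidence to the shared prediction-table schema."""
    ctx = context if context is not None else "pan-cancer"
    records = []
    for pred in predictions:
        for ev in pred.evidence:
            records.append(PredictionRecord(
                query_gene=ev.query_gene,
                partner_gene=ev.partner_gene,
                workflow=f"daisy-{pred.mode}",
                module=ev.module,
                dataset_label=ev.dataset_label,
                context=ctx,
                statistic=(ev.result.statistic if ev.result else math.nan),
                effect_size=ev.effect_size,
                p_value=ev.p_value,
                q_value=ev.q_value,
                n_query_group=ev.n_query_group,
                n_other_group=ev.n_other_group,
                passed=pred.pass_flags.get(ev.module, False),
            ))
    return records
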