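"""Seeded generators for synthetic cohorts and yeast screens.

The cohort generator plants ground-truth synthetic-lethal pairs carrying the
three statistical footprints the screens look for:

* dependency: the partner's gene-effect score is shifted down by the
  dependency shift (delta) in samples where the query is inactivated
  (functionally mutated, or lowly expressed with copy loss);
* co-expression: query and partner expression share a latent factor tuned
  to a target correlation rho;
* co-loss depletion: the joint probability of copy-losing both members is
  multiplied by (1 - depletion), with the partner's marginal loss rate
  preserved.

Background genes are independent of everything, so null screens are
calibrated by construction.  All randomness flows from one seeded
``numpy.random.Generator`` with a fixed draw order, making cohorts
bit-reproducible from (parameters, seed).

The yeast-screen generator emulates a pairwise SGA interaction table with a
chosen number of planted negative interactions; array identifiers carry an
allele suffix as real SGA tables do.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .dataio import (
    Cohort,
    MutationCatalog,
    OmicsMatrix,
    OrthologMap,
    Role,
    SampleAnnotation,
    YeastInteractionTable,
)
from .states import DEFAULT_DAMAGING_CLASSES


@dataclass(frozen=True)
class PlantedPair:
    """Ground truth for one planted pair and its effect parameters."""

    query: str
    partner: str
    dependency_shift: float
    coexpression_rho: float
    co_loss_depletion: float
    mutation_rate: float


@dataclass
class CohortParams:
    """Knobs of the cohort generator.

    Defaults encode the strong-signal regime of the planted pairs (delta of
    one gene-effect unit against 0.3 residual noise, rho 0.7, 90% co-loss
    depletion, 20% query mutation rate) at a 500-line cohort; background
    layers mimic log-scale expression around 8 +/- 1, copy-number log ratios
    around 0 with occasional deep losses, and gene effects around 0.
    """

    n_samples: int = 500
    n_genes: int = 50
    n_planted_pairs: int = 1
    mutation_rate: float = 0.2
    dependency_shift: float = 1.0  # gene-effect units, applied as -delta
    noise_sd: float = 0.3  # gene-effect residual sd
    coexpression_rho: float = 0.7
    co_loss_depletion: float = 0.9
    n_contexts: int = 4
    seed: int = 0
    # background layer parameters
    expr_mean: float = 8.0
    expr_sd: float = 1.0
    cn_sd: float = 0.15
    loss_rate: float = 0.30  # per-gene copy-loss probability
    loss_cn_mean: float = -0.8
    loss_cn_sd: float = 0.2
    dosage_effect: float = 1.2  # expression drop (in sd units x expr_sd) on loss
    silent_decoy_rate: float = 0.05  # samples given a Silent decoy record

    def validate(self) -> None:
        for name in ("mutation_rate", "coexpression_rho", "co_loss_depletion",
                     "loss_rate", "silent_decoy_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_samples < 1:
            raise ValueError(f"n_samples must be positive, got {self.n_samples}")
        if self.n_genes < 2:
            raise ValueError(f"n_genes must be >= 2, got {self.n_genes}")
        if self.n_planted_pairs < 0 or self.n_planted_pairs > self.n_genes // 2:
            raise ValueError(
                f"n_planted_pairs must lie in [0, n_genes/2], "
                f"got {self.n_planted_pairs}"
            )
        if not self.noise_sd > 0:
            raise ValueError(f"noise_sd must be positive, got {self.noise_sd}")
        if self.n_contexts < 1:
            raise ValueError(f"n_contexts must be >= 1, got {self.n_contexts}")


def null_params(seed: int, n_samples: int = 200, n_genes: int = 50,
                n_planted_pairs: int = 1) -> CohortParams:
    """A cohort whose planted pairs carry no signal at all."""
    return CohortParams(
        n_samples=n_samples, n_genes=n_genes,
        n_planted_pairs=n_planted_pairs, dependency_shift=0.0,
        coexpression_rho=0.0, co_loss_depletion=0.0, seed=seed,
    )


def strong_signal_params(seed: int, n_samples: int = 500, n_genes: int = 50,
                         n_planted_pairs: int = 5) -> CohortParams:
    """The strong-signal preset: delta 1.0, sd 0.3, rho 0.7, depletion 0.9."""
    return CohortParams(
        n_samples=n_samples, n_genes=n_genes,
        n_planted_pairs=n_planted_pairs, seed=seed,
    )


@dataclass
class SyntheticCohort(Cohort):
    """A generated cohort bundle plus its ground truth."""

    truth: list = field(default_factory=list)
    params: CohortParams | None = None
    seed: int = 0

    @property
    def planted_queries(self) -> list[str]:
        return [t.query for t in self.truth]

    @property
    def planted_partners(self) -> list[str]:
        return [t.partner for t in self.truth]


def generate_cohort(params: CohortParams) -> SyntheticCohort:
    """Generate a reproducible cohort with planted SL structure."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    n, g = params.n_samples, params.n_genes
    samples = [f"S{i:04d}" for i in range(n)]
    genes = [f"G{i:03d}" for i in range(g)]
    pairs = [(genes[2 * i], genes[2 * i + 1], 2 * i, 2 * i + 1)
             for i in range(params.n_planted_pairs)]

    # 1. functional mutations of planted queries
    qmut = rng.random((n, params.n_planted_pairs)) < params.mutation_rate

    # 2. copy-loss indicators and the two candidate value layers
    loss = rng.random((n, g)) < params.loss_rate
    cn_normal = rng.normal(0.0, params.cn_sd, size=(n, g))
    cn_deep = rng.normal(params.loss_cn_mean, params.loss_cn_sd, size=(n, g))

    # 3. latent expression: shared factor couples each planted pair at rho
    base = rng.standard_normal((n, g))
    rho = params.coexpression_rho
    for k, (_, _, qi, pi) in enumerate(pairs):
        z = rng.standard_normal(n)
        for col in (qi, pi):
            base[:, col] = np.sqrt(rho) * z + np.sqrt(1.0 - rho) * base[:, col]

    # 4. query inactivation state, under the same rule the screens apply
    #    (functional mutation OR expression below the 10th percentile with
    #    copy number under -0.3); the partner's loss probability is then
    #    depleted on that state, preserving its marginal loss rate
    p_l = params.loss_rate
    p_in = p_l * (1.0 - params.co_loss_depletion)
    inactive_states = []
    for k, (_, _, qi, pi) in enumerate(pairs):
        cn_q = np.where(loss[:, qi], cn_deep[:, qi], cn_normal[:, qi])
        expr_q = (params.expr_mean + params.expr_sd * base[:, qi]
                  - params.dosage_effect * params.expr_sd * loss[:, qi])
        cutoff = np.percentile(expr_q, 10.0)
        inactive = qmut[:, k] | ((expr_q < cutoff) & (cn_q < -0.3))
        inactive_states.append(inactive)
        frac = float(inactive.mean())
        p_out = p_l if frac >= 1.0 else min(
            1.0, max(0.0, (p_l - frac * p_in) / (1.0 - frac))
        )
        loss[:, pi] = rng.random(n) < np.where(inactive, p_in, p_out)

    # 5. final value layers
    cn = np.where(loss, cn_deep, cn_normal)
    expr = (params.expr_mean + params.expr_sd * base
            - params.dosage_effect * params.expr_sd * loss)

    # 6. gene-effect scores: background noise, planted dependency shift in
    #    query-inactive samples
    effect = rng.normal(0.0, params.noise_sd, size=(n, g))
    for k, (_, _, qi, pi) in enumerate(pairs):
        effect[:, pi] -= params.dependency_shift * inactive_states[k]

    # 7. mutation records (damaging classes for planted queries, Silent decoys)
    damaging = sorted(DEFAULT_DAMAGING_CLASSES)
    rec_samples, rec_genes, rec_classes = [], [], []
    for k, (qname, _, _, _) in enumerate(pairs):
        hit = np.flatnonzero(qmut[:, k])
        classes = rng.choice(damaging, size=hit.size)
        rec_samples.extend(samples[i] for i in hit)
        rec_genes.extend([qname] * hit.size)
        rec_classes.extend(classes)
    decoy = np.flatnonzero(rng.random(n) < params.silent_decoy_rate)
    decoy_genes = rng.integers(0, g, size=decoy.size)
    rec_samples.extend(samples[i] for i in decoy)
    rec_genes.extend(genes[j] for j in decoy_genes)
    rec_classes.extend(["Silent"] * decoy.size)
    catalog = MutationCatalog(pd.DataFrame({
        "sample": rec_samples,
        "gene": rec_genes,
        "variant_classification": rec_classes,
    }))

    annotation = SampleAnnotation(pd.Series(
        [f"type{i % params.n_contexts}" for i in range(n)], index=samples,
    ))
    truth = [
        PlantedPair(qn, pn, params.dependency_shift, rho,
                    params.co_loss_depletion, params.mutation_rate)
        for (qn, pn, _, _) in pairs
    ]

    def _mat(values, role):
        return OmicsMatrix(
            pd.DataFrame(values, index=samples, columns=genes), role
        )

    return SyntheticCohort(
        label=f"synthetic-seed{params.seed}",
        expression=_mat(expr, Role.EXPRESSION),
        copy_number=_mat(cn, Role.COPY_NUMBER),
        gene_effect=_mat(effect, Role.GENE_EFFECT),
        mutations=catalog,
        annotation=annotation,
        truth=truth,
        params=params,
        seed=params.seed,
    )


def generate_yeast_screen(
    n_genes: int = 100,
    n_negative: int = 20,
    eps_negative_mean: float = -0.25,
    seed: int = 0,
    eps_negative_sd: float = 0.03,
    eps_background_sd: float = 0.05,
) -> YeastInteractionTable:
    """Emulate a pairwise SGA table with planted negative interactions.

    Planted pairs draw epsilon from a normal truncated below -0.12 and a
    p-value below 0.05, so they pass the default CGI filters; background
    pairs that happen to draw a strongly negative epsilon get their p-value
    redrawn above 0.05, so exactly the planted pairs survive the defaults.
    Array genes carry an allele suffix, as SGA arrays encode strains.
    """
    n_pairs_total = n_genes * (n_genes - 1) // 2
    if not 0 <= n_negative <= n_pairs_total:
        raise ValueError(
            f"n_negative must lie in [0, {n_pairs_total}], got {n_negative}"
        )
    rng = np.random.default_rng(seed)
    genes = [f"Y{i:04d}" for i in range(n_genes)]
    all_pairs = [(i, j) for i in range(n_genes) for j in range(i + 1, n_genes)]
    chosen = rng.choice(n_pairs_total, size=n_negative, replace=False)
    planted = {all_pairs[int(c)] for c in chosen}

    eps = rng.normal(0.0, eps_background_sd, size=n_pairs_total)
    pvals = rng.uniform(0.0, 1.0, size=n_pairs_total)
    # keep the construction guarantee: background survivors are excluded by p
    strong_bg = eps <= -0.12
    pvals[strong_bg] = 0.05 + 0.95 * rng.random(int(strong_bg.sum()))

    planted_idx = sorted(all_pairs.index(p) for p in planted)
    for idx in planted_idx:
        e = rng.normal(eps_negative_mean, eps_negative_sd)
        while e > -0.12:  # truncate below the negative-interaction cutoff
            e = rng.normal(eps_negative_mean, eps_negative_sd)
        eps[idx] = e
        pvals[idx] = rng.uniform(0.0, 0.0499)

    records = pd.DataFrame({
        "query_gene": [genes[i] for i, _ in all_pairs],
        "array_gene": [f"{genes[j]}_damp" for _, j in all_pairs],
        "epsilon": eps,
        "p_value": pvals,
    })
    return YeastInteractionTable(records)


def one_to_one_orthologs(yeast_genes, prefix: str = "H") -> OrthologMap:
    """A complete 1:1 yeast-to-human map (testing aid for the CGI pipeline)."""
    return OrthologMap({g: frozenset({f"{prefix}{g}"}) for g in yeast_genes})


def planted_yeast_pairs(table: YeastInteractionTable,
                        eps_max: float = -0.12,
                        p_max: float = 0.05) -> set[tuple[str, str]]:
    """Unordered (suffix-stripped) yeast pairs passing the default filters."""
    from .dataio import strip_strain_suffix

    rec = table.records
    keep = (rec["epsilon"] <= eps_max) & (rec["p_value"] <= p_max)
    return {
        tuple(sorted((strip_strain_suffix(q), strip_strain_suffix(a))))
        for q, a in zip(rec["query_gene"][keep], rec["array_gene"][keep])
    }


def params_to_dict(params: CohortParams) -> dict:
    return asdict(params)
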