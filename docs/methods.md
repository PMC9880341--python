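# Methods

## Statistical model and procedures

### Conditioning states

All cohort screens condition on binary molecular states derived from the
omics layers:

* **functional mutation** — the sample carries at least one record for the
  gene whose MAF variant class is in the damaging set (default: nonsense,
  missense, frameshift indels, splice site, nonstop, start-codon classes;
  silent/UTR/intron/intergenic excluded).  Whether every missense variant
  truly damages the protein is unknowable from class labels alone, so the
  set is fully user-overridable.
* **inactivation** — functional mutation OR (expression strictly below the
  gene's 10th percentile AND copy-number log-ratio < −0.3).
* **overactivation** — expression strictly above the 90th percentile AND
  copy-number log-ratio > +0.3.

Percentiles are computed per gene with linear interpolation **across the
analyzed sample subset**, not the full cohort, so tissue-restricted runs
are self-contained; a restricted run is therefore identical to a pan-cancer
run on the pre-filtered cohort (an invariant the tests assert).  Missing
omics values never satisfy a clause.  The 10% / ±0.3 defaults are the
conventional thresholds of the DAISY family of methods; all are flags.

### DAISY

For query *q* and candidate partner *p*:

* **SoF**: one-sided Wilcoxon rank-sum of *p*'s copy number, inactive(*q*)
  vs rest, alternative "greater" — co-loss of a true SL pair is depleted in
  surviving tumor populations, so the partner's copy number is higher where
  the query is already lost.  In SDL mode the conditioning switches to
  overactive(*q*) and the alternative flips to "less".
* **FunEx**: one-sided rank-sum of *p*'s gene-effect score, inactive(*q*)
  (or overactive(*q*) in SDL) vs rest, alternative "less" (lower effect =
  more essential).
* **Co-expression**: one-sided Spearman test for positive correlation.

Benjamini–Hochberg q-values are computed within each (module, dataset)
family — modules test different hypotheses on different data, so pooling
across modules would mix null distributions.  A module passes for a pair if
any dataset reaches its q cutoff (default 0.05 per module); a pair is a
combined prediction iff all three modules pass.  Pairs whose groups fall
below `min_group` (default 3) or with fewer than `min_pairs` (default 10)
complete expression pairs are *untestable*, not failures; by default
(strict mode) an untestable module blocks the combination, and in lenient
mode it is skipped and the prediction flagged.  Effect sizes are the
rank-biserial correlation (rank-sum modules) and Spearman rho.

### MDSLP

For mutated gene *m* and partner *p*, a two-sided **Welch** *t*-test
compares *p*'s gene-effect scores between *m*-mutant and wild-type lines,
after optional restriction to one cancer type.  Welch rather than pooled-
variance Student is used because mutant groups are small and their variance
need not match the wild-type group's.  Reported per test: *t*, Δ =
mean(mutant) − mean(wild-type) (negative supports SL), p, BH q within the
(context, dataset) family, group sizes.  Group minima default to 3 per arm
(two are needed for a variance; three guard near-degenerate estimates).
shRNA- and CRISPR-derived matrices are interchangeable inputs distinguished
only by a dataset label; any cross-platform discordance is a property of
the data, not of the code path.  Whether the FDR family should pool
contexts is a genuinely open choice; per-(context, dataset) families are
used so each reported screen controls its own FDR.

### CGI

Negative genetic interactions are yeast double mutants whose fitness falls
below the multiplicative single-mutant expectation: records with
ε ≤ ε_max (default −0.12; must be negative) and p ≤ p_max (default 0.05),
the stringent convention for SGA data.  Duplicate unordered yeast pairs
keep the most negative ε.  Identifiers are stripped of allele suffixes
(text after the first underscore) before ortholog lookup, because arrays
encode strains while orthology is gene-level.  One-to-many orthology
expands as a full cross-product — the workflow generates candidates and
downstream evidence filters — and pairs with an unmapped member, or that
collapse to self-pairs in human space, are dropped with counts.  Output
pairs are unordered, canonicalized alphabetically, with merged provenance.

### Enrichment

Partner sets are scored per gene set by the upper hypergeometric tail
P(X ≥ k) with N = |universe|, K = |set ∩ universe|, n = |query ∩ universe|,
then BH-corrected across sets.  The universe defaults to the candidate
space the screen actually tested — the sampling frame of the null — rather
than the whole genome.  Both p and q are reported because display
conventions differ; when several prediction approaches' partner sets are
supplied, terms significant in at least two are flagged.

## Statistical kernels: numerical choices

* **Rank-sum**: statistic is the rank-sum of the first group on pooled
  average ranks.  Exact p by enumerating all C(n, n_a) rank assignments
  when n ≤ `exact_limit` (default 10, bounding enumeration at C(10,5) =
  252); otherwise tie-corrected normal approximation with 0.5 continuity
  correction.  One-sided p-values use the inclusive convention
  P(W ≤ w) / P(W ≥ w), matching scipy and R; fully tied data give p = 1.
* **Welch t**: Welch–Satterthwaite df; sign follows mean(a) − mean(b).
  Both groups constant and equal → t = 0, p = 1; both constant but unequal
  → p = 0 with a degeneracy flag (perfect separation, no variance
  estimate).
* **Spearman**: rho on average ranks; exact p by enumerating all n!
  pairings when n ≤ 7 and no ties, else the t approximation with n − 2 df;
  |rho| = 1 under the approximation maps to p = 0 on the matching side.
  Zero-variance input → flagged undefined correlation with p = 1, which
  one-sided screens treat as "never passes".
* **Hypergeometric tail**: summed in log space (gammaln + logsumexp), exact
  to ~1e-13 against integer-arithmetic summation over the full N ≤ 60 grid.
* **BH**: step-up q-values, order-preserving, q ≥ p, q ≤ 1, monotone along
  sorted p; NaN inputs propagate as NaN without entering m.

Exact-path equivalence against brute-force enumeration, the normal
approximation's ≤ 0.02 error, Welch's null rejection rate, and BH's
realized FDR are all asserted in the test suite.

## The synthetic-data generator

`generate_cohort` emulates a cell-line cohort in which designated pairs
(A, B) carry the three footprints the screens detect; all randomness comes
from one seeded generator with a fixed draw order, so cohorts are
bit-reproducible from (parameters, seed).

* Background layers: expression ~ N(8, 1) (log2-like scale), copy number ~
  N(0, 0.15) with per-gene deep-loss events at rate 0.30 drawn from
  N(−0.8, 0.2), gene effect ~ N(0, `noise_sd`).  A copy-lost gene's
  expression drops by 1.2 expression-sd (dosage coupling), which makes the
  low-expression/low-copy clause of the inactivation rule meaningful.
  The loss rate and dosage drop were set by a power analysis of the SoF
  rank-sum contrast so that the planted co-loss footprint is detectable at
  the default cohort size; a 30% per-gene loss rate corresponds to a
  deletion-prone locus in an aneuploid cohort.
* Planted mutation: each planted query is functionally mutated in a
  Bernoulli(`mutation_rate`, default 0.2) subset of samples, with classes
  drawn from the damaging set; 5% of samples also receive Silent decoy
  records to exercise the functional-mutation filter.
* Planted dependency: B's gene effect is shifted by −`dependency_shift`
  (default 1.0) in samples where A is *inactive under the same rule the
  screens apply* (mutation, or low expression with copy loss).  The state
  depends only on A's layers, which are drawn first, so there is no
  circularity.
* Planted co-expression: A and B share a latent factor,
  x = √ρ·z + √(1−ρ)·ε, giving latent correlation `coexpression_rho`
  (default 0.7).  The realized Spearman correlation is lower — roughly
  ρ/(1 + d²·l(1−l)) minus a small penalty from depleted co-loss, ≈ 0.45 at
  the defaults (d = dosage drop, l = loss rate) — because dosage events add
  independent variance.  Tests therefore assert the realized value, not the
  latent ρ.
* Planted co-loss depletion: B's loss probability is `loss_rate` × (1 −
  `co_loss_depletion`) in A-inactive samples, re-balanced elsewhere so B's
  marginal loss rate is preserved.
* Contexts are assigned round-robin, so every cancer type has balanced
  sample counts.

`generate_yeast_screen` writes every unordered gene pair once, with array
identifiers carrying an allele suffix.  Planted pairs draw ε from
N(`eps_negative_mean`, 0.03) truncated below −0.12 and p < 0.05; background
pairs draw ε ~ N(0, 0.05) and uniform p, and any background pair that
happens to draw ε ≤ −0.12 has its p redrawn above 0.05.  This preserves the
background ε marginal while guaranteeing that exactly the planted pairs
survive the default filters — the property the CGI recovery check relies
on.

What the generator does **not** emulate: real marginal distributions of
TCGA/CCLE/DepMap data, mutation spectra, gene–gene correlation structure
beyond the planted pairs, batch effects, copy-number segmentation, or
missing data.  Passing the recovery and calibration tests therefore shows
that the inference machinery is correct and calibrated under its own
assumptions — not that it will reproduce any particular result on real
cohorts, where signals are far weaker and confounded.

## Problem sizes used in the checks

Null calibration uses ten 200-line cohorts with 500 background partner
tests each (MDSLP) and ten 200-line cohorts with five signal-free planted
pairs among ~100 genes (DAISY).  Recovery uses twenty 500-line cohorts
with five planted pairs among 50 genes under the strong-signal preset
(Δ = 1.0, noise sd 0.3, ρ = 0.7, depletion 0.9, mutation rate 0.2), and a
100-gene yeast screen with 20 planted negatives.  Kernel oracles sweep all
group-size splits with n ≤ 8 (rank-sum), n ≤ 6 (Spearman permutations) and
the full N ≤ 60 hypergeometric grid.

## Known limitations

* The DAISY SoF direction ("greater" in SL mode) encodes the co-loss
  depletion rationale; datasets where query inactivation is driven by
  broad deletions spanning both genes would violate it.
* Exact rank-sum enumeration is exponential; above `exact_limit` the normal
  approximation is used, which is only accurate to ~0.02 for small groups.
* BH controls FDR under independence/PRDS; strongly correlated partner
  tests (e.g. co-essential gene modules) can inflate realized FDR.
* CGI transfers interactions purely by orthology; it scores no conservation
  confidence and inherits the ortholog map's quality.
* Gene identifiers are taken as-is; harmonization across datasets is the
  caller's responsibility.
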