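# Methods

## The model

The workflow predicts a binary outcome (coded 0 = control, 1 = case) from
analytes measured on several omes. It is deterministic end to end: given a
dataset and a parameter configuration, every stage — including tie-breaks —
is reproducible.

### Pairwise cross-ome regressions

For a response analyte y and predictor analyte x from two different omes,
interaction mode fits ordinary least squares on the design
[1, g, x, g·x], where g is the group indicator:

    y = β₀ + β₁ g + β₂ x + β₃ g x + ε .

The group-0 line is β₀ + β₂x and the group-1 line (β₀+β₁) + (β₂+β₃)x, so
β₃ is the between-group slope difference and its two-sided t-test p-value
is the ranking statistic. Correlation mode fits y = β₀ + β₂x; its slope
p-value is algebraically identical to the Pearson-correlation p-value
(tested to 1e-10). Fits are computed by QR decomposition; a design whose R
factor has a near-zero diagonal (constant x, or x constant within one
group, which makes g·x collinear) is flagged invalid and excluded
downstream rather than silently dropped. A fit with numerically zero
residual variance has an undefined p-value and is likewise flagged.

Interaction p-values depend on which analyte is the response. The default
pair plan for the canonical microbiome trio is enzyme ~ metabolite,
microbe ~ enzyme, metabolite ~ microbe (microbes as producers/consumers of
metabolites); any plan can be supplied explicitly and is logged with the
results.

### Influence and prevalence filters

DFFITS_i — the externally studentized residual times √(hᵢ/(1−hᵢ)), hᵢ the
leverage — equals the number of standard deviations by which observation
i's fitted value changes when the model is refit without it (verified
against an explicit leave-one-out refit oracle to 1e-8). Fits with
max |DFFITS| ≥ 4 are removed; the absolute value is used because DFFITS is
signed and influence is two-sided. A leverage of exactly 1 (an exact-fit
point) makes the maximum infinite, hence removed. Microbes with non-zero
values in strictly fewer than 10% of samples are removed ("fewer than" is
taken literally: retained iff count ≥ 0.10·n, so no rounding rule is
needed for non-integer thresholds).

The filters matter statistically, not just cosmetically: with
heavy-tailed (log-normal) analytes the raw null positive rate of the
interaction t-test at n = 60 is inflated to ~9%, and the DFFITS cut
restores it to ~5% (measured in the test suite). Under normal errors the
engine is calibrated as-is. A side effect worth knowing: a genuinely strong
relationship whose predictor spans a wide log-normal range can fail its own
influence cut — the filter trades a small loss of sensitivity for
protection against outlier-driven edges.

### Top table and network

Within each assay pair (response ome, predictor ome), surviving fits with
p < 0.05 are ranked by (p, −|t|, response name, predictor name) — the
secondary keys make ties deterministic — and the best 35 are kept. The top
table becomes an undirected graph: one node per analyte, one edge per
entry, the edge carrying the fit's coefficients and statistics. If both
regression directions of the same analyte pair survive, the smaller-p
entry keeps the edge (the duplicate is logged). Edges are undirected for
neighborhood purposes; the fitted orientation is retained as edge
metadata. The graph serializes to a versioned node-link JSON dialect
(`cantare-net/1`) with strict referential-integrity checks on read.

### Neighborhood-seeded logistic models

The order-k neighborhood of a seed node is the breadth-first closure to
depth k, seed included; member counts include the seed. For every
microbe-ome node whose order-2 neighborhood has at least 4 nodes, a
logistic regression of the outcome on the neighborhood analytes plus the
covariates (age, fecal calprotectin) is fit by IRLS maximum likelihood
(statsmodels GLM with a binomial family, the same estimator as R's glm),
with AIC = 2k − 2 log L.

Backward selection then repeatedly refits the model with each single
predictor removed and accepts the removal with the lowest AIC while any
removal lowers it. Exact AIC ties are broken by removing the predictor
that sorts later by name; candidate refits that fail to converge are
skipped (logged); the intercept-only model is reachable. Covariates are
eligible for removal like any predictor — selection, not forcing — with a
`force_keep` option for analysts who want them pinned. Pure backward
elimination is used (no re-entry of dropped terms). Greedy backward search
is not guaranteed to find the global AIC optimum, but every accepted step
strictly decreases AIC, and on the seeded designs in the test suite it
matches an exhaustive all-subsets oracle.

Non-convergence is declared when IRLS hits 25 iterations or when the fit
shows quasi-complete separation: some fitted probability within 1e-10 of
0 or 1 *together with* coefficient blow-up (any |coefficient|·SD(predictor)
above 15 log-odds). The conjunction matters — a legitimately strong model
can push an extreme sample's probability to the numerical boundary without
any coefficient degenerating, and flagging on probabilities alone would
discard exactly the best models. Constant predictors are dropped with a
warning before fitting. Reported probabilities are clipped to the open
interval (1e-15, 1 − 1e-15) so downstream code can rely on 0 < p̂ < 1.

Models are scored by in-sample AUC in its concordance form
(concordant + ½·tied) / (cases × controls), computed via the rank
(Mann–Whitney) identity so ties get exactly half credit. No
cross-validation is performed; within-sample optimism is a known property
of the workflow and is measured on permuted outcomes (see below). Models
whose reduced predictor sets are identical as unordered sets collapse to
one unique model listing all contributing seeds; nested-but-unequal sets
stay distinct. De-duplication is keyed on predictor sets, not coefficient
values.

### Effect sizes and cumulative fits

For each predictor, the reported odds ratio is exp(β̂·(Q3 − Q1)) with
linear-interpolation (type-7) quantiles computed on the analysis samples —
the quantile convention matters because ORs and the predictor ordering
depend on it. When Q1 = Q3 (typical for zero-heavy microbes) the overall
range substitutes and the entry is marked kind = "range". Tables are
sorted ascending by odds ratio.

The fit matrix decomposes the linear predictor: entry (i, j) = x_ij·β̂_j
with a constant intercept column; row sums reproduce x·β̂ to machine
precision. Cumulative columns accumulate contributions in ascending
effect-size order with the intercept folded into the first column; each
running sum maps through 1/(1+e^−z). The final column equals the model's
fitted probabilities regardless of the accumulation order (telescoping).
The plot draws one probability path per sample, green for controls and
orange for cases, a dotted trend line, and a thick vertical marker at the
final column. The trend line is the arithmetic mean of the cumulative
*log-odds* transformed to probability — averaging on the accumulation
scale keeps the trend line a valid path of the same construction; the
mean-of-probabilities alternative would generally differ (Jensen). SVG
output is byte-deterministic for fixed input (fixed hash salt, no
timestamp metadata).

## The synthetic generator

`simulate()` emulates a three-ome gut-microbiome case/control cohort. Its
defaults are the study shape: 153 samples with case fraction 111/153, omes
of 201 microbes / 386 metabolites / 76 enzymes, age ~ Normal(40, 12²)
clipped to [18, 80] years, fecal calprotectin log-normal (median ≈ 55,
heavy right tail).

- **Microbes** are relative-abundance fractions: zero-inflated (default
  structural-zero probability 0.5, reflecting zero-heavy species) times a
  log-normal positive component (log-mean log 0.005, log-SD 1.5).
  Compositional closure is *not* enforced — abundances are treated as plain
  non-negative predictors — but a renormalization switch exists for realism
  studies.
- **Metabolites and enzymes** are log-normal ppm intensities (log-mean
  log 200, log-SD 1.0): heavy right tails, as in LC/MS data.
- **Outcome.** If outcome effects are specified, the group is drawn from a
  logistic model whose linear predictor sums the stated log-odds-per-SD
  effects of the named analytes (z-scored) and covariates, with the
  intercept calibrated by bisection so the expected case fraction matches
  the spec; otherwise group counts are exact. The calprotectin effect acts
  on the z-score of log(calprotectin) — on the raw scale a handful of
  log-normal outliers absorb the entire SD and the covariate signal
  becomes unrealistically weak for everyone else.
- **Planted pairs** regenerate a response column as
  β₀ + β₁g + β₂x + β₃gx + Normal(0, σ), clipped at zero to respect
  non-negativity (clipping slightly attenuates planted effects; the demo
  coefficients keep the clipped fraction near zero). Pairs are applied in
  list order, so chains (a planted response reused as a later predictor)
  must be listed parents-first.

`demo_spec()` is the showcase configuration: twelve planted pairs forming
small connected hubs (real analyte networks are well connected, not
isolated edges) in the canonical regression directions, three
outcome-linked analytes (one per ome, ±0.8–1.0 log-odds/SD) that also
appear as planted-pair predictors so they can reach the network the same
way outcome-associated analytes do in real cohorts, a strong calprotectin
effect (1.5/SD of the log) and a mild age effect (0.3/SD). Planted
interaction strengths were chosen at roughly 2 standardized units
(β₃·SD(x)/σ ≈ 2) — strong enough that a screen of ~10⁵ hypotheses with a
top-35-per-pair cut is *expected* to find most of them, which is the
regime the workflow is designed for. Because the realized SD of a
log-normal column varies several-fold between draws, per-seed top-table
sensitivity at full scale fluctuates (typically 0.4–0.9); this is honest
behavior of a stringent screen, reported as measured.

What the generator does **not** emulate: sequencing-depth/count noise,
compositional coupling between microbes, correlated analyte blocks beyond
the planted edges, batch effects, or missingness. Passing tests therefore
demonstrate correctness of the machinery and recoverability of planted
linear structure under realistic marginals — not performance on any real
cohort.

## Numerical choices and tie-breaks

- OLS by QR; rank deficiency declared when min |diag(R)| falls below a
  scaled machine-epsilon threshold.
- DFFITS at an exact-fit point (leverage 1) is +∞; an all-zero-residual
  fit has undefined influence (NaN) and an undefined p-value, and is
  excluded from ranking.
- Exclusion precedence in top-table bookkeeping: invalid → undefined-p →
  prevalence → DFFITS → retained; the categories are disjoint and sum to
  the attempted count (asserted by the workflow tests).
- CV deduplication: CV = SD/mean (n−1 denominator); a zero-mean column has
  undefined CV and is never selected unless all candidates are undefined
  (then the lexicographically first name wins); exact CV ties also go to
  the lexicographically first name.
- Mean/variance analyte filter uses strict inequalities; a whitelist
  bypasses it.
- Sample alignment across omes uses the intersection of ids, preserving
  metadata order; dropped ids are logged. CSVs are parsed with
  round-trip float precision so load → write → load is bit-stable.
- Backward-AIC ties: remove the predictor later in name order. Top-table
  p ties: larger |t| first, then names.
- Quantiles: numpy `method="linear"` (type-7) everywhere.

## Problem sizes used by the acceptance script

The acceptance script runs the full pipeline at the native study shape
(153 × 201/386/76 ≈ 122,000 pairwise fits, ~30 s on one CPU), plus
Monte-Carlo checks at the sizes the properties are stated for: 1,500
null interaction fits at n = 60; 20 outcome permutations at n = 300;
60 power seeds at n = 150; 50 retention seeds at n = 300. The unit-test
demo cohort uses scale 0.08 (16/31/8 analytes) so the whole suite stays
fast while exercising every stage.

## Known limitations

- In-sample AUC is optimistic; the permuted-outcome check quantifies the
  optimism after backward selection (median ≈ 0.5) but full models on
  small n retain optimism of a few points.
- Greedy backward AIC can in principle miss the all-subsets optimum.
- The influence cut can discard strong true relationships with
  wide-ranging predictors (observed in the synthetic demo).
- Raw p-values are ranked without multiple-testing correction by design;
  the top table is a screening device, not an inference.
- Planted-pair injection replaces a column's marginal distribution with a
  regression construction; induced correlations elsewhere are measured,
  not controlled.
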