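# Methods

## Scoring model

Nutri-Score for general foods (the table set applicable to processed meat)
assigns points per 100 g of product. Unfavourable *N*-components — energy
density (kJ), sugars (g), saturated fatty acids (g), sodium (mg) — earn 0–10
points each from ten-row threshold tables (energy in 335 kJ steps, sodium in
90 mg steps, SFA in 1 g steps; the sugar ladder is non-uniform around 31 g).
Favourable *P*-components earn 0–5 points: the fruit/vegetable/pulse/nut/
permitted-oil percentage (FVL; its table has no 3- or 4-point rows, so
attainable points are {0, 1, 2, 5}), fibre, and protein. The combination rule
is conditional: all P points are subtracted from the N total when N < 11 or
when FVL scored 5; otherwise only FVL and fibre are subtracted. Letter
classes: A ≤ −1, B 0–2, C 3–10, D 11–18, E ≥ 19.

Threshold semantics are strict-greater: a value earns the points of the
highest bound it strictly exceeds, and a value sitting exactly on a bound
takes the lower score. This convention is confirmed by the worked
single-product examples the test suite pins (346 kJ → 1 point, 600 mg sodium
→ 6, 8.2 g protein → 5). Nutrient values are scored exactly as read — no
pre-rounding — since label declarations are already rounded by the producer
and no rounding rule is part of the algorithm.

Two variants are implemented. They differ in exactly one place: the protein
table used for red meat (domestic ungulates). The original algorithm scores
all meat on the 0–5 white-meat ladder (thresholds 1.6, 3.2, 4.8, 6.4, 8.0 g);
the refined algorithm caps red-meat protein at 2 points (thresholds 2.4,
4.8 g). Consequences proved as properties in the suite: white-meat scores are
identical under both variants; red-meat refined totals exceed original totals
by 0–3 points, and only when protein enters the subtraction and exceeds
1.6 g (the point where the two ladders diverge). The broader 2022/2023
official revision of other components is deliberately not modelled.

Sodium is taken from the label when declared; otherwise it is derived from
salt as sodium (mg) = salt (g) / 2.5 × 1000. A declared sodium value always
wins over the conversion. A missing FVL percentage is scored as 0 % —
processed meats essentially never approach the 40 % threshold.

The threshold tables ship as a human-readable YAML file
(`nutriscore_tables.yaml`) loaded at run time; the engine refuses tables
whose bounds are not strictly increasing, whose points decrease, or whose
maximum is inconsistent, so an edited table cannot silently corrupt scores.

## Taxonomy and data handling

Products are classified as meat preparations vs meat products (the two EU
regulatory categories), meat products into smoked meats / sausages / offal
meats / other meats, and by species into red vs white meat. This yields nine
analysis groups (preparations are not split by species). Products declaring
both red and white species are assigned to red meat — the conservative choice
under the refined protein cap — and flagged (`meat_class_mixed`) so the rule
is visible rather than silent.

CSV reading accepts comma or dot decimal separators (Polish labels use
commas). Malformed rows (negative nutrients, unparseable numbers,
inconsistent taxonomy, unknown species) are collected into a rejects report
with reasons, never silently dropped. A record is scoreable when energy,
sugars, SFA and protein are declared and sodium is resolvable; fibre may be
missing, because labels are not required to declare it.

Missing fibre is imputed as the arithmetic mean of observed fibre within the
product's analysis group (a grouping callable allows finer levels). Observed
values and non-fibre fields are never touched; imputed records are flagged;
the result is order-independent; a group with no observed fibre raises an
explicit error naming the group.

## Reformulation scenarios

A scenario is a pair of multiplicative factors in (0, 1] on sodium (salt
scales with it, keeping the pair consistent) and SFA. The studied scenarios
are −30 % sodium, −10 % SFA, and both combined. Energy is held fixed in SFA
scenarios: the replacing fat is unknown, so any energy correction would be
speculation; scenario totals may therefore be optimistic if substitutes add
energy. Protein and sugars are never touched.

Each product is scored at baseline and under the scenario; moves are
accumulated in a 5×5 transition matrix whose row sums reproduce the baseline
class distribution exactly. Because factors never increase a nutrient and
the score is monotone, no product's class ever moves toward E — the suite
checks the matrix's strict upper triangle is empty on a full-size synthetic
market. Distribution reports use the group's own size as the percentage
denominator at all three hierarchy levels (category, technological group,
group × species subgroup).

## Analytics

Group summaries report median and quartiles (linear interpolation between
order statistics, numpy's default — stated here because published summary
tables rarely say which quantile rule they used) for the total score and for
each nutrient's content and points. Variant comparison scores every product
under both algorithms and aggregates the 5×5 move matrix; group means are
reported to 2 decimals.

The flavour-enhancer model is a univariate logistic regression of enhancer
presence (1/0) on salt content (g/100 g), exposed as `SaltEnhancerModel`
with a `fit()` returning a `LogisticFit` results object. Estimation is
maximum likelihood (statsmodels' Logit, IRLS/Newton); an independent
cross-check in the tests compares coefficients against scikit-learn's
unpenalised solver. Reported alongside the coefficients: the likelihood-ratio
χ² against the intercept-only null (df = 1), the percentage of correctly
classified cases at a configurable probability cut-off (default 0.5), and
the AUC computed as the rank-based concordance of fitted probabilities with
outcomes, ties counting 1/2 via midranks — identical to trapezoidal ROC
integration, which the tests verify. Complete separation raises a dedicated
error rather than returning divergent estimates. The predicted probability
curve carries a delta-method confidence band computed on the linear predictor
and mapped through the inverse logit, so it stays inside (0, 1) and narrows
as n grows.

## Synthetic market generator

The generator emulates a national market survey of processed meat labels:
nine analysis groups with sizes (27, 58, 476, 115, 751, 30, 125, 63, 55) —
1700 products in total — and per-group nutrient marginals targeted at
published median/quartile summaries for energy, sugars, SFA, sodium, protein
and fibre.

Each strictly positive nutrient is drawn from a log-normal with
μ = log(median) and σ = log(q75/q25) / (2 z₀.₇₅): positive support and right
skew are typical of label data. This two-parameter fit reproduces the median
exactly and the quartile *ratio*; when the printed quartiles are asymmetric
about the median on the log scale, the individual quartiles are approximated
rather than matched. Nutrients with printed median 0 (fibre and sugars in
several groups) are drawn zero-inflated: zero with probability 1/2, otherwise
log-normal with median equal to the group's q75, which matches both printed
quantiles. Nutrients are drawn independently within a product — real
inter-nutrient correlations (e.g. SFA with energy density) are unknown, so
synthetic data cannot support any statistic that depends on them, and the
tests avoid such statistics.

Fibre is undeclared with probability 374/1700 ≈ 0.22 in every group
(surveys obtain fibre from producers for roughly 78 % of products; per-group
rates are unknown, so the overall rate is applied uniformly). Salt is derived
from sodium by the inverse label conversion. The enhancer flag is Bernoulli
with logit = intercept + slope × salt; the defaults (intercept 1.55, slope
−0.65 per g salt) are tuned, not estimated: they give roughly even enhancer
prevalence and an AUC near 0.65 — the weak-discrimination regime observed on
real labels, where salt alone explains enhancer presence significantly but
classifies poorly. Meat preparations are generated as red meat (surveys do
not split preparations by species; red is the conservative choice under the
refined cap).

Randomness: one root seed spawns independent per-group substreams
(`numpy.random.SeedSequence`), so adding or resizing a group never perturbs
another group's draws, and identical (config, seed) yields byte-identical
CSVs.

With the default configuration the scored market concentrates heavily in
classes D and E (the suite asserts a D+E share above 70 %), sodium is the
dominant N-component, and a 30 % sodium reduction moves several hundred of
the 1700 products into better classes. These are qualitative reproductions
of the real-market pattern; exact published dataset-level figures (class
percentages, transition counts, χ², AUC) depend on the undeposited survey
data and on correlations the generator does not model, and are not claimed.

## Pipeline and problem sizes

`run_pipeline` composes acquire (read or simulate) → completeness filter →
fibre imputation → scoring under both variants → scenario transitions and
distribution reports → descriptive analytics → the logistic fit, and writes
a manifest with a configuration echo and SHA-256 per output. All randomness
flows from the single configured seed, so a manifest fully determines a
re-run.

Problem sizes used in the test suite: property checks run on 10⁴ random
profiles per law; scenario invariants and downstream distribution checks on
the full 1700-product default market; logistic parameter recovery at
n = 5000 over 20 seeds (mean estimates within 3 standard errors, slope-sign
recovery in at least 19 of 20); Monte-Carlo quantile calibration at n = 10⁵.
The whole suite runs in a few seconds.

## Known limitations

- Independence of nutrients within a product: any statistic involving
  inter-nutrient correlation is outside what the generator can emulate. A
  Gaussian-copula hook would be the natural extension.
- The two-parameter log-normal cannot match asymmetric printed quartiles
  exactly (median and quartile ratio only).
- The refined variant models only the protein-cap change for meat; other
  components of the broader official revision are out of scope, as are the
  beverage/fat/cheese table sets and portion-size adjustment.
- Reformulation scenarios ignore technological feasibility (texture,
  preservation, taste) and substitute-ingredient effects on energy.
- The enhancer model is univariate by design; it quantifies an association
  on labels, not a causal reformulation mechanism.
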