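# nutriprofiler

Nutri-Score nutrient profiling for processed meat products: the full scoring
algorithm (original and 2022-refined variants), product taxonomy, reformulation
scenario simulation with class-transition accounting, group summary statistics,
and a logistic model of flavour-enhancer presence against salt content.

## What problem this addresses

Nutri-Score is a five-class front-of-pack nutrition label (A, dark green, to E,
dark orange) computed from per-100 g nutrient content. Four unfavourable
*N*-components each earn 0–10 points from a threshold table — energy density
(kJ), sugars (g), saturated fatty acids (g), and sodium (mg, derived from the
labelled salt as sodium = salt / 2.5 × 1000. Three favourable *P*-components —
the fruit/vegetable/pulse/nut/oil percentage (FVL, 0–5 points), fibre (0–5),
and protein (0–5) — are subtracted under a conditional rule:

```
N = energy + sugars + SFA + sodium points
total = N − (FVL + fibre + protein)   if N < 11 or FVL points = 5
        N − (FVL + fibre)             otherwise
```

Classes: A ≤ −1, B 0–2, C 3–10, D 11–18, E ≥ 19. Threshold semantics are
strict: a value earns the points of the highest bound it *strictly* exceeds,
so 335 kJ scores 0 energy points and 336 kJ scores 1.

The *refined* algorithm (the 2022 Scientific Committee change for meat) caps
protein points at 2 for red meat and its products; white meat (poultry,
lagomorphs) keeps the 0–5 scale. That is the only difference between the two
variants implemented here.

The package is aimed at food-science and public-health researchers who want to
score market catalogues of processed meat products, ask how reformulation
(e.g. the WHO 30 % salt-reduction target, a 10 % SFA cut) would reallocate
products between classes, and analyse label co-occurrence patterns such as the
negative association between salt content and declared flavour enhancers.
Because market survey datasets are rarely deposited, a synthetic-market
generator reproduces the statistical skeleton of such a catalogue (nine
analysis groups, log-normal nutrient marginals matched to published
median/quartile summaries, a missing-fibre mechanism, and the salt–enhancer
logistic link), so every pipeline stage is testable end to end.

## Worked example

```python
from nutriprofiler import (
    AlgorithmVariant, MeatClass, NutrientProfile, ProductRecord, nutriscore,
)
from nutriprofiler.catalog import Category, TechGroup

record = ProductRecord(
    product_id="smoked-breast-001", name="smoked chicken breast",
    category=Category.MEAT_PRODUCT, group=TechGroup.SMOKED,
    meat_class=MeatClass.WHITE,
    profile=NutrientProfile(energy_kj=346, sugars_g=0.1, sfa_g=1.1,
                            sodium_mg=80, protein_g=13.0, fibre_g=0.0,
                            fvl_pct=0.0),
)
result = nutriscore(record, AlgorithmVariant.REFINED)
print(result.total, result.letter)
print(result.components)
```

prints

```
-3 A
ComponentScores(energy_pts=1, sugars_pts=0, sfa_pts=1, sodium_pts=0,
                fvl_pts=0, fibre_pts=0, protein_pts=5)
```

Energy 346 kJ exceeds the 335 kJ bound (1 point), SFA 1.1 g exceeds 1 g
(1 point), sodium 80 mg stays at or below 90 mg (0 points): N = 2. Since
N < 11, all P points are subtracted — protein 13 g earns the white-meat
maximum of 5 — giving total 2 − 5 = −3, class A.

Scoring a full synthetic market and fitting the salt → enhancer model:

```python
from nutriprofiler import (
    class_distribution, default_config, fit_salt_enhancer_logistic,
    generate_market, impute_fibre,
)

products = impute_fibre(generate_market(default_config(), seed=1))
dist = class_distribution(products)
print(dist[dist.group == "all products"][["class", "count", "pct"]])
print(fit_salt_enhancer_logistic(products).summary())
```

```
class  count        pct
    A      0   0.000000
    B      3   0.176471
    C    146   8.588235
    D    826  48.588235
    E    725  42.647059
Flavour-enhancer presence ~ salt content (logistic regression)
  n = 1700, converged = True
  intercept = +1.3861 (SE 0.1460)
  slope     = -0.6183 (SE 0.0571)  [log-odds per g salt/100 g]
  LR chi2 = 149.2, df = 1, p = 2.65e-34
  correctly classified at 0.5 cut-off: 60.5%
  AUC = 0.653
```

The synthetic market lands overwhelmingly in classes D and E, as processed
meat does on real shelves, and the enhancer model recovers the configured
negative salt association with deliberately weak discrimination (AUC ≈ 0.65):
lower-salt products are the ones more likely to declare flavour enhancers.

## Command line

```sh
nutriprofiler simulate --seed 1 --out market.csv
nutriprofiler score --in market.csv --variant refined --out scores.csv
nutriprofiler reformulate --in market.csv --sodium-factor 0.7 --out-dir ref/
nutriprofiler report --in market.csv --out-dir report/
nutriprofiler run --out-dir out/ --seed 1     # full pipeline + manifest
```

`run` writes a manifest (`manifest.json`) with the configuration echo and a
SHA-256 per output file; re-running with the same seed reproduces every
output byte for byte.

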