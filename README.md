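# biomimqsar

A pipeline for hybrid biomimetic-chromatography / QSAR studies of small
organic acids (phenoxyacetic-acid-type herbicide panels and similar): it
takes raw chromatographic retention times, hemolysis-assay absorbances and
an in-silico descriptor table, and produces validated multiple-linear-
regression QSPR models with leverage-based applicability domains.

It is written for medicinal/environmental chemists who screen candidate
compounds with an immobilized-artificial-membrane (IAM) column and/or
biopartitioning micellar chromatography (BMC, Brij 35 micellar mobile
phase), and who want the whole statistical workflow — not just the final
fit — to be scripted, tested and reproducible.

## What it computes

* **Retention factors.** For each compound and system,
  `log k = log10((t_r − t_0)/t_0)` with triplicate retention times averaged
  on the time scale. Collander-type calibrations `log P₁ = a·log P₂ + b`
  link the chromatographic lipophilicity scales to each other and to
  log P_o/w (ordinary univariate OLS with full statistics).
* **Hemolytic potency.** Percent hemolysis
  `= (Abs_sample − Abs_blank)/(Abs_control − Abs_blank) × 100` and HC50 by
  the classical probit method: OLS of `Φ⁻¹(p) + 5` on log10(concentration),
  inverted at probit 5.
* **Descriptor orthogonality.** Variable clustering on the distance
  `d = 1 − |r|` (average linkage; similarity printed as 100·|r| %) and
  variance inflation factors `VIF_j = 1/(1 − R²_j)`. Admissible predictor
  sets contain exactly one lipophilicity descriptor (log k_BMC or
  log k_IAM) and at most one member per flat descriptor cluster.
* **Model search and statistics.** Exhaustive OLS over all admissible sets;
  each fit reports SD, R², R²_adj, MSE = RSS/n,
  `PRESS = Σ(eᵢ/(1 − hᵢᵢ))²`, R²_pred = 1 − PRESS/SST, Q²_cv (identical by
  the leave-one-out identity, verified against an explicit refit loop),
  F, coefficient standard errors and standardized coefficients
  `bⱼ·sd(xⱼ)/sd(y)`. Ranking: R²_adj descending, PRESS as tie-break.
* **Validation.** Leave-one-out and repeated leave-33%-out
  cross-validation; Williams-plot applicability domain with warning
  leverage `h* = 3(p + 1)/n` and a ±3 SD band on internally studentized
  residuals.
* **Synthetic benchmark data.** A seeded generator producing compound
  panels with the realistic two-block descriptor correlation structure,
  Collander-linked retention, linear endpoint responses, a planted
  high-leverage compound, and probit hemolysis curves with known HC50 —
  so every stage is testable without laboratory data.

## Worked example

```bash
$ biomimqsar simulate --seed 7 --out demo
wrote synthetic bundle (29 compounds) to demo

$ biomimqsar collander --in demo/panel.csv --x logk_IAM --y logk_BMC
logk_BMC = 0.4139(±0.0248) logk_IAM + 0.6558(±0.0203); SD = 0.1091, R2 = 0.9119, R2_adj = 0.9086, R2_pred = 0.8970, n = 29
```

The two biomimetic retention scales are tightly linearly related (the
generator's true slope is 0.437); R²_pred close to R² says the calibration
predicts held-out compounds nearly as well as it fits.

```bash
$ biomimqsar search --in demo/panel.csv --response logP_wpc --top 3
24 candidates, ranked by R2_adj desc, PRESS asc
#1 ['logk_BMC', 'HBD_HBA', 'alpha'] R2=0.9942 R2_adj=0.9935 PRESS=0.2999 R2_pred=0.9924
#2 ['logk_BMC', 'HBD_HBA', 'NRB'] R2=0.9840 R2_adj=0.9820 PRESS=0.8339 R2_pred=0.9790
#3 ['logk_BMC', 'TPSA', 'alpha'] R2=0.9745 R2_adj=0.9714 PRESS=1.319 R2_pred=0.9667
```

The exhaustive search over the 24 admissible predictor sets ranks the
generating model (micellar lipophilicity + polarizability + hydrogen-bond
donor/acceptor sum) first for the plant-cuticle permeation endpoint.

```bash
$ biomimqsar ad --in demo/panel.csv --response logP_wpc --predictors logk_BMC,alpha,HBD_HBA
h* = 0.4138; outside domain: ['12']
```

Compound 12 — the deliberately extreme, highly lipophilic member of the
panel — exceeds the warning leverage 3(p+1)/n = 0.41 and is flagged as
structurally outside the applicability domain, exactly the behaviour such
a compound shows in real panels.

```bash
$ biomimqsar hc50 --in demo/hemolysis.csv --out hc50.csv
HC50 for 29 compounds written to hc50.csv
$ head -4 hc50.csv
compound_id,HC50_uM,slope,intercept,n_points
29,1134,2.903311833,-3.86808581378,10
28,1190,2.84554949386,-3.75133096774,10
9,1232,3.27554877348,-5.12345343113,10
```

Probit HC50 estimates (µM) per compound, most hemolytic first, with the
fitted probit slope and intercept.

The whole study (retention → HC50 → clustering → per-endpoint model search
→ cross-validation → Williams tables, plus a run manifest) runs from one
config:

```bash
printf 'simulate:\n  seed: 7\nout_dir: study\n' > study.yaml
biomimqsar run --config study.yaml
```

## Layout

```
src/biomimqsar/
  io_tables.py    CSV/JSON schemas, CompoundPanel, model reports
  retention.py    log k, Collander calibrations
  hemolysis.py    percent hemolysis, probit HC50, toxicity ranking
  clustering.py   variable dendrogram, VIF, admissible predictor sets
  mlr.py          OLS fits, PRESS/R2_pred/Q2, exhaustive model search
  validation.py   Williams plots, LOO / leave-33%-out cross-validation
  synthetic.py    seeded study-condition generator
  pipeline.py     end-to-end orchestration with manifest
  cli.py          `biomimqsar` command group
docs/methods.md   modelling assumptions, defaults, numerical choices
```
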