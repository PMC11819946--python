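# Methods

This note documents the models, conventions and defaults behind the
package, the design choices made where several conventions were defensible,
and what the synthetic benchmark does and does not demonstrate.

## Retention factors and Collander calibrations

Retention on both biomimetic systems (IAM column with pH 7.4 phosphate/
citrate buffer; ODS column with 0.04 M Brij 35 micellar eluent) is reduced
to `log k = log10((t_r − t_0)/t_0)`. Replicate retention times are averaged
on the *time* scale before the log transform, because the instrument
measures times and a single log k per compound/system is the quantity
carried forward; averaging after the transform differs only at third-
decimal level for typical replicate noise but the convention is fixed.
Base-10 logarithms are used throughout. `log k_IAM` is the directly
measured retention factor in the fully aqueous buffer (no organic-modifier
extrapolation is implemented, since none is needed for an aqueous eluent).
A solute with mean t_r ≤ t_0 is rejected as unretained rather than given a
fictitious log k.

Collander-type relations `y = a·x + b` between lipophilicity scales are
ordinary univariate least squares. Their standard errors come from the OLS
covariance matrix and they carry the same SD/R²/R²_adj/R²_pred statistics
as the multivariate models, so calibration quality and model quality are
directly comparable.

## Percent hemolysis and probit HC50

Percent hemolysis is computed from replicate-averaged absorbances (the
assay measures absorbance, so replicates are pooled on that scale, not on
the percent scale):
`p = 100·(Abs_sample − Abs_blank)/(Abs_control − Abs_blank)`.
The quantity is affine-invariant in the three absorbances, so baseline
shifts of the plate reader cancel.

HC50 is defined as the concentration producing 50 % hemolysis and is
estimated by the classical probit method: `Φ⁻¹(p/100) + 5` is regressed on
log10(concentration) by OLS and the line inverted at probit 5,
`HC50 = 10^((5 − b₀)/b₁)`. The +5 offset is cosmetic — the estimate is
identical with an offset-free probit, which the test suite asserts.
Observed percentages outside (0, 100) are clipped to [0.5, 99.5] before the
transform (standard Finney practice), which keeps saturated 0 %/100 %
points usable at the price of a small bias (a few µM) when the response at
a grid extreme falls below 0.5 %. A fitted slope ≤ 0 (non-monotone or flat
response) is an error, not a number. The "lowest tested grid concentration
with ≥ 50 %" reading is available as a diagnostic (`grid_hc50`) but the
probit interpolation is the primary estimator. Maximum-likelihood probit
with iterative reweighting and Abbott's correction for spontaneous
hemolysis are deliberate non-features; for the 10-point curves this assay
produces, the OLS probit line is the transparent choice. Reported HC50
values are rounded to 1 µM; ranking ties break lexicographically on
compound id.

## Descriptor orthogonality

Similarity between descriptors is `100·|r|` % (Pearson correlation across
compounds); the clustering distance is `d = 1 − |r|` with average linkage.
Signed-correlation distance and single/complete linkage are available as
options, but the absolute-value/average-linkage convention is the default:
percent-similarity dendrogram labels in this field refer to correlation
magnitude, and sign is irrelevant for collinearity. The hydrogen-bond
donor/acceptor sum (HBD + HBA) is materialized as a panel column because
models use the sum, never the addends separately alongside it. TPSA is kept
apart from HBD + HBA by the clustering itself (they are near-collinear in
any realistic panel), never by a hard-coded rule.

Flat clusters are cut at a configurable similarity threshold (default
50 %). Admissible predictor sets contain exactly one lipophilicity
descriptor plus at most one member of each flat cluster, up to a maximum
size (default 3, i.e. one lipophilic + one steric + one electronic term).
With the default variable set {MW, TPSA, α, HBD_HBA, NRB}, two flat
clusters and two lipophilicity scales, the exhaustive enumeration yields
exactly 24 candidate models per endpoint. VIFs are computed from
least-squares projections so perfectly collinear descriptors report an
infinite VIF with a flag instead of crashing.

## MLR statistics

All fits are OLS with intercept (statsmodels under the hood). Definitions,
chosen once and printed side by side to avoid the usual ambiguities:

| quantity | definition |
|---|---|
| SD | √(RSS/(n − p − 1)) — residual standard deviation |
| MSE | RSS/n — reported distinctly from SD² |
| R² | 1 − RSS/SST (SST centered) |
| R²_adj | 1 − (1 − R²)(n − 1)/(n − p − 1) |
| PRESS | Σ(eᵢ/(1 − hᵢᵢ))² — hat-matrix leave-one-out identity |
| R²_pred | 1 − PRESS/SST |
| Q²_cv | same construction; equals R²_pred by the LOO identity |

`press_statistics` recomputes PRESS by an explicit n-fold refit loop and
aborts if the two routes disagree beyond 1e−10 — the shortcut is never
trusted unchecked. Standardized coefficients are `bⱼ·sd(xⱼ)/sd(y)` with
n−1 denominators and equal the slopes of a z-scored refit (asserted in
tests). Model search ranks by R²_adj (comparable across predictor counts)
descending with PRESS ascending as tie-break and predictor names as the
final total order, so rankings are deterministic. An F statistic is
computed for every model even though it is not part of the ranking.
Responses are taken from the panel columns exactly as supplied (in-silico
endpoint values, or probit HC50 on the µM scale untransformed); the package
never recomputes in-silico descriptors.

## Applicability domain and cross-validation

Leverages are the diagonal of the hat matrix of the intercept-augmented
design (computed by dense QR; Σhᵢᵢ = p + 1 is asserted to 1e−10).
The warning leverage is `h* = 3(p + 1)/n`. Residuals in the Williams plot
are internally studentized, `eᵢ/(SD·√(1 − hᵢᵢ))`, with plain `eᵢ/SD`
available as an option; the band is ±3. Flags are `high_leverage`
(hᵢᵢ > h*), `outlier_response` (|residual| > 3), `both`, or `in_domain`.
Out-of-domain compounds are flagged, never removed — refitting without them
is an explicit user action. Extreme input values (e.g. one compound with
log P_o/w far outside the panel range) are retained at parse time for the
same reason: outlier status is the AD module's verdict, not the reader's.

Leave-one-out Q² equals the PRESS-based R²_pred (cross-checked to 1e−10).
Leave-33%-out draws ⌈n/3⌉ compounds per repeat, 100 repeats by default,
from a generator seeded with a recorded seed (default 20250204), so every
report is bit-reproducible. Rank-deficient training folds are skipped with
a warning and counted rather than silently imputed.

## Synthetic data: what it emulates

The generator reproduces the statistical structure a phenoxyacetic-acid
congener panel presents to this pipeline, at the study geometry of n = 29
compounds:

* **Descriptor envelopes** — MW 166–293 g·mol⁻¹, TPSA 46.5–95.4 Å²,
  α 16.3–33.8 ų, HBD 1–2, HBA 3–6, NRB 3–7, log P_o/w 0.42–3.38.
* **Two correlated blocks.** One latent uniform per compound drives the
  electronic block: integer HBD/HBA are quantized from it and TPSA is a
  linear map of HBD + HBA plus Gaussian noise whose SD is solved
  analytically for a target correlation of 0.96. A second latent drives the
  structural block: NRB is quantized and MW and α are linear-plus-noise
  with the pairwise correlation r solving (2r + r²)/3 = 0.84 for the block
  mean. Quantizing integers *first* and deriving the continuous partners
  from them keeps the discrete marginals from destroying the intended
  correlations. Achieved values average 0.97 and 0.85 over 200 seeds.
* **Collander chain** — log k_IAM linear in log P_o/w (noise SD 0.10);
  log k_BMC = 0.437·log k_IAM + 0.684 + N(0, 0.1062).
* **A planted outlier** — compound "12" at log P_o/w = 6.535, far outside
  the panel envelope, as a known high-leverage point (switchable off). Its
  leverage fluctuates around h* across seeds, so recovery tests assert a
  ≥ 90 % flag rate over 100 seeds rather than certainty.
* **Endpoints** — linear three-descriptor responses with positive
  coefficients on lipophilicity and polarizability and negative on
  HBD + HBA; HC50 (µM) positive on lipophilicity and MW, negative on HBA,
  spanning roughly 1.1–1.8 mM.
* **Emitted raw data** — triplicate retention times
  t_r = t₀(1 + 10^{log k})(1 + ε), t₀ = 1 min, ε ~ N(0, 0.002), and
  hemolysis absorbance curves on the standard ten-concentration grid
  (250–4000 µM) from a probit model with slope 3 probits/decade,
  blank 0.05 AU, control 1.00 AU, replicate noise 2 % of the span.

All randomness flows from a single integer seed; identical seeds give
bit-identical bundles.

What the generator does *not* emulate: nonlinear structure–retention
relations, ionization effects (pKa is drawn but inert), heteroscedastic or
drifting assay noise, inter-plate effects, and measurement error in the
in-silico descriptors themselves. Tests passing on synthetic panels
therefore demonstrate that the pipeline recovers the structure it assumes
when that structure is present — they do not validate the linear-QSPR
assumption for any particular real chemistry.

## Numerical choices and degenerate inputs

* Exact fits: SD below 1e−10 of the response scale is treated as zero and
  studentized residuals are reported as 0 rather than noise ratios.
* Leverage numerically ≥ 1 (self-predicting point) is an error everywhere
  PRESS or studentized residuals are needed.
* Rank-deficient designs raise an error naming the dependent columns;
  candidate sets that cannot be fitted are dropped from a search with the
  reason recorded, and a search errors only if *no* candidate fits.
* Complete-case fitting per candidate: compounds missing a response or a
  predictor are dropped for that model only; missing cells parse as
  missing, never as zero.
* Pipeline outputs serialize floats at 12 significant digits so reruns with
  the same config and seed are byte-identical; the panel CSV writer uses
  shortest-roundtrip reprs so read(write(panel)) is bit-exact.

## Test-suite problem sizes

Property tests run at the study geometry (n = 29, p ≤ 3): 500-curve probit
recovery, 500-fit coefficient coverage (3-SE coverage asserted as the
pooled rate ≥ 99 %, the t-distribution expectation being ≈ 99.4 %),
200-panel planted-model recovery, 100-instance PRESS-identity checks and a
100-seed end-to-end run; the full suite completes in well under a minute.
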