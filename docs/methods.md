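# Methods

## Statistical model

All estimation assumes the balanced randomized-complete-block (RCBD)
plot model

    y_ij = μ + g_i + ρ_j + e_ij ,   i = 1..f families, j = 1..r replicates,

with family effects `g_i` (variance σ²g), block effects `ρ_j`, and plot
errors `e_ij` (variance σ²e).  The two-way decomposition gives the
family mean square `MF` with expectation `σ²e + r·σ²g` and the error
mean square `ME` with expectation `σ²e`; components follow as

    σ²g = (MF − ME)/r ,   σ²e = ME ,   σ²p = σ²g + σ²e .

The same decomposition applied to cross-products of trait pairs yields
genotypic (G), error (E) and phenotypic (P = G + E) covariance
matrices.  Two conventions in this definition matter:

* **Plot-mean expectation scale.**  σ²p is σ²g + σ²e, *not*
  σ²g + σ²e/r.  Under this convention broad-sense heritability obeys
  `h²_b = 100·(GCV/PCV)²` exactly, which is the internal-consistency
  identity of the source study's summary tables, and the per-trait
  predicted gains `h²·(X_S − x̄)` reproduce its gain tables.
* **Family-mean scale for response prediction.**  Selection in a family
  trial operates on family means, whose phenotypic variance is
  σ²g + σ²e/r.  The regression of the genotypic effect on the observed
  family mean — hence the expected realized response — uses that
  variance.  `predicted_gain_direct(K, σg_wi, σp_i)` is deliberately
  basis-agnostic: reproducing the study's printed tables feeds it
  plot-basis quantities; the breeder's-equation recovery check feeds it
  family-mean-basis quantities, which is the exact prediction under the
  generative model.  Reports use the plot-basis convention throughout.

Negative estimated genotypic *variances* (possible whenever MF < ME)
are truncated to zero with a warning, preventing imaginary GCV values;
off-diagonal covariances are left untouched and the raw matrix is kept
on the result (`G_raw`) for audit.

F2 heritability uses the parent-variance estimator
`h²_b = 100·(VF₂ − (VP₁ + VP₂))/VF₂`, taking the *sum* of the two
parents' phenotypic variances as the environmental term (config
`f2_env="sum"`).  The conventional estimator uses the parents' *mean*;
both are available, the sum is the default because it is the form the
source study states.  With the sum convention the estimate can fall
below zero for low-heritability traits; it is then clamped to [0, 100]
with a warning.

Correlations: `r_p = σp_ij/√(σp_ii σp_jj)`, `r_g` analogously from G.
Genotypic correlations can legitimately exceed |1| when component
estimates are noisy; they are never clamped.  Significance for both
uses the two-sided t approximation `t = r·√((n−2)/(1−r²))` with n − 2
degrees of freedom and n the family count (configurable to plot count);
for r_g this is an approximation of convenience — no exact small-sample
test exists for ratio-of-components correlations — and pairs with
|r| ≥ 1 are flagged `**` directly.  Pairs with a zero variance are
reported missing, not zero.

## Selection procedures

Eight procedures are built in (any custom `IndexDefinition` works too):

| name  | kind            | traits                               |
|-------|-----------------|--------------------------------------|
| Ped.1 | direct          | lint yield/plant                     |
| Ped.2 | direct          | lint percentage                      |
| Ped.3 | direct          | lint index                           |
| I.1   | Smith–Hazel     | yield + components (7 traits)        |
| I.2   | Smith–Hazel     | BW, S/B, SI, FL, PI                  |
| I.3   | Smith–Hazel     | LP%, LI, FL, UI%                     |
| I.4   | Smith–Hazel     | all 11 traits                        |
| I.5   | multiplicative  | all 11 traits                        |

Smith–Hazel weights solve `P_sub·b = G_sub·a` by LU factorization
(`numpy.linalg.solve`); the phenotypic submatrix is rejected when its
condition number exceeds 1e12, naming the offending traits.  Economic
weights default to `a = 1` ("equally important").  A direct procedure
is the single-trait degenerate case `b = σ²g/σ²p`, a positive scalar
whenever σ²g > 0, so its ranking coincides with ranking on the trait
mean.

The multiplicative index's exact historical form is not fully
specified in the source material; an Elston-style weight-free form is
adopted: orient each trait so larger is better (`z = d·x`, micronaire
d = −1), set the baseline `k_j = min(z_j) − ε_j` with
`ε_j = 0.01·range(z_j)` (one trait unit when the range is zero, so a
constant trait contributes a constant positive factor and never zeroes
the product), and score each family as `Π_j (z_ij − k_j)`.  The ε rule
keeps every factor strictly positive while staying proportional to the
trait's observed spread; rankings are invariant to positive affine
rescaling of any trait.

Truncation selection takes the top `max(1, round_half_up(intensity·f))`
families (or an explicit count); ties at the cut break by original
listing order, which is deterministic and documented.  At the study's
dimensions, 10% of 76 families selects 8.

## Gains bookkeeping

For each procedure and each trait w the selected group induces an
achieved differential `X_S,w − x̄_w`; the tabulated predicted gain is
`h²_w · (X_S,w − x̄_w)` — this single rule covers direct procedures
(where it is the textbook response) and index procedures (where it is
the correlated response through the group the index actually selected),
and is the rule consistent with the source study's gain tables.  The
index-theoretic selection advance is also available:
`predicted_gain_index` with `mode="standard"` computes
`SD_I·b′g_w/(b′Pb)` (achieved index-scale differential times the
regression of the target's genotypic value on the index) and reduces
exactly to the direct formula for one-trait indices; the source's
square-root form `SD·(Σ b_i σg_iw)^½` is kept verbatim under
`mode="as_printed"` although it is dimensionally anomalous (NaN with a
warning when the bracket is negative).

Realized gain is `procedure group mean − generation mean` in the *next*
generation's trial, matching offspring to parents by family id.  Note
that when the next trial contains only selected material (as in the
emulated design), its generation mean is itself elevated, so realized
gains systematically undershoot predictions — a property of the design,
not an estimator defect.

Percentages divide by the same generation's mean for predicted gains
and by the next generation's mean for realized gains.  Report values
round half-up to 2 decimals, and the percentage columns are computed
*after* rounding the gain — both conventions chosen to reproduce the
source tables' cells from their own inputs.  Better-parent percentages
use the direction-aware better parent (larger mean, except smaller for
micronaire).

## Synthetic-data generator

`default_scenario()` back-solves the generator's parameters from the
published F3 trial summaries of the Giza 86 × Menoufi cross:
`σg = GCV·x̄/100`, `σp = PCV·x̄/100`, `σ²e = σ²p − σ²g` per trait;
off-diagonals from the published F3 genotypic/phenotypic correlations;
and each assembled matrix is projected to the nearest positive
semi-definite matrix by eigenvalue clipping at zero (the published
correlations, being estimates, do not form a valid covariance matrix
verbatim — one genotypic correlation even exceeds |1|).  E is obtained
as the PSD projection of P − G, and the model's P is then G + E, so the
component identity holds exactly.  Defaults mirror the study: 76 F3
families, 3 replicates, 439 F2 plants, 30 plants per parent, selection
intensities 0.15 (F2 plants) and 0.10 (F3 families), block-effect
variance 0 (the replicate stratum is estimated but never used
downstream).  Generation means are the published F2/F3/F4 means; the F2
nursery carries only the seven yield traits recorded there.

Sampling is multivariate normal via a symmetric eigendecomposition
square root, fully deterministic under a seed (`numpy` Generator;
nested stages use spawned child seeds).  Draws are clipped to trait
domains (counts ≥ 0, percentages in (0, 100)); at the calibrated
parameters this touches well under 0.1% of draws and its moment
distortion is far below Monte-Carlo resolution.

Response to selection: each selected family founds one offspring family
with genotypic effect `t·g_parent + MVN(0, (1 − t²)·G)`, transmission
`t = 1` by default (fully heritable family effects, variance-
preserving).  This is an idealization — real selfing series change
genetic variance through inbreeding and segregation — and is what makes
the breeder's-equation recovery an exact benchmark rather than a
biological claim.

What the generator does *not* emulate: genotype × environment
interaction, spatial field trends, within-family plant variance in
replicated trials (plots are the observational unit), inbreeding
depression, non-normal trait distributions, and any genetic linkage
between the simulated F2 nursery and the F3 families (the F3 founders
are drawn directly from G).  Consequences worth knowing: emulated F2
summaries inherit the F3-calibrated variances, so they are tamer than
the published F2 generation (whose variability was much larger), and
the `sum`-convention F2 heritability can clamp at zero for
low-heritability traits.  Passing tests demonstrate that the estimators
recover the generative model's truth — not that field data meet the
model's assumptions.

## Monte-Carlo problem sizes and tolerances

The recovery studies use 500 simulated trials at f = 200 (component
recovery, each genotypic covariance entry within 3 Monte-Carlo SE of
truth), 500 two-generation replicates at the study dimensions
(breeder's equation, paired 3-SE check), 1000 random positive-definite
systems (Smith–Hazel residual ≤ 1e-8 relative), and 100 random
scenarios for the single-trait degeneracy identity — sizes at which the
3-SE bands are a few percent of the target quantities while the whole
suite stays fast.  Matrix symmetry is enforced to 1e-9 on the
standardized scale; sums-of-squares additivity is verified to 1e-8
relative.

Deterministic reproduction checks of the published cells compare at the
printed precision: exact 2-dp equality where the inputs are exact
(gains, realized gain, better-parent percentage) and ±0.01 for the
heritability–CV identity, whose printed inputs (GCV, PCV) are
themselves rounded to 2 dp and propagate up to one unit in the last
digit.

## Known limitations

* Balanced designs only; any missing plot is a hard error by design
  (the expected-mean-square algebra assumes balance).  No REML, no
  unbalanced or incomplete blocks, no spatial adjustment.
* Broad-sense parameters only; no additive/dominance partition, so
  "heritability" here includes all genotypic variance among selfed
  families.
* The r_g significance test is an approximation (see above).
* The F2 index procedure (I.1 on plants) estimates G as the F2 plant
  covariance minus the pooled parent-plant covariance — a classical
  trick that requires parent plants grown alongside and assumes a
  shared environmental covariance.
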