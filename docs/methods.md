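# Methods

This note documents the models implemented in `trophont`, the choices made
where the underlying field conventions leave room, and what the synthetic
study system does and does not emulate.

## Diet model

Stomach contents are recorded as *fullness points*: each prey category's
contribution to the visually estimated total stomach fullness (0–100 %).
Individual diet proportions are points normalized within the fish;
categories are standardized across lakes through an explicit prey-category
map (every raw label must resolve, unknown labels are an error, and a
subset of standardized categories is marked as fish prey).

**Population diet `q`.** By default `q_j` is the unweighted arithmetic
mean of the individual proportion rows, so a full stomach counts no more
than a nearly empty one; a pooled-points alternative (rows weighted by
total fullness) is available via `population_diet(..., method="pooled")`.
The population is the lake by default; a pooled-per-community-type scope
(`q_scope: community`) is available for cross-lake analyses.

**Specialization.** `1 − PS_i = 0.5 Σ_j |p_ij − q_j|`, half the L1
distance between the individual and population simplex vectors. Inputs
are validated to sum to 1 within 1e−6; the statistic is exactly 0 iff
`p = q` and bounded by 1.

**Empty stomachs** carry no diet information: they are excluded from the
diet matrix *and* from piscivory-prevalence denominators. This is a
package design decision (prevalence could alternatively count empty
stomachs as non-piscivorous); the pipeline logs every exclusion so the
denominators are auditable.

**Unidentifiable remains** are kept as an explicit `unidentified`
category rather than discarded; they can be excluded by supplying a map
without that category.

## Two-source mixing model

Littoral reliance is the two-point linear mixing proportion on the carbon
axis, `α = (δ¹³C_c − δ¹³C_pel)/(δ¹³C_lit − δ¹³C_pel)`, clamped to [0, 1]
(clamping events are counted and reported). Trophic position references
the consumer's δ¹⁵N against the α-weighted baseline:
`TP = λ + (δ¹⁵N_c − [α δ¹⁵N_lit + (1−α) δ¹⁵N_pel]) / Δ¹⁵N`.

The cited two-source formulation does not fix its constants, so they are
parameters with the conventional defaults: baseline trophic level
`λ = 2.0` (primary-consumer end-members), fractionation
`Δ¹⁵N = 3.4 ‰` per trophic level, and no trophic correction of δ¹³C
(carbon fractionation treated as 0, keeping the model two-parameter).
These are reconstructions of the standard convention, not values taken
from a specific dataset, and all three are configurable.

End-members must be separated by more than `ε = 0.5 ‰` in δ¹³C;
below that the mixing line is numerically meaningless and baseline
aggregation fails loudly. Baselines are habitat-wise arithmetic means of
the invertebrate samples (no gear weighting). Single-member summary
groups report SD = 0 with an explicit `n1_flag` rather than omitting the
row.

## Piscivory onset

Fish-prey presence/absence in the stomach is modelled as a binomial GLM
with logit link on fork length, fitted by IRLS with step-halving so the
deviance is monotone non-increasing (tolerance 1e−8 on the relative
deviance change, at most 100 iterations). Standard errors come from the
inverse Fisher information. Complete separation is detected exactly for
the single covariate (disjoint length ranges of the two classes) before
fitting, and a divergence guard catches quasi-separation. One-class data
— every trout-only system — raise a dedicated degenerate-classes error:
an onset length is undefined where piscivory never occurs, and the
pipeline reports the row as such instead of a number.

The onset is `L₅₀ = −β₀/β₁`, and more generally
`L_p = (logit(p) − β₀)/β₁`, defined only for β₁ > 0.

## Spline trend models

Each trend model is a Gaussian additive mixed model
`y = f(x) + b_lake + e` with

* `f`: natural cubic regression spline in value-at-knot parameterization
  (Green–Silverman construction) on `k = 3` knots at evenly spaced
  covariate quantiles, with the exact curvature penalty
  `∫ f''(x)² dx = δ' D' B⁻¹ D δ`. Three knots cap the curve at a single
  bend, a deliberate guard against overfitting at field sample sizes.
* sum-to-zero centering of the smooth over the data (QR null-space
  reparameterization), leaving the model intercept identifiable; the
  smooth's unpenalized null space is the linear trend, so its effective
  degrees of freedom run from 1 to `k − 1`;
* per-lake random intercepts as a ridge-penalized dummy block — with
  three lakes per community type the data cannot support random slopes
  or smooths;
* the two penalty weights selected by REML (Gaussian restricted
  likelihood with the penalty as an improper prior), optimized by
  Nelder–Mead over log-weights from a coarse grid start, penalty blocks
  rescaled to the magnitude of their design blocks. GCV is available as
  an alternative criterion.

Significance of the smooth uses a Wald-type statistic on the whitened
fitted-smooth coefficients with a fractional-rank pseudo-inverse of
their Bayesian covariance at rank = edf, referred to
`F(edf, n − edf_total)` — the standard approximate test for penalized
smooths. Against R's `mgcv` (`s(x, k=3, bs="cr") + s(lake, bs="re")`,
REML) the fitted curves agree to ~1e−7 and edf to ~1e−6 on shared test
data; the F statistics differ by under 1 % due to the rank-handling
convention. Reported degrees of freedom are the smooth's edf, which is
why they are non-integer. A within-lake permutation test (covariate
permuted within each lake, seeded) is provided as a small-sample
alternative.

Predictions are defined on the observed covariate range only; requests
outside it raise. A constant response yields the degenerate flat fit
(edf → 1, F = 0, p = 1) rather than an error.

**Sensitivity analysis.** The trend models are refitted after excluding
fish above 400 mm fork length; the threshold is inclusive (a fish of
exactly 400 mm is retained, since the exclusion targets fish *above*
400 mm). The rerun differs from the main fit only through this filter,
which the pipeline verifies is inert for communities without large fish.

## Remaining statistics

Community-type contrasts of TP and `1 − PS_i` use the tie-corrected
Kruskal–Wallis H with a χ² approximation on `groups − 1` degrees of
freedom (delegated to scipy behind the package surface). Some reports in
this literature label the three-group statistic "Z"; this package reports
H with its df and does not emulate that labeling. The
piscivory–abundance association is reported as Pearson's r by default —
"Pearson's rank correlation" is a contradiction in terms, so both
Pearson and Spearman are provided and the choice is a config switch.
All-identical samples return H = 0, p = 1 (no separation) rather than an
error. CPUE is `100 · count / (net area · nights)` summed over rows of a
lake × habitat × species cell, so splitting one catch across rows of the
same recorded effort is neutral.

## Synthetic study system

The generator emulates the nine-lake design: three community
configurations × three lakes, brown trout sampled in each. Defaults are
chosen once to be field-realistic for subarctic lakes rather than
calibrated to any particular dataset:

| parameter | trout_only | two_species | three_species |
|---|---|---|---|
| trout per lake | 90 | 45 | 74 |
| length median (mm) / lognormal σ | 170 / 0.45 | 230 / 0.50 | 240 / 0.55 |
| length truncation (mm) | 80–380 | 90–560 | 90–650 |
| piscivory logit (β₀, β₁ per mm) | disabled | (−5.4, 0.01) | (−3.9, 0.01) |
| implied L₅₀ (mm) | — | 540 | 390 |
| TP link (intercept, slope per mm) | (1.85, 0.0018) | (2.2, 0.0015) | (2.1, 0.0024) |

Littoral reliance is Beta(4, 2) (trout are predominantly littoral
feeders; Beta(5, 2) in trout-only systems), isotope noise is independent
Gaussian with SD 0.3 ‰ (δ¹³C) and 0.2 ‰ (δ¹⁵N) — instrument-scale
working-standard variability — and baselines are 8 samples per habitat
with 0.5 ‰ scatter around littoral (−20, 3) and pelagic (−30, 4) ‰
end-members. Diet proportions are Dirichlet over eight invertebrate
categories with small concentration totals (≈3), which produces the
strong between-individual heterogeneity (mean `1 − PS_i` near 0.5–0.6)
typical of these generalist populations; piscivores additionally receive
a Beta(4, 2) fish-prey share, tying the specialization signal to the
size-dependent piscivory. Stomachs are empty with probability 0.1.
Catches are Poisson counts per habitat from per-species expected CPUE
(net area 270 m², 2 nights — the survey effort is configurable since no
standard value exists).

Two structural choices make the generator a usable oracle: fish isotopes
are generated by inverting the mixing model against the lake's *realized*
baseline sample means (so zero-noise recovery is exact, independent of
baseline scatter), and the piscivory indicator is drawn first with the
fish-prey share forced positive iff the indicator fired (so stomach flags
and underlying state never disagree on non-empty stomachs). Per-lake
seeds are spawned from the master `SeedSequence` in fixed lake order,
making multi-lake studies reproducible piecewise.

**What the generator does not emulate** — and hence what passing tests do
not establish about field data: prey-availability-driven diet composition
(diet heterogeneity is exchangeable across individuals given the
community, not habitat- or density-structured), length-dependent
invertebrate diet shifts, isotopic routing and turnover, lake-to-lake
variation in baselines beyond sampling scatter, charr and stickleback
stomachs (only the trout analyses need stomach data), and any covariance
between emptiness and fish size. Parameter-recovery results therefore
validate the estimators under the stated model, not the model itself.

## Problem sizes and tolerances

Calibration checks use 500 replicate spline fits (null) and 100
(power) at n = 120–220, 1000 Kruskal–Wallis null replicates at
3 × 30, 200 logistic replicates at n = 500, and a 50 × 50 inversion
grid — sizes chosen so the whole suite runs in about a minute while
keeping Monte-Carlo error well inside the asserted bands (±2 percentage
points on rejection rates). Exact identities are asserted at 1e−9–1e−12;
cross-library comparisons at the agreement levels stated above. The
pipeline writes floats at 10 significant digits with fixed line endings,
which is what makes byte-identical determinism checks possible.
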