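# Methods

## The stability model and its estimation

The package models the g × e table of within-environment variety means
for one trait as `y_ij = V_i + b_i E_j + error_ij`. The bilinear part is
only identified up to `(b, E) → (b/c, cE)` and a shift of `E` absorbed
into `V`, so two constraints are imposed: `Σ_j E_j = 0` (unweighted) and
`mean_i(b_i) = 1`. The mean-1 convention makes `b_i` directly readable
as relative environmental sensitivity (1 = average response) and is the
convention under which published sensitivity quadruples for this kind of
trial average to ≈ 1; the reference variety summaries embedded in
`oatmet.datasets` satisfy it to within rounding (all twelve trait-wise
slope means lie in [0.989, 1.0]).

Estimation is alternating least squares (ALS) on the observed cells:

1. given `E`: per-variety ordinary least squares of `y_i·` on `E`
   yields `(V_i, b_i)`;
2. given `(V, b)`: `E_j = Σ_i b_i (y_ij − V_i) / Σ_i b_i²` over
   observed cells — the exact conditional least-squares update;
3. re-identification: `mean(E)` is absorbed into `V`, then `(b, E)` is
   rescaled so `mean(b) = 1`. Fitted values are invariant to this.

Both updates are exact coordinate minimisations, so the residual sum of
squares is non-increasing across sweeps.

**Initialisation.** The sweep loop starts from `b = 1` and `E` equal to
the leading right singular direction of the row-centred matrix (missing
cells zero-filled), centred. This start is deterministic (no RNG) and,
for complete tables, already lies on the least-squares solution, so the
number of sweeps does not blow up when the top two singular values of
the row-centred matrix are nearly equal. A simpler start at the centred
observed environment means turns ALS into power iteration, whose
contraction factor is the squared singular-value ratio: with a ratio of
0.997 it cannot reach 1e-8 parameter accuracy within any reasonable
sweep budget. With missing cells the warm start is only approximate and
the ALS sweeps do the real work.

**Convergence.** The loop stops when the relative RSS change between
sweeps is ≤ `tol` (default 1e-10) *and* the parameters themselves have
stabilised (relative change ≤ 1e-12), or immediately when the RSS falls
below 1e-12 of the data's total sum of squares (an interpolating,
"exact" fit — flagged as such). The RSS criterion alone is insufficient
because the RSS flattens quadratically in the parameter error while the
bilinear direction can still rotate. Exceeding `max_iter` (default 500)
flags `converged=False` on the result rather than raising, so batch
studies can filter instead of crash.

**Degenerate inputs.** If the row-centred matrix is numerically zero
(environments indistinguishable once variety means are removed), slopes
are undefined and the fit raises with advice to use an additive model.
A mean sensitivity collapsing to zero (an anti-symmetric interaction
pattern with no common response direction) also raises: the mean-1
constraint cannot be imposed there.

**Inference.** Error degrees of freedom are
`N_obs − (2g + e − 2)`: g means, g slopes and e indices less the two
identification constraints; missing cells reduce `N_obs` only. Slope
heterogeneity is tested with
`F = [Σ_i (b_i − 1)² Σ_{j∈obs(i)} E_j² / (g − 1)] / MS_resid` on
`(g − 1, df_err)`; variety means with the analogous weighted
between-variety sum of squares. Standard errors and these F tests are
**conditional on the final E** — the classical joint-regression
reporting convention. They ignore the sampling variability of `E`
itself and therefore understate uncertainty slightly; the fit records
this in `notes["se_convention"]`. The Monte-Carlo calibration below
measures the practical size distortion at the reference-trial geometry:
the slope-heterogeneity test rejects at 4.5–7% for nominal 5% over
1000 null simulations (g = 4, e = 22, σ_noise = 0.3 σ_E), i.e. close to
nominal but not exact, as expected for a conditional test. Stability
labels use a two-sided t test of `b_i = 1` at α = 0.05 on the pooled
error df (`sensitive` above, `stable` below, `average` otherwise); with
an interpolating fit the s.e. are zero and the label degenerates to the
sign of `b_i − 1` with a 1e-9 numerical guard.

For exact fits (zero residual) the heterogeneity and variety-effect
p-values are reported as 0 when the corresponding effect sum of squares
is positive (and 1 when it is exactly zero), with an `exact_fit` flag,
since no error variance is estimable.

## Trait formulas

* Groat content (%) = 100 × groat mass / (initial − residual mass);
  undefined when nothing was dehulled.
* Hullability (%) = 100 − 100 × residual / initial. Both percentages
  are invariant to rescaling all masses.
* Roundness = width / length; width > length warns (likely swapped
  dimensions) rather than errors.
* Protein (%) = N (%) × 5.36, the oat-specific nitrogen-to-protein
  (Jones) factor.
* Grain number (thousand m⁻²) = yield (t ha⁻¹) × 100 / TGW (g), since
  1 t ha⁻¹ = 100 g m⁻².
* Moisture adjustment conserves dry matter:
  `adjusted = fresh × (100 − measured) / (100 − target)`; the formula
  itself is a package choice, with 15% the standard UK trading target.

Checked against the embedded reference tables, the recomputed roundness
column matches the printed one to ≤ 0.0014 in 21 of 22 environments and
0.0022 in the last, and grain number to ≤ 1.7% relative in the 21
autumn-sown environments and 3.2% in the spring-sown one. The residual
discrepancies are an averaging-order artefact: the printed cells are
means of per-plot ratios, whereas recomputation can only form the ratio
of the printed means (plot-level data were never published), and
Jensen-type gaps grow with within-environment spread — largest in the
atypical spring-sown trial.

## Weather windows and correlations

Covariate windows are month/day spans anchored to the harvest year with
the autumn-sown crop calendar: window months from September onward
belong to the calendar year before harvest (so "Dec to April" before a
2013 harvest is 2012-12-01 .. 2013-04-30); explicit year offsets can
override this. Rainfall and radiation aggregate by summation, daily
temperature as the mean of the midrange `(tmin + tmax)/2` (the daily
mean definition is a package convention; weather records here carry no
hourly data). An aggregate is declared missing when more than 10% of
window days are absent.

Correlation grids use Pearson's product-moment r with *pairwise*
deletion: each trait × covariate cell keeps every environment where
both values exist, so traits with unrecorded sites lose only their own
degrees of freedom (the reference hectoliter-weight row has df 17 where
complete traits have df 19). Two-sided p-values come from
`t = r√(df/(1−r²))` on `df = n − 2`; stars are `*` p<0.05, `**` p<0.01,
`***` p<0.001. Spring-sown environments are excluded through a metadata
flag, not hard-coding.

## Biplot

Rows are variety–environment mean combinations, columns traits. Because
trait units are heterogeneous, columns are centred and scaled to unit
variance (correlation-matrix PCA) — the assumed convention, since such
plots are rarely published with their scaling stated. From
`Z = U S Vᵀ`, scores are `U S^α` and loadings `V S^(1−α)` with
symmetric `α = 0.5` by default (`row`/`column` variants available);
variance fractions are squared singular values over their total. Signs
are fixed by making the largest-magnitude loading on each axis
positive, so output is reproducible across linear-algebra back-ends.
Missing entries are mean-imputed per trait with the count logged (or
rows dropped on request); constant columns are dropped with a warning.

Per-variety convex hulls of the 2-D scores use the Andrew monotone
chain (counter-clockwise vertices, shoelace area), degrading to a
segment or point for collinear or tiny groups — cases qhull-style
libraries reject. A larger hull means greater between-environment
variation for that variety.

## Synthetic trial generator

`SyntheticTruth` draws `V ~ N(0, σ_V)`, `b ~ N(1, σ_b)` re-centred
affinely to mean exactly 1, and `E ~ N(0, σ_E)` re-centred to sum
exactly 0 (users may supply any of the three), then emits replicate
values `y_ijk = μ + V_i + b_i E_j + ε_ijk` in the long CSV dialect the
readers accept. Whole cells are deleted with a configurable
probability, except where deletion would leave a row or column with
fewer than two observed cells. Defaults are fixed at the reference
trial's geometry and scale: g = 4, e = 22, r = 3, μ = 8.16 t ha⁻¹,
σ_E = 1.6 (the sd of the trial's 22 printed environment yield means),
σ_noise = 0.48 = 0.3 σ_E, σ_b = 0.2 (between the tight printed yield
quadruple and the wide TGW one), σ_V = 0.5.

Weather linkage constructs the windowed aggregate directly as
`A_j = μ_A + σ_A (ρ·z(E_j) + √(1−ρ²)·noise)` and spreads it uniformly
over the window days (temperature as a constant midrange), so the
aggregate–index correlation converges to ρ and is exactly affine at
ρ = ±1. Constraints (rain ≥ 0, tmin ≤ tmax) hold by construction at the
default levels.

One root seed is split via `SeedSequence.spawn` into independent
streams for the truth draw, replicate noise, missingness and weather,
so sub-experiments are individually reproducible; identical seeds give
bit-identical tables.

What the generator does **not** emulate: spatial field trend and block
effects (noise is iid), heteroscedasticity across environments,
correlated multi-trait error structure, realistic rain
occurrence/intensity patterns, and the mean-of-ratios averaging that
produced the printed reference tables. Passing recovery and calibration
tests therefore certify the estimator under the model's own
assumptions, not robustness to field artefacts.

## Problem sizes used in the checks

The recovery study uses 200 simulated trials at the reference geometry
(4 × 22 × 3, σ_noise = 0.3 σ_E), where the slope-recovery RMSE is
≈ 0.035 against the ≤ 0.1 requirement; the null-calibration study uses
1000 simulated mean tables; the SVD-oracle check uses ten random
complete 4 × 6 matrices. All together they run in a few seconds on one
CPU.

## Known limitations

* Standard errors conditional on `E` (see above); no REML/mixed-model
  alternative (Shukla variance, AMMI with more than one multiplicative
  term) is provided.
* The exact weighting a particular commercial package applies to
  unbalanced tables in its joint-regression procedure is not public;
  with missing cells this implementation is the straightforward
  observed-cell least squares, and published s.e. columns from
  plot-level data are not reproducible without those data.
* Published per-environment tables are means of per-plot quantities, so
  ratio-type traits recomputed from them differ at the third decimal
  (quantified above).
* Weather covariates require daily series; no gap-filling beyond the
  10% missing-day tolerance.
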