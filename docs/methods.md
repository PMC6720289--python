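# Methods

## Goal-programming formulation

The panel supplies one goal per (country, indicator) pair: the composite
score `MEP_i = Σ_j w_j epi_ij` should match `epi_ij`.  Each goal equation
`Σ_k w_k epi_ik + d⁻_ij − d⁺_ij = epi_ij` introduces a nonnegative
deviation pair, and the weight vector is constrained to the unit simplex.
All three models are linear programs over the variable blocks
(`w`: m, `d⁻`, `d⁺`: n·m each, `D_j`: m, `Z`: 1, and `D`: 1 when the
minmax cap rows `Σ_i α_j d⁻_ij + β_j d⁺_ij ≤ D` are present).  `D_j`
(the per-indicator disagreement `Σ_i d⁻_ij + d⁺_ij`), and `Z = Σ_j D_j`
are carried as accounting variables/constraints; they never enter an
objective directly.  The objectives are

* weighted model: `Σ_ij (α_j d⁻_ij + β_j d⁺_ij)` (the "penalized Z"),
* minmax model: `D`,
* extended model: `λ · Σ_ij (α_j d⁻_ij + β_j d⁺_ij) + (1−λ) · D`.

The extended objective mixes the two terms **unnormalized**.  The two
requirements the extended model must satisfy — recovering the weighted
optimum at `λ=1` and the minmax optimum at `λ=0` — hold under this form,
and the smooth, monotone interpolation of `Z` and `D` across the sweep is
consistent with it.  Normalizing the terms to comparable scales would
change which intermediate `λ` corresponds to which compromise but not the
endpoint behaviour; we keep the plain convex mix.

Because `MEP_i` is a convex combination of country `i`'s scores, it always
lies inside `[min_j epi_ij, max_j epi_ij]` and hence in `[0, 100]`.

### Penalty switches

`α_j, β_j ∈ {0,1}` choose which deviation direction of indicator `j` is
penalized (e.g. penalize only overshooting a cost-like indicator).  The
default is all ones, in which case the penalized objective equals the
accounting total `Z` exactly.  `α_j = β_j = 0` is rejected: that
indicator's deviations would be costless and its disagreement accounting
meaningless.

### Degeneracy

The optimal *objective value* of each LP is unique; the optimal *weight
vector* often is not (flat faces of the polytope, zero weights on
redundant indicators).  The solver's basic optimal solution is reported
as-is — no secondary objective is added, keeping the problem linear — and
downstream summaries that must be stable (rankings, category ranges) are
treated as functions of the solve family, not of one weight vector.
Tests therefore pin objective values, accounting identities and score
ranges, not individual weights.

## Solving and post-processing

LPs are assembled sparse (CSR) and solved with HiGHS via
`scipy.optimize.linprog` (backends `highs`, `highs-ds`, `highs-ipm` are
selectable; all must agree on objectives to 1e−6).  HiGHS is
deterministic, so every solve — and hence the whole λ sweep — is
bit-reproducible.  After a solve:

1. weights are clipped of negative round-off (no renormalization needed;
   the simplex residual stays below 1e−9);
2. the elementwise minimum of `(d⁻, d⁺)` is subtracted from both, so the
   reported deviations satisfy complementarity `d⁻·d⁺ = 0` (a basic
   optimum already does under all-ones penalties; one-sided penalties can
   leave costless slack pairs);
3. `D_j`, `Z`, the penalized total and `D = max_j Σ_i α_j d⁻ + β_j d⁺`
   are recomputed from the cleaned deviations.

Every solution is validated before being returned: simplex membership,
goal-equation residuals (≤ 1e−6, scaled by the score magnitude),
complementarity, `Z = Σ_j D_j`, and the per-country score range.  A
failed check raises rather than returning a silently wrong solution.

The λ grid is built by index (`λ_k = start + k·step`, endpoint assigned
exactly) to avoid floating-point drift at `λ = 1`; the default sweep is
the inclusive 101-point grid with step 0.01.

## Brute-force verification oracle

`grid_oracle` enumerates the weight lattice `{w : w_j = k_j·step, Σ w = 1}`
(guarded at 10⁷ points) and minimizes any of the three criteria through
the closed-form evaluator (`d⁻ = max(epi − MEP, 0)`, etc. — solver-free).
The lattice is a finite subset of the feasible region, so the LP optimum
is a lower bound for the oracle minimum; refining the step through nested
lattices (0.1, 0.01, 0.001) shrinks the gap.  The residual gap at a fixed
step is governed by the objective's Lipschitz constant in `w` — of order
`n·m·100` index points per unit of weight — times the distance from the
optimum to the nearest lattice point, so on small panels it is typically
of order 10⁻² rather than solver precision; when the optimum happens to
sit on a lattice vertex the gap is exactly zero.

## Quartiles, ranking, tie-breaks

Per-country MEP distributions over the sweep are summarized with min,
quartiles and max using linear interpolation between order statistics
(numpy's default, the common "type 7" rule); the convention only affects
summary edges, never the median ranking.  Ranking sorts by descending
median MEP with ties broken alphabetically by country identifier (stable
sort on an alphabetically pre-sorted index).  Issue-category weights are
sums of member-indicator weights, so they sum to one at every λ.

## Descriptive statistics

Skewness and kurtosis use the population-moment conventions
`g1 = m3/m2^{3/2}` and excess `g2 = m4/m2² − 3` (no small-sample bias
adjustment); the standard deviation uses the n−1 denominator.  For broad
0–100 distributions the excess-kurtosis convention is the one that yields
the familiar values near −1, and at n ≈ 90 the adjusted/unadjusted
difference is within reporting precision, which is why published tables
are only asserted to one decimal for the shape statistics.  Correlations
are Pearson product-moment coefficients; constant columns yield NaN with
a warning.

## Synthetic panels

The generator emulates the three features of real standardized
environmental panels that the models are sensitive to:

* **bounded 0–100 scores** — per-indicator beta marginals scaled by 100;
* **mild left skew** — beta shape parameters are moment-matched to target
  mean/sd, so means above the midpoint automatically give left-skewed,
  platykurtic marginals like those observed in practice;
* **weak dependence with signed anchors** — a Gaussian copula with a
  target correlation matrix, by default identity plus a −0.49
  drinking-water/wastewater trade-off pair and a +0.48
  biome-protection/PM2.5 synergy pair.

The default study conditions (`epi_like_spec`) are 91 countries and the
24 indicators of the 2018 EPI hierarchy, with per-indicator means and
standard deviations set to the published values of the 91-country
complete-case sample.  The copula was chosen over a truncated
multivariate normal so marginal shape and dependence can be controlled
independently; the monotone marginal transforms (and the final clip to
[0, 100], which almost never binds) slightly attenuate extreme target
correlations.  Seeds are mandatory — there is no hidden global
randomness, and the same seed reproduces a panel bit-for-bit.

What the generator does **not** emulate: the full 24×24 empirical
correlation structure (only the two signed anchors are targeted), spatial
or income clustering of countries, and any particular country's profile.
Tests passing on synthetic panels therefore demonstrate the correctness
and stability of the estimation machinery under realistic marginals and
dependence, not the numerical results of any specific published dataset;
those are reproduced separately when the deposited panel CSV is supplied.

## Problem sizes

The unit and property tests run on panels up to 8×4 plus a handful of
5000-row draws for Monte-Carlo checks of the generator; the brute-force
oracle is exercised at steps down to 0.001 with m ≤ 3 (≈ 5·10⁵ lattice
points).  The acceptance script runs the full-scale configuration: a
91×24 panel and the 101-point sweep (101 LPs of ~4,400 variables each,
about a minute on one CPU).

## Known limitations

* Weight vectors at degenerate optima depend on the solver's pivoting;
  only objective values are solver-independent.
* The minmax model's "equidistant" solution (all `D_j` equal) is a
  property of particular datasets, not a theorem; on synthetic panels the
  cap is typically active on a subset of indicators.
* Indicator construction (log transforms, 0–100 standardization of raw
  data) is out of scope: inputs must arrive already standardized.
* With one-sided penalties the unpenalized direction of an indicator is
  only determined up to the post-processing convention.
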