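# mepgp

Objective weighting and aggregation of environmental performance
indicators into a single Multicriteria Environmental Performance (MEP)
score per country, via goal programming.

Composite environmental indices (such as the Environmental Performance
Index, EPI) rank countries by a weighted sum of standardized indicator
scores, with weights fixed by expert judgment.  Because indicators are
correlated — some pairs are synergistic, others are trade-offs — fixed
weights can silently over- or under-count whole environmental dimensions.
`mepgp` instead *estimates* the weights from the data: it finds the convex
combination of indicators that stays as close as possible to all of them
at once, and quantifies how the resulting country ranking shifts as the
notion of "close" moves between two extremes.

## The model

Given a complete panel of scores `epi_ij` (country `i = 1..n`, indicator
`j = 1..m`, each on a 0–100 scale), the composite score is
`MEP_i = Σ_j w_j · epi_ij` with `w` on the unit simplex.  Writing the
residual of each goal with nonnegative deviation variables,

```
Σ_k w_k epi_ik + d⁻_ij − d⁺_ij = epi_ij        Σ_j w_j = 1,  w, d⁻, d⁺ ≥ 0
```

three linear programs differ only in the norm applied to the deviations
(with per-indicator penalty switches `α_j, β_j ∈ {0,1}`):

* **weighted model (L1)** — minimize `Σ_ij (α_j d⁻_ij + β_j d⁺_ij)`:
  consensus with the majority trend of the indicators;
* **minmax model (L∞)** — minimize `D = max_j Σ_i (α_j d⁻_ij + β_j d⁺_ij)`:
  attention to the most conflicting indicator;
* **extended model** — minimize `λ·L1 + (1−λ)·D` for `λ ∈ [0,1]`,
  interpolating between the two (`λ=1` is the weighted model, `λ=0` the
  minmax one).

Sweeping `λ` over a grid yields a *distribution* of MEP values per country
rather than a single crisp score; countries are ranked by the median.  The
per-indicator disagreement `D_j = Σ_i (d⁻_ij + d⁺_ij)` and its total
`Z = Σ_j D_j` measure how far the composite sits from each indicator.
Zero weights are legitimate outcomes (a redundant indicator is explained
by the rest), and optimal weight vectors need not be unique — objective
values are the canonical quantities.

## Worked example

```python
import mepgp as M

# a 91 x 24 panel emulating the 2018 EPI complete-case sample
panel = M.synth_panel(M.epi_like_spec(seed=7))

wgp = M.solve_wgp(panel)
mm = M.solve_minmax(panel)
print(f"weighted model:  Z = {wgp.z:.1f}   D = {wgp.d:.1f}")
print(f"minmax model:    Z = {mm.z:.1f}   D = {mm.d:.1f}")

result = M.sweep(panel, step=0.1)          # 11 lambda values
print(M.rank_countries(result).head(3))
cw = M.category_weights(result, M.epi2018_hierarchy())
print("CCE weight range:", cw.ranges.loc["CCE"].round(3).to_dict())
```

prints

```
weighted model:  Z = 52842.4   D = 2999.4
minmax model:    Z = 54770.2   D = 2394.0
         rank  median_mep
country
C052        1   76.928630
C090        2   75.140955
C032        3   74.741106
CCE weight range: {'min': 0.155, 'max': 0.231}
```

The weighted model attains a lower total disagreement `Z` (its objective)
while the minmax model attains a lower supremum disagreement `D` (its
objective) — the trade-off the `λ` sweep explores.  Country `C052` keeps
the top median MEP across the sweep, and the Climate & Energy (CCE) issue
category carries between 15.5% and 23.1% of the total weight depending on
`λ`, against its fixed 18% in the EPI hierarchy.

The same operations are available from the shell:

```sh
mepgp synth --n 91 --seed 7 --out panel.csv
mepgp sweep --panel panel.csv --out tables/
mepgp describe --panel panel.csv --out stats.csv --corr corr.csv
mepgp epi-score --panel panel.csv --normalize --out epi.csv
```

To analyse a real panel, supply a CSV with a `country` column and one
0–100 numeric column per indicator code; countries with missing values are
dropped at load time.  The published 91-country EPI 2018 analysis is
reproduced by placing that dataset at `data/epi2018_scores.csv`.

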