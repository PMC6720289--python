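"""Sensitivity analysis over the extended-model mixing parameter.

Solving the extended goal program over a grid of ``lam`` values yields a
family of weight vectors and hence a distribution of composite scores per
country, summarized with boxplot statistics and a median-based ranking.
Category-level weight totals and the fixed-hierarchy (report-style) score
support comparison with conventional composite indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gp import DeviationConfig, GPSolution, SolverError, solve_extended
from .hierarchy import Hierarchy, composite_weights
from .panel import IndicatorPanel, aggregate_mep

__all__ = [
    "SweepResult",
    "CategoryWeights",
    "sweep",
    "rank_countries",
    "category_weights",
    "epi_score",
]


@dataclass(frozen=True)
class SweepResult:
    """Extended-model solutions over a lam grid plus per-country summaries."""

    lam_grid: np.ndarray
    solutions: list[GPSolution] = field(repr=False)
    mep_summary: pd.DataFrame
    ranking: pd.DataFrame

    @property
    def country_ids(self) -> list[str]:
        return self.solutions[0].country_ids

    def mep_matrix(self) -> pd.DataFrame:
        """Composite scores, one row per lam value, one column per country."""
        return pd.DataFrame(
            np.vstack([s.mep for s in self.solutions]),
            index=pd.Index(self.lam_grid, name="lam"),
            columns=self.country_ids,
        )

    def weights_matrix(self) -> pd.DataFrame:
        """Estimated weights, one row per lam value, one column per indicator."""
        return pd.DataFrame(
            np.vstack([s.weights for s in self.solutions]),
            index=pd.Index(self.lam_grid, name="lam"),
            columns=self.solutions[0].indicator_codes,
        )


@dataclass(frozen=True)
class CategoryWeights:
    """Issue-category weight totals per lam, with their ranges over the grid."""

    per_lambda: pd.DataFrame  # index lam, columns category codes
    ranges: pd.DataFrame  # index category code, columns min/max


def _lam_grid(lam_start: float, lam_end: float, step: float) -> np.ndarray:
    if not 0.0 <= lam_start <= lam_end <= 1.0:
        raise ValueError("need 0 <= lam_start <= lam_end <= 1")
    if step <= 0:
        raise ValueError("step must be positive")
    # build by index (lam_k = start + k*step) so the endpoint is hit exactly
    n_steps = int(round((lam_end - lam_start) / step))
    grid = lam_start + step * np.arange(n_steps + 1)
    grid[-1] = lam_end
    return np.round(np.clip(grid, 0.0, 1.0), 12)


def sweep(panel: IndicatorPanel, config: DeviationConfig | None = None,
          lam_start: float = 0.0, lam_end: float = 1.0, step: float = 0.01,
          solver: str = "highs") -> SweepResult:
    """Solve the extended model on an inclusive lam grid (default 101 points).

    The per-country summary reports min, quartiles (linear interpolation
    between order statistics) and max of the composite score across the
    grid; the ranking sorts by descending median, ties broken
    alphabetically by country identifier.
    """
    grid = _lam_grid(lam_start, lam_end, step)
    solutions = []
    for lam in grid:
        try:
            solutions.append(solve_extended(panel, float(lam), config, solver=solver))
        except SolverError as exc:
            raise SolverError(f"extended solve failed at lam={lam}: {exc}") from exc
    mep = np.vstack([s.mep for s in solutions])  # (n_lam, n_countries)
    q = np.percentile(mep, [0, 25, 50, 75, 100], axis=0)
    summary = pd.DataFrame(
        {"min": q[0], "q1": q[1], "median": q[2], "q3": q[3], "max": q[4]},
        index=pd.Index(panel.country_ids, name="country"),
    )
    result = SweepResult(
        lam_grid=grid, solutions=solutions, mep_summary=summary,
        ranking=_rank_from_summary(summary),
    )
    return result


def _rank_from_summary(summary: pd.DataFrame) -> pd.DataFrame:
    # alphabetical pre-sort + stable descending sort on the median
    # implements the documented tie-break
    order = summary.sort_index().sort_values("median", ascending=False, kind="stable")
    ranking = order[["median"]].copy()
    ranking.insert(0, "rank", np.arange(1, len(ranking) + 1))
    ranking.columns = ["rank", "median_mep"]
    return ranking


def rank_countries(result: SweepResult) -> pd.DataFrame:
    """Countries in descending order of median composite score.

    Ties are broken alphabetically by country identifier (stable sort on
    an alphabetically pre-sorted index).
    """
    if not result.solutions:
        raise ValueError("empty sweep result")
    return _rank_from_summary(result.mep_summary)


def category_weights(result: SweepResult, hierarchy: Hierarchy) -> CategoryWeights:
    """Aggregate estimated indicator weights to the issue-category level.

    A category's weight at each lam is the sum of its member indicators'
    weights, so the category totals sum to one for every lam.
    """
    weights = result.weights_matrix()
    mapping = hierarchy.category_of()
    missing = set(weights.columns) - set(mapping)
    extra = set(mapping) - set(weights.columns)
    if missing or extra:
        raise ValueError(
            f"hierarchy/panel indicator mismatch: panel-only {sorted(missing)}, "
            f"hierarchy-only {sorted(extra)}"
        )
    cat_codes = [c.code for c in hierarchy.categories]
    per_lam = pd.DataFrame(
        {code: weights[[i for i in weights.columns if mapping[i] == code]].sum(axis=1)
         for code in cat_codes},
        index=weights.index,
    )
    ranges = pd.DataFrame(
        {"min": per_lam.min(axis=0), "max": per_lam.max(axis=0)},
    )
    ranges.index.name = "category"
    return CategoryWeights(per_lambda=per_lam, ranges=ranges)


def epi_score(panel: IndicatorPanel, hierarchy: Hierarchy,
              normalize: bool = False) -> pd.Series:
    """Fixed-hierarchy composite score (report-style weights).

    ``score_i = sum_j w_j epi_ij`` with ``w`` the hierarchy's composite
    weights; with ``normalize`` the 0-100 result is divided by 100.
    """
    w = composite_weights(hierarchy)
    ordered = panel.subset(list(w)) if list(w) != panel.indicator_codes else panel
    values = aggregate_mep(ordered, np.array([w[c] for c in ordered.indicator_codes]))
    if normalize:
        values = values / 100.0
    return pd.Series(values, index=pd.Index(panel.country_ids, name="country"), name="epi_score")
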