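"""Country x indicator score panels.

An :class:`IndicatorPanel` holds a complete matrix of indicator scores,
one row per country and one column per indicator, every entry standardized
to the 0-100 scale used by environmental performance reports.  The panel is
the sole data input of the goal-programming models: completeness (no missing
cells) is a hard requirement because every score enters a goal equation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["IndicatorPanel", "load_panel", "write_panel", "aggregate_mep"]

logger = logging.getLogger(__name__)

#: tolerance for validating that user-supplied weights lie on the simplex
WEIGHT_TOL = 1e-9


@dataclass(frozen=True)
class IndicatorPanel:
    """A complete n x m matrix of 0-100 indicator scores.

    Parameters
    ----------
    country_ids
        Unique country identifiers, length n.
    indicator_codes
        Unique short indicator codes (e.g. three-letter acronyms), length m.
    scores
        Array of shape (n, m); every entry finite and in [0, 100].
    """

    country_ids: list[str]
    indicator_codes: list[str]
    scores: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "country_ids", [str(c) for c in self.country_ids])
        object.__setattr__(self, "indicator_codes", [str(c) for c in self.indicator_codes])
        n, m = self.shape
        if n < 1 or m < 1:
            raise ValueError("panel must contain at least one country and one indicator")
        if scores.shape != (n, m):
            raise ValueError(
                f"scores shape {scores.shape} does not match "
                f"{n} countries x {m} indicators"
            )
        if len(set(self.country_ids)) != n:
            raise ValueError("duplicate country identifiers")
        if len(set(self.indicator_codes)) != m:
            raise ValueError("duplicate indicator codes")
        if not np.all(np.isfinite(scores)):
            i, j = np.argwhere(~np.isfinite(scores))[0]
            raise ValueError(
                f"non-finite score for country {self.country_ids[i]!r}, "
                f"indicator {self.indicator_codes[j]!r}"
            )
        bad = (scores < 0) | (scores > 100)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"score out of [0, 100] for country {self.country_ids[i]!r}, "
                f"indicator {self.indicator_codes[j]!r}: {scores[i, j]}"
            )

    @property
    def n_countries(self) -> int:
        return len(self.country_ids)

    @property
    def n_indicators(self) -> int:
        return len(self.indicator_codes)

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.country_ids), len(self.indicator_codes)

    def to_frame(self) -> pd.DataFrame:
        """Return the panel as a DataFrame indexed by country."""
        return pd.DataFrame(
            self.scores, index=pd.Index(self.country_ids, name="country"),
            columns=self.indicator_codes,
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "IndicatorPanel":
        """Build a panel from a country-indexed DataFrame of scores."""
        return cls(
            country_ids=[str(c) for c in frame.index],
            indicator_codes=[str(c) for c in frame.columns],
            scores=frame.to_numpy(dtype=float),
        )

    def subset(self, indicator_codes: list[str]) -> "IndicatorPanel":
        """Return a panel restricted to (and ordered by) the given codes."""
        idx = [self.indicator_codes.index(c) for c in indicator_codes]
        return IndicatorPanel(self.country_ids, list(indicator_codes), self.scores[:, idx])


def load_panel(
    path,
    drop_incomplete: bool = False,
    country_col: str = "country",
) -> IndicatorPanel:
    """Read a panel CSV (one country column, one numeric column per indicator).

    Rows containing any missing indicator value are dropped when
    ``drop_incomplete`` is true (the number dropped is logged); otherwise a
    missing value is an error.  Scores must lie in [0, 100].

    The deposited-dataset convention is followed: UTF-8, comma separated,
    header row, decimal point, country identifiers in ``country_col``.
    """
    # round_trip parsing keeps write -> load -> write bit-identical
    frame = pd.read_csv(path, float_precision="round_trip")
    if country_col not in frame.columns:
        raise ValueError(
            f"country column {country_col!r} not found in {list(frame.columns)}"
        )
    frame = frame.set_index(country_col)
    frame.index.name = "country"
    if frame.shape[1] < 1:
        raise ValueError("panel CSV has no indicator columns")
    non_numeric = [c for c in frame.columns if not pd.api.types.is_numeric_dtype(frame[c])]
    if non_numeric:
        raise ValueError(f"non-numeric indicator columns: {non_numeric}")
    if drop_incomplete:
        complete = frame.notna().all(axis=1)
        n_dropped = int((~complete).sum())
        if n_dropped:
            logger.info(
                "dropped %d of %d countries with incomplete indicator coverage",
                n_dropped, len(frame),
            )
        frame = frame.loc[complete]
    elif frame.isna().any().any():
        row = frame.index[frame.isna().any(axis=1)][0]
        raise ValueError(
            f"missing indicator values (first offending country: {row!r}); "
            "pass drop_incomplete=True to exclude incomplete countries"
        )
    if len(frame) == 0:
        raise ValueError("no complete countries remain in the panel")
    return IndicatorPanel.from_frame(frame)


def write_panel(panel: IndicatorPanel, path) -> None:
    """Write a panel to CSV in the dialect :func:`load_panel` reads."""
    panel.to_frame().to_csv(path)


def _check_simplex(w: np.ndarray, m: int) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.shape != (m,):
        raise ValueError(f"weight vector has length {w.size}, expected {m}")
    if (w < -WEIGHT_TOL).any():
        raise ValueError("weights must be nonnegative")
    if abs(w.sum() - 1.0) > WEIGHT_TOL:
        raise ValueError(f"weights must sum to 1 (got {w.sum()!r})")
    return w


def aggregate_mep(panel: IndicatorPanel, weights) -> np.ndarray:
    """Aggregate indicator scores into one composite score per country.

    The multicriteria environmental performance of country *i* is the
    weighted sum ``MEP_i = sum_j w_j * epi_ij`` with ``w`` on the unit
    simplex, so each country's score is a convex combination of its
    indicator scores.

    ``weights`` may be a mapping/Series keyed by indicator code or a plain
    vector aligned with ``panel.indicator_codes``.
    """
    if isinstance(weights, (dict, pd.Series)):
        weights = pd.Series(weights).reindex(panel.indicator_codes).to_numpy()
        if np.isnan(weights).any():
            raise ValueError("weights missing for some panel indicators")
    w = _check_simplex(np.asarray(weights, dtype=float), panel.n_indicators)
    return panel.scores @ w
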