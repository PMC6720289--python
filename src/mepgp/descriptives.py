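"""Per-indicator descriptive statistics and correlation structure.

Skewness and kurtosis use the population-moment conventions
``g1 = m3 / m2**1.5`` and excess ``g2 = m4 / m2**2 - 3`` (no small-sample
bias adjustment); the standard deviation uses the sample (n-1)
denominator.  Correlations are Pearson product-moment coefficients.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .panel import IndicatorPanel

__all__ = ["describe", "correlations"]


def describe(panel: IndicatorPanel) -> pd.DataFrame:
    """Mean, sd, median, skewness and excess kurtosis per indicator.

    A constant indicator has sd 0 and undefined shape statistics, which
    are reported as NaN with a warning.  Requires at least two countries.
    """
    if panel.n_countries < 2:
        raise ValueError("descriptive statistics need at least 2 countries")
    S = panel.scores
    sd = S.std(axis=0, ddof=1)
    constant = sd == 0.0
    if constant.any():
        bad = [c for c, f in zip(panel.indicator_codes, constant) if f]
        warnings.warn(
            f"constant indicator column(s) {bad}: skewness/kurtosis undefined",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        skew = stats.skew(S, axis=0, bias=True)
        kurt = stats.kurtosis(S, axis=0, fisher=True, bias=True)
    skew = np.where(constant, np.nan, skew)
    kurt = np.where(constant, np.nan, kurt)
    return pd.DataFrame(
        {
            "mean": S.mean(axis=0),
            "sd": sd,
            "median": np.median(S, axis=0),
            "skewness": skew,
            "kurtosis": kurt,
        },
        index=pd.Index(panel.indicator_codes, name="indicator"),
    )


def correlations(panel: IndicatorPanel) -> pd.DataFrame:
    """Pearson correlation matrix of the indicators.

    Requires at least three countries.  Pairs involving a constant column
    are NaN (with a warning); the diagonal is exactly one elsewhere.
    """
    if panel.n_countries < 3:
        raise ValueError("correlations need at least 3 countries")
    S = panel.scores
    sd = S.std(axis=0)
    if (sd == 0.0).any():
        bad = [c for c, f in zip(panel.indicator_codes, sd == 0.0) if f]
        warnings.warn(
            f"constant indicator column(s) {bad}: correlations undefined",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(S, rowvar=False)
    idx = pd.Index(panel.indicator_codes, name="indicator")
    return pd.DataFrame(corr, index=idx, columns=idx)
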