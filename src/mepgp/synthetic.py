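"""Synthetic indicator panels with controllable statistical structure.

Real environmental-performance panels have three salient features the
models are sensitive to: scores standardized to [0, 100], mildly
left-skewed marginals (most countries sit above the midpoint), and a weak
correlation structure containing both synergies (positive pairs around
+0.5) and trade-offs (negative pairs around -0.5).  The generator emulates
exactly these: a Gaussian copula supplies the dependence, and per-indicator
beta marginals (moment-matched to target mean/sd, then scaled to [0, 100])
supply bounded, skewed margins whose skew direction follows the mean.

:func:`epi_like_spec` bundles the defaults used throughout: 91 countries,
the 24 indicators of the 2018 EPI hierarchy with their published
per-indicator means and standard deviations, a -0.49 drinking-water /
wastewater-treatment trade-off and a +0.48 biome-protection / PM2.5
synergy, all other target correlations zero.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import ndtr

from .panel import IndicatorPanel

__all__ = [
    "SynthSpec",
    "synth_panel",
    "epi_like_spec",
    "known_answer_panel",
    "panel_digest",
    "KNOWN_CASES",
]

# Published 2018 EPI per-indicator mean and standard deviation on the
# 91-country complete-case sample, in hierarchy leaf order.
_EPI_MOMENTS: dict[str, tuple[float, float]] = {
    "HAD": (53.95, 27.16), "PME": (59.04, 33.55), "PMW": (58.85, 30.47),
    "UWD": (61.46, 26.74), "USD": (51.67, 29.88), "PBD": (68.25, 26.44),
    "MPA": (60.58, 26.34), "TBN": (67.74, 29.60), "TBG": (61.72, 27.78),
    "SPI": (48.98, 32.27), "PAR": (52.43, 28.78), "SHI": (70.36, 27.16),
    "TCL": (59.19, 29.15), "FSS": (57.92, 25.68), "MTR": (55.88, 28.47),
    "DCT": (69.43, 29.33), "DPT": (58.24, 27.00), "DMT": (60.09, 27.75),
    "DNT": (57.32, 26.81), "DBT": (62.89, 29.98), "DST": (66.77, 29.17),
    "DXT": (54.90, 28.39), "WWT": (60.22, 29.92), "SNM": (57.44, 28.65),
}

#: anchor correlations emulating the observed trade-off and synergy pairs
_EPI_CORR_ANCHORS = [("UWD", "WWT", -0.49), ("TBN", "PMW", 0.48)]


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for one synthetic panel draw.

    ``corr`` is the m x m Gaussian-copula correlation target (symmetric,
    PSD, unit diagonal); ``means``/``sds`` are per-indicator targets on
    the 0-100 scale.  The seed is mandatory: there is no hidden global
    randomness.
    """

    n_countries: int
    indicator_codes: list[str]
    corr: np.ndarray = field(repr=False)
    means: np.ndarray
    sds: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        m = len(self.indicator_codes)
        corr = np.asarray(self.corr, dtype=float)
        means = np.asarray(self.means, dtype=float)
        sds = np.asarray(self.sds, dtype=float)
        for name, v in (("corr", corr), ("means", means), ("sds", sds)):
            object.__setattr__(self, name, v)
        if self.n_countries < 2:
            raise ValueError("need at least 2 countries")
        if corr.shape != (m, m):
            raise ValueError(f"corr shape {corr.shape} != ({m}, {m})")
        if not np.allclose(corr, corr.T, atol=1e-12):
            raise ValueError("correlation target must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-12):
            raise ValueError("correlation target must have unit diagonal")
        eigmin = float(np.linalg.eigvalsh(corr).min())
        if eigmin < -1e-10:
            raise ValueError(
                f"correlation target is not positive semidefinite "
                f"(smallest eigenvalue {eigmin})"
            )
        if means.shape != (m,) or sds.shape != (m,):
            raise ValueError("means and sds must have one entry per indicator")
        if ((means <= 0) | (means >= 100)).any() or (sds <= 0).any():
            raise ValueError("means must lie in (0, 100) and sds be positive")

    @property
    def m(self) -> int:
        return len(self.indicator_codes)


def _beta_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched beta shape parameters on the unit interval."""
    p = mean / 100.0
    v = (sd / 100.0) ** 2
    if v >= p * (1 - p):
        raise ValueError(
            f"sd {sd} too large for mean {mean}: no beta distribution matches"
        )
    kappa = p * (1 - p) / v - 1.0
    return p * kappa, (1 - p) * kappa


def _psd_factor(corr: np.ndarray) -> np.ndarray:
    """A factor L with L L^T = corr, tolerant of semidefinite targets."""
    try:
        return np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        vals, vecs = np.linalg.eigh(corr)
        return vecs @ np.diag(np.sqrt(np.clip(vals, 0.0, None)))


def synth_panel(spec: SynthSpec) -> IndicatorPanel:
    """Draw one panel: Gaussian copula + moment-matched beta marginals.

    Deterministic given ``spec.seed``.  Empirical Pearson correlations
    approach the copula targets as n grows (the monotone marginal
    transforms attenuate them slightly).  Country identifiers are C001,
    C002, ...
    """
    rng = np.random.default_rng(spec.seed)
    L = _psd_factor(spec.corr)
    z = rng.standard_normal((spec.n_countries, spec.m)) @ L.T
    u = ndtr(z)
    scores = np.empty_like(u)
    for j in range(spec.m):
        a, b = _beta_params(spec.means[j], spec.sds[j])
        scores[:, j] = 100.0 * stats.beta.ppf(u[:, j], a, b)
    scores = np.clip(scores, 0.0, 100.0)
    countries = [f"C{i + 1:03d}" for i in range(spec.n_countries)]
    return IndicatorPanel(countries, list(spec.indicator_codes), scores)


def epi_like_spec(seed: int, n_countries: int = 91) -> SynthSpec:
    """Default study-condition generator: a 91 x 24 EPI-like panel."""
    codes = list(_EPI_MOMENTS)
    m = len(codes)
    corr = np.eye(m)
    for a, b, rho in _EPI_CORR_ANCHORS:
        i, j = codes.index(a), codes.index(b)
        corr[i, j] = corr[j, i] = rho
    moments = np.array([_EPI_MOMENTS[c] for c in codes])
    return SynthSpec(
        n_countries=n_countries,
        indicator_codes=codes,
        corr=corr,
        means=moments[:, 0],
        sds=moments[:, 1],
        seed=int(seed),
    )


def _hand_2x2() -> tuple[IndicatorPanel, dict]:
    panel = IndicatorPanel(["A", "B"], ["X1", "X2"], np.array([[10.0, 30.0], [50.0, 70.0]]))
    # at w = (1/2, 1/2): MEP = (20, 60); every |residual| = 10
    expected = {
        "weights": np.array([0.5, 0.5]),
        "mep": np.array([20.0, 60.0]),
        "disagreements": np.array([20.0, 20.0]),
        "z": 40.0,
        "d": 20.0,
    }
    return panel, expected


def _single_indicator() -> tuple[IndicatorPanel, dict]:
    panel = IndicatorPanel(["A", "B", "C"], ["X1"], np.array([[15.0], [55.0], [95.0]]))
    return panel, {"weights": np.array([1.0]), "z": 0.0, "d": 0.0,
                   "mep": panel.scores[:, 0].copy()}


def _duplicate_columns() -> tuple[IndicatorPanel, dict]:
    col = np.array([12.0, 48.0, 77.0, 91.0])
    panel = IndicatorPanel(
        ["A", "B", "C", "D"], ["X1", "X2"], np.column_stack([col, col])
    )
    return panel, {"z": 0.0, "d": 0.0, "mep": col.copy()}


#: registry of tiny panels with analytically known optima
KNOWN_CASES = {
    "hand_2x2": _hand_2x2,
    "single_indicator": _single_indicator,
    "duplicate_columns": _duplicate_columns,
}


def known_answer_panel(case_id: str) -> tuple[IndicatorPanel, dict]:
    """Return a registered hand-built panel and its expected solution fragments."""
    try:
        factory = KNOWN_CASES[case_id]
    except KeyError:
        raise KeyError(
            f"unknown case {case_id!r}; registered: {sorted(KNOWN_CASES)}"
        ) from None
    return factory()


def panel_digest(panel: IndicatorPanel) -> str:
    """Stable hash of a panel's contents (used to check reproducibility)."""
    h = hashlib.sha256()
    h.update("\x1f".join(panel.country_ids).encode())
    h.update("\x1f".join(panel.indicator_codes).encode())
    h.update(np.ascontiguousarray(panel.scores).tobytes())
    return h.hexdigest()
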