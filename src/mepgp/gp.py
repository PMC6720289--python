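"""Goal-programming estimation of indicator weights.

The models treat every indicator column of the panel as a goal: the
composite score ``MEP_i = sum_j w_j epi_ij`` should deviate as little as
possible from each single indicator.  Writing the signed residual of
country *i* against indicator *j* with nonnegative deviation variables,

    sum_k w_k epi_ik + d-_ij - d+_ij = epi_ij,      w on the unit simplex,

three linear programs arise, differing only in the norm applied to the
deviations:

* the weighted model (L1 norm) minimizes the penalized sum of all
  deviations, ``sum_j sum_i (alpha_j d-_ij + beta_j d+_ij)`` — consensus
  with the majority trend of the indicators;
* the minmax model (L-infinity norm) minimizes the largest per-indicator
  deviation total ``D`` — attention to the most conflicting indicator;
* the extended model minimizes the convex mixture
  ``lam * L1 + (1 - lam) * D`` and interpolates between the two
  (``lam = 1`` recovers the weighted model, ``lam = 0`` the minmax one).

The per-indicator disagreement ``D_j = sum_i (d-_ij + d+_ij)`` and its
total ``Z = sum_j D_j`` are accounting quantities carried on every
solution.  Weight vectors at the optimum need not be unique (zero weights
and degenerate optima are normal); objective values are the canonical
quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .panel import IndicatorPanel, _check_simplex

__all__ = [
    "DeviationConfig",
    "GPSolution",
    "LPSpec",
    "WeightEvaluation",
    "solve_wgp",
    "solve_minmax",
    "solve_extended",
    "evaluate_weights",
    "grid_oracle",
    "simplex_lattice",
    "SolverError",
]

#: residual acceptance for solver outputs (feasibility/identities)
SOLUTION_TOL = 1e-6
#: guard on the number of lattice points the brute-force oracle may visit
MAX_GRID_POINTS = 10_000_000


class SolverError(RuntimeError):
    """The LP backend failed to return an optimal solution."""


@dataclass(frozen=True)
class DeviationConfig:
    """Deviation-penalty switches per indicator.

    ``alpha[j] = 1`` penalizes the negative deviation of indicator *j*
    (the indicator exceeding the composite), ``beta[j] = 1`` the positive
    one.  At least one direction must be penalized for every indicator,
    otherwise its deviations would be costless.
    """

    alpha: np.ndarray
    beta: np.ndarray

    def __post_init__(self) -> None:
        alpha = np.asarray(self.alpha, dtype=float)
        beta = np.asarray(self.beta, dtype=float)
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "beta", beta)
        if alpha.ndim != 1 or beta.shape != alpha.shape:
            raise ValueError("alpha and beta must be equal-length vectors")
        for name, v in (("alpha", alpha), ("beta", beta)):
            if not np.isin(v, (0.0, 1.0)).all():
                raise ValueError(f"{name} entries must be 0 or 1")
        if ((alpha + beta) < 1).any():
            j = int(np.argmax((alpha + beta) < 1))
            raise ValueError(f"indicator {j}: alpha_j + beta_j must be >= 1")

    @classmethod
    def all_ones(cls, m: int) -> "DeviationConfig":
        """Penalize both deviation directions for every indicator (default)."""
        return cls(np.ones(m), np.ones(m))

    @property
    def m(self) -> int:
        return self.alpha.size


@dataclass(frozen=True)
class WeightEvaluation:
    """Closed-form deviation accounting for a fixed weight vector."""

    z_weighted: float
    z: float
    d: float
    disagreements: np.ndarray
    mep: np.ndarray


@dataclass(frozen=True)
class GPSolution:
    """One goal-programming solve: weights, deviations and accounting totals.

    ``z_weighted`` is the penalized deviation sum actually entering the
    objective; ``z`` is the unpenalized total ``sum_j D_j`` (they coincide
    when all penalties are on); ``d`` is the supremum per-indicator
    disagreement.  ``lam`` is 1 for the weighted model and 0 for minmax.
    """

    country_ids: list[str]
    indicator_codes: list[str]
    weights: np.ndarray
    dev_neg: np.ndarray = field(repr=False)
    dev_pos: np.ndarray = field(repr=False)
    disagreements: np.ndarray
    z: float
    z_weighted: float
    d: float
    mep: np.ndarray
    lam: float
    config: DeviationConfig
    solver_status: str

    @property
    def objective(self) -> float:
        """The value of the objective this solution minimized."""
        return self.lam * self.z_weighted + (1.0 - self.lam) * self.d

    def weights_by_code(self) -> dict[str, float]:
        return dict(zip(self.indicator_codes, self.weights.tolist()))


@dataclass(frozen=True)
class LPSpec:
    """Sparse LP over the variable blocks (w, d-, d+, D_j, Z[, D]).

    Variable layout (column offsets in ``blocks``): weights ``w`` (m),
    row-major deviation matrices ``d-`` and ``d+`` (n*m each), per-indicator
    disagreements ``D_j`` (m), their total ``Z`` (1) and, when the minmax
    cap rows are present, the supremum ``D`` (1).  All variables are
    nonnegative; the sense is minimization.
    """

    c: np.ndarray
    A_eq: sparse.csr_matrix
    b_eq: np.ndarray
    A_ub: sparse.csr_matrix | None
    b_ub: np.ndarray | None
    blocks: dict[str, slice]
    n: int
    m: int


def _build_lp(scores: np.ndarray, config: DeviationConfig, lam: float, with_cap: bool) -> LPSpec:
    """Assemble the extended-model LP; ``lam`` weights the L1 term.

    ``with_cap`` adds the m rows ``sum_i alpha_j d-_ij + beta_j d+_ij <= D``
    and the D variable (minmax and extended models).
    """
    n, m = scores.shape
    nm = n * m
    i_w, i_dn, i_dp, i_Dj, i_Z = 0, m, m + nm, m + 2 * nm, m + 2 * nm + m
    n_var = i_Z + 1 + (1 if with_cap else 0)
    i_D = i_Z + 1  # only meaningful when with_cap
    blocks = {
        "w": slice(i_w, m),
        "dev_neg": slice(i_dn, i_dn + nm),
        "dev_pos": slice(i_dp, i_dp + nm),
        "D_j": slice(i_Dj, i_Dj + m),
        "Z": slice(i_Z, i_Z + 1),
    }
    if with_cap:
        blocks["D"] = slice(i_D, i_D + 1)

    arange_nm = np.arange(nm)
    # goal rows: S_i . w + d-_ij - d+_ij = epi_ij  (row index r = i*m + j)
    rows = [np.repeat(arange_nm, m), arange_nm, arange_nm]
    cols = [np.tile(np.arange(m), nm), i_dn + arange_nm, i_dp + arange_nm]
    vals = [np.repeat(scores, m, axis=0).ravel(), np.ones(nm), -np.ones(nm)]
    # simplex row
    r = nm
    rows.append(np.full(m, r)); cols.append(np.arange(m)); vals.append(np.ones(m))
    # D_j accounting rows: sum_i (d-_ij + d+_ij) - D_j = 0
    r += 1
    dev_cols_j = np.arange(m)[:, None] + m * np.arange(n)[None, :]  # (m, n) col offsets
    row_j = np.repeat(r + np.arange(m), n)
    rows += [row_j, row_j, r + np.arange(m)]
    cols += [i_dn + dev_cols_j.ravel(), i_dp + dev_cols_j.ravel(), i_Dj + np.arange(m)]
    vals += [np.ones(nm), np.ones(nm), -np.ones(m)]
    # Z accounting row: sum_j D_j - Z = 0
    r += m
    rows.append(np.full(m + 1, r))
    cols.append(np.concatenate([i_Dj + np.arange(m), [i_Z]]))
    vals.append(np.concatenate([np.ones(m), [-1.0]]))
    n_eq = r + 1
    A_eq = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_eq, n_var),
    ).tocsr()
    b_eq = np.concatenate([scores.ravel(), [1.0], np.zeros(m + 1)])

    A_ub = b_ub = None
    if with_cap:
        # cap rows: sum_i (alpha_j d-_ij + beta_j d+_ij) - D <= 0
        row_c = np.repeat(np.arange(m), n)
        u_rows = np.concatenate([row_c, row_c, np.arange(m)])
        u_cols = np.concatenate(
            [i_dn + dev_cols_j.ravel(), i_dp + dev_cols_j.ravel(), np.full(m, i_D)]
        )
        u_vals = np.concatenate(
            [np.repeat(config.alpha, n), np.repeat(config.beta, n), -np.ones(m)]
        )
        A_ub = sparse.coo_matrix((u_vals, (u_rows, u_cols)), shape=(m, n_var)).tocsr()
        b_ub = np.zeros(m)

    c = np.zeros(n_var)
    if lam > 0.0:
        c[i_dn:i_dn + nm] = lam * np.tile(config.alpha, n)
        c[i_dp:i_dp + nm] = lam * np.tile(config.beta, n)
    if with_cap:
        c[i_D] = 1.0 - lam
    return LPSpec(c=c, A_eq=A_eq, b_eq=b_eq, A_ub=A_ub, b_ub=b_ub, blocks=blocks, n=n, m=m)


_BACKENDS = {"highs": "highs", "highs-ds": "highs-ds", "highs-ipm": "highs-ipm"}


def _solve_lp(spec: LPSpec, solver: str):
    if solver not in _BACKENDS:
        raise ValueError(f"unknown solver backend {solver!r}; choose from {sorted(_BACKENDS)}")
    res = linprog(
        spec.c,
        A_ub=spec.A_ub,
        b_ub=spec.b_ub,
        A_eq=spec.A_eq,
        b_eq=spec.b_eq,
        bounds=(0, None),
        method=_BACKENDS[solver],
    )
    if res.status != 0:
        raise SolverError(f"LP solve failed (status {res.status}): {res.message}")
    return res


def _finalize(panel: IndicatorPanel, config: DeviationConfig, lam: float,
              x: np.ndarray, spec: LPSpec, status: str) -> GPSolution:
    """Post-process a raw LP point into a validated :class:`GPSolution`.

    Weights are clipped of solver-level negative round-off; the elementwise
    minimum of (d-, d+) is removed from both so deviations satisfy
    complementarity; all accounting totals are recomputed from the cleaned
    deviations.
    """
    n, m = spec.n, spec.m
    w = np.clip(x[spec.blocks["w"]], 0.0, None)
    dn = x[spec.blocks["dev_neg"]].reshape(n, m)
    dp = x[spec.blocks["dev_pos"]].reshape(n, m)
    common = np.minimum(dn, dp)
    dn = np.clip(dn - common, 0.0, None)
    dp = np.clip(dp - common, 0.0, None)
    mep = panel.scores @ w
    disagreements = (dn + dp).sum(axis=0)
    z = float(disagreements.sum())
    z_weighted = float((config.alpha * dn + config.beta * dp).sum())
    d = float((config.alpha * dn + config.beta * dp).sum(axis=0).max())
    sol = GPSolution(
        country_ids=list(panel.country_ids),
        indicator_codes=list(panel.indicator_codes),
        weights=w,
        dev_neg=dn,
        dev_pos=dp,
        disagreements=disagreements,
        z=z,
        z_weighted=z_weighted,
        d=d,
        mep=mep,
        lam=lam,
        config=config,
        solver_status=status,
    )
    _validate_solution(sol, panel)
    return sol


def _validate_solution(sol: GPSolution, panel: IndicatorPanel, tol: float = SOLUTION_TOL) -> None:
    """Assert the structural identities every solve must satisfy."""
    S = panel.scores
    if (sol.weights < 0).any() or abs(sol.weights.sum() - 1.0) > tol:
        raise SolverError(f"weights off the simplex (sum={sol.weights.sum()!r})")
    resid = np.abs(sol.mep[:, None] + sol.dev_neg - sol.dev_pos - S).max()
    if resid > tol * max(1.0, np.abs(S).max()):
        raise SolverError(f"goal-equation residual {resid} exceeds tolerance")
    if (np.minimum(sol.dev_neg, sol.dev_pos) > tol).any():
        raise SolverError("deviation complementarity violated")
    if abs(sol.z - sol.disagreements.sum()) > tol * max(1.0, sol.z):
        raise SolverError("Z does not equal the sum of per-indicator disagreements")
    lo, hi = S.min(axis=1), S.max(axis=1)
    if ((sol.mep < lo - tol) | (sol.mep > hi + tol)).any():
        raise SolverError("composite score outside a country's indicator range")


def _config_for(panel: IndicatorPanel, config: DeviationConfig | None) -> DeviationConfig:
    if config is None:
        return DeviationConfig.all_ones(panel.n_indicators)
    if config.m != panel.n_indicators:
        raise ValueError(
            f"deviation config length {config.m} != {panel.n_indicators} indicators"
        )
    return config


def solve_wgp(panel: IndicatorPanel, config: DeviationConfig | None = None,
              solver: str = "highs") -> GPSolution:
    """Weighted (L1-norm) model: minimize the penalized sum of deviations."""
    config = _config_for(panel, config)
    spec = _build_lp(panel.scores, config, lam=1.0, with_cap=False)
    res = _solve_lp(spec, solver)
    return _finalize(panel, config, 1.0, res.x, spec, str(res.message))


def solve_minmax(panel: IndicatorPanel, config: DeviationConfig | None = None,
                 solver: str = "highs") -> GPSolution:
    """Minmax (L-infinity) model: minimize the largest per-indicator disagreement."""
    config = _config_for(panel, config)
    spec = _build_lp(panel.scores, config, lam=0.0, with_cap=True)
    res = _solve_lp(spec, solver)
    return _finalize(panel, config, 0.0, res.x, spec, str(res.message))


def solve_extended(panel: IndicatorPanel, lam: float,
                   config: DeviationConfig | None = None,
                   solver: str = "highs") -> GPSolution:
    """Extended model: minimize ``lam * L1 + (1 - lam) * D``.

    ``lam = 1`` reproduces :func:`solve_wgp`'s optimum, ``lam = 0``
    :func:`solve_minmax`'s.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lam must lie in [0, 1], got {lam}")
    config = _config_for(panel, config)
    spec = _build_lp(panel.scores, config, lam=float(lam), with_cap=True)
    res = _solve_lp(spec, solver)
    return _finalize(panel, config, float(lam), res.x, spec, str(res.message))


def evaluate_weights(panel: IndicatorPanel, weights,
                     config: DeviationConfig | None = None) -> WeightEvaluation:
    """Deviation accounting for a fixed weight vector, no solver involved.

    For given ``w`` the goal equations pin the deviations down in closed
    form: ``d-_ij = max(epi_ij - MEP_i, 0)`` and
    ``d+_ij = max(MEP_i - epi_ij, 0)``.
    """
    config = _config_for(panel, config)
    w = _check_simplex(np.asarray(weights, dtype=float), panel.n_indicators)
    S = panel.scores
    mep = S @ w
    resid = S - mep[:, None]
    dn = np.clip(resid, 0.0, None)
    dp = np.clip(-resid, 0.0, None)
    disagreements = (dn + dp).sum(axis=0)
    weighted_cols = (config.alpha * dn + config.beta * dp).sum(axis=0)
    return WeightEvaluation(
        z_weighted=float(weighted_cols.sum()),
        z=float(disagreements.sum()),
        d=float(weighted_cols.max()),
        disagreements=disagreements,
        mep=mep,
    )


def simplex_lattice(k: int, m: int) -> np.ndarray:
    """All nonnegative integer m-tuples summing to k, as an array of rows.

    Dividing by ``k`` gives the step-``1/k`` lattice on the unit simplex.
    """
    if m == 1:
        return np.array([[k]], dtype=np.int64)
    if m == 2:
        a = np.arange(k + 1, dtype=np.int64)
        return np.column_stack([a, k - a])
    parts = []
    for first in range(k + 1):
        rest = simplex_lattice(k - first, m - 1)
        parts.append(
            np.column_stack([np.full(len(rest), first, dtype=np.int64), rest])
        )
    return np.vstack(parts)


def grid_oracle(panel: IndicatorPanel, step: float,
                config: DeviationConfig | None = None,
                criterion: str = "z_weighted",
                lam: float | None = None,
                chunk: int = 65536) -> tuple[float, np.ndarray]:
    """Brute-force minimum of a criterion over the simplex weight lattice.

    Exhaustively evaluates :func:`evaluate_weights` on
    ``{w : w_j = k_j * step, sum w_j = 1}`` and returns ``(best value,
    best w)``.  ``criterion`` is one of ``"z_weighted"``, ``"d"`` or
    ``"composite"`` (which needs ``lam``).  Intended as an independent
    check of the LP solvers on small panels; the lattice relaxes nothing,
    so the LP optimum is a lower bound for the returned value.
    """
    config = _config_for(panel, config)
    if criterion not in ("z_weighted", "d", "composite"):
        raise ValueError(f"unknown criterion {criterion!r}")
    if criterion == "composite":
        if lam is None or not 0.0 <= lam <= 1.0:
            raise ValueError("criterion 'composite' needs lam in [0, 1]")
    k = round(1.0 / step)
    if abs(k * step - 1.0) > 1e-9:
        raise ValueError("step must divide 1 exactly (e.g. 0.5, 0.1, 0.001)")
    m = panel.n_indicators
    n_points = comb(k + m - 1, m - 1)
    if n_points > MAX_GRID_POINTS:
        raise ValueError(
            f"simplex lattice has {n_points} points, above the "
            f"{MAX_GRID_POINTS} guard; increase step or reduce m"
        )
    lattice = simplex_lattice(k, m)
    S = panel.scores
    alpha, beta = config.alpha, config.beta
    best_val, best_w = np.inf, None
    for start in range(0, len(lattice), chunk):
        W = lattice[start:start + chunk].astype(float) / k  # (P, m)
        mep = W @ S.T  # (P, n)
        resid = S[None, :, :] - mep[:, :, None]  # (P, n, m)
        dn = np.clip(resid, 0.0, None)
        dp = np.clip(-resid, 0.0, None)
        weighted_cols = (alpha * dn + beta * dp).sum(axis=1)  # (P, m)
        if criterion == "z_weighted":
            vals = weighted_cols.sum(axis=1)
        elif criterion == "d":
            vals = weighted_cols.max(axis=1)
        else:
            vals = lam * weighted_cols.sum(axis=1) + (1.0 - lam) * weighted_cols.max(axis=1)
        i = int(vals.argmin())
        if vals[i] < best_val:
            best_val = float(vals[i])
            best_w = W[i].copy()
    return best_val, best_w
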