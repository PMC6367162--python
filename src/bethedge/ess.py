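"""Evolutionarily stable germination fractions by invasion analysis.

A rare mutant with germination fraction g-tilde invading a resident at
stationarity with fraction g grows at the stochastic rate

    r(g, g~) = E[ ln( g~ K_t s_new / (1 + a g n_t) + (1 - g~) s_old ) ]

with the expectation taken over the resident's stationary joint
distribution of yield K_t and seed density n_t.  Writing
Q_t = K_t s_new / (1 + a g n_t) for the per-germinant return, the
selection gradient — the derivative of invasion fitness in the mutant
trait, evaluated at the resident — is

    h(g) = E[ (Q_t - s_old) / (g Q_t + (1 - g) s_old) ].

Because invasion fitness is strictly concave in the mutant trait, an
interior root of h is the unique ESS; h > 0 throughout (0, 1) pushes
the ESS to full germination (g = 1).

The solver evaluates h on a sign pre-scan grid and bisects the
bracketing interval.  One yield stream K_t (drawn once per solve from
the precipitation model and the hurdle) is shared by every candidate
resident — common random numbers — so h is a smooth deterministic
function of g within a solve and bracketing is robust to Monte-Carlo
noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hurdle import sample_yield_series
from .params import SpeciesParams
from .seedbank import (
    DEFAULT_BURN_IN,
    DEFAULT_N0,
    DEFAULT_YEARS,
    StationaryRun,
    estimate_stationary,
    iterate_seedbank,
    low_density_growth_rate,
)
from .synthetic import PrecipModel, sample_precip

__all__ = [
    "ESSResult",
    "invasion_growth_rate",
    "selection_gradient",
    "find_ess",
    "verify_ess",
]

DEFAULT_TOL = 1e-3
DEFAULT_GRID = 21


def _mutant_terms(mutant_g: float, Q: np.ndarray, s_old: float) -> np.ndarray:
    return np.log(mutant_g * Q + (1.0 - mutant_g) * s_old)


def _per_germinant_return(resident_g: float, stationary: StationaryRun, params: SpeciesParams) -> np.ndarray:
    return stationary.K * params.s_new / (1.0 + params.a * resident_g * stationary.n)


def _check_resident(resident_g: float, stationary: StationaryRun) -> None:
    if abs(stationary.g - resident_g) > 1e-12:
        raise ValueError(
            f"stationary run was generated with resident g = {stationary.g}, "
            f"not {resident_g}"
        )


def invasion_growth_rate(
    resident_g: float,
    mutant_g: float,
    stationary: StationaryRun,
    params: SpeciesParams,
) -> tuple[float, float]:
    """Mutant stochastic growth rate r(g, g~) and its standard error.

    Time-averages ln(g~ K_t s_new / (1 + a g n_t) + (1 - g~) s_old)
    over the resident's stationary run, pairing each year's yield with
    the same year's pre-update density.
    """
    _check_resident(resident_g, stationary)
    if not 0.0 <= mutant_g <= 1.0:
        raise ValueError("mutant germination fraction must lie in [0, 1]")
    if mutant_g == 0.0:
        return float(np.log(params.s_old)), 0.0
    terms = _mutant_terms(mutant_g, _per_germinant_return(resident_g, stationary, params), params.s_old)
    return float(terms.mean()), float(terms.std(ddof=1) / np.sqrt(terms.size))


def selection_gradient(
    resident_g: float,
    stationary: StationaryRun,
    params: SpeciesParams,
) -> tuple[float, float]:
    """h(g): derivative of invasion fitness in the mutant trait at g~ = g.

    Uses the analytic inner derivative (Q_t - s_old) / (g Q_t +
    (1 - g) s_old) averaged over the stationary run — lower variance
    than differencing the invasion rate numerically.
    """
    _check_resident(resident_g, stationary)
    Q = _per_germinant_return(resident_g, stationary, params)
    w = (Q - params.s_old) / (resident_g * Q + (1.0 - resident_g) * params.s_old)
    return float(w.mean()), float(w.std(ddof=1) / np.sqrt(w.size))


@dataclass
class ESSResult:
    """Solved evolutionarily stable germination fraction with diagnostics."""

    species_code: str
    g_ess: float
    boundary_flag: str  # "interior" | "g_equals_1" | "nonpersistent"
    h_at_ess: float
    h_se: float
    h_values: list[tuple[float, float, float, bool]] = field(default_factory=list)
    r_resident: float = float("nan")
    r_resident_se: float = float("nan")
    tolerance: float = DEFAULT_TOL
    seed: int | None = None
    burn_in: int = DEFAULT_BURN_IN
    years: int = DEFAULT_YEARS

    @property
    def converged(self) -> bool:
        return self.boundary_flag in ("interior", "g_equals_1")


class _GradientEvaluator:
    """h(g) over one common-random-number yield stream.

    Persistent residents (r > 0) are re-equilibrated over the shared
    stream; nonpersistent ones are evaluated against an empty
    stationary distribution (n-hat = 0, so Q_t = K_t s_new).
    """

    def __init__(self, params: SpeciesParams, K: np.ndarray, burn_in: int, n0: float):
        self.params = params
        self.K = K
        self.burn_in = burn_in
        self.n0 = n0

    def r_low(self, g: float) -> float:
        return low_density_growth_rate(self.params, g, K=self.K)[0]

    def __call__(self, g: float) -> tuple[float, float, bool]:
        p = self.params
        persistent = self.r_low(g) > 0.0
        if persistent:
            n = iterate_seedbank(self.n0, g, self.K, p)
            Q = self.K[self.burn_in :] * p.s_new / (1.0 + p.a * g * n[self.burn_in : -1])
        else:
            Q = self.K * p.s_new
        w = (Q - p.s_old) / (g * Q + (1.0 - g) * p.s_old)
        return float(w.mean()), float(w.std(ddof=1) / np.sqrt(w.size)), persistent


def find_ess(
    params: SpeciesParams,
    precip_model: PrecipModel,
    tol: float = DEFAULT_TOL,
    seed: int | None = None,
    burn_in: int = DEFAULT_BURN_IN,
    years: int = DEFAULT_YEARS,
    n0: float = DEFAULT_N0,
    residual_sd: float = 0.0,
    grid_points: int = DEFAULT_GRID,
    max_iter: int = 200,
) -> ESSResult:
    """Solve for the ESS germination fraction by bisection on h(g).

    One precipitation stream and one hurdle yield stream are drawn up
    front and reused for every candidate resident (common random
    numbers).  h's sign is pre-scanned on a ``grid_points`` grid in
    (0, 1); a sign change is bisected to width ``tol``.  If h > 0
    across (0, 1] the ESS is the boundary g = 1; if no g in (0, 1]
    persists, the result is flagged nonpersistent (the root of h
    against an empty environment is still reported when bracketed).
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    rng = np.random.default_rng(seed)
    P = sample_precip(precip_model, burn_in + years, rng)
    K = sample_yield_series(params, P, rng, residual_sd)
    h = _GradientEvaluator(params, K, burn_in, n0)

    grid = np.linspace(0.0, 1.0, grid_points + 2)[1:-1]
    evals: list[tuple[float, float, float, bool]] = []
    for g in grid:
        hv, se, pers = h(g)
        evals.append((float(g), hv, se, pers))
    h1, se1, pers1 = h(1.0)
    evals.append((1.0, h1, se1, pers1))

    any_persistent = any(e[3] for e in evals)

    def result(g_ess, flag, h_at, se_at, it_count):
        if it_count > max_iter:
            raise RuntimeError("bisection budget exhausted before convergence")
        r_res, r_se = float("nan"), float("nan")
        if flag != "nonpersistent" and g_ess > 0:
            n = iterate_seedbank(n0, g_ess, K, params)
            growth = np.log(n[burn_in + 1 :] / n[burn_in:-1])
            r_res = float(growth.mean())
            r_se = float(growth.std(ddof=1) / np.sqrt(growth.size))
        return ESSResult(
            species_code=params.species_code,
            g_ess=float(g_ess),
            boundary_flag=flag,
            h_at_ess=h_at,
            h_se=se_at,
            h_values=evals,
            r_resident=r_res,
            r_resident_se=r_se,
            tolerance=tol,
            seed=seed,
            burn_in=burn_in,
            years=years,
        )

    hs = [e[1] for e in evals]
    if all(v > 0 for v in hs):
        flag = "g_equals_1" if pers1 else "nonpersistent"
        return result(1.0, flag, h1, se1, 0)

    # first sign change along the (decreasing) scan, including the g=1 point
    gs = [e[0] for e in evals]
    lo = hi = None
    for i in range(len(evals) - 1):
        if hs[i] > 0 >= hs[i + 1]:
            lo, hi = gs[i], gs[i + 1]
            break
    if lo is None:
        if hs[0] <= 0 and not any_persistent:
            # selection never favours germination and no strategy persists
            return result(0.0, "nonpersistent", hs[0], evals[0][2], 0)
        # h starts negative: root (if any) lies below the grid
        lo, hi = tol / 10.0, gs[0]
        h_lo, _, _ = h(lo)
        if h_lo <= 0:
            flag = "interior" if any_persistent else "nonpersistent"
            return result(lo, flag, h_lo, evals[0][2], 0)

    it = 0
    h_mid, se_mid, pers_mid = h((lo + hi) / 2.0)
    while hi - lo > tol and it < max_iter:
        mid = (lo + hi) / 2.0
        h_mid, se_mid, pers_mid = h(mid)
        evals.append((mid, h_mid, se_mid, pers_mid))
        if h_mid > 0:
            lo = mid
        else:
            hi = mid
        it += 1
    g_ess = (lo + hi) / 2.0
    h_at, se_at, pers_at = h(g_ess)
    flag = "interior" if pers_at else "nonpersistent"
    return result(g_ess, flag, h_at, se_at, it)


def verify_ess(
    result: ESSResult,
    params: SpeciesParams,
    precip_model: PrecipModel,
    mutant_grid: np.ndarray | None = None,
    seed: int | None = None,
    burn_in: int | None = None,
    years: int | None = None,
    residual_sd: float = 0.0,
) -> dict:
    """Check uninvadability of a solved ESS over a mutant grid.

    Re-equilibrates the resident at g_ess (independent draw unless
    ``seed`` is given), evaluates r(g_ess, g~) over the grid, and flags
    any mutant whose invasion rate exceeds +3 standard errors.
    """
    if not result.converged:
        raise ValueError("verify_ess needs a converged (interior or boundary) ESS")
    burn_in = result.burn_in if burn_in is None else burn_in
    years = result.years if years is None else years
    if mutant_grid is None:
        mutant_grid = np.linspace(0.0, 1.0, 21)
    rng = np.random.default_rng(result.seed if seed is None else seed)
    P = sample_precip(precip_model, burn_in + years, rng)
    stat = estimate_stationary(
        params, result.g_ess, P, burn_in=burn_in, rng=rng, residual_sd=residual_sd
    )
    rows = []
    for gm in np.asarray(mutant_grid, dtype=float):
        r, se = invasion_growth_rate(result.g_ess, gm, stat, params)
        rows.append(
            {
                "mutant_g": float(gm),
                "r": r,
                "se": se,
                "is_resident": bool(abs(gm - result.g_ess) <= result.tolerance),
                "invades": bool(r > 3.0 * se and abs(gm - result.g_ess) > result.tolerance),
            }
        )
    others = [row for row in rows if not row["is_resident"]]
    max_r = max((row["r"] for row in others), default=float("nan"))
    return {
        "grid": rows,
        "max_mutant_r": max_r,
        "any_invader": any(row["invades"] for row in rows),
        "stationary_summary": stat.summary,
    }
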