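"""Density-dependent stochastic seed-bank dynamics.

Seed density n_t (seeds per m^2) follows the annual-plant recursion

    n_{t+1} = g K_t s_new n_t / (1 + a g n_t) + (1 - g) s_old n_t

where a fraction g germinates, germinants yield K_t seeds each at low
density (discounted by Beverton-Holt competition among the g n_t
seedlings), fresh seeds survive to autumn with probability s_new, and
the dormant fraction survives with probability s_old.

When the low-density stochastic growth rate

    r = E[ln(g K s_new + (1 - g) s_old)]

is positive the density converges to a unique stationary distribution,
which is approximated here by one long post-burn-in run; when r < 0 the
population goes extinct.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .hurdle import sample_yield_series
from .params import SpeciesParams

__all__ = [
    "PersistenceError",
    "SeedBankTrajectory",
    "StationaryRun",
    "step_seedbank",
    "simulate_seedbank",
    "low_density_growth_rate",
    "estimate_stationary",
]

DEFAULT_BURN_IN = 1000
DEFAULT_YEARS = 50_000
DEFAULT_N0 = 100.0


class PersistenceError(RuntimeError):
    """The resident's low-density growth rate is not positive.

    The stationary density is then 0 (extinction); callers should treat
    the resident as absent rather than simulating a vanishing run.
    """


@njit(cache=False)
def _iterate(n0: float, g: float, K: np.ndarray, s_new: float, s_old: float, a: float):
    n = np.empty(K.shape[0] + 1)
    n[0] = n0
    dormant = (1.0 - g) * s_old
    for t in range(K.shape[0]):
        dens = n[t]
        n[t + 1] = g * K[t] * s_new * dens / (1.0 + a * g * dens) + dormant * dens
    return n


def step_seedbank(n: float, g: float, K: float, params: SpeciesParams) -> float:
    """One year of the seed-bank recursion."""
    if n < 0:
        raise ValueError("seed density must be >= 0")
    if not 0.0 <= g <= 1.0:
        raise ValueError("germination fraction must lie in [0, 1]")
    if K <= 0:
        raise ValueError("low-density yield must be > 0")
    return g * K * params.s_new * n / (1.0 + params.a * g * n) + (1.0 - g) * params.s_old * n


def iterate_seedbank(n0: float, g: float, K: np.ndarray, params: SpeciesParams) -> np.ndarray:
    """Iterate the recursion over a given yield stream; returns n_0..n_T."""
    return _iterate(float(n0), float(g), np.asarray(K, dtype=float), params.s_new, params.s_old, params.a)


@dataclass
class SeedBankTrajectory:
    """A simulated resident trajectory.

    ``n[t]`` is the pre-update seed density in the year whose yield is
    ``K[t]`` (n has one extra trailing entry, the final density).
    """

    g: float
    precip: np.ndarray
    K: np.ndarray
    n: np.ndarray
    seed: int | None
    burn_in: int = 0

    def __post_init__(self) -> None:
        if len(self.n) != len(self.K) + 1:
            raise ValueError("n must be one longer than K (initial density included)")


@dataclass
class StationaryRun:
    """Post-burn-in slice of a trajectory approximating n-hat(g).

    ``n`` and ``K`` are paired year by year (pre-update density with the
    same year's yield).  ``summary`` holds mean/sd/quantiles of n.
    """

    g: float
    K: np.ndarray
    n: np.ndarray
    seed: int | None
    burn_in: int
    summary: dict

    def __len__(self) -> int:
        return len(self.n)


def simulate_seedbank(
    params: SpeciesParams,
    g: float,
    precip: np.ndarray,
    seed: int | None = None,
    n0: float = DEFAULT_N0,
    residual_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    K: np.ndarray | None = None,
) -> SeedBankTrajectory:
    """Simulate the seed bank over a precipitation series.

    Each year's yield K_t is drawn through the hurdle model from that
    year's precipitation (independently of density, which only enters
    through the competition term).  Pass ``K`` to reuse a pre-drawn
    yield stream (common random numbers across candidate g).
    """
    if n0 <= 0:
        raise ValueError("initial density n0 must be > 0")
    precip = np.asarray(precip, dtype=float)
    if precip.size < 1:
        raise ValueError("need at least one year of precipitation")
    if K is None:
        if rng is None:
            rng = np.random.default_rng(seed)
        K = sample_yield_series(params, precip, rng, residual_sd)
    n = iterate_seedbank(n0, g, K, params)
    return SeedBankTrajectory(g=g, precip=precip, K=np.asarray(K, float), n=n, seed=seed)


def low_density_growth_rate(
    params: SpeciesParams,
    g: float,
    K: np.ndarray | None = None,
    K_dist: tuple | None = None,
) -> tuple[float, float]:
    """Stochastic low-density growth rate r = E[ln(g K s_new + (1-g) s_old)].

    Either a Monte-Carlo yield stream ``K`` or an exact finite-support
    distribution ``K_dist = (values, probabilities)`` must be given.
    Returns (r, standard_error); the standard error is 0 in exact mode.
    g = 0 short-circuits to ln(s_old) exactly.
    """
    if not 0.0 <= g <= 1.0:
        raise ValueError("germination fraction must lie in [0, 1]")
    if g == 0.0:
        return float(np.log(params.s_old)), 0.0
    if K_dist is not None:
        vals, probs = (np.asarray(v, float) for v in K_dist)
        if not np.isclose(probs.sum(), 1.0):
            raise ValueError("K_dist probabilities must sum to 1")
        terms = np.log(g * vals * params.s_new + (1.0 - g) * params.s_old)
        return float(np.dot(probs, terms)), 0.0
    if K is None:
        raise ValueError("provide either K (samples) or K_dist (values, probs)")
    K = np.asarray(K, dtype=float)
    terms = np.log(g * K * params.s_new + (1.0 - g) * params.s_old)
    return float(terms.mean()), float(terms.std(ddof=1) / np.sqrt(terms.size))


def estimate_stationary(
    params: SpeciesParams,
    g: float,
    precip: np.ndarray,
    seed: int | None = None,
    burn_in: int = DEFAULT_BURN_IN,
    n0: float = DEFAULT_N0,
    residual_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    K: np.ndarray | None = None,
) -> StationaryRun:
    """Approximate the stationary seed-density distribution n-hat(g).

    Runs the recursion over ``precip`` (length burn_in + T), discards
    the first ``burn_in`` years, and returns densities paired with the
    same-year yields.  Raises :class:`PersistenceError` when the
    low-density growth rate over the supplied environment is <= 0.
    """
    precip = np.asarray(precip, dtype=float)
    if burn_in < 1 or len(precip) <= burn_in:
        raise ValueError("need burn_in >= 1 and more years than burn_in")
    if K is None:
        if rng is None:
            rng = np.random.default_rng(seed)
        K = sample_yield_series(params, precip, rng, residual_sd)
    K = np.asarray(K, dtype=float)
    r, _ = low_density_growth_rate(params, g, K=K)
    if r <= 0:
        raise PersistenceError(
            f"{params.species_code}: low-density growth rate r = {r:.4f} <= 0 at "
            f"g = {g:.4f}; the resident goes extinct and has no positive "
            "stationary distribution"
        )
    n = iterate_seedbank(n0, g, K, params)
    n_post = n[burn_in:-1]
    K_post = K[burn_in:]
    q = np.quantile(n_post, [0.025, 0.25, 0.5, 0.75, 0.975])
    summary = {
        "mean": float(n_post.mean()),
        "sd": float(n_post.std(ddof=1)),
        "q025": float(q[0]),
        "q25": float(q[1]),
        "median": float(q[2]),
        "q75": float(q[3]),
        "q975": float(q[4]),
    }
    return StationaryRun(g=g, K=K_post, n=n_post, seed=seed, burn_in=burn_in, summary=summary)
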