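"""Synthetic environments, observation tables and communities.

The demographic record behind the packaged parameter table (30 years of
per-species yields, seedling densities and winter precipitation) is not
redistributable, so everything the pipeline consumes can be emulated:

* annual precipitation as i.i.d. lognormal totals (desert winter rain
  is positive and right-skewed), or resampled/cycled from a user series;
* per-species observation tables produced by running the seed-bank
  recursion forward with hurdle-drawn yields and recording what a field
  crew would: seedling density N_t = g n_t and per-germinant yield
  Y_t = K_t / (1 + a N_t);
* whole communities of parameter sets drawn within the ranges spanned
  by the packaged table, for end-to-end directional experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hurdle import sample_yield_series
from .params import PrecipSeries, SpeciesParams
from .seedbank import iterate_seedbank

__all__ = [
    "PrecipModel",
    "winter_precip_model",
    "calibrate_precip_model",
    "sample_precip",
    "generate_precip",
    "generate_observations",
    "generate_community",
    "observed_fraction_standins",
]

# Generic right-skewed desert annual totals (nominally mm): median 60.
DEFAULT_MEANLOG = float(np.log(60.0))
DEFAULT_SDLOG = 0.6

# Scale consistent with the packaged hurdle coefficients, whose logistic
# midpoints sit at ln(P+1) of about 0.7-1.6, i.e. seasonal totals of a
# few units (Tucson cool-season rainfall in inches, median ~6); on this
# scale every packaged species both persists (r > 0 for some g) and
# still faces failure years, as the species demonstrably do in reality.
WINTER_MEANLOG = float(np.log(6.0))
WINTER_SDLOG = 0.6


@dataclass(frozen=True)
class PrecipModel:
    """Annual-precipitation sampler specification.

    kind "lognormal" draws exp(Normal(meanlog, sdlog)); "empirical"
    resamples a supplied series i.i.d.; "fixed" cycles it in order.
    """

    kind: str = "lognormal"
    meanlog: float = DEFAULT_MEANLOG
    sdlog: float = DEFAULT_SDLOG
    series: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("lognormal", "empirical", "fixed"):
            raise ValueError(f"unknown precipitation model kind {self.kind!r}")
        if self.kind == "lognormal":
            if self.sdlog < 0 or not np.isfinite(self.meanlog):
                raise ValueError("need finite meanlog and sdlog >= 0")
        else:
            if self.series is None or len(self.series) < 1:
                raise ValueError(f"{self.kind!r} model needs a non-empty series")
            s = np.asarray(self.series, dtype=float)
            if np.any(s <= 0) or not np.all(np.isfinite(s)):
                raise ValueError("precipitation series must be positive and finite")
            object.__setattr__(self, "series", s)


def winter_precip_model(meanlog: float = WINTER_MEANLOG, sdlog: float = WINTER_SDLOG) -> PrecipModel:
    """Lognormal surrogate for Sonoran winter-season totals.

    Calibrated to the scale implied by the packaged hurdle coefficients
    (seasonal totals in inches, median ~6, matching Tucson cool-season
    normals), so that every packaged species persists yet still
    experiences reproductive-failure years.  This is the default
    environment for the ESS pipeline.
    """
    return PrecipModel(kind="lognormal", meanlog=meanlog, sdlog=sdlog)


def calibrate_precip_model(series) -> PrecipModel:
    """Fit a lognormal model to an empirical series by log-moment matching."""
    s = np.asarray(series, dtype=float)
    if np.any(s <= 0) or s.size < 2:
        raise ValueError("need >= 2 positive precipitation values")
    logs = np.log(s)
    return PrecipModel(kind="lognormal", meanlog=float(logs.mean()), sdlog=float(logs.std(ddof=1)))


def sample_precip(model: PrecipModel, T: int, rng: np.random.Generator) -> np.ndarray:
    """Draw T annual totals from a precipitation model."""
    if T < 1:
        raise ValueError("need T >= 1 years")
    if model.kind == "lognormal":
        return np.exp(model.meanlog + model.sdlog * rng.standard_normal(T))
    if model.kind == "empirical":
        return rng.choice(model.series, size=T, replace=True)
    reps = int(np.ceil(T / len(model.series)))
    return np.tile(model.series, reps)[:T]


def generate_precip(model: PrecipModel, T: int, seed: int | None = None) -> PrecipSeries:
    """Generate a :class:`PrecipSeries` of T years (years labelled 1..T)."""
    rng = np.random.default_rng(seed)
    return PrecipSeries(years=np.arange(1, T + 1), precip=sample_precip(model, T, rng))


def generate_observations(
    params: SpeciesParams,
    g: float,
    precip: PrecipSeries | np.ndarray,
    residual_sd: float = 0.0,
    n0: float = 100.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate a per-species observation table.

    Runs the seed-bank recursion with hurdle-drawn yields and records,
    per year: precipitation, seedling density N_t = g n_t and the
    observed per-germinant yield Y_t = K_t / (1 + a N_t).

    The recorded yield is on the offset scale (the failure branch is
    the offset-zero value 0.5), so refitting should invert it with
    ``yield_is_offset=True`` for an exact round trip.
    """
    if isinstance(precip, PrecipSeries):
        years, P = precip.years, precip.precip
    else:
        P = np.asarray(precip, dtype=float)
        years = np.arange(1, P.size + 1)
    if rng is None:
        rng = np.random.default_rng(seed)
    K = sample_yield_series(params, P, rng, residual_sd)
    n = iterate_seedbank(n0, g, K, params)[:-1]  # pre-update densities
    N = g * n
    Y = K / (1.0 + params.a * N)
    return pd.DataFrame(
        {
            "species_code": params.species_code,
            "year": years,
            "precip": P,
            "seedling_density": N,
            "observed_yield": Y,
        }
    )


# Ranges spanned by the packaged ten-species table.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "s_old": (0.27, 0.83),
    "s_new": (0.10, 0.22),
    "alpha1": (-3.9, -0.1),
    "beta1": (1.4, 3.1),
    "log_alpha2": (-1.7, 1.8),
    "beta2": (0.79, 2.38),
    "a": (0.007, 0.054),
}


@dataclass
class SyntheticCommunity:
    """A generated community: parameter rows plus downstream artifacts."""

    species: list[SpeciesParams]
    ess: dict[str, float] = field(default_factory=dict)
    observations: pd.DataFrame | None = None
    observed_fractions: dict[str, float] = field(default_factory=dict)


def generate_community(
    n_species: int,
    ranges: dict[str, tuple[float, float]] | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> SyntheticCommunity:
    """Draw a community of parameter rows uniformly within ranges."""
    if n_species < 2:
        raise ValueError("need at least 2 species")
    use = dict(DEFAULT_RANGES)
    if ranges:
        unknown = set(ranges) - set(use)
        if unknown:
            raise ValueError(f"unknown parameter ranges: {sorted(unknown)}")
        use.update(ranges)
    for name, (lo, hi) in use.items():
        if hi < lo:
            raise ValueError(f"inverted range for {name}: ({lo}, {hi})")
    if rng is None:
        rng = np.random.default_rng(seed)
    species = []
    for i in range(n_species):
        draw = {name: float(rng.uniform(lo, hi)) for name, (lo, hi) in use.items()}
        species.append(SpeciesParams(species_code=f"SP{i + 1:02d}", **draw))
    return SyntheticCommunity(species=species)


def observed_fraction_standins(
    g_ess: dict[str, float],
    sigma: float = 0.5,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """Stand-in "observed" germination fractions around predicted ESSs.

    inverse_logit(logit(g) + Normal(0, sigma)): correlated with the
    predictions but not equal to them, mimicking how field germination
    fractions track model predictions imperfectly.  Boundary ESSs are
    nudged inside (0, 1) before the logit.
    """
    from .traits import inverse_logit, logit

    if rng is None:
        rng = np.random.default_rng(seed)
    out = {}
    for code, g in g_ess.items():
        gc = min(max(g, 1e-4), 1.0 - 1e-4)
        out[code] = float(inverse_logit(logit(gc) + sigma * rng.standard_normal()))
    return out
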