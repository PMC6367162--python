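"""Species life-history parameters and precipitation series.

Each species is summarized by seven numbers: survival of dormant seeds in
the soil seed bank (``s_old``), survival of freshly produced seeds to the
next autumn (``s_new``), the intercept/slope pair of the logistic
reproductive hurdle (``alpha1``, ``beta1``), the intercept/slope pair of
the log-log yield regression (``log_alpha2``, ``beta2``) and an
intraspecific competition coefficient ``a`` (m^2 per germinant).

A table for ten Sonoran Desert winter annuals ships with the package and
is returned by :func:`packaged_species`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "SpeciesParams",
    "PrecipSeries",
    "packaged_species",
    "packaged_species_table",
]

SPECIES_COLUMNS = [
    "species_code",
    "s_old",
    "s_new",
    "alpha1",
    "beta1",
    "log_alpha2",
    "beta2",
    "a",
]


@dataclass(frozen=True)
class SpeciesParams:
    """One species' life-history and yield-response parameters.

    Parameters
    ----------
    species_code
        Short label (e.g. ``"ERLA"``).
    s_old
        Annual survival probability of dormant seeds in the seed bank,
        in (0, 1).
    s_new
        Survival probability of freshly produced seeds to the next
        autumn, in (0, 1).
    alpha1, beta1
        Reproductive intercept and slope: the probability that a
        germinant reproduces at all is ``logistic(alpha1 + beta1 *
        ln(P + 1))`` for precipitation ``P``.
    log_alpha2, beta2
        Log-yield intercept and slope: conditional on reproducing, the
        low-density yield is ``exp(log_alpha2 + beta2 * ln(P + 1))``
        seeds per germinant.
    a
        Competition coefficient (m^2 per germinant); yield is divided
        by ``1 + a * N`` at seedling density ``N`` per m^2.
    """

    species_code: str
    s_old: float
    s_new: float
    alpha1: float
    beta1: float
    log_alpha2: float
    beta2: float
    a: float

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "species_code":
                continue
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"{self.species_code}: {f.name} must be finite, got {v!r}")
        if not 0.0 < self.s_old < 1.0:
            raise ValueError(f"{self.species_code}: s_old must lie in (0, 1), got {self.s_old}")
        if not 0.0 < self.s_new < 1.0:
            raise ValueError(f"{self.species_code}: s_new must lie in (0, 1), got {self.s_new}")
        if not self.a > 0.0:
            raise ValueError(f"{self.species_code}: competition coefficient a must be > 0, got {self.a}")


@dataclass(frozen=True)
class PrecipSeries:
    """Annual precipitation totals, one per year, strictly positive."""

    years: np.ndarray
    precip: np.ndarray

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=int)
        precip = np.asarray(self.precip, dtype=float)
        if years.shape != precip.shape or years.ndim != 1:
            raise ValueError("years and precip must be 1-d arrays of equal length")
        if precip.size < 1:
            raise ValueError("precipitation series must contain at least one year")
        if not np.all(np.isfinite(precip)) or np.any(precip <= 0):
            raise ValueError("precipitation values must be finite and strictly positive")
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "precip", precip)

    def __len__(self) -> int:
        return len(self.precip)


def _species_from_row(row: pd.Series) -> SpeciesParams:
    return SpeciesParams(
        species_code=str(row["species_code"]),
        s_old=float(row["s_old"]),
        s_new=float(row["s_new"]),
        alpha1=float(row["alpha1"]),
        beta1=float(row["beta1"]),
        log_alpha2=float(row["log_alpha2"]),
        beta2=float(row["beta2"]),
        a=float(row["a"]),
    )


def packaged_species_table() -> pd.DataFrame:
    """The packaged ten-species parameter table as a DataFrame."""
    with resources.files("bethedge.data").joinpath("species_params.csv").open("r") as fh:
        return pd.read_csv(fh, float_precision="round_trip")


def packaged_species() -> list[SpeciesParams]:
    """The packaged ten-species parameter set, MOBE through EVMU."""
    return [_species_from_row(row) for _, row in packaged_species_table().iterrows()]
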