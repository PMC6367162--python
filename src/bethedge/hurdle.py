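"""Two-stage hurdle model relating low-density yield to precipitation.

Reproduction by a germinated individual is modelled in two parts.  A
logistic ("reproductive hurdle") stage gives the probability that the
individual reproduces at all in a year with precipitation ``P``:

    pi = logistic(alpha1 + beta1 * ln(P + 1))

Conditional on clearing the hurdle, the low-density yield follows a
power law in precipitation, linear on the log-log scale:

    ln(K) = log_alpha2 + beta2 * ln(P + 1)

Failure years are assigned the yield 0.5 — a zero-seed year under the
convention that 0.5 is added to all yields before log-transforming, so
that K < 1 marks reproductive failure and K >= 1 success.

Fitting uses a binomial GLM (IRLS) for the hurdle stage and ordinary
least squares for the conditional-yield stage, in three nested forms:
per-species intercepts and slopes (``full``), a shared slope
(``common_slope``) or a shared intercept (``common_intercept``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

from .params import SpeciesParams

__all__ = [
    "SeparationWarning",
    "StageFit",
    "HurdleFit",
    "log_precip",
    "offset_yield",
    "reproduction_probability",
    "success_yield",
    "sample_low_density_yield",
    "sample_yield_series",
    "observed_to_low_density_yield",
    "prepare_hurdle_data",
    "fit_binomial_stage",
    "fit_yield_stage",
    "fit_hurdle",
    "compare_submodels",
    "pairwise_wald",
]

MODEL_FORMS = ("full", "common_slope", "common_intercept")

FAILURE_YIELD = 0.5  # offset-scale yield assigned to a zero-seed year
SUCCESS_THRESHOLD = 1.0  # K >= 1 counts as reproductive success


class SeparationWarning(UserWarning):
    """Raised when a logistic fit shows signs of complete separation."""


def log_precip(P):
    """ln(P + 1): the log-precipitation covariate.

    A unit offset keeps the transform finite at zero precipitation.
    Accepts scalars or arrays; values must be finite and >= 0.
    """
    P = np.asarray(P, dtype=float)
    if not np.all(np.isfinite(P)) or np.any(P < 0):
        raise ValueError("precipitation must be finite and non-negative")
    out = np.log1p(P)
    return float(out) if out.ndim == 0 else out


def offset_yield(Y):
    """Y + 0.5: the yield offset applied before any log transform."""
    Y = np.asarray(Y, dtype=float)
    if not np.all(np.isfinite(Y)) or np.any(Y < 0):
        raise ValueError("yield must be finite and non-negative")
    out = Y + 0.5
    return float(out) if out.ndim == 0 else out


def reproduction_probability(params: SpeciesParams, P):
    """Probability pi that a germinant reproduces at precipitation ``P``."""
    x = log_precip(P)
    out = expit(params.alpha1 + params.beta1 * np.asarray(x))
    return float(out) if np.ndim(out) == 0 else out


def success_yield(params: SpeciesParams, P):
    """Expected low-density yield conditional on reproductive success."""
    x = log_precip(P)
    out = np.exp(params.log_alpha2 + params.beta2 * np.asarray(x))
    return float(out) if np.ndim(out) == 0 else out


def sample_yield_series(
    params: SpeciesParams,
    precip,
    rng: np.random.Generator,
    residual_sd: float = 0.0,
):
    """Draw one low-density yield K_t per precipitation value.

    With probability pi(P) the success-branch yield is returned,
    multiplied by a lognormal residual of log-scale sd ``residual_sd``
    (deterministic when 0); otherwise the failure value 0.5.

    Both the hurdle uniforms and the residual normals are always drawn,
    so a fixed generator state yields the same K stream regardless of
    which branch each year takes.
    """
    if residual_sd < 0:
        raise ValueError("residual_sd must be >= 0")
    P = np.atleast_1d(np.asarray(precip, dtype=float))
    pi = reproduction_probability(params, P)
    u = rng.random(P.size)
    z = rng.standard_normal(P.size)
    succ = u < pi
    K = np.where(
        succ,
        np.exp(params.log_alpha2 + params.beta2 * np.log1p(P) + residual_sd * z),
        FAILURE_YIELD,
    )
    return K


def sample_low_density_yield(
    params: SpeciesParams,
    P: float,
    rng: np.random.Generator,
    residual_sd: float = 0.0,
) -> float:
    """Single hurdle draw of the low-density yield at precipitation ``P``."""
    return float(sample_yield_series(params, [P], rng, residual_sd)[0])


def observed_to_low_density_yield(
    observed_yield,
    seedling_density,
    a: float,
    yield_is_offset: bool = False,
):
    """Invert density dependence: recover K from the observed yield.

    The observed per-germinant yield is Y = K / (1 + a N) at seedling
    density N.  Field yields are offset by +0.5 before inversion
    (``yield_is_offset=False``); yields already on the offset scale —
    e.g. tables written by the synthetic generator, whose failure years
    carry K = 0.5 — invert exactly without a second offset.
    """
    if a <= 0:
        raise ValueError("competition coefficient a must be > 0")
    N = np.asarray(seedling_density, dtype=float)
    if np.any(N < 0):
        raise ValueError("seedling density must be >= 0")
    Y = np.asarray(observed_yield, dtype=float) if yield_is_offset else offset_yield(observed_yield)
    if yield_is_offset and (np.any(Y < 0) or not np.all(np.isfinite(Y))):
        raise ValueError("yield must be finite and non-negative")
    out = Y * (1.0 + a * N)
    return float(out) if out.ndim == 0 else out


def prepare_hurdle_data(
    observations: pd.DataFrame,
    species: dict[str, SpeciesParams] | list[SpeciesParams],
    yield_is_offset: bool = False,
) -> pd.DataFrame:
    """Build the fitting frame from an observation table.

    ``observations`` needs columns species_code, precip,
    seedling_density, observed_yield.  Returns one row per observation
    with the log-precipitation covariate ``x``, the recovered
    low-density yield ``K``, the success indicator (K >= 1) and
    ``log_K`` (NaN on failure years).
    """
    if isinstance(species, list):
        species = {sp.species_code: sp for sp in species}
    required = {"species_code", "precip", "seedling_density", "observed_yield"}
    missing = required - set(observations.columns)
    if missing:
        raise ValueError(f"observation table missing columns: {sorted(missing)}")
    if observations.empty:
        raise ValueError("observation table is empty")

    rows = []
    for code, grp in observations.groupby("species_code", sort=False):
        if code not in species:
            raise KeyError(f"no parameters supplied for species {code!r}")
        a = species[code].a
        K = observed_to_low_density_yield(
            grp["observed_yield"].to_numpy(),
            grp["seedling_density"].to_numpy(),
            a,
            yield_is_offset=yield_is_offset,
        )
        rows.append(
            pd.DataFrame(
                {
                    "species_code": code,
                    "x": log_precip(grp["precip"].to_numpy()),
                    "K": K,
                    "success": K >= SUCCESS_THRESHOLD,
                    "log_K": np.where(K >= SUCCESS_THRESHOLD, np.log(K), np.nan),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# fitting


@dataclass
class StageFit:
    """One fitted stage (binomial hurdle or conditional log-yield).

    ``params``/``vcov`` are indexed by coefficient names of the form
    ``intercept[CODE]`` / ``slope[CODE]`` (or unsuffixed when shared).
    """

    stage: str  # "binomial" | "yield"
    model_form: str
    params: pd.Series
    vcov: pd.DataFrame
    loglik: float
    k: int
    n: int
    species: list[str] = field(default_factory=list)
    residual_sd: float | None = None
    _fingerprint: tuple = ()

    @property
    def aic(self) -> float:
        return 2 * self.k - 2 * self.loglik

    @property
    def bic(self) -> float:
        return self.k * np.log(self.n) - 2 * self.loglik

    def _coef(self, family: str, code: str) -> float:
        key = f"{family}[{code}]"
        if key in self.params.index:
            return float(self.params[key])
        if family in self.params.index:  # shared coefficient
            return float(self.params[family])
        raise KeyError(key)

    def species_coefs(self) -> pd.DataFrame:
        """Per-species (intercept, slope), expanding shared coefficients."""
        return pd.DataFrame(
            {
                "intercept": [self._coef("intercept", c) for c in self.species],
                "slope": [self._coef("slope", c) for c in self.species],
            },
            index=self.species,
        )


@dataclass
class HurdleFit:
    """Both stages of the hurdle model fitted under one model form."""

    binomial: StageFit
    yield_: StageFit

    @property
    def model_form(self) -> str:
        return self.binomial.model_form

    def species_params(self, base: dict[str, SpeciesParams]) -> list[SpeciesParams]:
        """Merge fitted coefficients into existing parameter sets."""
        bc = self.binomial.species_coefs()
        yc = self.yield_.species_coefs()
        out = []
        for code, sp in base.items():
            out.append(
                SpeciesParams(
                    species_code=code,
                    s_old=sp.s_old,
                    s_new=sp.s_new,
                    alpha1=bc.loc[code, "intercept"],
                    beta1=bc.loc[code, "slope"],
                    log_alpha2=yc.loc[code, "intercept"],
                    beta2=yc.loc[code, "slope"],
                    a=sp.a,
                )
            )
        return out


def _design_matrix(data: pd.DataFrame, model_form: str) -> pd.DataFrame:
    """Species-indicator design for the three nested model forms."""
    if model_form not in MODEL_FORMS:
        raise ValueError(f"model_form must be one of {MODEL_FORMS}, got {model_form!r}")
    codes = list(dict.fromkeys(data["species_code"]))
    x = data["x"].to_numpy()
    cols: dict[str, np.ndarray] = {}
    if model_form in ("full", "common_slope"):
        for c in codes:
            cols[f"intercept[{c}]"] = (data["species_code"] == c).to_numpy(float)
    else:
        cols["intercept"] = np.ones(len(data))
    if model_form in ("full", "common_intercept"):
        for c in codes:
            cols[f"slope[{c}]"] = (data["species_code"] == c).to_numpy(float) * x
    else:
        cols["slope"] = x
    return pd.DataFrame(cols, index=data.index)


def _fingerprint(data: pd.DataFrame, ycol: str) -> tuple:
    y = data[ycol].to_numpy(float)
    return (len(data), round(float(np.nansum(y)), 9), round(float(data["x"].sum()), 9))


def fit_binomial_stage(data: pd.DataFrame, model_form: str = "full") -> StageFit:
    """Fit the reproductive hurdle by binomial GLM (IRLS).

    ``data`` needs columns species_code, x (log-precipitation) and
    success (bool/0-1).  Warns :class:`SeparationWarning` and keeps the
    guarded estimates when a species shows complete separation.
    """
    if data.empty:
        raise ValueError("no observations to fit")
    counts = data.groupby("species_code")["success"].agg(["size", "sum"])
    if (counts["size"] < 2).any():
        raise ValueError("need at least 2 observations per species")
    y = data["success"].to_numpy(float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need at least one success and one failure overall")
    X = _design_matrix(data, model_form)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # statsmodels' own separation chatter
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
    if not res.converged or np.max(np.abs(res.params)) > 15.0:
        warnings.warn(
            "logistic fit shows diverging coefficients (possible complete "
            "separation); estimates are truncated at the IRLS iteration cap",
            SeparationWarning,
            stacklevel=2,
        )
    return StageFit(
        stage="binomial",
        model_form=model_form,
        params=pd.Series(res.params, index=X.columns),
        vcov=pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns),
        loglik=float(res.llf),
        k=X.shape[1],
        n=len(data),
        species=list(dict.fromkeys(data["species_code"])),
        _fingerprint=_fingerprint(data, "success"),
    )


def fit_yield_stage(data: pd.DataFrame, model_form: str = "full") -> StageFit:
    """OLS fit of log yield on log precipitation over success years.

    Failure-year rows (log_K NaN) are dropped.  The Gaussian
    log-likelihood counts the residual variance as an estimated
    parameter, so k = (number of coefficients) + 1.
    """
    data = data.loc[data["log_K"].notna()] if "log_K" in data.columns else data
    if data.empty:
        raise ValueError("no success-year observations to fit")
    counts = data.groupby("species_code")["x"].agg(["size", "nunique"])
    if (counts["size"] < 2).any():
        raise ValueError("need at least 2 success-year observations per species")
    if model_form in ("full", "common_intercept") and (counts["nunique"] < 2).any():
        raise np.linalg.LinAlgError(
            "need >= 2 distinct precipitation values per fitted slope"
        )
    X = _design_matrix(data, model_form)
    res = sm.OLS(data["log_K"].to_numpy(), X).fit()
    resid_sd = float(np.sqrt(res.ssr / res.df_resid)) if res.df_resid > 0 else 0.0
    return StageFit(
        stage="yield",
        model_form=model_form,
        params=pd.Series(res.params, index=X.columns),
        vcov=pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns),
        loglik=float(res.llf),
        k=X.shape[1] + 1,
        n=len(data),
        species=list(dict.fromkeys(data["species_code"])),
        residual_sd=resid_sd,
        _fingerprint=_fingerprint(data, "log_K"),
    )


def fit_hurdle(data: pd.DataFrame, model_form: str = "full") -> HurdleFit:
    """Fit both hurdle stages under one model form."""
    return HurdleFit(
        binomial=fit_binomial_stage(data, model_form),
        yield_=fit_yield_stage(data, model_form),
    )


def compare_submodels(fits: list[StageFit]) -> dict:
    """Rank nested model forms and LR-test each against the full model.

    All fits must be of the same stage on identical data.  Returns a
    dict with a ranking ``table`` (sorted by AIC) and ``lr_tests``.
    """
    if not fits:
        raise ValueError("no fits to compare")
    stages = {f.stage for f in fits}
    if len(stages) != 1:
        raise ValueError("cannot compare fits of different stages")
    fps = {f._fingerprint for f in fits}
    if len(fps) != 1:
        raise ValueError("fits were not produced from identical data")
    table = pd.DataFrame(
        {
            "model_form": [f.model_form for f in fits],
            "k": [f.k for f in fits],
            "loglik": [f.loglik for f in fits],
            "aic": [f.aic for f in fits],
            "bic": [f.bic for f in fits],
        }
    ).sort_values("aic", kind="stable", ignore_index=True)
    ties = table["aic"].round(9).duplicated(keep=False)
    table["aic_tie"] = ties

    full = next((f for f in fits if f.model_form == "full"), None)
    lr_rows = []
    if full is not None:
        for f in fits:
            if f.model_form == "full":
                continue
            stat = 2.0 * (full.loglik - f.loglik)
            df = max(full.k - f.k, 1)
            lr_rows.append(
                {
                    "model_form": f.model_form,
                    "lr_stat": stat,
                    "df": df,
                    "p_value": float(stats.chi2.sf(max(stat, 0.0), df)),
                }
            )
    return {"table": table, "lr_tests": pd.DataFrame(lr_rows)}


def pairwise_wald(fit: StageFit, family: str = "intercept", bonferroni: bool = True) -> dict:
    """Pairwise Wald z tests between species-specific coefficients.

    ``family`` is "intercept" or "slope".  z_ij = (b_i - b_j) /
    sqrt(v_ii + v_jj - 2 v_ij) with two-sided normal p-values; an
    optional Bonferroni column multiplies by the number of pairs.
    """
    keys = [k for k in fit.params.index if k.startswith(f"{family}[")]
    if len(keys) < 2:
        raise ValueError(f"fit has no per-species {family} coefficients to compare")
    if fit.vcov is None or fit.vcov.empty:
        raise ValueError("fit carries no coefficient covariance")
    codes = [k[len(family) + 1 : -1] for k in keys]
    b = fit.params[keys].to_numpy()
    V = fit.vcov.loc[keys, keys].to_numpy()
    m = len(codes)
    z = np.zeros((m, m))
    for i in range(m):
        for j in range(m):
            if i == j:
                continue
            var = V[i, i] + V[j, j] - 2 * V[i, j]
            z[i, j] = (b[i] - b[j]) / np.sqrt(var) if var > 0 else np.inf
    p = 2.0 * stats.norm.sf(np.abs(z))
    np.fill_diagonal(p, 1.0)
    out = {
        "z": pd.DataFrame(z, index=codes, columns=codes),
        "p": pd.DataFrame(p, index=codes, columns=codes),
    }
    if bonferroni:
        n_pairs = m * (m - 1) // 2
        out["p_bonferroni"] = pd.DataFrame(
            np.minimum(p * n_pairs, 1.0), index=codes, columns=codes
        )
    return out
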