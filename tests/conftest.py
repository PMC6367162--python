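import numpy as np
import pytest

from bethedge import PrecipModel, SpeciesParams, packaged_species, winter_precip_model


@pytest.fixture(scope="session")
def species10():
    return packaged_species()


@pytest.fixture(scope="session")
def erla(species10):
    return next(sp for sp in species10 if sp.species_code == "ERLA")


@pytest.fixture(scope="session")
def winter_model():
    return winter_precip_model()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_species(**overrides) -> SpeciesParams:
    """A plain, persistent species for constructed scenarios."""
    base = dict(
        species_code="TEST",
        s_old=0.5,
        s_new=0.15,
        alpha1=-2.0,
        beta1=2.0,
        log_alpha2=0.0,
        beta2=1.5,
        a=0.01,
    )
    base.update(overrides)
    return SpeciesParams(**base)


def constant_yield_species(K: float, s_old: float = 0.5, s_new: float = 0.15, a: float = 0.01) -> SpeciesParams:
    """Hurdle degenerates to a constant yield K: pi = 1, flat log-yield."""
    return make_species(
        species_code="CONST",
        s_old=s_old,
        s_new=s_new,
        alpha1=30.0,  # logistic(30) = 1 to double precision
        beta1=0.0,
        log_alpha2=float(np.log(K)),
        beta2=0.0,
        a=a,
    )


def two_point_species(K_hi: float = 60.0, s_old: float = 0.8, s_new: float = 0.15, a: float = 0.01) -> SpeciesParams:
    """Yield is K_hi or the failure value 0.5, each with probability 1/2."""
    return make_species(
        species_code="TWOPT",
        s_old=s_old,
        s_new=s_new,
        alpha1=0.0,
        beta1=0.0,
        log_alpha2=float(np.log(K_hi)),
        beta2=0.0,
        a=a,
    )


@pytest.fixture(scope="session")
def fixed_precip_model():
    return PrecipModel(kind="fixed", series=np.full(10, 5.0))
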