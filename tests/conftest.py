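import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cartqsp import (
    VariabilityParams,
    default_params,
    fit_population,
    generate_cohort,
    simulate_survival,
)
from cartqsp.estimation import CarTPopulationModel

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def recovery_cohort(params):
    """n = 100 virtual cohort generated at the default (truth) parameters."""
    sp, vp = params
    return generate_cohort(100, sp, vp, rng=11)


@pytest.fixture(scope="session")
def recovery_model(params, recovery_cohort):
    """Mixture fit of the recovery cohort: Vmax1 baselines + MIXP free."""
    sp, vp = params
    model = CarTPopulationModel(
        structural=sp,
        variability=vp,
        free=("Vmax1_base_ref", "Vmax1_base_low", "MIXP"),
        maxfev=150,
        xatol=5e-3,
        fatol=0.05,
    )
    model.fit(recovery_cohort)
    return model


@pytest.fixture(scope="session")
def lrt_fits(params):
    """Full vs no-ASCT fits of a single-population cohort with a true ASCT effect."""
    sp, vp = params
    sp1 = sp.replace(MIXP=1.0)
    ds = generate_cohort(100, sp1, vp, rng=21)
    full = fit_population(
        ds, sp1, vp, free=("Vmax1_base_ref", "ASCT_Vmax1"),
        maxfev=120, xatol=5e-3, fatol=0.05,
    )
    reduced = fit_population(
        ds, sp1.replace(ASCT_Vmax1=0.0), vp, free=("Vmax1_base_ref",),
        maxfev=60, xatol=5e-3, fatol=0.05,
    )
    return full, reduced


@pytest.fixture(scope="session")
def sigma_fit(params):
    """Residual-variance recovery on a zero-IIV cohort (isolates the RUV)."""
    sp, vp = params
    sp1 = sp.replace(MIXP=1.0)
    vp0 = VariabilityParams(0.0, 0.0, dict(vp.sigma2))
    ds = generate_cohort(100, sp1, vp0, rng=31)
    from cartqsp.parameters import SPECIES

    init = vp0.replace(**{f"sigma2_{s}": 0.25 for s in SPECIES})
    fit = fit_population(
        ds, sp1, init, free=tuple(f"sigma2_{s}" for s in SPECIES),
        maxfev=600, xatol=2e-3, fatol=0.01,
    )
    return fit, vp


@pytest.fixture(scope="session")
def chain_cohort(params):
    """n = 200 cohort with survival linked to the expansion subpopulation."""
    sp, vp = params
    ds = generate_cohort(200, sp, vp, rng=7)
    simulate_survival(ds, rng=8)
    return ds


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
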