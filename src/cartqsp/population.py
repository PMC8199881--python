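"""Mixed-effects layers: exponential IIV, covariate model, residual model.

Between-patient variability uses the exponential model θᵢ = θ·e^η with
η ~ N(0, ω²), i.e. individual parameters are log-normal around the typical
value. Residual variability is additive on the log scale
(log-transform-both-sides), with one variance per observed species.

Two typical-value subpopulations exist for the baseline maximum expansion
rate: a reference population and a low-expansion subpopulation (~92% lower
rate); a Bernoulli mixture with probability MIXP assigns patients to the
reference population.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import norm

from .parameters import (
    DEFAULT_DOSE_PER_PHENOTYPE,
    IndividualParams,
    PatientCovariates,
    StructuralParams,
    VariabilityParams,
    cv_to_omega2,
    omega2_to_cv,
)

__all__ = [
    "iiv_transform",
    "omega2_to_cv",
    "cv_to_omega2",
    "apply_covariates",
    "residual_log_density",
    "sample_individual",
    "individual_from_eta",
]

#: Default limit of quantification for tumor scans recorded as 0 mL, in mL.
DEFAULT_LOQ = 0.1


def iiv_transform(theta_k: float, eta: float) -> float:
    """Individual parameter value θ·e^η under the exponential IIV model."""
    if theta_k < 0:
        raise ValueError(f"typical value must be non-negative, got {theta_k}")
    return theta_k * math.exp(eta)


def apply_covariates(
    params: StructuralParams, cov: PatientCovariates, subpop: str
) -> float:
    """Typical Vmax1 for a patient given subpopulation and covariates.

    Reference population::

        Vmax1_base_ref · (1 + ASCT_Vmax1·ASCT) · (cd4cd8_day7)^CD4CD8_exp

    Low-expansion subpopulation keeps only the ASCT effect — exploratory
    analysis showed no day-7 CD4/CD8 influence there::

        Vmax1_base_low · (1 + ASCT_Vmax1·ASCT)
    """
    asct_factor = 1.0 + params.ASCT_Vmax1 * cov.ASCT
    if subpop == "reference":
        if not cov.cd4cd8_day7 > 0:
            raise ValueError(
                f"cd4cd8_day7 must be positive for the reference subpopulation, "
                f"got {cov.cd4cd8_day7}"
            )
        return params.Vmax1_base_ref * asct_factor * cov.cd4cd8_day7**params.CD4CD8_exp
    if subpop == "low":
        return params.Vmax1_base_low * asct_factor
    raise ValueError(f"subpop must be 'reference' or 'low', got {subpop!r}")


def residual_log_density(
    observed: float,
    predicted: float,
    sigma2: float,
    censored: bool = False,
    loq: float = DEFAULT_LOQ,
) -> float:
    """Log-density contribution of one observation under the log-residual model.

    Uncensored: normal log-density of ln(observed) − ln(predicted) with
    variance sigma2. Censored (tumor volumes recorded as 0 mL at complete
    response): left-censoring at ``loq``, i.e. the normal log-CDF of
    ln(loq) − ln(predicted).
    """
    if predicted <= 0:
        raise ValueError(f"predicted value must be positive, got {predicted}")
    if sigma2 <= 0:
        raise ValueError(f"sigma2 must be positive, got {sigma2}")
    sd = math.sqrt(sigma2)
    if censored:
        return float(norm.logcdf((math.log(loq) - math.log(predicted)) / sd))
    if observed <= 0:
        raise ValueError(
            f"uncensored observation must be positive, got {observed}"
        )
    return float(norm.logpdf(math.log(observed) - math.log(predicted), scale=sd))


def individual_from_eta(
    params: StructuralParams,
    cov: PatientCovariates,
    subpop: str,
    eta_Vmax1: float = 0.0,
    eta_Vmax5_2: float = 0.0,
    dose_per_phenotype: float = DEFAULT_DOSE_PER_PHENOTYPE,
) -> IndividualParams:
    """Deterministic assembly of an individual parameter set from given etas.

    The four killing rates keep their fixed phenotype ratios: the random
    effect acts on the TCM rate and the other phenotypes scale with it.
    """
    vmax1_typ = apply_covariates(params, cov, subpop)
    vmax1_i = iiv_transform(vmax1_typ, eta_Vmax1 if subpop == "reference" else 0.0)
    vmax5_2_i = iiv_transform(params.Vmax5_2, eta_Vmax5_2)
    vmax5_i = tuple(r * vmax5_2_i for r in params.vmax5_ratios)
    return IndividualParams(
        patient_id=cov.patient_id,
        Vmax1_i=vmax1_i,
        Vmax5_i=vmax5_i,
        subpop=subpop,
        baseline_mtv=cov.baseline_mtv,
        dose_per_phenotype=dose_per_phenotype,
    )


def sample_individual(
    params: StructuralParams,
    variability: VariabilityParams,
    cov: PatientCovariates,
    rng,
    dose_per_phenotype: float = DEFAULT_DOSE_PER_PHENOTYPE,
):
    """Draw one patient's subpopulation, random effects, and parameters.

    The subpopulation is Bernoulli(MIXP → reference). The Vmax1 random
    effect is applied only in the reference population (its variability in
    the low subpopulation was negligible); the Vmax5_2 random effect applies
    in both.

    Returns ``(IndividualParams, eta_dict, subpop)``; reproducible given a
    seeded generator.
    """
    rng = np.random.default_rng(rng)
    subpop = "reference" if rng.random() < params.MIXP else "low"
    eta1 = (
        rng.normal(0.0, math.sqrt(variability.omega2_Vmax1))
        if variability.omega2_Vmax1 > 0 and subpop == "reference"
        else 0.0
    )
    eta5 = (
        rng.normal(0.0, math.sqrt(variability.omega2_Vmax5_2))
        if variability.omega2_Vmax5_2 > 0
        else 0.0
    )
    ind = individual_from_eta(
        params, cov, subpop, eta1, eta5, dose_per_phenotype=dose_per_phenotype
    )
    return ind, {"eta_Vmax1": eta1, "eta_Vmax5_2": eta5}, subpop
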