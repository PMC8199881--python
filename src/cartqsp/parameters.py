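"""Parameter containers for the CD19 CAR-T quantitative systems pharmacology model.

The model tracks four CAR-T cell phenotypes (naïve ``TN``, central memory
``TCM``, effector memory ``TEM``, terminally differentiated effector ``TEFF``,
all in cells·µL⁻¹) and the CD19⁺ metabolic tumor volume (``CD19``, in mL).
Units are deliberately kept mixed (µL for the T-cell distribution volume, mL
for the tumor volume) — resolving them would obscure the different physical
origins of the two scales.

:class:`StructuralParams` holds the population typical values ("fixed
effects"), :class:`VariabilityParams` the between-patient (IIV) and residual
(RUV) variances on the log scale, :class:`PatientCovariates` one patient's
covariate record, and :class:`IndividualParams` one patient's realized
parameter set after mixture assignment, covariates, and random effects.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import yaml

#: Canonical species order used throughout the package.
SPECIES = ("TN", "TCM", "TEM", "TEFF", "CD19")

#: Default imputed post-distribution dose, cells·µL⁻¹ per phenotype.
DEFAULT_DOSE_PER_PHENOTYPE = 0.1


def omega2_to_cv(omega2: float) -> float:
    """Convert a log-scale variance to a coefficient of variation in percent.

    Uses the log-normal convention ``CV% = sqrt(exp(ω²) − 1)·100``, the
    standard reading in population modeling (it makes variability rows
    expressed as "% CV" internally consistent with the exponential
    random-effect model θ·e^η).
    """
    if omega2 < 0:
        raise ValueError(f"variance must be non-negative, got {omega2}")
    return math.sqrt(math.expm1(omega2)) * 100.0


def cv_to_omega2(cv_percent: float) -> float:
    """Inverse of :func:`omega2_to_cv`: ``ω² = ln((CV/100)² + 1)``."""
    if cv_percent < 0:
        raise ValueError(f"CV must be non-negative, got {cv_percent}")
    return math.log1p((cv_percent / 100.0) ** 2)


@dataclass
class StructuralParams:
    """Typical-value ("fixed effects") parameters of the structural model.

    See ``data/default_parameters.yaml`` for units and the packaged default
    estimates.
    """

    Vmax1_base_ref: float
    Vmax1_base_low: float
    ASCT_Vmax1: float
    CD4CD8_exp: float
    KM1: float
    kp1: float
    kp2: float
    kp3: float
    k12: float
    k23: float
    k34: float
    ke1: float
    ke2: float
    ke3: float
    ke4: float
    Vmax5_1: float
    Vmax5_2: float
    Vmax5_3: float
    Vmax5_4: float
    KM5: float
    K0: float
    k5: float
    MIXP: float

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        nonneg = (
            "Vmax1_base_ref Vmax1_base_low KM1 kp1 kp2 kp3 k12 k23 k34 "
            "ke1 ke2 ke3 ke4 Vmax5_1 Vmax5_2 Vmax5_3 Vmax5_4 KM5 K0 k5"
        ).split()
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)}")
        if not 0.0 <= self.MIXP <= 1.0:
            raise ValueError(f"MIXP must lie in [0, 1], got {self.MIXP}")
        if self.Vmax1_base_low >= self.Vmax1_base_ref:
            raise ValueError(
                "Vmax1_base_low must be below Vmax1_base_ref "
                f"({self.Vmax1_base_low} >= {self.Vmax1_base_ref})"
            )
        for name in ("KM1", "KM5", "K0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")

    @property
    def vmax5(self) -> tuple[float, float, float, float]:
        """Typical killing rates in phenotype order (TN, TCM, TEM, TEFF)."""
        return (self.Vmax5_1, self.Vmax5_2, self.Vmax5_3, self.Vmax5_4)

    @property
    def vmax5_ratios(self) -> tuple[float, float, float, float]:
        """Killing rates expressed as fixed multiples of the TCM rate."""
        v2 = self.Vmax5_2
        return (self.Vmax5_1 / v2, 1.0, self.Vmax5_3 / v2, self.Vmax5_4 / v2)

    def replace(self, **changes) -> "StructuralParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


@dataclass
class VariabilityParams:
    """IIV variances (log scale) and per-species residual variances.

    IIV is supported on exactly the two parameters retained in the final
    model: the baseline maximum expansion rate in the reference population
    and the TCM maximum killing rate.
    """

    omega2_Vmax1: float
    omega2_Vmax5_2: float
    sigma2: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.omega2_Vmax1 < 0 or self.omega2_Vmax5_2 < 0:
            raise ValueError("IIV variances must be non-negative")
        for sp, v in self.sigma2.items():
            if sp not in SPECIES:
                raise ValueError(f"unknown species {sp!r} in sigma2")
            if v < 0:
                raise ValueError(f"sigma2[{sp}] must be non-negative, got {v}")

    def replace(self, **changes) -> "VariabilityParams":
        out = dataclasses.replace(self, **{k: v for k, v in changes.items() if not k.startswith("sigma2_")})
        sig = dict(out.sigma2)
        for k, v in changes.items():
            if k.startswith("sigma2_"):
                sig[k.removeprefix("sigma2_")] = v
        out.sigma2 = sig
        out.validate()
        return out

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PatientCovariates:
    """One patient's covariate record.

    ``cd4cd8_day7`` is the CD4⁺/CD8⁺ CAR-T cell ratio measured on day 7;
    when unavailable it is imputed with the covariate-neutral reference
    value 1.
    """

    patient_id: str
    ASCT: int
    cd4cd8_day7: float
    baseline_mtv: float

    def __post_init__(self) -> None:
        if self.ASCT not in (0, 1):
            raise ValueError(f"ASCT must be 0 or 1, got {self.ASCT}")
        if not self.cd4cd8_day7 > 0:
            raise ValueError(f"cd4cd8_day7 must be positive, got {self.cd4cd8_day7}")
        if not self.baseline_mtv > 0:
            raise ValueError(f"baseline_mtv must be positive, got {self.baseline_mtv}")


@dataclass
class IndividualParams:
    """One patient's realized parameter set entering the ODE system.

    ``Vmax5_i`` preserves the fixed phenotype ratios of the typical killing
    rates: only the TCM rate carries between-patient variability and the
    other three phenotypes are scaled from it.
    """

    patient_id: str
    Vmax1_i: float
    Vmax5_i: tuple[float, float, float, float]
    subpop: str
    baseline_mtv: float
    dose_per_phenotype: float = DEFAULT_DOSE_PER_PHENOTYPE

    def __post_init__(self) -> None:
        if self.Vmax1_i < 0:
            raise ValueError(f"Vmax1_i must be non-negative, got {self.Vmax1_i}")
        if not self.baseline_mtv > 0:
            raise ValueError(f"baseline_mtv must be positive, got {self.baseline_mtv}")
        # zero dose is permitted: it is the tumor-only (logistic) limit
        if self.dose_per_phenotype < 0:
            raise ValueError(
                f"dose_per_phenotype must be non-negative, got {self.dose_per_phenotype}"
            )
        if self.subpop not in ("reference", "low"):
            raise ValueError(f"subpop must be 'reference' or 'low', got {self.subpop!r}")
        if any(v < 0 for v in self.Vmax5_i):
            raise ValueError("Vmax5_i entries must be non-negative")


def _params_from_mapping(cfg: Mapping) -> tuple[StructuralParams, VariabilityParams]:
    structural = StructuralParams(**cfg["structural"])
    var = cfg.get("variability", {})
    iiv = var.get("iiv_cv", {})
    ruv = var.get("ruv_cv", {})
    variability = VariabilityParams(
        omega2_Vmax1=cv_to_omega2(iiv.get("Vmax1", 0.0)),
        omega2_Vmax5_2=cv_to_omega2(iiv.get("Vmax5_2", 0.0)),
        sigma2={sp: cv_to_omega2(ruv[sp]) for sp in ruv},
    )
    return structural, variability


def load_params(path) -> tuple[StructuralParams, VariabilityParams]:
    """Load structural and variability parameters from a YAML config file.

    The file uses the same flat key names as :class:`StructuralParams`;
    variability is given as % CV and converted to log-scale variances.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return _params_from_mapping(cfg)


def default_params() -> tuple[StructuralParams, VariabilityParams]:
    """Packaged default parameter set (final population estimates)."""
    text = resources.files("cartqsp.data").joinpath("default_parameters.yaml").read_text()
    return _params_from_mapping(yaml.safe_load(text))


def save_params(structural: StructuralParams, variability: VariabilityParams, path) -> None:
    """Write a parameter set back to the YAML layout used by :func:`load_params`."""
    cfg = {
        "structural": {k: float(v) for k, v in structural.to_dict().items()},
        "variability": {
            "iiv_cv": {
                "Vmax1": omega2_to_cv(variability.omega2_Vmax1),
                "Vmax5_2": omega2_to_cv(variability.omega2_Vmax5_2),
            },
            "ruv_cv": {sp: omega2_to_cv(v) for sp, v in variability.sigma2.items()},
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
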