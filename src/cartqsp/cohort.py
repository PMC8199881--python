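"""Virtual-cohort generator emulating the clinical study design.

Generates long-format observation tables with the study's sampling scheme:
CAR-T phenotype concentrations sampled at days 7, 14, and ~26 after
infusion, and CD19⁺ metabolic tumor volume scans at baseline, ~1 month, and
~3 months. Observations carry log-normal residual noise per species; tumor
scans falling below the limit of quantification are recorded as 0 mL and
flagged censored (complete response). The generating truth — individual
parameters, random effects, and subpopulation labels — is retained so
downstream estimation and endpoint stages can be tested without any
clinical download.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dynamics
from .parameters import SPECIES, PatientCovariates, StructuralParams, VariabilityParams
from .population import DEFAULT_LOQ, sample_individual

CELL_SPECIES = SPECIES[:4]


@dataclass
class StudyDesign:
    """Sampling design: which days each species is observed on."""

    cell_days: tuple = (7.0, 14.0, 26.0)
    tumor_days: tuple = (0.0, 30.0, 90.0)
    dose_per_phenotype: float = 0.1
    loq: float = DEFAULT_LOQ
    cell_day_jitter: float = 0.0  # optional ±jitter (days) on the last cell sample

    @property
    def horizon(self) -> float:
        return max(max(self.cell_days), max(self.tumor_days))


@dataclass
class CovariateConfig:
    """Marginal covariate distributions for the virtual cohort.

    Baseline metabolic tumor volume is log-normal (median ``mtv_median`` mL,
    log-sd ``mtv_log_sd``) truncated to the plausible clinical span; previous
    ASCT is Bernoulli with the cohort prevalence; the day-7 CD4/CD8 CAR-T
    ratio is log-normal around 1. Covariates are drawn independently.
    """

    mtv_median: float = 100.0
    mtv_log_sd: float = 1.5
    mtv_range: tuple = (2.5, 3600.0)
    asct_prevalence: float = 0.37
    cd4cd8_median: float = 1.0
    cd4cd8_log_sd: float = 0.5


@dataclass
class HazardConfig:
    """Exponential survival model linking hazard to the expansion subpopulation."""

    median_ref_months: float = 12.0
    hazard_ratio_low: float = 4.0
    max_follow_up_months: float = 24.0


@dataclass
class CohortDataset:
    """Long-format observations + covariates (+ hidden truth for synthetic data)."""

    observations: pd.DataFrame
    covariates: pd.DataFrame
    truth: dict | None = None
    survival: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        obs, cov = self.observations, self.covariates
        required = {"patient_id", "time_days", "species", "value", "censored"}
        if not required.issubset(obs.columns):
            raise ValueError(f"observations missing columns {required - set(obs.columns)}")
        known = set(cov["patient_id"])
        missing = set(obs["patient_id"]) - known
        if missing:
            raise ValueError(f"observations reference unknown patients {sorted(missing)}")
        if (obs["time_days"] < 0).any():
            raise ValueError("observation times must be non-negative")
        if (obs["value"] < 0).any():
            raise ValueError("observation values must be non-negative")
        bad = obs["censored"] & (obs["species"] != "CD19")
        if bad.any():
            raise ValueError("censoring is only allowed for CD19 tumor scans")

    def patient_ids(self) -> list[str]:
        return list(self.covariates["patient_id"])

    def patient_covariates(self, patient_id: str) -> PatientCovariates:
        row = self.covariates.set_index("patient_id").loc[patient_id]
        return PatientCovariates(
            patient_id=patient_id,
            ASCT=int(row["ASCT"]),
            cd4cd8_day7=float(row["cd4cd8_day7"]),
            baseline_mtv=float(row["baseline_mtv"]),
        )

    def write(self, outdir) -> None:
        """Write observation/covariate (and survival/truth) files to a directory."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.observations.to_csv(outdir / "observations.csv", index=False)
        self.covariates.to_csv(outdir / "covariates.csv", index=False)
        if self.survival is not None:
            self.survival.to_csv(outdir / "survival.csv", index=False)
        if self.truth is not None:
            with open(outdir / "truth.json", "w") as fh:
                json.dump(self.truth, fh, indent=1, default=float)

    @classmethod
    def read(cls, indir) -> "CohortDataset":
        indir = Path(indir)
        obs = pd.read_csv(indir / "observations.csv")
        cov = pd.read_csv(indir / "covariates.csv")
        surv = None
        if (indir / "survival.csv").exists():
            surv = pd.read_csv(indir / "survival.csv")
        truth = None
        if (indir / "truth.json").exists():
            truth = json.loads((indir / "truth.json").read_text())
        return cls(observations=obs, covariates=cov, truth=truth, survival=surv)


def sample_covariates(
    n: int, config: CovariateConfig | None = None, rng=None
) -> list[PatientCovariates]:
    """Draw ``n`` patient covariate records from the configured marginals."""
    if n < 1:
        raise ValueError(f"n must be at least 1, got {n}")
    config = config or CovariateConfig()
    rng = np.random.default_rng(rng)
    out = []
    lo, hi = config.mtv_range
    for i in range(n):
        # rejection-sample the truncated log-normal tumor volume
        while True:
            mtv = config.mtv_median * math.exp(rng.normal(0.0, config.mtv_log_sd))
            if lo <= mtv <= hi:
                break
        out.append(
            PatientCovariates(
                patient_id=f"P{i + 1:03d}",
                ASCT=int(rng.random() < config.asct_prevalence),
                cd4cd8_day7=config.cd4cd8_median
                * math.exp(rng.normal(0.0, config.cd4cd8_log_sd)),
                baseline_mtv=mtv,
            )
        )
    return out


def generate_cohort(
    n: int,
    structural: StructuralParams,
    variability: VariabilityParams,
    design: StudyDesign | None = None,
    rng=None,
    covariate_config: CovariateConfig | None = None,
    add_residual: bool = True,
    sim_rtol: float = 1e-8,
) -> CohortDataset:
    """Generate a complete virtual cohort.

    Per patient: sample covariates → draw subpopulation and random effects →
    simulate the ODE system → evaluate at the design sampling times →
    multiply by log-normal residual noise per species → mark tumor values
    below the limit of quantification as censored at 0 mL. Patients whose
    simulation fails are skipped with a warning, never silently.
    """
    design = design or StudyDesign()
    rng = np.random.default_rng(rng)
    covs = sample_covariates(n, covariate_config, rng)

    records = []
    truth: dict = {}
    kept = []
    for cov in covs:
        ind, etas, subpop = sample_individual(
            structural, variability, cov, rng,
            dose_per_phenotype=design.dose_per_phenotype,
        )
        cell_days = list(design.cell_days)
        if design.cell_day_jitter > 0:
            cell_days[-1] += rng.uniform(-design.cell_day_jitter, design.cell_day_jitter)
        t_all = np.unique(np.concatenate([cell_days, design.tumor_days]))
        try:
            states = dynamics.solve(ind, structural, t_all, rtol=sim_rtol)
        except dynamics.SimulationError as err:
            warnings.warn(
                f"simulation failed for {cov.patient_id}: {err}; patient skipped",
                stacklevel=2,
            )
            continue
        kept.append(cov)
        pred = {t: states[i] for i, t in enumerate(t_all)}
        for t in cell_days:
            for j, sp in enumerate(CELL_SPECIES):
                value = pred[t][j]
                if add_residual:
                    value *= math.exp(rng.normal(0.0, math.sqrt(variability.sigma2[sp])))
                records.append((cov.patient_id, t, sp, value, False))
        for t in design.tumor_days:
            value = pred[t][4]
            if add_residual:
                value *= math.exp(rng.normal(0.0, math.sqrt(variability.sigma2["CD19"])))
            censored = value < design.loq
            records.append((cov.patient_id, t, "CD19", 0.0 if censored else value, censored))
        truth[cov.patient_id] = {
            "subpop": subpop,
            "eta_Vmax1": etas["eta_Vmax1"],
            "eta_Vmax5_2": etas["eta_Vmax5_2"],
            "Vmax1_i": ind.Vmax1_i,
            "Vmax5_2_i": ind.Vmax5_i[1],
        }

    observations = pd.DataFrame(
        records, columns=["patient_id", "time_days", "species", "value", "censored"]
    )
    covariates = pd.DataFrame(
        [
            {
                "patient_id": c.patient_id,
                "ASCT": c.ASCT,
                "cd4cd8_day7": c.cd4cd8_day7,
                "baseline_mtv": c.baseline_mtv,
            }
            for c in kept
        ],
        columns=["patient_id", "ASCT", "cd4cd8_day7", "baseline_mtv"],
    )
    return CohortDataset(observations=observations, covariates=covariates, truth=truth)


def simulate_survival(
    cohort: CohortDataset,
    hazard_config: HazardConfig | None = None,
    rng=None,
) -> pd.DataFrame:
    """Attach exponential survival times linked to the expansion subpopulation.

    Patients in the low-expansion subpopulation carry ``hazard_ratio_low``
    times the reference hazard; follow-up is administratively censored at
    ``max_follow_up_months``. Requires the cohort's truth labels.
    """
    if cohort.truth is None:
        raise ValueError("simulate_survival requires a cohort with truth labels")
    cfg = hazard_config or HazardConfig()
    rng = np.random.default_rng(rng)
    rate_ref = math.log(2.0) / cfg.median_ref_months
    rows = []
    for pid in cohort.patient_ids():
        subpop = cohort.truth[pid]["subpop"]
        rate = rate_ref * (cfg.hazard_ratio_low if subpop == "low" else 1.0)
        t = rng.exponential(1.0 / rate) if rate > 0 else math.inf
        event = int(t <= cfg.max_follow_up_months)
        rows.append(
            {
                "patient_id": pid,
                "time_months": min(t, cfg.max_follow_up_months),
                "event": event,
            }
        )
    surv = pd.DataFrame(rows)
    cohort.survival = surv
    return surv
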