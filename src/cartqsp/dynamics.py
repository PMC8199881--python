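"""Five-species ODE system for CAR-T cell kinetics and CD19⁺ tumor dynamics.

The structural model follows the progressive differentiation lineage
TN → TCM → TEM → TEFF. Naïve and memory phenotypes expand on tumor contact
via a Michaelis–Menten term saturating in the respective T-cell
concentration, proliferate homeostatically, differentiate forward, and die;
terminally differentiated effectors are only formed and die. The CD19⁺
metabolic tumor volume grows logistically toward carrying capacity K0 and is
killed by each phenotype through a Michaelis–Menten term saturating in tumor
volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .parameters import SPECIES, IndividualParams, StructuralParams

#: Negative solver excursions above this magnitude are a hard error.
NEGATIVITY_TOLERANCE = 1e-9


class SimulationError(RuntimeError):
    """Raised when the ODE solver fails or produces non-physical output."""


def expansion_term(Vmax1: float, CD19: float, T: float, KM1: float) -> float:
    """Tumor-contact expansion rate ``Vmax1·CD19·T/(KM1 + T)``.

    Saturates at ``Vmax1·CD19`` for large T: at high CAR-T concentrations
    the expansion becomes proportional to the tumor burden alone.
    """
    if KM1 <= 0:
        raise ValueError(f"KM1 must be positive, got {KM1}")
    if Vmax1 < 0 or CD19 < 0 or T < 0:
        raise ValueError("expansion_term inputs must be non-negative")
    return Vmax1 * CD19 * T / (KM1 + T)


def killing_term(Vmax5x: float, T: float, CD19: float, KM5: float) -> float:
    """Tumor killing rate by one phenotype, ``Vmax5x·T·CD19/(KM5 + CD19)``."""
    if KM5 <= 0:
        raise ValueError(f"KM5 must be positive, got {KM5}")
    if Vmax5x < 0 or T < 0 or CD19 < 0:
        raise ValueError("killing_term inputs must be non-negative")
    return Vmax5x * T * CD19 / (KM5 + CD19)


def ode_rhs(
    state,
    structural: StructuralParams,
    individual: IndividualParams,
    expansion_denominator: str = "tcell",
):
    """Time derivatives of (TN, TCM, TEM, TEFF, CD19).

    ``expansion_denominator`` selects what saturates the expansion term:
    ``"tcell"`` (the selected model form — the respective T-cell
    concentration) or ``"tumor"`` (an explored alternative where the tumor
    volume saturates expansion instead; exposed for comparison only).
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (5,):
        raise ValueError(f"state must have 5 entries, got shape {state.shape}")
    if not np.all(np.isfinite(state)):
        raise ValueError(f"state contains non-finite entries: {state}")
    if np.any(state < 0):
        raise ValueError(f"state contains negative entries: {state}")
    rhs = _make_rhs(
        individual.Vmax1_i, individual.Vmax5_i, structural, expansion_denominator
    )
    return np.asarray(rhs(0.0, state))


def _make_rhs(vmax1, vmax5, sp: StructuralParams, denominator: str):
    """Build a fast RHS closure with all parameters bound to locals.

    The likelihood machinery evaluates the system hundreds of thousands of
    times; avoiding per-call attribute lookups roughly halves solve time.
    """
    km1, kp1, kp2, kp3 = sp.KM1, sp.kp1, sp.kp2, sp.kp3
    k12, k23, k34 = sp.k12, sp.k23, sp.k34
    ke1, ke2, ke3, ke4 = sp.ke1, sp.ke2, sp.ke3, sp.ke4
    km5, k0, k5 = sp.KM5, sp.K0, sp.k5
    v51, v52, v53, v54 = vmax5
    if denominator not in ("tcell", "tumor"):
        raise ValueError(f"unknown expansion_denominator {denominator!r}")
    tcell_form = denominator == "tcell"

    def rhs(t, y):
        tn, tcm, tem, teff, cd19 = y
        if tcell_form:
            vc = vmax1 * cd19
            exp_tn = vc * tn / (km1 + tn)
            exp_tcm = vc * tcm / (km1 + tcm)
            exp_tem = vc * tem / (km1 + tem)
        else:
            frac = vmax1 * cd19 / (km1 + cd19)
            exp_tn = frac * tn
            exp_tcm = frac * tcm
            exp_tem = frac * tem
        kill = cd19 / (km5 + cd19)
        return (
            exp_tn + kp1 * tn - k12 * tn - ke1 * tn,
            exp_tcm + kp2 * tcm + k12 * tn - k23 * tcm - ke2 * tcm,
            exp_tem + kp3 * tem + k23 * tcm - k34 * tem - ke3 * tem,
            k34 * tem - ke4 * teff,
            k5 * (1.0 - cd19 / k0) * cd19
            - kill * (v51 * tn + v52 * tcm + v53 * tem + v54 * teff),
        )

    return rhs


@dataclass
class Trajectory:
    """Dense simulated time course of the five model species."""

    patient_id: str
    times: np.ndarray
    states: np.ndarray  # shape (n_times, 5), columns in SPECIES order

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (self.times.size, 5):
            raise ValueError("states must have shape (n_times, 5)")

    def species(self, name: str) -> np.ndarray:
        return self.states[:, SPECIES.index(name)]

    @property
    def total_cart(self) -> np.ndarray:
        """Summed concentration of all four CAR-T phenotypes, cells·µL⁻¹."""
        return self.states[:, :4].sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format export (patient_id, time_days, species, value)."""
        n = self.times.size
        return pd.DataFrame(
            {
                "patient_id": np.repeat(self.patient_id, n * 5),
                "time_days": np.tile(self.times, 5).reshape(5, n).T.ravel(),
                "species": np.repeat(SPECIES, n).reshape(5, n).T.ravel(),
                "value": self.states.ravel(),
            }
        )


def initial_state(individual: IndividualParams) -> np.ndarray:
    """Initial condition at infusion: the imputed dose in each phenotype and
    the baseline metabolic tumor volume (the pre-infusion distribution phase
    is discounted)."""
    d = individual.dose_per_phenotype
    return np.array([d, d, d, d, individual.baseline_mtv])


def solve(
    individual: IndividualParams,
    structural: StructuralParams,
    t_eval,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    expansion_denominator: str = "tcell",
    y0=None,
) -> np.ndarray:
    """Integrate the system and return states at ``t_eval`` (clipped at 0).

    Low-level entry used by both :func:`simulate_patient` and the likelihood
    machinery (which evaluates only at observation times).
    """
    t_eval = np.asarray(t_eval, dtype=float)
    if y0 is None:
        y0 = initial_state(individual)
    rhs = _make_rhs(
        individual.Vmax1_i, individual.Vmax5_i, structural, expansion_denominator
    )
    sol = solve_ivp(
        rhs,
        (0.0, float(t_eval[-1])) if t_eval[-1] > 0 else (0.0, 1e-12),
        y0,
        method=method,
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise SimulationError(
            f"ODE solver failed for patient {individual.patient_id!r}: {sol.message}"
        )
    states = sol.y.T
    worst = states.min()
    if worst < -NEGATIVITY_TOLERANCE:
        raise SimulationError(
            f"solver produced negative state {worst:.3e} for patient "
            f"{individual.patient_id!r}; tighten tolerances"
        )
    return np.clip(states, 0.0, None)


def simulate_patient(
    individual: IndividualParams,
    structural: StructuralParams,
    t_end: float,
    grid_step: float = 0.1,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    expansion_denominator: str = "tcell",
) -> Trajectory:
    """Simulate one patient from infusion (day 0) to ``t_end`` days.

    Initial conditions are the imputed dose per phenotype and the baseline
    tumor volume. A stiff-capable solver is required because the expansion /
    collapse phase is stiff; tiny negative solver excursions are clipped to
    zero in the reported trajectory.
    """
    if t_end <= 0:
        raise ValueError(f"t_end must be positive, got {t_end}")
    n = int(round(t_end / grid_step))
    times = np.linspace(0.0, t_end, n + 1)
    states = solve(
        individual,
        structural,
        times,
        rtol=rtol,
        atol=atol,
        method=method,
        expansion_denominator=expansion_denominator,
    )
    return Trajectory(individual.patient_id, times, states)
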