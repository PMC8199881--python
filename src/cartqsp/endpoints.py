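"""Cell-kinetic metrics, clinical composite score, ROC cut-off, survival.

The clinical composite score (CCS) is the maximum CAR-T cell concentration
of a phenotype divided by the baseline metabolic tumor volume,
(cells·µL⁻¹)·mL⁻¹ — a model-free surrogate for the maximum expansion
capacity that can be computed directly from clinical measurements (it works
unchanged on the qPCR copies·µg⁻¹DNA scale). A ROC analysis over the CCS
yields a cut-off separating low-expansion patients, and survival is
stratified at that cut-off (Kaplan–Meier, log-rank, univariate Cox).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test, pairwise_logrank_test
from scipy.stats import mannwhitneyu, pearsonr
from sklearn.metrics import roc_auc_score, roc_curve

#: Imputed total CAR-T concentration at infusion (four phenotypes × 0.1).
TOTAL_IMPUTED_DOSE = 0.4


@dataclass
class KineticMetrics:
    """Cell-kinetic summary of one patient's total CAR-T concentration curve."""

    cmax: float
    tmax: float
    auc_0_28: float
    cmax_over_mtv: float | None
    basis: str  # "observed" or "model"


@dataclass
class CCSResult:
    score: float
    cutoff: float | None
    exceeds_cutoff: bool | None


@dataclass
class ROCResult:
    cutoff: float
    sensitivity: float
    specificity: float
    auc: float
    criterion: str


@dataclass
class KMGroup:
    label: str
    n: int
    n_events: int
    median: float | None  # None encodes "not reached"
    times: np.ndarray
    survival: np.ndarray


@dataclass
class KMResult:
    groups: list
    statistic: float
    pvalue: float
    pairwise: pd.DataFrame | None = None


@dataclass
class CoxResult:
    hr: float
    ci_low: float
    ci_high: float
    pvalue: float
    ph_pvalue: float | None = None
    separation_flag: bool = False


def kinetic_metrics(
    times,
    concentrations,
    basis: str = "observed",
    baseline_mtv: float | None = None,
    anchor_dose: float = TOTAL_IMPUTED_DOSE,
    horizon: float = 28.0,
) -> KineticMetrics:
    """Cmax, Tmax, and trapezoidal AUC over days 0–28 of a concentration series.

    Observed basis: if the series lacks a day-0 sample, it is anchored at
    the total imputed dose (0.4 cells·µL⁻¹); the AUC uses linear
    interpolation, truncated at day 28. Model basis: the series is assumed
    to be a dense simulation grid and used as-is.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if t.size == 0:
        raise ValueError("empty concentration series")
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if basis == "observed":
        if t[0] > 0.0:
            t = np.concatenate([[0.0], t])
            c = np.concatenate([[anchor_dose], c])
    elif basis != "model":
        raise ValueError(f"basis must be 'observed' or 'model', got {basis!r}")

    imax = int(np.argmax(c))  # earliest index at the maximum
    cmax = float(c[imax])
    tmax = float(t[imax])

    end = min(horizon, float(t[-1]))
    grid = t[t <= end]
    vals = c[: grid.size]
    if end not in grid:
        vals = np.concatenate([vals, [np.interp(end, t, c)]])
        grid = np.concatenate([grid, [end]])
    auc = float(np.trapezoid(vals, grid))
    return KineticMetrics(
        cmax=cmax,
        tmax=tmax,
        auc_0_28=auc,
        cmax_over_mtv=cmax / baseline_mtv if baseline_mtv else None,
        basis=basis,
    )


def ccs(cmax_phenotype: float, baseline_mtv: float, cutoff: float | None = None) -> CCSResult:
    """Clinical composite score: Cmax of a phenotype / baseline tumor volume."""
    if baseline_mtv <= 0:
        raise ValueError(f"baseline_mtv must be positive, got {baseline_mtv}")
    if cmax_phenotype < 0:
        raise ValueError(f"cmax must be non-negative, got {cmax_phenotype}")
    score = cmax_phenotype / baseline_mtv
    return CCSResult(
        score=score,
        cutoff=cutoff,
        exceeds_cutoff=None if cutoff is None else bool(score > cutoff),
    )


def roc_cutoff(scores, labels, criterion: str = "youden") -> ROCResult:
    """Empirical ROC over all candidate thresholds with an optimal cut-off.

    ``labels`` are binary with 1 = positive class; higher scores are assumed
    to indicate the positive class. The default criterion maximizes the
    Youden index (sensitivity + specificity − 1); ties break toward higher
    specificity. AUC is the trapezoidal area under the empirical curve.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("both classes must be present")
    if criterion != "youden":
        raise ValueError(f"unsupported criterion {criterion!r}")
    fpr, tpr, thresholds = roc_curve(labels, scores)
    youden = tpr - fpr
    # ties toward higher specificity = lower fpr; roc_curve orders by
    # decreasing threshold i.e. increasing fpr, so take the first argmax
    best = int(np.argmax(youden))
    auc = float(roc_auc_score(labels, scores))
    return ROCResult(
        cutoff=float(thresholds[best]),
        sensitivity=float(tpr[best]),
        specificity=float(1.0 - fpr[best]),
        auc=auc,
        criterion=criterion,
    )


def km_logrank(
    times, events, groups, alpha: float = 0.05
) -> KMResult:
    """Kaplan–Meier curves per group with a log-rank comparison.

    Medians that the curve never crosses are reported as ``None`` ("not
    reached"). With more than two groups, pairwise log-rank comparisons are
    returned alongside the global test.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    if np.any(times < 0):
        raise ValueError("survival times must be non-negative")
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("at least two groups required")
    out_groups = []
    for lab in labels:
        mask = groups == lab
        if mask.sum() == 0:
            raise ValueError(f"empty group {lab!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        med = kmf.median_survival_time_
        med = None if not math.isfinite(med) else float(med)
        sf = kmf.survival_function_
        out_groups.append(
            KMGroup(
                label=str(lab),
                n=int(mask.sum()),
                n_events=int(events[mask].sum()),
                median=med,
                times=sf.index.to_numpy(dtype=float),
                survival=sf.iloc[:, 0].to_numpy(dtype=float),
            )
        )
    if len(labels) == 2:
        m0 = groups == labels[0]
        res = logrank_test(times[m0], times[~m0], events[m0], events[~m0])
        pairwise = None
        stat, p = float(res.test_statistic), float(res.p_value)
    else:
        from lifelines.statistics import multivariate_logrank_test

        res = multivariate_logrank_test(times, groups, events)
        stat, p = float(res.test_statistic), float(res.p_value)
        pw = pairwise_logrank_test(times, groups, events)
        pairwise = pw.summary
    return KMResult(groups=out_groups, statistic=stat, pvalue=p, pairwise=pairwise)


def cox_hr(times, events, covariate, alpha: float = 0.05) -> CoxResult:
    """Univariate Cox proportional-hazards estimate for a binary covariate.

    Breslow tie handling; Wald confidence interval and p-value; a
    Schoenfeld-residual proportional-hazards test is attached as a
    diagnostic. Monotone-likelihood separation (a group without events)
    is flagged rather than silently reported.
    """
    df = pd.DataFrame(
        {
            "time": np.asarray(times, dtype=float),
            "event": np.asarray(events, dtype=int),
            "x": np.asarray(covariate, dtype=float),
        }
    )
    levels = sorted(df["x"].unique())
    if len(levels) != 2:
        raise ValueError("covariate must be binary with both levels present")
    events_per_level = df.groupby("x")["event"].sum()
    separation = bool((events_per_level == 0).any())
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    summary = cph.summary.loc["x"]
    ph_p = None
    try:
        from lifelines.statistics import proportional_hazard_test

        ph = proportional_hazard_test(cph, df, time_transform="rank")
        ph_p = float(ph.summary["p"].iloc[0])
    except Exception:  # diagnostic only; never fail the estimate
        pass
    return CoxResult(
        hr=float(summary["exp(coef)"]),
        ci_low=float(summary["exp(coef) lower 95%"]),
        ci_high=float(summary["exp(coef) upper 95%"]),
        pvalue=float(summary["p"]),
        ph_pvalue=ph_p,
        separation_flag=separation,
    )


def hr_to_risk_reduction(hr: float) -> int:
    """Percent risk reduction implied by a hazard ratio, (1 − HR)·100, rounded."""
    if hr <= 0:
        raise ValueError(f"hazard ratio must be positive, got {hr}")
    return int(round((1.0 - hr) * 100.0))


def group_compare(values_a, values_b):
    """Two-sided rank-sum (Wilcoxon–Mann–Whitney) comparison of two groups."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    res = mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def pearson_r(x, y, log_scale: bool = False):
    """Pearson correlation, optionally on log10-transformed variables.

    The log scale is used when comparing flow-cytometry against qPCR-based
    composite scores, whose values span orders of magnitude.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least three pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input has undefined correlation")
    if log_scale:
        if np.any(x <= 0) or np.any(y <= 0):
            raise ValueError("log-scale correlation requires positive values")
        x, y = np.log10(x), np.log10(y)
    r, p = pearsonr(x, y)
    return float(r), float(p)


def cohort_ccs_table(cohort, phenotype: str = "TN") -> pd.DataFrame:
    """Observed-basis CCS per patient for one phenotype from a cohort dataset.

    Cmax is the maximum observed concentration of the phenotype across the
    sampled days (day 0 anchored at the imputed per-phenotype dose).
    """
    obs = cohort.observations
    cells = obs[obs["species"] == phenotype]
    rows = []
    for pid, grp in cells.groupby("patient_id"):
        cov = cohort.patient_covariates(pid)
        cmax = max(float(grp["value"].max()), 0.1)  # day-0 imputed dose anchor
        rows.append(
            {
                "patient_id": pid,
                "cmax": cmax,
                "baseline_mtv": cov.baseline_mtv,
                "ccs": cmax / cov.baseline_mtv,
            }
        )
    return pd.DataFrame(rows)
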