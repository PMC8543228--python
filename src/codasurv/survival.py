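"""Per-study compositional Cox regression.

Each study fits a proportional-hazards model whose linear predictor is
built from the ilr balance coordinates of the subject's daily time-use
composition plus ordinary covariates:

    ln h(t; z, v) / h0(t) = gamma' z + beta' v

so ``exp(gamma_j)`` is the hazard ratio for a one-unit increase of the
j-th time balance holding the others fixed.  In a federated design only
the coefficient vector and its variance-covariance matrix leave the
study, never subject-level rows.

Fitting is by partial-likelihood maximisation with Efron tie handling
(delegated to :class:`lifelines.CoxPHFitter`).  A landmark filter that
drops deaths within the first years of follow-up limits
reverse-causation bias, and the proportional-hazards assumption is
checked with the Grambsch-Therneau scaled-Schoenfeld-residual test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import proportional_hazard_test

from codasurv.coda import Composition, IlrVector, ilr_from_matrix

__all__ = [
    "SubjectRecord",
    "Cohort",
    "StudyFit",
    "PHTestResult",
    "landmark_filter",
    "fit_compositional_cox",
    "predict_survival",
    "test_proportional_hazards",
    "ConvergenceError",
]

logger = logging.getLogger(__name__)

ILR_NAMES_4 = ("z1", "z2", "z3")
ILR_NAMES_3 = ("z2", "z3")


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class SubjectRecord:
    id: str
    composition: Composition
    followup: float  # years
    event: int  # 1 = death
    covariates: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.followup <= 0:
            raise ValueError(f"subject {self.id}: follow-up must be positive")
        if self.event not in (0, 1):
            raise ValueError(f"subject {self.id}: event must be 0 or 1")


@dataclass
class Cohort:
    """Subject records plus the study metadata pooling needs."""

    records: List[SubjectRecord]
    study_name: str = "study"
    device_placement: str = "hip"  # {"hip", "wrist"}
    waking_total: float = 960.0

    def __post_init__(self) -> None:
        arities = {r.composition.has_sleep for r in self.records}
        if len(arities) > 1:
            raise ValueError("mixed 3- and 4-part compositions in one cohort")
        if self.device_placement not in ("hip", "wrist"):
            raise ValueError("device_placement must be 'hip' or 'wrist'")

    @property
    def measures_sleep(self) -> bool:
        return bool(self.records) and self.records[0].composition.has_sleep

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def n_events(self) -> int:
        return sum(r.event for r in self.records)

    @property
    def covariate_names(self) -> List[str]:
        return sorted(self.records[0].covariates) if self.records else []

    def to_frame(self) -> pd.DataFrame:
        """Model frame: ilr coordinates, covariates, follow-up and event."""
        comp = np.array([r.composition.parts() for r in self.records])
        z = ilr_from_matrix(comp)
        names = ILR_NAMES_4 if self.measures_sleep else ILR_NAMES_3
        df = pd.DataFrame(z, columns=list(names))
        for name in self.covariate_names:
            df[name] = [r.covariates[name] for r in self.records]
        df["followup"] = [r.followup for r in self.records]
        df["event"] = [r.event for r in self.records]
        df.index = pd.Index([r.id for r in self.records], name="id")
        return df


@dataclass
class StudyFit:
    """Coefficients and covariance a study shares for pooling.

    ``gamma`` holds the ilr coefficients keyed z1/z2/z3 (z1 absent for
    waking-only studies), ``beta`` the covariate coefficients.
    ``vcov_gamma`` is ordered like ``gamma_names``.
    """

    study_name: str
    gamma: Dict[str, float]
    beta: Dict[str, float]
    vcov_gamma: np.ndarray
    n: int
    n_events: int
    measures_sleep: bool
    device_placement: str = "hip"
    baseline_cumhaz: Optional[pd.Series] = None  # Breslow estimate at lp=0

    def __post_init__(self) -> None:
        v = np.asarray(self.vcov_gamma, float)
        if v.shape != (len(self.gamma),) * 2:
            raise ValueError("vcov_gamma shape does not match gamma")
        if not np.allclose(v, v.T, atol=1e-8):
            raise ValueError("vcov_gamma must be symmetric")
        if np.any(np.linalg.eigvalsh((v + v.T) / 2) < -1e-8):
            raise ValueError("vcov_gamma must be positive semi-definite")
        self.vcov_gamma = (v + v.T) / 2

    @property
    def gamma_names(self) -> List[str]:
        return [n for n in ILR_NAMES_4 if n in self.gamma]

    def gamma_vector(self) -> np.ndarray:
        return np.array([self.gamma[n] for n in self.gamma_names])


@dataclass(frozen=True)
class PHTestResult:
    per_coefficient: pd.DataFrame  # columns: statistic, p
    global_statistic: float
    global_p: float
    df: int


def landmark_filter(cohort: Cohort, cutoff: float = 2.0, drop_all_early: bool = False) -> Cohort:
    """Exclude deaths within the first ``cutoff`` years of follow-up.

    By default only early deaths are removed; subjects censored before the
    landmark are retained.  ``drop_all_early`` removes every subject with
    follow-up below the cutoff instead.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    if drop_all_early:
        kept = [r for r in cohort.records if r.followup >= cutoff]
    else:
        kept = [r for r in cohort.records if not (r.event == 1 and r.followup < cutoff)]
    removed = cohort.n - len(kept)
    if removed:
        logger.info("landmark filter (%g y): removed %d of %d subjects", cutoff, removed, cohort.n)
    out = replace(cohort, records=kept)
    if out.n_events == 0 and cohort.n_events > 0:
        raise ValueError(f"landmark cutoff {cutoff} y removed every event")
    return out


def fit_compositional_cox(
    cohort: Cohort,
    landmark_years: Optional[float] = None,
    penalizer: float = 0.0,
) -> StudyFit:
    """Fit the compositional Cox model by partial-likelihood maximisation.

    Ties use the Efron approximation.  The returned variance-covariance
    matrix is the inverse observed information restricted to the ilr
    coefficients.  Raises :class:`ConvergenceError` on failure and warns
    on near-degenerate (separated / collinear) predictors.
    """
    if landmark_years is not None:
        cohort = landmark_filter(cohort, landmark_years)
    if cohort.n_events < 2:
        raise ValueError("at least 2 events are required to fit")
    df = cohort.to_frame()
    pred_cols = [c for c in df.columns if c not in ("followup", "event")]
    variances = df[pred_cols].var()
    degenerate = variances[variances < 1e-12]
    if not degenerate.empty:
        warnings.warn(
            "no variation in predictor(s) "
            f"{list(degenerate.index)}; coefficients are unidentifiable"
        )
    cph = CoxPHFitter(penalizer=penalizer)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # lifelines re-warns on low variance
            cph.fit(df, duration_col="followup", event_col="event")
    except Exception as exc:  # lifelines raises ConvergenceError/ValueError
        raise ConvergenceError(f"Cox fit failed for {cohort.study_name}: {exc}") from exc

    se = cph.standard_errors_
    big = se[se > 100].index.tolist()
    if big:
        warnings.warn(f"possible separation / monotone likelihood in {big}")

    names = list(ILR_NAMES_4 if cohort.measures_sleep else ILR_NAMES_3)
    params = cph.params_
    vcov = cph.variance_matrix_
    gamma = {k: float(params[k]) for k in names}
    beta = {k: float(params[k]) for k in params.index if k not in names}
    vg = vcov.loc[names, names].to_numpy()
    baseline = cph.baseline_cumulative_hazard_["baseline cumulative hazard"]
    return StudyFit(
        study_name=cohort.study_name,
        gamma=gamma,
        beta=beta,
        vcov_gamma=vg,
        n=cohort.n,
        n_events=cohort.n_events,
        measures_sleep=cohort.measures_sleep,
        device_placement=cohort.device_placement,
        baseline_cumhaz=baseline,
    )


def predict_survival(
    fit: StudyFit,
    z: IlrVector,
    covariates: Optional[Dict[str, float]] = None,
    t: float | np.ndarray = 0.0,
) -> np.ndarray | float:
    """Survival probability S(t) = exp(-H0(t) * exp(gamma'z + beta'v)).

    ``H0`` is the Breslow baseline cumulative hazard stored on the fit
    (step function, evaluated by last-value interpolation).  Warns when
    ``t`` exceeds the observed follow-up range.
    """
    if fit.baseline_cumhaz is None:
        raise ValueError("fit carries no baseline cumulative hazard")
    t_arr = np.atleast_1d(np.asarray(t, float))
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    times = fit.baseline_cumhaz.index.to_numpy(float)
    if np.any(t_arr > times.max()):
        warnings.warn(f"t beyond observed follow-up range ({times.max():.3g} y); extrapolating")
    h0 = np.concatenate([[0.0], fit.baseline_cumhaz.to_numpy(float)])
    idx = np.searchsorted(times, t_arr, side="right")
    lp = float(np.dot(fit.gamma_vector(), z.values()))
    for name, value in (covariates or {}).items():
        lp += fit.beta[name] * value
    s = np.exp(-h0[idx] * np.exp(lp))
    return float(s[0]) if np.isscalar(t) or np.ndim(t) == 0 else s


def test_proportional_hazards(fit_df: pd.DataFrame, time_transform: str = "km") -> PHTestResult:
    """Grambsch-Therneau test on scaled Schoenfeld residuals.

    ``fit_df`` is the model frame from :meth:`Cohort.to_frame`.  Returns
    per-coefficient score tests (via lifelines) and the global statistic

        T = u' (d V) u / sum_k (g_k - gbar)^2,   u = sum_k (g_k - gbar) s_k

    where ``s_k`` are Schoenfeld residuals at the d event times, ``g`` the
    (Kaplan-Meier transformed) event times and ``V`` the coefficient
    covariance; T is chi-square with p degrees of freedom under
    proportional hazards.
    """
    if fit_df["event"].sum() < 2:
        raise ValueError("at least 2 events are required for the PH test")
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(fit_df, duration_col="followup", event_col="event")
    res = proportional_hazard_test(cph, fit_df, time_transform=time_transform)
    per = res.summary[["test_statistic", "p"]].rename(columns={"test_statistic": "statistic"})
    per.index = per.index.get_level_values(0)

    # global statistic from unscaled Schoenfeld residuals
    sch = cph.compute_residuals(fit_df, kind="schoenfeld")
    event_times = fit_df.loc[sch.index, "followup"].to_numpy(float)
    order = np.argsort(event_times, kind="stable")
    sch_mat = sch.to_numpy(float)[order]
    times = event_times[order]
    if time_transform == "km":
        km = KaplanMeierFitter().fit(fit_df["followup"], fit_df["event"])
        surv = km.survival_function_["KM_estimate"]
        # left-continuous KM at the event time
        g = 1.0 - np.asarray(
            [surv[surv.index < t].iloc[-1] if (surv.index < t).any() else 1.0 for t in times]
        )
    elif time_transform == "rank":
        g = np.argsort(np.argsort(times)).astype(float)
    else:
        g = times.copy()
    g -= g.mean()
    d = len(times)
    u = g @ sch_mat
    vcov = cph.variance_matrix_.loc[sch.columns, sch.columns].to_numpy(float)
    denom = float(np.sum(g**2))
    t_global = float(u @ (d * vcov) @ u / denom)
    p_global = float(1.0 - _chi2_cdf(t_global, sch_mat.shape[1]))
    return PHTestResult(
        per_coefficient=per, global_statistic=t_global, global_p=p_global, df=sch_mat.shape[1]
    )


def _chi2_cdf(x: float, df: int) -> float:
    from scipy.stats import chi2

    return chi2.cdf(x, df)
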