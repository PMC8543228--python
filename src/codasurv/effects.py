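"""Compositional effect estimation from a pooled model.

Because the Cox linear predictor is linear in the ilr coordinates, the
hazard ratio between any two compositions depends only on the difference
of their coordinates:

    HR(comp, ref) = exp( gamma' (z(comp) - z(ref)) )

with a Wald confidence interval from the pooled coefficient covariance
(the log-HR is exactly linear in the coefficients, so no delta-method
approximation is involved; compositions are treated as fixed).  On top of
this single identity the module builds

* unit hazard ratios per balance coordinate (exp of each coefficient),
* data-driven reference compositions on a Mahalanobis contour of the
  fitted ilr-normal distribution,
* dose-response curves that reallocate time into one behaviour while the
  remaining behaviours keep the reference's mutual ratios (or with
  sedentary time held fixed),
* isotime heat maps over an (MVPA, SB) grid of the waking day, and
* minutes-of-substitution solving: the time that must move from
  sedentary behaviour into (M)VPA or LIPA to reach a target hazard ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from codasurv.coda import (
    Composition,
    IlrVector,
    ilr_forward,
    ilr_inverse,
)
from codasurv.pooling import PooledModel

__all__ = [
    "ReferenceComposition",
    "EffectCurve",
    "EffectSurface",
    "hazard_ratio",
    "unit_hazard_ratios",
    "select_reference",
    "dose_response",
    "joint_heatmap",
    "solve_reallocation",
    "SubstitutionResult",
]

Z_975 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class ReferenceComposition:
    """A reference composition chosen on a Mahalanobis contour in ilr space."""

    composition: Composition
    ilr_mean: np.ndarray
    ilr_cov: np.ndarray
    coverage: float


@dataclass
class EffectCurve:
    """Hazard ratios (with 95% CI) along a reallocation grid."""

    focal: str
    grid: np.ndarray  # minutes of the focal behaviour
    compositions: List[Optional[Composition]]
    hr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    reference: Composition

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {self.focal: self.grid, "hr": self.hr, "ci_low": self.ci_low, "ci_high": self.ci_high}
        )


@dataclass
class EffectSurface:
    """HR over an (MVPA, SB) grid of the waking day; LIPA is the remainder."""

    mvpa_grid: np.ndarray
    sb_grid: np.ndarray
    hr: np.ndarray  # shape (len(sb_grid), len(mvpa_grid))
    ci_low: np.ndarray
    ci_high: np.ndarray
    feasible: np.ndarray  # bool mask, False where implied LIPA <= 0
    reference: Composition
    waking_total: float

    def to_frame(self) -> pd.DataFrame:
        m, s = np.meshgrid(self.mvpa_grid, self.sb_grid)
        df = pd.DataFrame(
            {
                "mvpa": m.ravel(),
                "sb": s.ravel(),
                "lipa": self.waking_total - m.ravel() - s.ravel(),
                "hr": self.hr.ravel(),
                "ci_low": self.ci_low.ravel(),
                "ci_high": self.ci_high.ravel(),
                "feasible": self.feasible.ravel(),
            }
        )
        return df


def _model_coords(model: PooledModel, comp: Composition) -> np.ndarray:
    z = ilr_forward(comp)
    names = model.gamma_names
    if "z1" in names and not comp.has_sleep:
        raise ValueError(
            "model includes the sleep balance z1 but the composition has no sleep part"
        )
    if "z1" not in names and comp.has_sleep:
        raise ValueError(
            "waking-day model cannot evaluate a sleep-including composition; "
            "use the waking subcomposition"
        )
    return z.values()


def hazard_ratio(
    model: PooledModel, comp: Composition, ref: Composition
) -> Dict[str, float]:
    """HR of ``comp`` versus ``ref`` with a 95% Wald CI.

    Both compositions must share arity and total; the CI uses
    var(log HR) = dz' V dz with dz the ilr difference and V the pooled
    coefficient covariance.
    """
    if comp.has_sleep != ref.has_sleep:
        raise ValueError("composition and reference must share arity")
    if abs(comp.total - ref.total) > 1e-6 * ref.total:
        raise ValueError("composition and reference must share the same total")
    dz = _model_coords(model, comp) - _model_coords(model, ref)
    log_hr = float(model.gamma_vector() @ dz)
    se = float(np.sqrt(max(dz @ model.vcov_gamma @ dz, 0.0)))
    return {
        "hr": float(np.exp(log_hr)),
        "ci_low": float(np.exp(log_hr - Z_975 * se)),
        "ci_high": float(np.exp(log_hr + Z_975 * se)),
        "log_hr": log_hr,
        "se_log_hr": se,
    }


def unit_hazard_ratios(model: PooledModel) -> pd.DataFrame:
    """Per-coordinate HR for a one-unit balance increase, with Wald p and CI."""
    rows = []
    v = np.diag(model.vcov_gamma)
    for j, name in enumerate(model.gamma_names):
        g = model.gamma[name]
        se = float(np.sqrt(v[j]))
        z = g / se if se > 0 else np.inf
        rows.append(
            {
                "coordinate": name,
                "coefficient": g,
                "hr": float(np.exp(g)),
                "se": se,
                "p": float(2 * stats.norm.sf(abs(z))),
                "ci_low": float(np.exp(g - Z_975 * se)),
                "ci_high": float(np.exp(g + Z_975 * se)),
            }
        )
    return pd.DataFrame(rows).set_index("coordinate")


def select_reference(
    ilr_samples: np.ndarray,
    coverage: float = 0.75,
    direction: Sequence[float] = (-1.0, -1.0),
    total: float = 960.0,
) -> ReferenceComposition:
    """Reference composition on a Mahalanobis contour of the ilr cloud.

    A normal distribution is fitted to the observed (z2, z3) samples; the
    returned composition is the inverse ilr of

        mu + r * Sigma^(1/2) * u,   r^2 = chi2_{2}^{-1}(coverage)

    with ``u`` the normalised ``direction``.  The default direction
    (-1, -1) targets compositions low in both the MVPA balance and the
    LIPA-vs-SB balance while staying in a region supported by the data.
    """
    z = np.asarray(ilr_samples, float)
    if z.ndim != 2 or z.shape[0] < 10:
        raise ValueError("need at least 10 ilr samples (rows)")
    u = np.asarray(direction, float)
    if np.allclose(u, 0):
        raise ValueError("direction must be a nonzero vector")
    u = u / np.linalg.norm(u)
    mu = z.mean(axis=0)
    sigma = np.cov(z, rowvar=False)
    if np.linalg.matrix_rank(sigma, tol=1e-12) < sigma.shape[0]:
        raise ValueError("singular ilr covariance; cannot place a contour")
    r = float(np.sqrt(stats.chi2.ppf(coverage, df=z.shape[1])))
    root = np.real(linalg.sqrtm(sigma))
    point = mu + r * root @ u
    d2 = float((point - mu) @ np.linalg.solve(sigma, point - mu))
    assert abs(d2 - r**2) < 1e-6 * max(1.0, r**2)
    comp = ilr_inverse(_ilr_from_point(point), total)
    return ReferenceComposition(
        composition=comp, ilr_mean=mu, ilr_cov=sigma, coverage=coverage
    )


def _ilr_from_point(point: np.ndarray) -> IlrVector:
    if len(point) == 2:
        return IlrVector(z2=point[0], z3=point[1])
    return IlrVector(z1=point[0], z2=point[1], z3=point[2])


def _rescale_remainder(ref: Composition, focal: str, value: float) -> Optional[Composition]:
    """Set focal part to ``value``; others keep the reference's mutual ratios."""
    names = list(ref.part_names)
    parts = dict(zip(names, ref.parts()))
    remainder = ref.total - value
    others_sum = sum(v for k, v in parts.items() if k != focal)
    if value <= 0 or remainder <= 0:
        return None
    scale = remainder / others_sum
    new = {k: (value if k == focal else v * scale) for k, v in parts.items()}
    return Composition(total=ref.total, **new)


def _fixed_sb_composition(ref: Composition, focal: str, value: float, sb: float) -> Optional[Composition]:
    """Two-behaviour mode: SB fixed, LIPA absorbs the remainder."""
    if focal not in ("mvpa",):
        raise ValueError("fixed-SB mode reallocates MVPA against LIPA")
    lipa = ref.total - (ref.sleep or 0.0) - sb - value
    if value <= 0 or lipa <= 0 or sb <= 0:
        return None
    kwargs = {"mvpa": value, "lipa": lipa, "sb": sb, "total": ref.total}
    if ref.has_sleep:
        kwargs["sleep"] = ref.sleep
    return Composition(**kwargs)


def dose_response(
    model: PooledModel,
    ref: Composition,
    focal: str,
    grid: Sequence[float],
    fixed_sb: Optional[float] = None,
) -> EffectCurve:
    """HR curve as time is reallocated into the focal behaviour.

    For each grid value the comparison composition sets the focal
    behaviour to that duration and rescales the remaining behaviours to
    keep their mutual ratios equal to the reference's; with ``fixed_sb``
    sedentary time is pinned and LIPA absorbs the remainder instead.
    Grid values forcing a non-positive part are masked (NaN) with a
    warning.
    """
    if focal not in ref.part_names:
        raise ValueError(f"focal behaviour {focal!r} not in composition parts {ref.part_names}")
    grid = np.asarray(grid, float)
    comps: List[Optional[Composition]] = []
    for value in grid:
        if fixed_sb is not None:
            comps.append(_fixed_sb_composition(ref, focal, value, fixed_sb))
        else:
            comps.append(_rescale_remainder(ref, focal, value))
    if any(c is None for c in comps):
        warnings.warn("grid values forcing a non-positive part were masked")
    hr = np.full(len(grid), np.nan)
    lo = np.full(len(grid), np.nan)
    hi = np.full(len(grid), np.nan)
    for i, c in enumerate(comps):
        if c is None:
            continue
        res = hazard_ratio(model, c, ref)
        hr[i], lo[i], hi[i] = res["hr"], res["ci_low"], res["ci_high"]
    return EffectCurve(
        focal=focal, grid=grid, compositions=comps, hr=hr, ci_low=lo, ci_high=hi, reference=ref
    )


def joint_heatmap(
    model: PooledModel,
    ref: Composition,
    mvpa_grid: Optional[Sequence[float]] = None,
    sb_grid: Optional[Sequence[float]] = None,
    waking_total: float = 960.0,
) -> EffectSurface:
    """HR surface over the waking day with LIPA as the implied remainder.

    Cell (m, s) is the waking composition (MVPA=m, SB=s,
    LIPA=waking_total-m-s); cells with non-positive implied LIPA are
    masked infeasible.  Default grids: MVPA 0-120 min step 1 (starting at
    1 min since MVPA=0 is not a valid log-ratio input), SB 420-900 min
    step 5.
    """
    if ref.has_sleep:
        ref = ref.waking()
    mvpa_grid = np.arange(1.0, 121.0) if mvpa_grid is None else np.asarray(mvpa_grid, float)
    sb_grid = np.arange(420.0, 901.0, 5.0) if sb_grid is None else np.asarray(sb_grid, float)
    if np.any(mvpa_grid <= 0) or np.any(sb_grid <= 0):
        raise ValueError("grids must be strictly positive minutes")
    n_s, n_m = len(sb_grid), len(mvpa_grid)
    hr = np.full((n_s, n_m), np.nan)
    lo = np.full((n_s, n_m), np.nan)
    hi = np.full((n_s, n_m), np.nan)
    m_mesh, s_mesh = np.meshgrid(mvpa_grid, sb_grid)
    lipa = waking_total - m_mesh - s_mesh
    feasible = lipa > 0
    if not feasible.any():
        raise ValueError("every grid cell implies non-positive LIPA")
    # vectorised Eq-6 evaluation over the feasible cells
    gamma = model.gamma_vector()
    if len(gamma) != 2:
        raise ValueError("heat maps are defined for waking-day (z2, z3) models")
    z_ref = _model_coords(model, ref)
    m_f, s_f, l_f = m_mesh[feasible], s_mesh[feasible], lipa[feasible]
    z2 = np.sqrt(2.0 / 3.0) * np.log(m_f / np.sqrt(l_f * s_f))
    z3 = np.sqrt(1.0 / 2.0) * np.log(l_f / s_f)
    dz = np.stack([z2 - z_ref[0], z3 - z_ref[1]], axis=1)
    log_hr = dz @ gamma
    se = np.sqrt(np.clip(np.einsum("ij,jk,ik->i", dz, model.vcov_gamma, dz), 0.0, None))
    hr[feasible] = np.exp(log_hr)
    lo[feasible] = np.exp(log_hr - Z_975 * se)
    hi[feasible] = np.exp(log_hr + Z_975 * se)
    return EffectSurface(
        mvpa_grid=mvpa_grid,
        sb_grid=sb_grid,
        hr=hr,
        ci_low=lo,
        ci_high=hi,
        feasible=feasible,
        reference=ref,
        waking_total=waking_total,
    )


@dataclass(frozen=True)
class SubstitutionResult:
    """Minutes moved out of SB to reach a target HR, with CI in minutes."""

    minutes: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    target_hr: float
    mode: str
    attained_infimum: Optional[float] = None  # smallest HR reachable if no solution

    @property
    def minutes_rounded(self) -> Optional[int]:
        return None if self.minutes is None else int(round(self.minutes))


def _substitution_hr(model, ref: Composition, delta: float, mode: str, which: str) -> float:
    if mode == "mvpa_for_sb":
        comp = Composition(
            mvpa=ref.mvpa + delta, lipa=ref.lipa, sb=ref.sb - delta,
            sleep=ref.sleep, total=ref.total,
        )
    elif mode == "lipa_for_sb":
        comp = Composition(
            mvpa=ref.mvpa, lipa=ref.lipa + delta, sb=ref.sb - delta,
            sleep=ref.sleep, total=ref.total,
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return hazard_ratio(model, comp, ref)[which]


def solve_reallocation(
    model: PooledModel,
    ref: Composition,
    target_hr: float = 0.90,
    mode: str = "mvpa_for_sb",
    tol_minutes: float = 1e-7,
) -> SubstitutionResult:
    """Minutes of SB that must move into MVPA (or LIPA) for a target HR.

    Solves HR(delta) = target on delta in (0, SB_ref - 1) by bracketed
    root search (brentq, resolved far below the reporting precision of a
    minute so the round trip through :func:`hazard_ratio` reproduces the
    target to ~1e-6 HR units); the CI bounds in minutes solve the same
    equation on the upper and lower Wald HR-bound curves.  If a curve
    never crosses the target within the feasible range the corresponding
    entry is None and the attained infimum is reported.
    """
    if not (0 < target_hr <= 1):
        raise ValueError("target_hr must be in (0, 1]")
    if target_hr == 1.0:
        return SubstitutionResult(0.0, 0.0, 0.0, target_hr, mode)
    d_max = ref.sb - 1.0
    if d_max <= 0:
        raise ValueError("reference SB leaves no room to reallocate")

    def solve_on(which: str) -> Tuple[Optional[float], Optional[float]]:
        f = lambda d: _substitution_hr(model, ref, d, mode, which) - target_hr
        f_hi = f(d_max)
        if f(1e-9) <= 0:
            return 0.0, None
        if f_hi > 0:  # never reaches the target
            return None, target_hr + f_hi
        return float(optimize.brentq(f, 1e-9, d_max, xtol=tol_minutes)), None

    minutes, inf_pt = solve_on("hr")
    ci_low, _ = solve_on("ci_low")  # lower HR bound crosses the target soonest
    ci_high, _ = solve_on("ci_high")
    return SubstitutionResult(
        minutes=minutes,
        ci_low=ci_low,
        ci_high=ci_high,
        target_hr=target_hr,
        mode=mode,
        attained_infimum=inf_pt,
    )
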