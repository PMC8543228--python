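"""Federated multivariate random-effects pooling of study fits.

Studies exchange only coefficient vectors and covariance matrices.  The
pooled model

    theta_i ~ N(mu, S_i + Psi)

allows the true ilr coefficients to vary between studies with covariance
``Psi`` (between-study heterogeneity); the pooled mean is the
generalised-least-squares combination with weights (S_i + Psi)^-1.  Psi
is estimated by REML over a log-Cholesky parameterisation, with a
per-coordinate DerSimonian-Laird method-of-moments fallback.

Waking-only studies carry no sleep balance: before pooling, their z1
coefficient is set to zero with an arbitrarily large variance
(``mask_missing_sleep``) so they receive negligible weight in the sleep
coordinate while still informing z2 and z3.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import optimize, stats

from codasurv.survival import StudyFit, ILR_NAMES_4

__all__ = [
    "PooledModel",
    "mask_missing_sleep",
    "pool_random_effects",
    "heterogeneity_stats",
    "leave_one_out",
    "DEFAULT_MASK_VARIANCE",
]

logger = logging.getLogger(__name__)

DEFAULT_MASK_VARIANCE = 1e6


@dataclass
class PooledModel:
    """Pooled ilr coefficients with between-study covariance and heterogeneity."""

    gamma: Dict[str, float]
    vcov_gamma: np.ndarray  # covariance of the pooled mean
    psi: np.ndarray  # between-study covariance
    k_studies: int
    stratum: str = "all"
    heterogeneity: Dict[str, Dict[str, float]] = field(default_factory=dict)
    study_names: List[str] = field(default_factory=list)
    method: str = "reml"

    def __post_init__(self) -> None:
        for name, m in (("vcov_gamma", self.vcov_gamma), ("psi", self.psi)):
            arr = np.asarray(m, float)
            if not np.allclose(arr, arr.T, atol=1e-8):
                raise ValueError(f"{name} must be symmetric")
            if np.any(np.linalg.eigvalsh((arr + arr.T) / 2) < -1e-8):
                raise ValueError(f"{name} must be positive semi-definite")
        self.vcov_gamma = np.asarray(self.vcov_gamma, float)
        self.psi = np.asarray(self.psi, float)

    @property
    def gamma_names(self) -> List[str]:
        return [n for n in ILR_NAMES_4 if n in self.gamma]

    def gamma_vector(self) -> np.ndarray:
        return np.array([self.gamma[n] for n in self.gamma_names])


def mask_missing_sleep(fit: StudyFit, mask_variance: float = DEFAULT_MASK_VARIANCE) -> StudyFit:
    """Extend a waking-only fit to the 3-coordinate system with a masked z1.

    The z1 coefficient is set to zero and its variance to ``mask_variance``
    (cross-covariances zero), so the study contributes essentially nothing
    to the pooled sleep balance while its z2/z3 information is kept intact.
    """
    if fit.measures_sleep:
        raise ValueError(f"{fit.study_name} measures sleep; masking would discard its z1")
    if "z1" in fit.gamma:
        raise ValueError(f"{fit.study_name} already has a z1 coordinate")
    gamma = {"z1": 0.0, **fit.gamma}
    k = len(fit.gamma)
    v = np.zeros((k + 1, k + 1))
    v[0, 0] = mask_variance
    v[1:, 1:] = fit.vcov_gamma
    return StudyFit(
        study_name=fit.study_name,
        gamma=gamma,
        beta=fit.beta,
        vcov_gamma=v,
        n=fit.n,
        n_events=fit.n_events,
        measures_sleep=False,
        device_placement=fit.device_placement,
        baseline_cumhaz=fit.baseline_cumhaz,
    )


def _align(fits: Sequence[StudyFit], mask_variance: float):
    """Common-coordinate arrays (y_i, S_i); waking-only fits are masked if needed."""
    any_sleep = any("z1" in f.gamma for f in fits)
    aligned = []
    for f in fits:
        if any_sleep and "z1" not in f.gamma:
            f = mask_missing_sleep(f, mask_variance)
        aligned.append(f)
    names = aligned[0].gamma_names
    if any(f.gamma_names != names for f in aligned):
        raise ValueError("fits are not on a common coordinate system")
    y = np.array([f.gamma_vector() for f in aligned])
    s = np.array([f.vcov_gamma for f in aligned])
    return aligned, names, y, s


def _psd_project(m: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh((m + m.T) / 2)
    return (vecs * np.clip(vals, 0.0, None)) @ vecs.T


def _gls_mean(y: np.ndarray, s: np.ndarray, psi: np.ndarray):
    w = np.array([np.linalg.inv(si + psi) for si in s])
    wsum = w.sum(axis=0)
    try:
        wsum_inv = np.linalg.inv(wsum)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular total weight matrix") from exc
    mu = wsum_inv @ np.einsum("kij,kj->i", w, y)
    return mu, wsum_inv, w


def _reml_nll(params: np.ndarray, y: np.ndarray, s: np.ndarray, p: int) -> float:
    l_mat = np.zeros((p, p))
    tril = np.tril_indices(p)
    l_mat[tril] = params
    l_mat[np.diag_indices(p)] = np.exp(np.clip(np.diag(l_mat), -30, 10))
    psi = l_mat @ l_mat.T
    try:
        mu, wsum_inv, w = _gls_mean(y, s, psi)
    except ValueError:
        return 1e10
    nll = 0.0
    for yi, si, wi in zip(y, s, w):
        sign, logdet = np.linalg.slogdet(si + psi)
        if sign <= 0:
            return 1e10
        r = yi - mu
        nll += 0.5 * (logdet + r @ wi @ r)
    sign, logdet = np.linalg.slogdet(np.linalg.inv(wsum_inv))
    if sign <= 0:
        return 1e10
    nll += 0.5 * logdet
    return float(nll)


def _estimate_psi_reml(y: np.ndarray, s: np.ndarray) -> np.ndarray:
    p = y.shape[1]
    n_par = p * (p + 1) // 2
    # start from the (diagonal) method-of-moments estimate
    psi0 = _psi_mm(y, s)
    diag0 = np.sqrt(np.clip(np.diag(psi0), 1e-8, None))
    x0 = np.zeros(n_par)
    l0 = np.zeros((p, p))
    l0[np.diag_indices(p)] = np.log(diag0)
    x0[:] = l0[np.tril_indices(p)]
    alt = np.zeros(n_par)
    alt_l = np.zeros((p, p))
    alt_l[np.diag_indices(p)] = -3.0  # small Psi start (sd ~ 0.05)
    alt[:] = alt_l[np.tril_indices(p)]
    best = None
    for start in (x0, alt):
        res = optimize.minimize(
            _reml_nll, start, args=(y, s, p), method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-9},
        )
        if best is None or res.fun < best.fun:
            best = res
    l_mat = np.zeros((p, p))
    l_mat[np.tril_indices(p)] = best.x
    l_mat[np.diag_indices(p)] = np.exp(np.clip(np.diag(l_mat), -30, 10))
    return _psd_project(l_mat @ l_mat.T)


def _psi_mm(y: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Per-coordinate DerSimonian-Laird tau^2; off-diagonals zero."""
    k, p = y.shape
    tau2 = np.zeros(p)
    for j in range(p):
        w = 1.0 / s[:, j, j]
        theta_fe = np.sum(w * y[:, j]) / np.sum(w)
        q = np.sum(w * (y[:, j] - theta_fe) ** 2)
        c = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2[j] = max(0.0, (q - (k - 1)) / c) if c > 0 else 0.0
    return np.diag(tau2)


def pool_random_effects(
    fits: Sequence[StudyFit],
    method: str = "reml",
    stratum: str = "all",
    mask_variance: float = DEFAULT_MASK_VARIANCE,
) -> PooledModel:
    """Multivariate random-effects pooling of study coefficient fits.

    With ``Psi = 0`` this reduces to the fixed-effect inverse-variance
    estimate; ``method`` selects the Psi estimator ("reml", "mm" or
    "fixed").  A single fit is passed through with Psi = 0 and a warning.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to pool")
    if len(fits) == 1:
        warnings.warn("only one study: returning it unpooled with Psi=0")
        f = fits[0]
        p = len(f.gamma)
        return PooledModel(
            gamma=dict(f.gamma), vcov_gamma=f.vcov_gamma.copy(), psi=np.zeros((p, p)),
            k_studies=1, stratum=stratum, study_names=[f.study_name], method=method,
        )
    aligned, names, y, s = _align(fits, mask_variance)
    if method == "fixed":
        psi = np.zeros((y.shape[1],) * 2)
    elif method == "mm":
        psi = _psi_mm(y, s)
    elif method == "reml":
        psi = _estimate_psi_reml(y, s)
    else:
        raise ValueError(f"unknown method {method!r}")
    try:
        mu, wsum_inv, _ = _gls_mean(y, s, psi)
    except ValueError as exc:
        worst = max(fits, key=lambda f: np.linalg.cond(f.vcov_gamma))
        raise ValueError(f"singular weight matrix (check study {worst.study_name})") from exc
    het = heterogeneity_stats(aligned, mask_variance=mask_variance)
    return PooledModel(
        gamma={n: float(v) for n, v in zip(names, mu)},
        vcov_gamma=wsum_inv,
        psi=psi,
        k_studies=len(fits),
        stratum=stratum,
        heterogeneity=het,
        study_names=[f.study_name for f in fits],
        method=method,
    )


def heterogeneity_stats(
    fits: Sequence[StudyFit],
    mask_variance: float = DEFAULT_MASK_VARIANCE,
) -> Dict[str, Dict[str, float]]:
    """Cochran's Q, its p-value and I^2 per ilr coordinate.

    Fixed-effect weights 1/var are used; Q ~ chi-square(k-1) under
    homogeneity and I^2 = max(0, (Q - df) / Q) * 100.  Studies whose
    coordinate is masked (variance >= mask_variance) are excluded from
    that coordinate's statistics.
    """
    fits = list(fits)
    if len(fits) < 2:
        raise ValueError("heterogeneity statistics need at least 2 fits")
    aligned, names, y, s = _align(fits, mask_variance)
    out: Dict[str, Dict[str, float]] = {}
    for j, name in enumerate(names):
        keep = s[:, j, j] < mask_variance * 0.999
        yj, vj = y[keep, j], s[keep, j, j]
        if keep.sum() < 2:
            out[name] = {"Q": np.nan, "df": float(max(keep.sum() - 1, 0)), "p": np.nan, "I2": np.nan}
            continue
        w = 1.0 / vj
        theta_fe = np.sum(w * yj) / np.sum(w)
        q = float(np.sum(w * (yj - theta_fe) ** 2))
        df = int(keep.sum() - 1)
        p = float(stats.chi2.sf(q, df))
        i2 = float(max(0.0, (q - df) / q) * 100.0) if q > 0 else 0.0
        out[name] = {"Q": q, "df": float(df), "p": p, "I2": i2}
    return out


def leave_one_out(
    fits: Sequence[StudyFit],
    method: str = "reml",
    include_strata: bool = True,
    mask_variance: float = DEFAULT_MASK_VARIANCE,
) -> Dict[str, PooledModel]:
    """Sensitivity pools: each study omitted in turn, plus placement strata.

    Returns a mapping from label ("without:<study>", "wrist", "hip") to the
    corresponding pooled model.  A stratum with a single study is passed
    through with a warning rather than dropped.
    """
    fits = list(fits)
    if len(fits) < 3:
        raise ValueError("leave-one-out needs at least 3 fits")
    out: Dict[str, PooledModel] = {}
    for f in fits:
        rest = [g for g in fits if g is not f]
        out[f"without:{f.study_name}"] = pool_random_effects(
            rest, method=method, stratum=f"without:{f.study_name}", mask_variance=mask_variance
        )
    if include_strata:
        for placement in ("wrist", "hip"):
            sub = [f for f in fits if f.device_placement == placement]
            if not sub:
                continue
            out[placement] = pool_random_effects(
                sub, method=method, stratum=placement, mask_variance=mask_variance
            )
    return out
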