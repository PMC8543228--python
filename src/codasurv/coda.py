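"""Composition algebra for daily movement behaviours.

A day is treated as a composition of time spent in sleep, sedentary
behaviour (SB), light physical activity (LIPA) and moderate-to-vigorous
physical activity (MVPA).  Only the relative information matters, so
compositions are closed to a constant total (1440 min for the full day,
typically 960 min for the waking day) and analysed through isometric
log-ratio (ilr) balance coordinates:

    z1 = sqrt(3/4) * ln( Sleep / (MVPA * LIPA * SB)^(1/3) )
    z2 = sqrt(2/3) * ln( MVPA  / (LIPA * SB)^(1/2) )
    z3 = sqrt(1/2) * ln( LIPA  / SB )

z1 contrasts sleep against the geometric mean of the waking behaviours
and is only defined when sleep was measured; z2 and z3 are identical
whether computed from the 4-part day or from the waking 3-part
subcomposition (subcompositional coherence), which is what makes pooling
of sleep-measuring and waking-only studies possible.

Internal part order is fixed as (Sleep, MVPA, LIPA, SB); the waking
subcomposition drops the leading Sleep column.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "Composition",
    "IlrVector",
    "DetectionLimits",
    "PART_NAMES",
    "WAKING_PART_NAMES",
    "ilr_basis",
    "close",
    "closure_matrix",
    "ilr_from_matrix",
    "ilr_to_matrix",
    "ilr_forward",
    "ilr_inverse",
    "geometric_center",
    "impute_zeros",
    "InvalidCompositionError",
]

logger = logging.getLogger(__name__)

#: canonical internal part order for the full day
PART_NAMES = ("sleep", "mvpa", "lipa", "sb")
#: part order for the waking-day subcomposition
WAKING_PART_NAMES = ("mvpa", "lipa", "sb")

FULL_DAY_MIN = 1440.0
DEFAULT_WAKING_MIN = 960.0

_CLOSURE_RTOL = 1e-6


class InvalidCompositionError(ValueError):
    """A vector that cannot be interpreted as a time-use composition."""


def ilr_basis(n_parts: int) -> np.ndarray:
    """Orthonormal contrast matrix of the nested sleep/MVPA/LIPA/SB balances.

    Rows are clr-space contrasts; ``B @ B.T`` is the identity.  For
    ``n_parts == 3`` the sleep balance row is dropped and columns refer to
    (MVPA, LIPA, SB).
    """
    b = np.array(
        [
            [np.sqrt(3.0 / 4.0) * c for c in (1.0, -1 / 3, -1 / 3, -1 / 3)],
            [np.sqrt(2.0 / 3.0) * c for c in (0.0, 1.0, -0.5, -0.5)],
            [np.sqrt(1.0 / 2.0) * c for c in (0.0, 0.0, 1.0, -1.0)],
        ]
    )
    if n_parts == 4:
        return b
    if n_parts == 3:
        return b[1:, 1:]
    raise ValueError(f"compositions have 3 or 4 parts, got {n_parts}")


@dataclass(frozen=True)
class Composition:
    """Daily minutes in each behaviour, closed to ``total``.

    ``sleep`` is ``None`` for a waking-day (3-part) composition.
    """

    mvpa: float
    lipa: float
    sb: float
    sleep: Optional[float] = None
    total: float = FULL_DAY_MIN

    def __post_init__(self) -> None:
        parts = self.parts()
        if np.any(parts < 0):
            raise InvalidCompositionError(f"negative part in {parts}")
        s = parts.sum()
        if s <= 0:
            raise InvalidCompositionError("all parts are zero")
        if abs(s - self.total) > _CLOSURE_RTOL * self.total:
            # real minute-level data rarely sums exactly; re-close with a warning
            warnings.warn(
                f"parts sum to {s:.6g}, re-closing to total {self.total:.6g}",
                stacklevel=2,
            )
            scaled = parts * self.total / s
            names = self.part_names
            for name, value in zip(names, scaled):
                object.__setattr__(self, name, float(value))

    @property
    def has_sleep(self) -> bool:
        return self.sleep is not None

    @property
    def part_names(self) -> tuple:
        return PART_NAMES if self.has_sleep else WAKING_PART_NAMES

    def parts(self) -> np.ndarray:
        """Parts in canonical (Sleep, MVPA, LIPA, SB) order (sleep omitted if absent)."""
        if self.has_sleep:
            return np.array([self.sleep, self.mvpa, self.lipa, self.sb], float)
        return np.array([self.mvpa, self.lipa, self.sb], float)

    def waking(self) -> "Composition":
        """The 3-part waking subcomposition, closed to ``total - sleep``."""
        if not self.has_sleep:
            return self
        return Composition(
            mvpa=self.mvpa, lipa=self.lipa, sb=self.sb, total=self.total - self.sleep
        )

    def replace_part(self, name: str, value: float) -> "Composition":
        return replace(self, **{name: value})

    def as_dict(self) -> dict:
        d = {"mvpa": self.mvpa, "lipa": self.lipa, "sb": self.sb, "total": self.total}
        if self.has_sleep:
            d["sleep"] = self.sleep
        return d


@dataclass(frozen=True)
class IlrVector:
    """Balance coordinates of a composition.

    ``z1`` (sleep vs waking behaviours) is ``None`` for waking-day input;
    ``z2`` is the MVPA balance, ``z3`` the LIPA-vs-SB balance.
    """

    z2: float
    z3: float
    z1: Optional[float] = None

    def __post_init__(self) -> None:
        vals = [v for v in (self.z1, self.z2, self.z3) if v is not None]
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"non-finite ilr coordinates: {vals}")

    @property
    def has_sleep(self) -> bool:
        return self.z1 is not None

    def values(self) -> np.ndarray:
        if self.has_sleep:
            return np.array([self.z1, self.z2, self.z3], float)
        return np.array([self.z2, self.z3], float)


@dataclass(frozen=True)
class DetectionLimits:
    """Smallest observable time per behaviour, minutes/day.

    Values below a part's smallest observed non-zero time are permitted
    but warned about, since they make the censoring model uninformative.
    """

    mvpa: float = 1.0
    lipa: float = 1.0
    sb: float = 1.0
    sleep: float = 1.0

    def __post_init__(self) -> None:
        for name in ("mvpa", "lipa", "sb", "sleep"):
            if getattr(self, name) <= 0:
                raise ValueError(f"detection limit for {name} must be positive")

    def for_parts(self, names: Sequence[str]) -> np.ndarray:
        return np.array([getattr(self, n) for n in names], float)


# ---------------------------------------------------------------------------
# closure and ilr transforms


def closure_matrix(mat: np.ndarray, total: float = 1.0) -> np.ndarray:
    """Close each row of ``mat`` to sum to ``total``."""
    mat = np.asarray(mat, float)
    s = mat.sum(axis=-1, keepdims=True)
    if np.any(s <= 0):
        raise InvalidCompositionError("row with non-positive sum cannot be closed")
    return mat * (total / s)


def close(parts: Sequence[float], total: float, sleep_first: Optional[bool] = None) -> Composition:
    """Build a :class:`Composition` by proportionally rescaling ``parts``.

    ``parts`` is (sleep, mvpa, lipa, sb) for length 4 and (mvpa, lipa, sb)
    for length 3, matching the canonical internal order.
    """
    arr = np.asarray(parts, float)
    if arr.ndim != 1 or len(arr) not in (3, 4):
        raise InvalidCompositionError(f"expected 3 or 4 parts, got shape {arr.shape}")
    if np.any(arr < 0):
        raise InvalidCompositionError(f"negative part in {arr}")
    if arr.sum() <= 0 or total <= 0:
        raise InvalidCompositionError("cannot close an all-zero vector or non-positive total")
    arr = arr * total / arr.sum()
    if len(arr) == 4:
        return Composition(sleep=arr[0], mvpa=arr[1], lipa=arr[2], sb=arr[3], total=total)
    return Composition(mvpa=arr[0], lipa=arr[1], sb=arr[2], total=total)


def ilr_from_matrix(mat: np.ndarray) -> np.ndarray:
    """ilr coordinates for rows of strictly positive parts in canonical order."""
    mat = np.asarray(mat, float)
    if np.any(mat <= 0):
        raise InvalidCompositionError(
            "zero or negative part: impute zeros (impute_zeros) before the ilr transform"
        )
    basis = ilr_basis(mat.shape[-1])
    return np.log(mat) @ basis.T


def ilr_to_matrix(coords: np.ndarray, total: float = 1.0) -> np.ndarray:
    """Inverse ilr: rows of coordinates back to compositions closed to ``total``."""
    coords = np.asarray(coords, float)
    basis = ilr_basis(coords.shape[-1] + 1)
    logx = coords @ basis
    logx -= logx.max(axis=-1, keepdims=True)  # guard overflow
    return closure_matrix(np.exp(logx), total)


def ilr_forward(c: Composition) -> IlrVector:
    """Balance coordinates of a composition (scale-invariant)."""
    z = ilr_from_matrix(c.parts())
    if c.has_sleep:
        return IlrVector(z1=z[0], z2=z[1], z3=z[2])
    return IlrVector(z2=z[0], z3=z[1])


def ilr_inverse(z: IlrVector, total: float = FULL_DAY_MIN) -> Composition:
    parts = ilr_to_matrix(z.values(), total)
    if z.has_sleep:
        return Composition(sleep=parts[0], mvpa=parts[1], lipa=parts[2], sb=parts[3], total=total)
    return Composition(mvpa=parts[0], lipa=parts[1], sb=parts[2], total=total)


def geometric_center(compositions: Sequence[Composition]) -> Composition:
    """Compositional geometric mean of a cohort, closed to the common total."""
    if len(compositions) == 0:
        raise InvalidCompositionError("no compositions")
    arity = {c.has_sleep for c in compositions}
    if len(arity) != 1:
        raise InvalidCompositionError("mixed 3- and 4-part compositions")
    totals = {c.total for c in compositions}
    if len(totals) != 1:
        raise InvalidCompositionError("compositions have differing totals")
    mat = np.array([c.parts() for c in compositions])
    if np.any(mat <= 0):
        raise InvalidCompositionError("zero part present; impute zeros first")
    center = np.exp(np.log(mat).mean(axis=0))
    return close(center, compositions[0].total)


# ---------------------------------------------------------------------------
# rounded-zero imputation (lrEM)


def _alr(mat: np.ndarray, ref: int) -> np.ndarray:
    cols = [j for j in range(mat.shape[1]) if j != ref]
    return np.log(mat[:, cols]) - np.log(mat[:, [ref]])


def _alr_inv(w: np.ndarray, ref: int, totals: np.ndarray) -> np.ndarray:
    n, d1 = w.shape
    x = np.empty((n, d1 + 1))
    cols = [j for j in range(d1 + 1) if j != ref]
    x[:, ref] = 1.0
    x[:, cols] = np.exp(w)
    return x / x.sum(axis=1, keepdims=True) * totals[:, None]


def impute_zeros(
    mat: np.ndarray,
    limits: DetectionLimits | np.ndarray,
    part_names: Sequence[str] = PART_NAMES,
    tol: float = 1e-4,
    max_iter: int = 50,
) -> np.ndarray:
    """Replace rounded zeros by small positive values with an lrEM algorithm.

    Zeros in time-use data are censored small values (a behaviour practised
    for less than the detection limit of the device/epoch), not true
    absences.  They are treated as left-censored at the per-part detection
    limit and imputed by EM on additive log-ratio coordinates: the M-step
    fits a multivariate normal to the current log-ratio data, the E-step
    replaces each censored coordinate with its conditional expectation
    truncated above at the censoring threshold.  Initialisation is
    multiplicative simple replacement at 0.65 x limit.

    Rows without zeros are returned unchanged up to closure; imputed raw
    values are strictly positive and strictly below their detection limit.
    Each output row is re-closed to its original total.
    """
    mat = np.asarray(mat, float)
    if mat.ndim != 2:
        raise InvalidCompositionError("expected an n x D matrix of compositions")
    if np.any(mat < 0):
        raise InvalidCompositionError("negative entries are not rounded zeros")
    if isinstance(limits, DetectionLimits):
        lim = limits.for_parts(part_names)
    else:
        lim = np.asarray(limits, float)
    if lim.shape != (mat.shape[1],):
        raise ValueError("one detection limit per part is required")

    zero_mask = mat == 0
    n, d = mat.shape
    totals = mat.sum(axis=1)
    if not zero_mask.any():
        return closure_matrix(mat, 1.0) * totals[:, None]

    col_zero_frac = zero_mask.mean(axis=0)
    for j, frac in enumerate(col_zero_frac):
        if frac == 1.0:
            raise InvalidCompositionError(
                f"part {part_names[j]!r} is zero in every row and cannot be imputed"
            )
        if frac > 0:
            nonzero_min = mat[~zero_mask[:, j], j].min()
            if lim[j] > nonzero_min:
                warnings.warn(
                    f"detection limit {lim[j]:.3g} for {part_names[j]!r} exceeds the "
                    f"smallest observed non-zero value {nonzero_min:.3g}"
                )
            logger.info("imputing %.2f%% zeros in part %r", 100 * frac, part_names[j])

    # alr reference: the part with fewest zeros (preferably none)
    ref = int(np.argmin(col_zero_frac))
    if zero_mask[:, ref].any():
        raise InvalidCompositionError(
            "every part contains zeros; lrEM needs one fully observed part"
        )

    # multiplicative simple replacement initialisation
    x = mat.copy()
    for i in range(n):
        zi = zero_mask[i]
        if zi.any():
            repl = 0.65 * lim[zi]
            x[i, zi] = repl
            x[i, ~zi] *= (totals[i] - repl.sum()) / x[i, ~zi].sum()

    cols = [j for j in range(d) if j != ref]
    # censoring thresholds in alr space (raw-scale limits over the reference part)
    thresh = np.log(lim[None, :].repeat(n, 0)[:, cols]) - np.log(mat[:, [ref]])
    cens = zero_mask[:, cols]

    w = _alr(x, ref)
    for _ in range(max_iter):
        mu = w.mean(axis=0)
        sigma = np.cov(w, rowvar=False, bias=True)
        sigma = np.atleast_2d(sigma) + 1e-10 * np.eye(d - 1)
        w_new = w.copy()
        for i in np.nonzero(cens.any(axis=1))[0]:
            miss = cens[i]
            obs = ~miss
            if obs.any():
                s_oo = sigma[np.ix_(obs, obs)]
                s_mo = sigma[np.ix_(miss, obs)]
                cond_mu = mu[miss] + s_mo @ np.linalg.solve(s_oo, w[i, obs] - mu[obs])
                cond_sig = sigma[np.ix_(miss, miss)] - s_mo @ np.linalg.solve(s_oo, s_mo.T)
            else:
                cond_mu = mu[miss]
                cond_sig = sigma[np.ix_(miss, miss)]
            sd = np.sqrt(np.clip(np.diag(np.atleast_2d(cond_sig)), 1e-12, None))
            alpha = (thresh[i, miss] - cond_mu) / sd
            # E[W | W <= threshold] for a normal, strictly below the threshold
            with np.errstate(divide="ignore"):
                ratio = np.exp(stats.norm.logpdf(alpha) - stats.norm.logcdf(alpha))
            w_new[i, miss] = np.minimum(cond_mu - sd * ratio, thresh[i, miss] - 1e-8)
        delta = np.max(np.abs(w_new[cens] - w[cens])) if cens.any() else 0.0
        w = w_new
        if delta < tol:
            break

    out = mat.astype(float).copy()
    x_imp = _alr_inv(w, ref, totals)
    rows = zero_mask.any(axis=1)
    out[rows] = x_imp[rows]
    # raw imputed values must sit strictly below the limit before re-closure
    out[rows] = closure_matrix(out[rows], 1.0) * totals[rows, None]
    return out
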