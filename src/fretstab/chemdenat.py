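"""Urea-denaturation midpoint analysis of intrinsic fluorescence.

Curves are fitted with the four-parameter logistic

    y(x) = A2 + (A1 - A2) / (1 + (x / x0)^p)

whose center x0 is the denaturation midpoint C_m.  Biphasic (three-state)
profiles are split at a low-slope plateau between the two transitions and
each segment fitted separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks, savgol_filter

from .errors import (
    DegenerateDataError,
    FitFailureError,
    InsufficientDataError,
    InvalidInputError,
)

__all__ = [
    "DenaturationCurve",
    "LogisticFit",
    "ThreeStateResult",
    "logistic_model",
    "fit_cm",
    "fit_three_state",
]


@dataclass(frozen=True)
class DenaturationCurve:
    """Normalized fluorescence versus denaturant concentration (M)."""

    sample_id: str
    urea_concs: np.ndarray
    normalized_fluorescence: np.ndarray
    replicate: int = 1

    def __post_init__(self):
        object.__setattr__(
            self, "urea_concs", np.asarray(self.urea_concs, dtype=float)
        )
        object.__setattr__(
            self,
            "normalized_fluorescence",
            np.asarray(self.normalized_fluorescence, dtype=float),
        )
        x, y = self.urea_concs, self.normalized_fluorescence
        if x.shape != y.shape:
            raise InvalidInputError("urea_concs and fluorescence must be aligned")
        if np.any(x < 0):
            raise InvalidInputError("urea concentrations must be >= 0")
        if np.any(np.diff(x) < 0):
            raise InvalidInputError("urea concentrations must be ascending")
        if not np.all(np.isfinite(y)):
            raise InvalidInputError("fluorescence values must be finite")


@dataclass(frozen=True)
class LogisticFit:
    """Fitted parameters of the power-logistic; ``x0`` is C_m (M)."""

    a1: float
    a2: float
    x0: float
    p: float
    a1_stderr: float
    a2_stderr: float
    x0_stderr: float
    p_stderr: float
    residual_norm: float

    def __post_init__(self):
        if self.x0 <= 0:
            raise InvalidInputError("x0 (C_m) must be > 0")


@dataclass(frozen=True)
class ThreeStateResult:
    """Two-segment fit of a biphasic denaturation profile."""

    split_point: float
    first: LogisticFit
    second: LogisticFit

    def __post_init__(self):
        if not (self.first.x0 < self.split_point < self.second.x0):
            raise InvalidInputError(
                "split point must lie between the two fitted midpoints"
            )


def logistic_model(x, a1: float, a2: float, x0: float, p: float):
    """y = A2 + (A1 - A2)/(1 + (x/x0)^p), with y(0) = A1 exactly.

    Returning A1 at x = 0 removes the 0^p singularity without changing
    the fit (it is the p > 0 limit).
    """
    x = np.asarray(x, dtype=float)
    out = np.full(x.shape, float(a1))
    nz = x > 0
    out[nz] = a2 + (a1 - a2) / (1.0 + (x[nz] / x0) ** p)
    return out if out.ndim else float(out)


def fit_cm(curve: DenaturationCurve) -> LogisticFit:
    """Nonlinear least-squares fit of all four logistic parameters.

    Requires >= 6 points with both plateaus represented; the reported
    x0 standard error is the standard error of the fit.
    """
    order = np.lexsort((curve.normalized_fluorescence, curve.urea_concs))
    x = curve.urea_concs[order]
    y = curve.normalized_fluorescence[order]
    if x.size < 6:
        raise InsufficientDataError(f"need >= 6 points, got {x.size}")
    span = float(np.ptp(y))
    if span <= 1e-9 * max(1.0, abs(float(np.mean(y)))):
        raise DegenerateDataError("constant response; no transition to fit")

    a1_0, a2_0 = float(y[0]), float(y[-1])
    mid = (a1_0 + a2_0) / 2.0
    i = int(np.argmin(np.abs(y - mid)))
    x0_0 = float(x[i]) if x[i] > 0 else float(np.median(x[x > 0]))
    p0 = [a1_0, a2_0, x0_0, 5.0]
    try:
        popt, pcov = curve_fit(
            logistic_model,
            x,
            y,
            p0=p0,
            bounds=([-np.inf, -np.inf, 1e-9, -np.inf], [np.inf, np.inf, np.inf, np.inf]),
            xtol=1e-10,
            ftol=1e-10,
            max_nfev=20000,
        )
    except RuntimeError as exc:
        raise FitFailureError(
            f"C_m fit did not converge: {exc}", p0=p0, details=str(exc)
        ) from exc
    a1, a2, x0, p = popt
    perr = np.sqrt(np.diag(pcov))
    resid = y - logistic_model(x, *popt)
    return LogisticFit(
        a1=float(a1),
        a2=float(a2),
        x0=float(x0),
        p=float(p),
        a1_stderr=float(perr[0]),
        a2_stderr=float(perr[1]),
        x0_stderr=float(perr[2]),
        p_stderr=float(perr[3]),
        residual_norm=float(np.linalg.norm(resid)),
    )


def _auto_split(x: np.ndarray, y: np.ndarray) -> float:
    """Urea value of minimal |dy/dx| between the two steepest descents."""
    w = min(7, x.size if x.size % 2 == 1 else x.size - 1)
    if w < 5:
        raise InsufficientDataError("too few points for automatic splitting")
    dx = float(np.mean(np.diff(x)))
    dy = savgol_filter(y, w, polyorder=2, deriv=1, delta=dx)
    steep = -dy  # transitions are fluorescence decreases
    rng = float(np.ptp(steep))
    if rng <= 0:
        raise DegenerateDataError("flat curve; cannot locate transitions")
    peaks, props = find_peaks(steep, prominence=0.10 * rng)
    if peaks.size < 2:
        raise InsufficientDataError(
            "fewer than two transitions detected; curve is effectively two-state"
        )
    top2 = peaks[np.argsort(props["prominences"])[-2:]]
    i0, i1 = sorted(int(i) for i in top2)
    between = slice(i0, i1 + 1)
    j = i0 + int(np.argmin(np.abs(dy[between])))
    return float(x[j])


def fit_three_state(
    curve: DenaturationCurve, split_point: Union[float, str, None] = "auto"
) -> ThreeStateResult:
    """Split a biphasic curve and fit each segment with `fit_cm`.

    ``split_point`` may be a urea concentration (M) or ``"auto"``, in
    which case the split is placed at the low-slope plateau between the
    two steepest-descent regions of the smoothed curve.
    """
    x = curve.urea_concs
    y = curve.normalized_fluorescence
    if split_point in (None, "auto"):
        split = _auto_split(x, y)
    else:
        split = float(split_point)
        if not (x.min() < split < x.max()):
            raise InvalidInputError(
                f"split point {split} M lies outside the measured range "
                f"[{x.min()}, {x.max()}] M"
            )

    lo = x <= split
    hi = x >= split
    segments = []
    for name, mask in (("first", lo), ("second", hi)):
        if int(mask.sum()) < 6:
            raise InsufficientDataError(
                f"{name} segment has only {int(mask.sum())} points (< 6); "
                "profile may be effectively two-state"
            )
        seg = DenaturationCurve(
            sample_id=curve.sample_id,
            urea_concs=x[mask],
            normalized_fluorescence=y[mask],
            replicate=curve.replicate,
        )
        segments.append(fit_cm(seg))
    first, second = segments
    if first.x0 > second.x0:
        first, second = second, first
    return ThreeStateResult(split_point=split, first=first, second=second)
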