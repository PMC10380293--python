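"""DSF melt-curve analysis.

The dye signal rises with unfolding, peaks, and then decays as the
unfolded protein aggregates, so all thermodynamic quantities are
computed on the pre-peak region only (curve truncated at the global
intensity maximum).

The fraction folded at temperature T is

    P_f = 1 - (F - F_min) / (F_max - F_min),            P_u = 1 - P_f

and the unfolding equilibrium constant K_u = P_u / P_f.  Over the part
of the transition where P_u lies inside a configurable window
(default 10-50 % unfolded), ln K_u is linear in 1/T with slope
-dH/R and intercept dS/R, which yields dG(T_ref) = dH - T_ref * dS.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.signal import find_peaks, savgol_filter
from scipy.stats import linregress

from .constants import R_KCAL, T_REF_DEFAULT
from .errors import (
    DegenerateCurveError,
    InsufficientDataError,
    InvalidInputError,
)

__all__ = [
    "MeltCurve",
    "StabilityFit",
    "normalize_melt",
    "find_tm",
    "fraction_folded",
    "vant_hoff_fit",
    "delta_delta_g",
]


@dataclass(frozen=True)
class MeltCurve:
    """Ordered (temperature [K], intensity) observations for one sample."""

    sample_id: str
    replicate: int
    temperatures: np.ndarray
    intensities: np.ndarray

    def __post_init__(self):
        object.__setattr__(
            self, "temperatures", np.asarray(self.temperatures, dtype=float)
        )
        object.__setattr__(
            self, "intensities", np.asarray(self.intensities, dtype=float)
        )
        t, f = self.temperatures, self.intensities
        if t.shape != f.shape:
            raise InvalidInputError("temperatures and intensities must be aligned")
        if t.size < 20:
            raise InvalidInputError(f"melt curve needs >= 20 points, got {t.size}")
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError("temperatures must be strictly increasing")
        if not np.all(np.isfinite(f)):
            raise InvalidInputError("intensities must be finite")


@dataclass(frozen=True)
class StabilityFit:
    """van't Hoff analysis result for one melt curve.

    ``delta_h`` in kcal/mol, ``delta_s`` in kcal/(mol K),
    ``delta_g_ref`` = dH - t_ref*dS in kcal/mol.  ``tm_list`` holds the
    derivative-extremum melting temperatures (K), ascending.
    """

    f_min: float
    f_max: float
    tm_list: tuple
    delta_h: float
    delta_s: float
    delta_g_ref: float
    t_ref: float
    window: Tuple[float, float]
    r_squared: float
    n_window_points: int


def _truncate_at_peak(curve: MeltCurve) -> MeltCurve:
    """Drop the post-aggregation decay: keep points up to the global max."""
    i = int(np.argmax(curve.intensities))
    if i < 19:  # keep the MeltCurve >=20-point invariant satisfiable
        i = max(i, min(19, curve.intensities.size - 1))
    return MeltCurve(
        sample_id=curve.sample_id,
        replicate=curve.replicate,
        temperatures=curve.temperatures[: i + 1],
        intensities=curve.intensities[: i + 1],
    )


def normalize_melt(curve: MeltCurve) -> MeltCurve:
    """Min-max rescale intensities to [0, 1]; idempotent, affine-invariant."""
    f = curve.intensities
    fmin, fmax = float(f.min()), float(f.max())
    if fmax <= fmin:
        raise DegenerateCurveError(
            f"constant melt curve for sample {curve.sample_id}"
        )
    return MeltCurve(
        sample_id=curve.sample_id,
        replicate=curve.replicate,
        temperatures=curve.temperatures,
        intensities=(f - fmin) / (fmax - fmin),
    )


def _refine_peak(t: np.ndarray, y: np.ndarray, i: int) -> float:
    """Sub-sample peak position via a parabola through three points."""
    if i == 0 or i == t.size - 1:
        return float(t[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return float(t[i])
    shift = 0.5 * (y0 - y2) / denom
    shift = float(np.clip(shift, -1.0, 1.0))
    return float(t[i] + shift * (t[i + 1] - t[i - 1]) / 2.0)


def find_tm(curve: MeltCurve, smoothing_window: int = 11) -> list[float]:
    """Melting temperatures from extrema of the smoothed dF/dT.

    A degree-2 Savitzky-Golay derivative is searched for local maxima
    with prominence above 5 % of the derivative range, restricted to the
    pre-peak (pre-aggregation) region.  Returns an ascending list; empty
    when no transition stands out (flagged downstream, not an error).
    """
    if smoothing_window < 5 or smoothing_window % 2 == 0:
        raise InvalidInputError("smoothing_window must be an odd integer >= 5")
    if smoothing_window >= curve.temperatures.size:
        raise InvalidInputError("smoothing_window must be smaller than the curve")
    t = curve.temperatures
    f = curve.intensities
    dt = float(np.mean(np.diff(t)))
    df = savgol_filter(f, smoothing_window, polyorder=2, deriv=1, delta=dt)

    stop = int(np.argmax(f)) + 1
    df_pre = df[:stop]
    if df_pre.size < 3:
        return []
    rng = float(df_pre.max() - df_pre.min())
    if rng <= 0:
        return []
    peaks, _ = find_peaks(df_pre, prominence=0.05 * rng)
    # A transition ending exactly at the curve maximum has its derivative
    # peak at the boundary; catch it if it dominates its neighborhood.
    tms = [_refine_peak(t, df, int(i)) for i in peaks]
    return sorted(tms)


def fraction_folded(curve: MeltCurve) -> np.ndarray:
    """P_f per pre-peak point; 1 at F_min, 0 at F_max by construction."""
    pre = _truncate_at_peak(curve)
    f = pre.intensities
    fmin, fmax = float(f.min()), float(f.max())
    if fmax <= fmin:
        raise DegenerateCurveError(
            f"constant melt curve for sample {curve.sample_id}"
        )
    return 1.0 - (f - fmin) / (fmax - fmin)


def vant_hoff_fit(
    curve: MeltCurve,
    window: Tuple[float, float] = (0.10, 0.50),
    t_ref: float = T_REF_DEFAULT,
    t_range: Optional[Tuple[float, float]] = None,
    smoothing_window: int = 11,
) -> StabilityFit:
    """Extract dH, dS and dG(t_ref) from ln K_u versus 1/T.

    Only points with unfolded fraction inside ``window`` enter the
    ordinary-least-squares fit.  For multi-transition curves the fit is
    restricted to the final transition (points above the midpoint of the
    last two derivative extrema) unless ``t_range`` overrides the
    selection explicitly.
    """
    lo, hi = window
    if not (0.0 < lo < hi < 1.0):
        raise InvalidInputError("window must satisfy 0 < lo < hi < 1")

    pre = _truncate_at_peak(curve)
    pf = fraction_folded(curve)
    pu = 1.0 - pf
    t = pre.temperatures

    tm_list = tuple(find_tm(curve, smoothing_window=smoothing_window))

    mask = (pu >= lo) & (pu <= hi) & (pf > 0)
    if t_range is not None:
        mask &= (t >= t_range[0]) & (t <= t_range[1])
    elif len(tm_list) >= 2:
        mask &= t >= (tm_list[-2] + tm_list[-1]) / 2.0

    n = int(mask.sum())
    if n < 5:
        raise InsufficientDataError(
            f"only {n} points with unfolded fraction in [{lo}, {hi}]; need >= 5"
        )

    ku = pu[mask] / pf[mask]
    res = linregress(1.0 / t[mask], np.log(ku))
    delta_h = -R_KCAL * res.slope
    delta_s = R_KCAL * res.intercept
    return StabilityFit(
        f_min=float(pre.intensities.min()),
        f_max=float(pre.intensities.max()),
        tm_list=tm_list,
        delta_h=float(delta_h),
        delta_s=float(delta_s),
        delta_g_ref=float(delta_h - t_ref * delta_s),
        t_ref=float(t_ref),
        window=(lo, hi),
        r_squared=float(res.rvalue**2),
        n_window_points=n,
    )


def delta_delta_g(g_ref: float, g_variant: float) -> float:
    """ddG = dG(reference) - dG(variant); positive means destabilized."""
    if not (np.isfinite(g_ref) and np.isfinite(g_variant)):
        raise InvalidInputError("free energies must be finite")
    return float(g_ref - g_variant)
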