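"""Competitive-inhibition analysis: IC50 fits, Ki conversion, hit calling."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import (
    DegenerateDataError,
    DomainError,
    FitFailureError,
    InvalidInputError,
    MissingControlError,
)
from .fret import ChannelReading, CrosstalkModel, sensitized_emission

__all__ = [
    "CompetitionSeries",
    "IC50Fit",
    "KiResult",
    "ScreenResult",
    "four_pl",
    "fit_ic50",
    "cheng_prusoff",
    "screen_compounds",
]


@dataclass(frozen=True)
class CompetitionSeries:
    """Normalized relative binding versus inhibitor dose (µM)."""

    inhibitor_id: str
    inhibitor_concs: np.ndarray
    relative_binding: np.ndarray
    donor_conc: float
    acceptor_conc: float

    def __post_init__(self):
        object.__setattr__(
            self, "inhibitor_concs", np.asarray(self.inhibitor_concs, dtype=float)
        )
        object.__setattr__(
            self, "relative_binding", np.asarray(self.relative_binding, dtype=float)
        )
        if self.inhibitor_concs.shape != self.relative_binding.shape:
            raise InvalidInputError("concentrations and responses must be aligned")
        if np.any(self.inhibitor_concs < 0):
            raise InvalidInputError("inhibitor concentrations must be >= 0")
        if not np.all(np.isfinite(self.relative_binding)):
            raise InvalidInputError("responses must be finite")


@dataclass(frozen=True)
class IC50Fit:
    """Four-parameter logistic fit in log10-concentration space."""

    ic50: float
    hill_slope: float
    top: float
    bottom: float
    ic50_stderr: float
    hill_stderr: float
    top_stderr: float
    bottom_stderr: float

    def __post_init__(self):
        if self.ic50 <= 0:
            raise DomainError("ic50 must be > 0")
        if self.top <= self.bottom:
            raise DomainError("top must exceed bottom")


@dataclass(frozen=True)
class KiResult:
    """Cheng-Prusoff conversion carrying its inputs for audit."""

    ki: float
    ic50: float
    labeled_conc: float
    kd: float


@dataclass(frozen=True)
class ScreenResult:
    """Single-concentration screening verdict for one compound."""

    compound_id: str
    se_reduction: float
    donor_dequench: float
    is_hit: bool


def four_pl(x, log_ic50: float, hill: float, top: float, bottom: float):
    """y = bottom + (top - bottom) / (1 + 10^(hill*(log10(x) - log_ic50)))."""
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (np.log10(x) - log_ic50)))


def fit_ic50(series: CompetitionSeries) -> IC50Fit:
    """Fit the variable-slope four-parameter logistic to a dose series.

    Zero-concentration points are excluded from the log-space fit (they
    only anchor the normalization upstream).  Requires >= 5 distinct
    nonzero doses spanning at least two log-units.
    """
    x_all = series.inhibitor_concs
    y_all = series.relative_binding
    pos = x_all > 0
    order = np.lexsort((y_all[pos], x_all[pos]))
    x = x_all[pos][order]
    y = y_all[pos][order]

    distinct = np.unique(x)
    if distinct.size < 5:
        raise InvalidInputError(
            f"need >= 5 distinct nonzero doses, got {distinct.size}"
        )
    if distinct.max() / distinct.min() < 99.0:
        raise InvalidInputError("doses must span at least 2 log-units")
    span = np.ptp(y)
    if span <= 1e-9 * max(1.0, abs(float(np.mean(y)))):
        raise DegenerateDataError("response is flat; no transition to fit")

    # Anchor the top plateau with zero-dose wells when present.
    if np.any(~pos):
        top0 = float(np.mean(y_all[~pos]))
    else:
        top0 = float(np.max(y))
    bottom0 = float(np.min(y))
    mid = (top0 + bottom0) / 2.0
    i = int(np.argmin(np.abs(y - mid)))
    p0 = [math.log10(x[i]), 1.0, top0, bottom0]
    try:
        popt, pcov = curve_fit(
            four_pl, x, y, p0=p0, xtol=1e-10, ftol=1e-10, maxfev=20000
        )
    except RuntimeError as exc:
        raise FitFailureError(
            f"IC50 fit did not converge: {exc}", p0=p0, details=str(exc)
        ) from exc
    log_ic50, hill, top, bottom = popt
    perr = np.sqrt(np.diag(pcov))
    ic50 = 10.0 ** log_ic50
    return IC50Fit(
        ic50=float(ic50),
        hill_slope=float(hill),
        top=float(top),
        bottom=float(bottom),
        ic50_stderr=float(math.log(10.0) * ic50 * perr[0]),
        hill_stderr=float(perr[1]),
        top_stderr=float(perr[2]),
        bottom_stderr=float(perr[3]),
    )


def cheng_prusoff(ic50: float, labeled_conc: float, kd: float) -> KiResult:
    """Ki = IC50 / (1 + L/K_D) for pure single-site competition."""
    if kd <= 0:
        raise DomainError(f"kd must be > 0, got {kd}")
    if ic50 <= 0:
        raise DomainError(f"ic50 must be > 0, got {ic50}")
    if labeled_conc < 0:
        raise DomainError(f"labeled_conc must be >= 0, got {labeled_conc}")
    ki = ic50 / (1.0 + labeled_conc / kd)
    return KiResult(ki=float(ki), ic50=float(ic50), labeled_conc=float(labeled_conc), kd=float(kd))


def _mean_channels(readings: Sequence[ChannelReading], crosstalk: CrosstalkModel):
    wells = sensitized_emission(readings, crosstalk)
    se = float(np.mean([w.se for w in wells]))
    dd = float(np.mean([r.intensity for r in readings if r.channel == "DD"]))
    return se, dd


def screen_compounds(
    readings: Sequence[ChannelReading],
    crosstalk: CrosstalkModel,
    se_threshold: float = 0.2,
    dd_threshold: float = 0.2,
) -> list[ScreenResult]:
    """Dual-criterion hit calling at a fixed inhibitor concentration.

    Wells with ``inhibitor_conc == 0`` form the uninhibited control pool;
    remaining wells are grouped by ``sample_id``.  For each compound,

    * ``se_reduction  = 1 - SE_compound / SE_control``  (binding loss)
    * ``donor_dequench = DD_compound / DD_control - 1`` (donor recovery)

    and a compound is a hit only when *both* exceed their thresholds.
    """
    controls = [r for r in readings if r.inhibitor_conc == 0]
    if not controls:
        raise MissingControlError("no uninhibited control wells (inhibitor_conc == 0)")
    se_ctrl, dd_ctrl = _mean_channels(controls, crosstalk)
    if se_ctrl == 0 or dd_ctrl == 0:
        raise MissingControlError("control wells have zero SE or DD signal")

    groups: dict[str, list[ChannelReading]] = {}
    for r in readings:
        if r.inhibitor_conc > 0:
            groups.setdefault(r.sample_id, []).append(r)

    results = []
    for compound_id in sorted(groups):
        se_c, dd_c = _mean_channels(groups[compound_id], crosstalk)
        se_red = 1.0 - se_c / se_ctrl
        dequench = dd_c / dd_ctrl - 1.0
        results.append(
            ScreenResult(
                compound_id=compound_id,
                se_reduction=se_red,
                donor_dequench=dequench,
                is_hit=bool(se_red > se_threshold and dequench > dd_threshold),
            )
        )
    return results
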