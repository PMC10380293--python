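"""Three-channel sensitized-emission FRET analysis and K_D fitting.

The raw observable is a trio of fluorescence channels per well:

* ``DD`` -- donor excitation / donor emission (488/525 nm),
* ``AA`` -- acceptor excitation / acceptor emission (561/610 nm),
* ``DA`` -- donor excitation / acceptor emission (488/610 nm).

``DA`` mixes true sensitized emission with donor bleed-through
(proportional to ``DD``) and directly excited acceptor emission
(proportional to ``AA``).  Single-fluorophore control wells calibrate
those two proportionality constants; the corrected sensitized emission
is then fitted with the quadratic ligand-depletion binding isotherm to
yield the dissociation constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import (
    DegenerateControlError,
    DegenerateDataError,
    DomainError,
    FitFailureError,
    InvalidInputError,
    MissingControlError,
)

CHANNELS = ("DD", "AA", "DA")

__all__ = [
    "CHANNELS",
    "ChannelReading",
    "CrosstalkModel",
    "WellSE",
    "TitrationSeries",
    "BindingFit",
    "TimeSeriesKd",
    "estimate_crosstalk",
    "sensitized_emission",
    "eq1_model",
    "fit_kd",
    "kd_time_course",
]


@dataclass(frozen=True)
class ChannelReading:
    """One channel intensity measured in one well.

    Concentrations are in µM; ``inhibitor_conc`` is 0 when no inhibitor
    is present.  ``extra`` carries unknown CSV columns as annotations.
    """

    sample_id: str
    well: str
    replicate: int
    donor_conc: float
    acceptor_conc: float
    inhibitor_conc: float
    channel: str
    intensity: float
    extra: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.channel not in CHANNELS:
            raise InvalidInputError(
                f"channel must be one of {CHANNELS}, got {self.channel!r} "
                f"(well {self.well})"
            )
        if self.replicate < 1:
            raise InvalidInputError(
                f"replicate must be a positive integer (well {self.well})"
            )
        for name in ("donor_conc", "acceptor_conc", "inhibitor_conc"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise InvalidInputError(
                    f"{name} must be finite and >= 0, got {v} (well {self.well})"
                )
        if not math.isfinite(self.intensity) or self.intensity < 0:
            raise InvalidInputError(
                f"intensity must be finite and >= 0, got {self.intensity} "
                f"(well {self.well})"
            )


@dataclass(frozen=True)
class CrosstalkModel:
    """Spectral-crosstalk coefficients of the three-channel correction.

    Attributes
    ----------
    delta : float
        Donor bleed-through into DA, as DA per unit DD (donor-only wells).
    alpha : float
        Acceptor direct excitation into DA, as DA per unit AA
        (acceptor-only wells).
    """

    delta: float
    alpha: float

    def __post_init__(self):
        if not (0.0 <= self.delta < 1.0):
            raise DomainError(f"delta must be in [0, 1), got {self.delta}")
        if not (0.0 <= self.alpha < 1.0):
            raise DomainError(f"alpha must be in [0, 1), got {self.alpha}")


@dataclass(frozen=True)
class WellSE:
    """Crosstalk-corrected sensitized emission of one well."""

    well: str
    acceptor_conc: float
    replicate: int
    se: float


@dataclass(frozen=True)
class TitrationSeries:
    """Sensitized emission versus titrated acceptor concentration.

    ``acceptor_concs`` and ``sensitized_emission`` are aligned per point
    (replicates appear as repeated concentrations).
    """

    donor_conc: float
    acceptor_concs: np.ndarray
    sensitized_emission: np.ndarray

    def __post_init__(self):
        object.__setattr__(
            self, "acceptor_concs", np.asarray(self.acceptor_concs, dtype=float)
        )
        object.__setattr__(
            self,
            "sensitized_emission",
            np.asarray(self.sensitized_emission, dtype=float),
        )
        if self.donor_conc <= 0:
            raise InvalidInputError("donor_conc must be > 0")
        if self.acceptor_concs.shape != self.sensitized_emission.shape:
            raise InvalidInputError(
                "acceptor_concs and sensitized_emission must be aligned"
            )
        if self.acceptor_concs.size == 0:
            raise InvalidInputError("empty titration series")
        if np.any(self.acceptor_concs < 0):
            raise InvalidInputError("acceptor concentrations must be >= 0")
        if np.all(self.acceptor_concs == self.acceptor_concs[0]):
            raise InvalidInputError("acceptor concentrations are all equal")

    @classmethod
    def from_readings(
        cls,
        readings: Sequence[ChannelReading],
        crosstalk: CrosstalkModel,
        control_se: Optional[Mapping[float, float]] = None,
    ) -> "TitrationSeries":
        """Build a series by correcting raw wells with `sensitized_emission`."""
        wells = sensitized_emission(readings, crosstalk, control_se)
        donor = {r.donor_conc for r in readings}
        if len(donor) != 1:
            raise InvalidInputError(
                f"series must have a constant donor concentration, got {sorted(donor)}"
            )
        x = np.array([w.acceptor_conc for w in wells])
        se = np.array([w.se for w in wells])
        return cls(donor.pop(), x, se)


@dataclass(frozen=True)
class BindingFit:
    """Result of the quadratic-isotherm K_D fit (concentrations in µM)."""

    kd: float
    em_fret_max: float
    kd_stderr: float
    em_fret_max_stderr: float
    residual_norm: float
    n_points: int

    def __post_init__(self):
        if self.kd <= 0 or self.em_fret_max <= 0:
            raise DomainError("kd and em_fret_max must be > 0")
        if self.n_points < 2:
            raise InvalidInputError("n_points must be >= number of free parameters")


@dataclass(frozen=True)
class TimeSeriesKd:
    """Per-incubation-time K_D fits plus kd(t)/kd(t_first) ratios."""

    incubation_times: tuple
    fits: tuple
    kd_ratios: tuple

    def __post_init__(self):
        if len(self.incubation_times) != len(self.fits):
            raise InvalidInputError("times and fits must be aligned")
        t = np.asarray(self.incubation_times, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError("incubation times must be strictly increasing")


def _group_wells(readings: Sequence[ChannelReading]):
    """Group readings into per-well channel maps, keyed by (well, replicate)."""
    wells: dict = {}
    for r in readings:
        key = (r.well, r.replicate)
        entry = wells.setdefault(key, {"reading": r, "channels": {}})
        if r.channel in entry["channels"]:
            raise InvalidInputError(
                f"duplicate channel {r.channel} for well {r.well} replicate {r.replicate}"
            )
        entry["channels"][r.channel] = r.intensity
    return wells


def estimate_crosstalk(
    donor_only_readings: Sequence[ChannelReading],
    acceptor_only_readings: Sequence[ChannelReading],
) -> CrosstalkModel:
    """Calibrate crosstalk coefficients from single-fluorophore wells.

    ``delta`` is the mean DA/DD over donor-only wells and ``alpha`` the
    mean DA/AA over acceptor-only wells.

    Raises
    ------
    InvalidInputError
        If a control list is empty or a well lacks a needed channel.
    DegenerateControlError
        If a denominator channel is <= 0.
    """
    if not donor_only_readings:
        raise InvalidInputError("donor-only control readings are empty")
    if not acceptor_only_readings:
        raise InvalidInputError("acceptor-only control readings are empty")

    def ratios(readings, num, den):
        out = []
        for (well, rep), entry in _group_wells(readings).items():
            ch = entry["channels"]
            for needed in (num, den):
                if needed not in ch:
                    raise InvalidInputError(
                        f"control well {well} (replicate {rep}) lacks channel {needed}"
                    )
            if ch[den] <= 0:
                raise DegenerateControlError(
                    f"control well {well} has {den} = {ch[den]} <= 0"
                )
            out.append(ch[num] / ch[den])
        return float(np.mean(out))

    delta = ratios(donor_only_readings, "DA", "DD")
    alpha = ratios(acceptor_only_readings, "DA", "AA")
    return CrosstalkModel(delta=delta, alpha=alpha)


def sensitized_emission(
    sample_readings: Sequence[ChannelReading],
    crosstalk: CrosstalkModel,
    control_se: Optional[Mapping[float, float]] = None,
) -> list[WellSE]:
    """Crosstalk-correct each well: SE = DA - alpha*AA - delta*DD.

    When ``control_se`` (non-binding-control SE keyed by acceptor
    concentration) is supplied, the matching control SE is additionally
    subtracted.  Negative results are retained, not clipped.
    """
    wells = _group_wells(sample_readings)
    out = []
    for (well, rep), entry in sorted(wells.items()):
        ch = entry["channels"]
        missing = [c for c in CHANNELS if c not in ch]
        if missing:
            raise InvalidInputError(
                f"well {well} (replicate {rep}) lacks channel(s) {missing}"
            )
        se = ch["DA"] - crosstalk.alpha * ch["AA"] - crosstalk.delta * ch["DD"]
        x = entry["reading"].acceptor_conc
        if control_se is not None:
            match = None
            for cx, cse in control_se.items():
                if math.isclose(cx, x, rel_tol=1e-6, abs_tol=1e-9):
                    match = cse
                    break
            if match is None:
                raise MissingControlError(
                    f"no control SE for acceptor concentration {x} µM (well {well})"
                )
            se -= match
        out.append(WellSE(well=well, acceptor_conc=x, replicate=rep, se=se))
    return out


def eq1_model(X, a: float, kd: float, em_fret_max: float):
    """Quadratic ligand-depletion binding isotherm.

    EmFRET(X) = EmFRETmax * [1 - 2 K_D / ((X - a + K_D)
                + sqrt((X - a - K_D)^2 + 4 K_D X))]

    which equals ``em_fret_max`` times the bound donor fraction of the
    exact two-component equilibrium at constant donor concentration
    ``a``.  Accepts scalar or array ``X`` (µM).
    """
    if a <= 0:
        raise DomainError(f"donor concentration a must be > 0, got {a}")
    if kd <= 0:
        raise DomainError(f"kd must be > 0, got {kd}")
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise DomainError("X must be >= 0")
    # Algebraically identical citardauq rearrangement of the printed
    # formula: stable when the bound fraction is tiny.  The radicand is
    # expanded into a sum of nonnegative terms for the same reason:
    # (X - a - kd)^2 + 4 kd X  ==  (a - X)^2 + kd^2 + 2 kd (a + X).
    root = np.sqrt((a - X) ** 2 + kd * kd + 2.0 * kd * (a + X))
    val = em_fret_max * 2.0 * X / ((X + a + kd) + root)
    return val if val.ndim else float(val)


def _initial_kd_guess(x: np.ndarray, y: np.ndarray) -> float:
    """Acceptor concentration at half-maximal mean SE, by interpolation."""
    xs = np.unique(x)
    means = np.array([y[x == xi].mean() for xi in xs])
    half = means.max() / 2.0
    above = np.nonzero(means >= half)[0]
    if above.size == 0:
        return float(np.median(xs[xs > 0])) if np.any(xs > 0) else 1.0
    i = above[0]
    if i == 0:
        guess = xs[0]
    else:
        x0, x1 = xs[i - 1], xs[i]
        y0, y1 = means[i - 1], means[i]
        guess = x0 + (half - y0) * (x1 - x0) / (y1 - y0) if y1 != y0 else x1
    if not np.isfinite(guess) or guess <= 0:
        guess = float(np.median(xs[xs > 0]))
    return float(guess)


def fit_kd(series: TitrationSeries) -> BindingFit:
    """Fit K_D and EmFRETmax by nonlinear least squares on all points.

    Points are sorted before fitting, so well/replicate order never
    affects the result.  Initialization: K_D at half-maximal SE,
    EmFRETmax at the maximal SE.
    """
    order = np.lexsort((series.sensitized_emission, series.acceptor_concs))
    x = series.acceptor_concs[order]
    y = series.sensitized_emission[order]

    if np.unique(x).size < 5:
        raise InvalidInputError(
            f"need >= 5 distinct acceptor concentrations, got {np.unique(x).size}"
        )
    if x.min() > 0.05 * x.max():
        raise InvalidInputError(
            "series must include an acceptor concentration near zero"
        )
    if np.all(y == 0):
        raise DegenerateDataError("all sensitized-emission values are zero")

    a = series.donor_conc
    p0 = [_initial_kd_guess(x, y), max(float(y.max()), 1e-9)]
    try:
        popt, pcov = curve_fit(
            lambda X, kd, emmax: eq1_model(X, a, kd, emmax),
            x,
            y,
            p0=p0,
            bounds=([1e-12, 1e-12], [np.inf, np.inf]),
            xtol=1e-8,
            ftol=1e-8,
            max_nfev=500 * 4,
        )
    except RuntimeError as exc:
        raise FitFailureError(
            f"K_D fit did not converge: {exc}", p0=p0, details=str(exc)
        ) from exc
    kd, emmax = popt
    perr = np.sqrt(np.diag(pcov))
    resid = y - eq1_model(x, a, kd, emmax)
    return BindingFit(
        kd=float(kd),
        em_fret_max=float(emmax),
        kd_stderr=float(perr[0]),
        em_fret_max_stderr=float(perr[1]),
        residual_norm=float(np.linalg.norm(resid)),
        n_points=int(x.size),
    )


def kd_time_course(series_by_time: Mapping[float, TitrationSeries]) -> TimeSeriesKd:
    """Fit K_D independently at each incubation time (minutes).

    Also reports kd(t)/kd(t_first) as a titrator-stability indicator:
    a stable titrator gives ratios near 1, a decaying one a rising trend.
    """
    if len(series_by_time) < 2:
        raise InvalidInputError("need at least 2 incubation time points")
    times = sorted(series_by_time)
    fits = []
    for t in times:
        try:
            fits.append(fit_kd(series_by_time[t]))
        except Exception as exc:
            raise FitFailureError(
                f"K_D fit failed at incubation time {t} min: {exc}"
            ) from exc
    ratios = tuple(f.kd / fits[0].kd for f in fits)
    return TimeSeriesKd(
        incubation_times=tuple(float(t) for t in times),
        fits=tuple(fits),
        kd_ratios=ratios,
    )
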