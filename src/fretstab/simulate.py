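"""Synthetic-data generators for every pipeline input.

Each generator is a deterministic function of its configuration and
seed, and is the adjoint of one analysis stage: with noise switched off
the corresponding analyzer recovers the generating parameters.  Noise is
multiplicative Gaussian (CV-parameterized) with an optional small
additive floor, as appropriate for gain-scaled plate-reader intensities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import brentq

from .chemdenat import DenaturationCurve
from .constants import R_KCAL, T_WORK_DEFAULT, celsius_to_kelvin
from .errors import DomainError, InvalidInputError
from .fret import ChannelReading
from .neq import WorkSet
from .thermal import MeltCurve

__all__ = [
    "FretSimConfig",
    "MeltSimConfig",
    "WorkSimConfig",
    "TitrationPlate",
    "simulate_binding_equilibrium",
    "simulate_titration_plate",
    "simulate_competition_plate",
    "simulate_melt_curve",
    "simulate_urea_curve",
    "simulate_work_values",
]

#: Default acceptor grid emulating a 0-3.09 µM two-fold dilution series.
DEFAULT_ACCEPTOR_GRID = (
    0.0,
    0.0483,
    0.0966,
    0.193,
    0.386,
    0.7725,
    1.545,
    3.09,
)


@dataclass(frozen=True)
class FretSimConfig:
    """Design constants of the simulated FRET titration plate."""

    kd: float = 0.4308
    em_fret_max: float = 1000.0
    donor_conc: float = 1.0
    acceptor_grid: tuple = DEFAULT_ACCEPTOR_GRID
    delta: float = 0.12
    alpha: float = 0.30
    donor_brightness: float = 1000.0
    acceptor_brightness: float = 800.0
    apparent_fret_efficiency: float = 0.4
    emission_gain: float = 1.0
    noise_cv: float = 0.0
    additive_sd: float = 0.0
    functional_decay_rate: float = 0.0  # fraction of titrator lost per hour
    replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.kd <= 0 or self.donor_conc <= 0:
            raise DomainError("kd and donor_conc must be > 0")
        if not (0 <= self.apparent_fret_efficiency < 1):
            raise DomainError("apparent_fret_efficiency must be in [0, 1)")
        if not (0 <= self.delta < 1 and 0 <= self.alpha < 1):
            raise DomainError("crosstalk coefficients must be in [0, 1)")
        if self.noise_cv < 0 or self.additive_sd < 0:
            raise DomainError("noise parameters must be >= 0")
        if self.replicates < 1:
            raise DomainError("replicates must be >= 1")


@dataclass(frozen=True)
class MeltSimConfig:
    """Two- or three-state thermal unfolding curve parameters.

    ``delta_h`` in kcal/mol, ``delta_s`` in kcal/(mol K); the transition
    midpoint is Tm = delta_h/delta_s.  Baselines are (intercept, slope)
    pairs evaluated as b0 + b1*(T - 303.15 K).
    """

    delta_h: float = 100.0
    delta_s: float = 100.0 / 323.0
    delta_h2: float = 150.0
    delta_s2: float = 150.0 / 327.69
    baseline_native: Tuple[float, float] = (100.0, 0.0)
    baseline_intermediate: Tuple[float, float] = (600.0, 0.0)
    baseline_unfolded: Tuple[float, float] = (1000.0, 0.0)
    aggregation_decay_rate: float = 0.0  # per K beyond the decay onset
    aggregation_onset_offset: float = 10.0  # K above the last Tm
    t_min_c: float = 30.0
    t_max_c: float = 95.0
    step_c: float = 0.5
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.delta_h <= 0 or self.delta_s <= 0:
            raise DomainError("delta_h and delta_s must be > 0")
        tm = self.delta_h / self.delta_s
        if not (celsius_to_kelvin(self.t_min_c) < tm < celsius_to_kelvin(self.t_max_c)):
            raise DomainError(f"Tm = {tm:.2f} K lies outside the temperature grid")


@dataclass(frozen=True)
class WorkSimConfig:
    """Crooks-consistent Gaussian work-distribution parameters."""

    true_dg: float = 1.0
    sigma: float = 0.5
    n_per_direction: int = 10000
    temperature: float = T_WORK_DEFAULT
    seed: int = 0

    def __post_init__(self):
        if self.sigma <= 0:
            raise DomainError("sigma must be > 0")
        if self.n_per_direction < 1:
            raise DomainError("n_per_direction must be >= 1")


@dataclass(frozen=True)
class TitrationPlate:
    """Simulated plate split into sample and control well groups."""

    sample: tuple
    donor_only: tuple
    acceptor_only: tuple
    nonbinding_control: tuple

    def all_readings(self) -> list:
        return list(self.sample + self.donor_only + self.acceptor_only
                    + self.nonbinding_control)


def simulate_binding_equilibrium(
    a: float,
    X: float,
    kd: float,
    competitor: Optional[Tuple[float, float]] = None,
) -> float:
    """Exact bound-complex concentration (µM) at equilibrium.

    Without a competitor this is the closed-form root of the quadratic
    mass-action balance.  With a competitor ``(conc, ki)`` sharing the
    binding site on the ``a`` partner, the free-partner concentration is
    solved by bracketed root finding to 1e-10 µM.
    """
    if kd <= 0:
        raise DomainError("kd must be > 0")
    if a < 0 or X < 0:
        raise DomainError("concentrations must be >= 0")
    if X == 0 or a == 0:
        return 0.0
    if competitor is None:
        # citardauq form of the quadratic root; radicand expanded into
        # nonnegative terms to avoid cancellation
        s = a + X + kd
        root = math.sqrt((a - X) ** 2 + kd * kd + 2.0 * kd * (a + X))
        return float(2.0 * a * X / (s + root))
    conc, ki = competitor
    if ki <= 0:
        raise DomainError("competitor ki must be > 0")
    if conc < 0:
        raise DomainError("competitor concentration must be >= 0")
    if conc == 0:
        return simulate_binding_equilibrium(a, X, kd)

    def balance(a_free):
        return (
            a_free
            + X * a_free / (kd + a_free)
            + conc * a_free / (ki + a_free)
            - a
        )

    a_free = brentq(balance, 0.0, a, xtol=1e-10, rtol=8.9e-16)
    return float(X * a_free / (kd + a_free))


def _noisy(rng, value, cv, additive_sd):
    v = value
    if cv > 0:
        v = v * (1.0 + cv * rng.standard_normal())
    if additive_sd > 0:
        v = v + additive_sd * rng.standard_normal()
    return max(float(v), 0.0)


def _well_channels(config: FretSimConfig, a: float, x: float, f_bound: float):
    """Noise-free three-channel intensities of one sample well."""
    e = config.apparent_fret_efficiency
    dd = config.donor_brightness * a * (1.0 - e * f_bound)
    aa = config.acceptor_brightness * x
    se = config.emission_gain * e * config.donor_brightness * a * f_bound
    da = se + config.alpha * aa + config.delta * dd
    return dd, aa, da


def simulate_titration_plate(
    config: FretSimConfig,
    incubation_time_min: float = 60.0,
) -> TitrationPlate:
    """Simulate a full titration plate with its three control groups.

    Per sample well: DD is the donor emission quenched in proportion to
    the bound fraction, AA the directly excited acceptor emission and DA
    the sensitized emission plus both crosstalk contributions.  When
    ``functional_decay_rate`` > 0 the functional titrator concentration
    decays linearly with the incubation time, emulating an unstable
    acceptor protein.
    """
    rng = np.random.default_rng(config.seed)
    a = config.donor_conc
    decay = config.functional_decay_rate * incubation_time_min / 60.0
    x_factor = max(0.0, 1.0 - decay)

    sample, donor_only, acceptor_only, nonbinding = [], [], [], []
    widx = 0
    for x in config.acceptor_grid:
        x_eff = x * x_factor
        bound = simulate_binding_equilibrium(a, x_eff, config.kd)
        f_bound = bound / a
        for rep in range(1, config.replicates + 1):
            widx += 1
            well = f"S{widx:03d}"
            dd, aa, da = _well_channels(config, a, x, f_bound)
            for channel, inten in (("DD", dd), ("AA", aa), ("DA", da)):
                sample.append(
                    ChannelReading(
                        sample_id="sample",
                        well=well,
                        replicate=rep,
                        donor_conc=a,
                        acceptor_conc=x,
                        inhibitor_conc=0.0,
                        channel=channel,
                        intensity=_noisy(rng, inten, config.noise_cv, config.additive_sd),
                    )
                )

    # Donor-only wells: no acceptor at all, DA is pure bleed-through.
    for rep in range(1, config.replicates + 1):
        dd = config.donor_brightness * a
        for channel, inten in (("DD", dd), ("AA", 0.0), ("DA", config.delta * dd)):
            donor_only.append(
                ChannelReading(
                    sample_id="donor_only",
                    well=f"D{rep:03d}",
                    replicate=rep,
                    donor_conc=a,
                    acceptor_conc=0.0,
                    inhibitor_conc=0.0,
                    channel=channel,
                    intensity=_noisy(rng, inten, config.noise_cv, config.additive_sd),
                )
            )

    # Acceptor-only wells across the grid: DA is pure direct excitation.
    widx = 0
    for x in config.acceptor_grid:
        if x == 0:
            continue
        for rep in range(1, config.replicates + 1):
            widx += 1
            aa = config.acceptor_brightness * x
            for channel, inten in (("DD", 0.0), ("AA", aa), ("DA", config.alpha * aa)):
                acceptor_only.append(
                    ChannelReading(
                        sample_id="acceptor_only",
                        well=f"A{widx:03d}",
                        replicate=rep,
                        donor_conc=0.0,
                        acceptor_conc=x,
                        inhibitor_conc=0.0,
                        channel=channel,
                        intensity=_noisy(rng, inten, config.noise_cv, config.additive_sd),
                    )
                )

    # Non-binding control: both fluorophores present, zero FRET.
    widx = 0
    for x in config.acceptor_grid:
        for rep in range(1, config.replicates + 1):
            widx += 1
            dd = config.donor_brightness * a
            aa = config.acceptor_brightness * x
            da = config.alpha * aa + config.delta * dd
            for channel, inten in (("DD", dd), ("AA", aa), ("DA", da)):
                nonbinding.append(
                    ChannelReading(
                        sample_id="nonbinding_control",
                        well=f"N{widx:03d}",
                        replicate=rep,
                        donor_conc=a,
                        acceptor_conc=x,
                        inhibitor_conc=0.0,
                        channel=channel,
                        intensity=_noisy(rng, inten, config.noise_cv, config.additive_sd),
                    )
                )

    return TitrationPlate(
        sample=tuple(sample),
        donor_only=tuple(donor_only),
        acceptor_only=tuple(acceptor_only),
        nonbinding_control=tuple(nonbinding),
    )


def simulate_competition_plate(
    config: FretSimConfig,
    ki: float,
    dose_grid: Sequence[float],
    compound_id: str = "compound",
    acceptor_conc: float = 1.0,
    artifact: Optional[str] = None,
) -> list:
    """Simulate a dose series of a competitive inhibitor.

    The competitor shares the donor's binding site (pure competition),
    so the fitted IC50 obeys IC50 = ki*(1 + L/kd) with L the labeled
    acceptor concentration.  ``artifact="quencher"`` instead attenuates
    all three channels uniformly with dose without touching the binding
    equilibrium - a signal artifact the dual-criterion hit rule rejects.
    """
    if artifact not in (None, "quencher"):
        raise InvalidInputError(f"unknown artifact mode {artifact!r}")
    rng = np.random.default_rng(config.seed)
    a = config.donor_conc
    x = acceptor_conc
    out = []
    widx = 0
    for dose in dose_grid:
        if artifact == "quencher":
            bound = simulate_binding_equilibrium(a, x, config.kd)
            atten = 1.0 / (1.0 + dose / 10.0)
        else:
            bound = simulate_binding_equilibrium(
                a, x, config.kd, competitor=(dose, ki) if dose > 0 else None
            )
            atten = 1.0
        f_bound = bound / a
        for rep in range(1, config.replicates + 1):
            widx += 1
            well = f"C{widx:03d}"
            dd, aa, da = _well_channels(config, a, x, f_bound)
            for channel, inten in (("DD", dd * atten), ("AA", aa * atten),
                                   ("DA", da * atten)):
                out.append(
                    ChannelReading(
                        sample_id=compound_id if dose > 0 else "control",
                        well=well,
                        replicate=rep,
                        donor_conc=a,
                        acceptor_conc=x,
                        inhibitor_conc=float(dose),
                        channel=channel,
                        intensity=_noisy(rng, inten, config.noise_cv, config.additive_sd),
                    )
                )
    return out


def _two_state_pu(t: np.ndarray, dh: float, ds: float) -> np.ndarray:
    ku = np.exp(-(dh - t * ds) / (R_KCAL * t))
    return ku / (1.0 + ku)


def simulate_melt_curve(
    config: MeltSimConfig,
    n_states: int = 2,
    sample_id: str = "sim",
    replicate: int = 1,
) -> MeltCurve:
    """Thermal unfolding curve with van't Hoff thermodynamics.

    Two-state: F = (1-P_u)*baseline_native + P_u*baseline_unfolded with
    P_u = K_u/(1+K_u), K_u = exp(-(dH - T dS)/(R T)).  Three-state: the
    population-weighted sum over sequential N <-> I <-> U transitions
    (first transition uses delta_h/delta_s, second delta_h2/delta_s2).
    Optional post-peak exponential decay emulates dye loss on
    aggregation.
    """
    if n_states not in (2, 3):
        raise InvalidInputError("n_states must be 2 or 3")
    rng = np.random.default_rng(config.seed)
    t = celsius_to_kelvin(
        np.arange(config.t_min_c, config.t_max_c + config.step_c / 2.0, config.step_c)
    )
    b = lambda coeffs: coeffs[0] + coeffs[1] * (t - 303.15)
    bn = b(config.baseline_native)
    bu = b(config.baseline_unfolded)

    if n_states == 2:
        pu = _two_state_pu(t, config.delta_h, config.delta_s)
        f = (1.0 - pu) * bn + pu * bu
        tm_last = config.delta_h / config.delta_s
    else:
        bi = b(config.baseline_intermediate)
        k1 = np.exp(-(config.delta_h - t * config.delta_s) / (R_KCAL * t))
        k2 = np.exp(-(config.delta_h2 - t * config.delta_s2) / (R_KCAL * t))
        pn = 1.0 / (1.0 + k1 + k1 * k2)
        pi = k1 * pn
        pu = k1 * k2 * pn
        f = pn * bn + pi * bi + pu * bu
        tm_last = max(config.delta_h / config.delta_s,
                      config.delta_h2 / config.delta_s2)

    if config.aggregation_decay_rate > 0:
        onset = tm_last + config.aggregation_onset_offset
        f = f * np.exp(-config.aggregation_decay_rate * np.clip(t - onset, 0.0, None))

    if config.noise_cv > 0:
        f = f * (1.0 + config.noise_cv * rng.standard_normal(f.shape))

    return MeltCurve(
        sample_id=sample_id, replicate=replicate, temperatures=t, intensities=f
    )


def simulate_urea_curve(
    a1: float = 1.0,
    a2: float = 0.0,
    x0: Union[float, Tuple[float, float]] = 3.32,
    p: Union[float, Tuple[float, float]] = 10.0,
    n_transitions: int = 1,
    noise_cv: float = 0.0,
    seed: int = 0,
    x_max: float = 8.0,
    n_points: int = 33,
    mid_level: Optional[float] = None,
    sample_id: str = "sim",
) -> DenaturationCurve:
    """Chemical-denaturation curve from the power-logistic model.

    One transition: y = a2 + (a1-a2)/(1 + (x/x0)^p).  Two transitions
    (biphasic): a1 -> mid_level around x0[0], then mid_level -> a2
    around x0[1]; defaults match a biphasic profile with midpoints at
    1.56 M and 3.95 M when ``x0=(1.56, 3.95)`` is passed.
    """
    rng = np.random.default_rng(seed)
    x = np.linspace(0.0, x_max, n_points)

    def step(xv, center, power):
        # rises 0 -> 1 around `center`; exact 0 at x = 0
        out = np.zeros_like(xv)
        nz = xv > 0
        r = (xv[nz] / center) ** power
        out[nz] = r / (1.0 + r)
        return out

    if n_transitions == 1:
        y = a1 + (a2 - a1) * step(x, float(x0), float(p))
    elif n_transitions == 2:
        x01, x02 = (x0 if isinstance(x0, (tuple, list)) else (1.56, 3.95))
        p1, p2 = (p if isinstance(p, (tuple, list)) else (p, p))
        mid = 0.5 * (a1 + a2) if mid_level is None else mid_level
        y = (
            a1
            + (mid - a1) * step(x, float(x01), float(p1))
            + (a2 - mid) * step(x, float(x02), float(p2))
        )
    else:
        raise InvalidInputError("n_transitions must be 1 or 2")

    if noise_cv > 0:
        y = y * (1.0 + noise_cv * rng.standard_normal(y.shape))
    return DenaturationCurve(
        sample_id=sample_id, urea_concs=x, normalized_fluorescence=y
    )


def simulate_work_values(config: WorkSimConfig, edge_label: str = "edge") -> WorkSet:
    """Gaussian work sets satisfying the Crooks fluctuation theorem.

    Wf ~ N(dG + sigma^2/(2RT), sigma^2) and, in the reverse direction's
    own frame, Wr ~ N(-dG + sigma^2/(2RT), sigma^2), so that the
    forward and negated-reverse densities intersect exactly at dG.
    """
    rng = np.random.default_rng(config.seed)
    rt = R_KCAL * config.temperature
    shift = config.sigma**2 / (2.0 * rt)
    n = config.n_per_direction
    wf = config.true_dg + shift + config.sigma * rng.standard_normal(n)
    wr = -config.true_dg + shift + config.sigma * rng.standard_normal(n)
    return WorkSet(
        edge_label=edge_label,
        forward_work=wf,
        reverse_work=wr,
        temperature=config.temperature,
    )
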