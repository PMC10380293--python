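"""Free energies from nonequilibrium work distributions.

Work values are stored as work performed on the system in each
direction's own frame: forward work accompanies A -> B transitions,
reverse work B -> A.  The Crooks fluctuation theorem then relates the
forward distribution to the *negated* reverse one, which is how the
Gaussian-intersection and Bennett-acceptance-ratio estimators below
consume the data.  All energies in kcal/mol, temperatures in K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

from .constants import R_KCAL, T_WORK_DEFAULT
from .errors import EstimationFailureError, InvalidInputError

__all__ = [
    "WorkSet",
    "FreeEnergyEstimate",
    "CycleEdge",
    "ThermoCycle",
    "ClosureReport",
    "DdgResult",
    "jarzynski",
    "crooks_gaussian_intersection",
    "bar",
    "ddg_from_legs",
    "cycle_closure",
]


@dataclass(frozen=True)
class WorkSet:
    """Forward/reverse work samples for one alchemical edge."""

    edge_label: str
    forward_work: np.ndarray
    reverse_work: np.ndarray
    temperature: float = T_WORK_DEFAULT

    def __post_init__(self):
        object.__setattr__(
            self, "forward_work", np.asarray(self.forward_work, dtype=float)
        )
        object.__setattr__(
            self, "reverse_work", np.asarray(self.reverse_work, dtype=float)
        )
        if self.temperature <= 0:
            raise InvalidInputError("temperature must be > 0")

    def require_bidirectional(self, n_min: int = 2):
        if self.forward_work.size < n_min or self.reverse_work.size < n_min:
            raise InvalidInputError(
                f"edge {self.edge_label}: need >= {n_min} samples in each "
                f"direction, got {self.forward_work.size} forward / "
                f"{self.reverse_work.size} reverse"
            )


@dataclass(frozen=True)
class FreeEnergyEstimate:
    delta_g: float
    method: str
    uncertainty: float
    n_forward: int
    n_reverse: int
    temperature: float

    def __post_init__(self):
        if self.uncertainty < 0:
            raise InvalidInputError("uncertainty must be >= 0")


@dataclass(frozen=True)
class CycleEdge:
    """One directed edge of a thermodynamic cycle (ddG in kcal/mol)."""

    from_state: str
    to_state: str
    ddg: float
    uncertainty: float = 0.0


@dataclass(frozen=True)
class ThermoCycle:
    edges: tuple

    def __post_init__(self):
        if len(self.edges) < 2:
            raise InvalidInputError("a cycle needs at least 2 edges")


@dataclass(frozen=True)
class ClosureReport:
    closure: float
    uncertainty: float
    tolerance: float
    flagged: bool


@dataclass(frozen=True)
class DdgResult:
    """ddG = dG(leg2) - dG(leg1); leg1 is the reference environment."""

    ddg: float
    delta_g1: float
    delta_g2: float
    kind: str
    uncertainty: float


def _jarzynski_core(work: np.ndarray, rt: float) -> float:
    # -RT ln <exp(-W/RT)> via log-sum-exp for numerical safety
    return float(-rt * (logsumexp(-work / rt) - math.log(work.size)))


def jarzynski(
    work: Sequence[float],
    temperature: float = T_WORK_DEFAULT,
    direction: str = "forward",
    n_bootstrap: int = 200,
    seed: int = 0,
) -> FreeEnergyEstimate:
    """Exponential-average estimator, one direction at a time.

    Forward: dG = -RT ln<exp(-W/RT)>.  Reverse works estimate the
    backward free energy; the returned value is its negation, i.e. the
    forward dG.  Uncertainty is a seeded bootstrap standard deviation.
    """
    w = np.asarray(work, dtype=float)
    if w.size == 0:
        raise InvalidInputError("work list is empty")
    if direction not in ("forward", "reverse"):
        raise InvalidInputError(f"unknown direction {direction!r}")
    rt = R_KCAL * temperature
    sign = 1.0 if direction == "forward" else -1.0
    dg = sign * _jarzynski_core(w, rt)

    if w.size > 1:
        rng = np.random.default_rng(seed)
        boots = np.empty(n_bootstrap)
        for i in range(n_bootstrap):
            boots[i] = _jarzynski_core(rng.choice(w, size=w.size, replace=True), rt)
        unc = float(np.std(boots, ddof=1))
    else:
        unc = 0.0
    method = "jarzynski_forward" if direction == "forward" else "jarzynski_reverse"
    return FreeEnergyEstimate(
        delta_g=dg,
        method=method,
        uncertainty=unc,
        n_forward=w.size if direction == "forward" else 0,
        n_reverse=w.size if direction == "reverse" else 0,
        temperature=temperature,
    )


def _gaussian_intersection(m1, s1, m2, s2):
    """Intersection abscissa of two Gaussian densities.

    Near-equal variances reduce to the midpoint of the means; otherwise
    the quadratic's root lying between the means is chosen.
    """
    if np.isclose(s1, s2, rtol=1e-6, atol=1e-12):
        return 0.5 * (m1 + m2)
    # solve (x-m1)^2/s1^2 - (x-m2)^2/s2^2 = 2 ln(s2/s1)
    A = 1.0 / s1**2 - 1.0 / s2**2
    B = -2.0 * (m1 / s1**2 - m2 / s2**2)
    C = m1**2 / s1**2 - m2**2 / s2**2 - 2.0 * math.log(s2 / s1)
    disc = B * B - 4.0 * A * C
    if disc < 0:
        raise EstimationFailureError(
            f"no real Gaussian intersection (m1={m1}, s1={s1}, m2={m2}, s2={s2})"
        )
    r1 = (-B + math.sqrt(disc)) / (2.0 * A)
    r2 = (-B - math.sqrt(disc)) / (2.0 * A)
    lo, hi = min(m1, m2), max(m1, m2)
    for r in (r1, r2):
        if lo <= r <= hi:
            return r
    # fall back to the root closest to the midpoint of the means
    mid = 0.5 * (m1 + m2)
    return min((r1, r2), key=lambda r: abs(r - mid))


def crooks_gaussian_intersection(
    workset: WorkSet, n_bootstrap: int = 200, seed: int = 0
) -> FreeEnergyEstimate:
    """dG at the intersection of N(Wf) and N(-Wr) fitted Gaussians."""
    workset.require_bidirectional()
    wf = workset.forward_work
    wr_neg = -workset.reverse_work

    def estimate(f, r):
        return _gaussian_intersection(
            float(np.mean(f)),
            max(float(np.std(f, ddof=1)), 1e-12),
            float(np.mean(r)),
            max(float(np.std(r, ddof=1)), 1e-12),
        )

    dg = estimate(wf, wr_neg)
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_bootstrap):
        try:
            boots.append(
                estimate(
                    rng.choice(wf, size=wf.size, replace=True),
                    rng.choice(wr_neg, size=wr_neg.size, replace=True),
                )
            )
        except EstimationFailureError:
            continue
    unc = float(np.std(boots, ddof=1)) if len(boots) > 1 else 0.0
    return FreeEnergyEstimate(
        delta_g=float(dg),
        method="cgi",
        uncertainty=unc,
        n_forward=wf.size,
        n_reverse=workset.reverse_work.size,
        temperature=workset.temperature,
    )


def _bar_objective(dg, wf, wr, m, beta):
    # logistic f(x) = 1/(1+exp(x)); both sums are O(n), keep vectorized
    xf = beta * (m + wf - dg)
    xr = beta * (-m + wr + dg)
    with np.errstate(over="ignore"):
        sf = np.sum(1.0 / (1.0 + np.exp(xf)))
        sr = np.sum(1.0 / (1.0 + np.exp(xr)))
    return sf - sr


def bar(workset: WorkSet) -> FreeEnergyEstimate:
    """Bennett acceptance ratio: maximum-likelihood two-sided estimator.

    Solves sum_i f(beta(M + Wf_i - dG)) = sum_j f(beta(-M + Wr_j + dG))
    with f the logistic function and M = RT ln(n_f/n_r), by bracketed
    root finding; reports the asymptotic standard error.
    """
    workset.require_bidirectional()
    wf = workset.forward_work
    wr = workset.reverse_work
    rt = R_KCAL * workset.temperature
    beta = 1.0 / rt
    m = rt * math.log(wf.size / wr.size)

    lo = min(float(wf.min()), float(-wr.max())) - 10.0 * rt
    hi = max(float(wf.max()), float(-wr.min())) + 10.0 * rt
    flo = _bar_objective(lo, wf, wr, m, beta)
    fhi = _bar_objective(hi, wf, wr, m, beta)
    for _ in range(60):
        if flo * fhi <= 0:
            break
        lo -= 10.0 * rt
        hi += 10.0 * rt
        flo = _bar_objective(lo, wf, wr, m, beta)
        fhi = _bar_objective(hi, wf, wr, m, beta)
    else:
        raise EstimationFailureError("BAR self-consistency equation has no root")
    dg = brentq(
        _bar_objective, lo, hi, args=(wf, wr, m, beta), xtol=1e-10, rtol=8.9e-16
    )

    # Bennett asymptotic variance; all samples mapped to the forward frame.
    t_all = beta * (m + np.concatenate([wf, -wr]) - dg)
    u = 1.0 / (2.0 + 2.0 * np.cosh(np.clip(t_all, -700, 700)))
    su = float(np.sum(u))
    if su <= 1e-300:
        raise EstimationFailureError(
            "work distributions do not overlap; collect more sampling"
        )
    var = (1.0 / su - (1.0 / wf.size + 1.0 / wr.size)) / beta**2
    unc = math.sqrt(max(var, 0.0))
    return FreeEnergyEstimate(
        delta_g=float(dg),
        method="bar",
        uncertainty=unc,
        n_forward=wf.size,
        n_reverse=wr.size,
        temperature=workset.temperature,
    )


def ddg_from_legs(
    leg1: FreeEnergyEstimate,
    leg2: FreeEnergyEstimate,
    kind: str = "folding",
    replica_ddgs: Optional[Sequence[float]] = None,
) -> DdgResult:
    """ddG = dG2 - dG1 for a two-leg thermodynamic cycle.

    Leg 1 is the reference environment (unfolded tripeptide, or free
    protein); leg 2 the folded protein or the complex.  Uncertainty is
    combined in quadrature, or the standard deviation across replica
    ddG estimates when those are supplied.
    """
    if kind not in ("folding", "affinity"):
        raise InvalidInputError(f"kind must be 'folding' or 'affinity', got {kind!r}")
    if not math.isclose(leg1.temperature, leg2.temperature, rel_tol=1e-9):
        raise InvalidInputError(
            f"leg temperatures differ: {leg1.temperature} K vs {leg2.temperature} K"
        )
    ddg = leg2.delta_g - leg1.delta_g
    if replica_ddgs is not None:
        reps = np.asarray(replica_ddgs, dtype=float)
        if reps.size < 2:
            raise InvalidInputError("need >= 2 replica estimates")
        unc = float(np.std(reps, ddof=1))
    else:
        unc = math.hypot(leg1.uncertainty, leg2.uncertainty)
    return DdgResult(
        ddg=float(ddg),
        delta_g1=leg1.delta_g,
        delta_g2=leg2.delta_g,
        kind=kind,
        uncertainty=unc,
    )


def cycle_closure(cycle: ThermoCycle, tolerance: float = 0.5) -> ClosureReport:
    """Signed sum of ddG values around a closed path of edges.

    Edges may be stored in either orientation; an edge traversed against
    its direction contributes with a flipped sign.  An open path raises,
    naming the state where the walk breaks.
    """
    edges = list(cycle.edges)
    start = edges[0].from_state
    current = start
    total = 0.0
    var = 0.0
    for e in edges:
        if e.from_state == current:
            total += e.ddg
            current = e.to_state
        elif e.to_state == current:
            total -= e.ddg
            current = e.from_state
        else:
            raise InvalidInputError(
                f"cycle breaks at state {current!r}: edge "
                f"{e.from_state}->{e.to_state} does not touch it"
            )
        var += e.uncertainty**2
    if current != start:
        raise InvalidInputError(
            f"path does not return to start: ends at {current!r}, began at {start!r}"
        )
    unc = math.sqrt(var)
    return ClosureReport(
        closure=float(total),
        uncertainty=unc,
        tolerance=float(tolerance),
        flagged=bool(abs(total) > tolerance),
    )
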