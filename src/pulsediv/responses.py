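"""Species-level disturbance responses and community response summaries.

Two notions of a species' response to the pulse:

* *fundamental* — the change in intrinsic growth rate between the disturbed
  and the control environment (IGR effect), measured in isolation;
* *realised* — the time-integrated (trapezoidal AUC over time normalized to
  [0, 1]) response ratio RR = (treat - con)/(treat + con) of its biomass in
  the disturbed vs the control community, bounded in [-1, 1].

Community summaries over a vector of responses:

* *mean response* — arithmetic mean; zero indicates balance of declines and
  gains;
* *dissimilarity* — Leinster-Cobbold diversity (sensitivity q = 0 by
  default) of a similarity matrix built from pairwise distances between
  responses; 1 when all species respond identically, 2 at a maximal
  two-point split;
* *divergence* — the extent to which declines are offset by gains,
  ((max-min) - ||max|-|min||)/(max-min) in [0, 1]; 0 when all responses
  share one sign, 1 when the extremes are equal and opposite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .community import SpeciesParams, intrinsic_growth_rate
from .simulate import TrajectoryPair

__all__ = [
    "SpeciesResponse",
    "ResponseSummary",
    "response_ratio",
    "auc",
    "normalize_times",
    "realised_response",
    "realised_responses",
    "fundamental_response",
    "mean_response",
    "dissimilarity",
    "divergence",
    "summarise_responses",
]


@dataclass(frozen=True)
class SpeciesResponse:
    """One species' fundamental and realised response to the disturbance."""

    species_id: int
    realised: float
    fundamental: float | None = None  # absent for empirical data
    included: bool = True


@dataclass(frozen=True)
class ResponseSummary:
    """Community-level summary of one response basis."""

    basis: str  # "fundamental" | "realised"
    mean: float
    dissimilarity: float
    divergence: float
    n_species: int


def response_ratio(treat, con):
    """RR = (treat - con) / (treat + con), elementwise; 0 where both are 0."""
    treat = np.asarray(treat, dtype=float)
    con = np.asarray(con, dtype=float)
    if np.any(treat < 0) or np.any(con < 0):
        raise ValueError("abundances must be non-negative")
    total = treat + con
    out = np.divide(treat - con, total, out=np.zeros_like(total), where=total > 0)
    return float(out) if out.ndim == 0 else out


def auc(times, y) -> float:
    """Signed trapezoidal area under ``y`` over ``times`` (strictly increasing)."""
    times = np.asarray(times, dtype=float)
    y = np.asarray(y, dtype=float)
    if times.ndim != 1 or times.shape != y.shape:
        raise ValueError("times and y must be 1-D and of equal length")
    if times.size < 2:
        raise ValueError("need at least two time points")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    return float(np.trapezoid(y, times))


def normalize_times(times) -> np.ndarray:
    """Affine map of a strictly increasing time vector onto [0, 1]."""
    times = np.asarray(times, dtype=float)
    if times.size < 2 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing with >= 2 points")
    return (times - times[0]) / (times[-1] - times[0])


def realised_response(times, control, treatment) -> float:
    """AUC of the per-time-point response ratio over normalized time, in [-1, 1]."""
    t = normalize_times(times)
    rr = response_ratio(treatment, control)
    return auc(t, rr)


def realised_responses(traj: TrajectoryPair) -> np.ndarray:
    """Realised response of every species over the trajectory's analysis window."""
    t = normalize_times(traj.window_times)
    rr = response_ratio(traj.window_disturbed, traj.window_control)
    return np.trapezoid(rr, t, axis=0)


def fundamental_response(
    sp: SpeciesParams, T_disturbed: float = 15.0, T_control: float = 22.0
) -> float:
    """IGR effect: intrinsic growth rate in the disturbed minus the control
    environment."""
    return intrinsic_growth_rate(sp, T_disturbed) - intrinsic_growth_rate(sp, T_control)


def mean_response(x) -> float:
    """Arithmetic mean of species responses."""
    x = np.asarray(x, dtype=float)
    if x.size < 1:
        raise ValueError("need at least one response value")
    return float(np.mean(x))


def dissimilarity(x, q: float = 0.0) -> float:
    """Response dissimilarity via similarity-sensitive (Leinster-Cobbold)
    diversity.

    Pairwise distances between responses are rescaled by their maximum,
    converted to a similarity matrix Z = 1 - d, and combined with uniform
    weights p_i = 1/S. The species' ordinariness is (Zp)_i = sum_j Z_ij p_j
    and the diversity of order ``q`` is
    ``(sum_i p_i (Zp)_i**(q-1)) ** (1/(1-q))`` (at q = 0:
    ``sum_i p_i / (Zp)_i``; the q = 1 limit is the exponential form). For
    scalar responses the result lies in [1, 2]; it is 1 iff all responses
    are equal.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("dissimilarity requires at least two species")
    S = x.size
    d = np.abs(x[:, None] - x[None, :])
    dmax = d.max()
    if dmax == 0.0:
        return 1.0
    Z = 1.0 - d / dmax
    p = np.full(S, 1.0 / S)
    Zp = Z @ p
    if q == 1.0:
        return float(np.exp(-np.sum(p * np.log(Zp))))
    return float(np.sum(p * Zp ** (q - 1.0)) ** (1.0 / (1.0 - q)))


def divergence(x) -> float:
    """Response divergence: how far declines are offset by gains.

    With a = max(x), b = min(x): 0 if a == b, else
    ((a - b) - ||a| - |b||) / (a - b). Zero when all responses share one
    sign; one iff a == -b. Invariant under negation and positive scaling.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("divergence requires at least two species")
    a, b = float(np.max(x)), float(np.min(x))
    if a == b:
        return 0.0
    return ((a - b) - abs(abs(a) - abs(b))) / (a - b)


def summarise_responses(x, basis: str) -> ResponseSummary:
    """Mean, dissimilarity and divergence of one response vector."""
    x = np.asarray(x, dtype=float)
    n = int(x.size)
    if n >= 2:
        dis, div = dissimilarity(x), divergence(x)
    else:
        dis, div = float("nan"), float("nan")
    return ResponseSummary(
        basis=basis,
        mean=mean_response(x),
        dissimilarity=dis,
        divergence=div,
        n_species=n,
    )
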