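"""Paired control/pulse simulations of discrete-time Lotka-Volterra dynamics.

The update rule is the Ricker-form competitive Lotka-Volterra map

    N_i(t+1) = N_i(t) * exp( r_i(T) * (1 - sum_j alpha_ij N_j(t) / K_i(T)) )

with temperature-dependent intrinsic growth rate ``r_i(T)`` and carrying
capacity ``K_i(T)``. The exponential form keeps abundances non-negative and
zero is absorbing. Dynamics are deterministic: all randomness lives in
community assembly.

Each community is simulated twice with identical initial conditions: a
control run at constant temperature and a disturbed run in which temperature
drops to the pulse value for a fixed window (default: 22 degC baseline,
15 degC for 50 steps starting at step 500 of 750, after a 500-step
equilibration). Only time points at/after pulse onset enter the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .community import Community, carrying_capacity

__all__ = [
    "TemperatureProfile",
    "TrajectoryPair",
    "SimulationDivergedError",
    "AllSpeciesExcludedError",
    "temperature_at",
    "step",
    "run_pair",
    "filter_rare_species",
    "DEFAULT_PROFILE",
]


class SimulationDivergedError(RuntimeError):
    """Raised when the dynamics produce a non-finite abundance."""


class AllSpeciesExcludedError(ValueError):
    """Raised when the rare-species filter removes every species."""


@dataclass(frozen=True)
class TemperatureProfile:
    """Pulse-disturbance temperature schedule.

    The disturbed run is at ``T_pulse`` for steps in the half-open window
    ``[t_onset, t_onset + pulse_len)`` and at ``T_control`` otherwise; the
    control run is at ``T_control`` throughout. ``pulse_len = 0`` is a
    control profile.
    """

    T_control: float = 22.0
    T_pulse: float = 15.0
    t_total: int = 750
    t_onset: int = 500
    pulse_len: int = 50

    def __post_init__(self) -> None:
        if self.t_onset <= 0:
            raise ValueError("t_onset must be positive")
        if self.pulse_len < 0:
            raise ValueError("pulse_len must be >= 0")
        if self.t_onset + self.pulse_len > self.t_total:
            raise ValueError("pulse must end at or before t_total")

    @property
    def t_pulse_end(self) -> int:
        return self.t_onset + self.pulse_len


DEFAULT_PROFILE = TemperatureProfile()


def temperature_at(profile: TemperatureProfile, t: int, disturbed: bool) -> float:
    """Temperature at step ``t`` under the control or disturbed schedule."""
    if not (0 <= t <= profile.t_total):
        raise ValueError(f"t={t} outside [0, {profile.t_total}]")
    if disturbed and profile.t_onset <= t < profile.t_pulse_end:
        return profile.T_pulse
    return profile.T_control


def _ricker_step(N: np.ndarray, r: np.ndarray, K: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    return N * np.exp(r * (1.0 - (alpha @ N) / K))


def step(community: Community, N, T: float) -> np.ndarray:
    """One Ricker-Lotka-Volterra update of the abundance vector at temperature ``T``."""
    N = np.asarray(N, dtype=float)
    if N.shape != (community.S,):
        raise ValueError(f"N must have shape ({community.S},), got {N.shape}")
    if np.any(N < 0):
        raise ValueError("abundances must be non-negative")
    r, K = community.rates_at(T)
    out = _ricker_step(N, r, K, community.alpha)
    if not np.all(np.isfinite(out)):
        raise SimulationDivergedError(
            f"non-finite abundance at T={T} for community "
            f"(alpha_sd={community.alpha_sd}, bopt_mean={community.bopt_mean}, "
            f"bopt_range={community.bopt_range}, replicate={community.replicate_id}, "
            f"seed={community.seed})"
        )
    return out


@dataclass
class TrajectoryPair:
    """Paired control/disturbed abundance trajectories for one community.

    ``N_control`` and ``N_disturbed`` are (t_total+1, S) matrices indexed by
    step; the two are identical for every t < t_onset. The analysis window is
    ``[t_onset, t_total]``.
    """

    times: np.ndarray
    N_control: np.ndarray
    N_disturbed: np.ndarray
    community: Community
    profile: TemperatureProfile

    @property
    def window(self) -> slice:
        return slice(self.profile.t_onset, self.profile.t_total + 1)

    @property
    def window_times(self) -> np.ndarray:
        return self.times[self.window]

    @property
    def window_control(self) -> np.ndarray:
        return self.N_control[self.window]

    @property
    def window_disturbed(self) -> np.ndarray:
        return self.N_disturbed[self.window]


def run_pair(
    community: Community,
    profile: TemperatureProfile = DEFAULT_PROFILE,
    N0: np.ndarray | None = None,
) -> TrajectoryPair:
    """Run the control and disturbed simulations for one community.

    Initial abundances default to ``K_i(T_control) / S``. The pre-onset
    segment is shared between the two runs (the schedules are identical
    there), so it is simulated once.
    """
    S = community.S
    if N0 is None:
        K0 = np.array([carrying_capacity(sp, profile.T_control) for sp in community.species])
        N0 = K0 / S
    N0 = np.asarray(N0, dtype=float)
    if np.any(N0 <= 0):
        raise ValueError("initial abundances must be strictly positive")

    r_c, K_c = community.rates_at(profile.T_control)
    r_p, K_p = community.rates_at(profile.T_pulse)
    alpha = community.alpha

    T_total, onset, pulse_end = profile.t_total, profile.t_onset, profile.t_pulse_end
    N_control = np.empty((T_total + 1, S))
    N_control[0] = N0
    for t in range(T_total):
        N_control[t + 1] = _ricker_step(N_control[t], r_c, K_c, alpha)

    N_disturbed = N_control.copy()
    for t in range(onset, T_total):
        r, K = (r_p, K_p) if t < pulse_end else (r_c, K_c)
        N_disturbed[t + 1] = _ricker_step(N_disturbed[t], r, K, alpha)

    if not (np.all(np.isfinite(N_control)) and np.all(np.isfinite(N_disturbed))):
        raise SimulationDivergedError(
            f"non-finite trajectory for community (alpha_sd={community.alpha_sd}, "
            f"bopt_mean={community.bopt_mean}, bopt_range={community.bopt_range}, "
            f"replicate={community.replicate_id}, seed={community.seed})"
        )

    return TrajectoryPair(
        times=np.arange(T_total + 1),
        N_control=N_control,
        N_disturbed=N_disturbed,
        community=community,
        profile=profile,
    )


def filter_rare_species(
    traj: TrajectoryPair,
    min_entries: int = 10,
    threshold: float = 1e-3,
    series: str = "union",
) -> np.ndarray:
    """Boolean mask of species retained for realised-response calculations.

    A species is kept if, within the analysis window, it has at least
    ``min_entries`` time points with abundance above ``threshold``
    ("fewer than ``min_entries``" are removed). ``series`` chooses which
    arm(s) count a time point: "union" (either arm above threshold, default),
    "control", or "disturbed". The mask is never applied to community totals.
    """
    con = traj.window_control > threshold
    dis = traj.window_disturbed > threshold
    if series == "union":
        present = con | dis
    elif series == "control":
        present = con
    elif series == "disturbed":
        present = dis
    else:
        raise ValueError(f"unknown series mode {series!r}")
    mask = present.sum(axis=0) >= min_entries
    if not mask.any():
        raise AllSpeciesExcludedError(
            "rare-species filter excluded every species in the community"
        )
    return mask
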