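"""Community-level (in)stability: signed OEV and its decomposition.

Overall Ecological Vulnerability (OEV) is the signed area under the curve of
the community-level response ratio

    tot.RR(t) = (Treat.Tot - Con.Tot) / (Treat.Tot + Con.Tot)

over time normalized to [0, 1], where the totals sum biomass across *all*
species (no rare-species filter). OEV = 0 means no net deviation from
control; the signed version keeps negative and positive deviations distinct,
and the absolute variant integrates |tot.RR|.

The decomposition into classical stability dimensions:

* resistance — tot.RR at the first sample at/after disturbance onset;
* resilience — OLS slope of tot.RR against normalized time over the recovery
  phase (from pulse end, or from the first post-onset sample when no pulse
  end is known, to the last sample);
* temporal stability — inverse coefficient of variation (mean/sd) of the
  disturbed community's total biomass over the window;
* recovery — tot.RR at the final sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .responses import auc, normalize_times, response_ratio
from .simulate import TrajectoryPair

__all__ = [
    "StabilityRecord",
    "total_response_ratio",
    "oev",
    "decompose",
    "stability_record",
]


@dataclass(frozen=True)
class StabilityRecord:
    """Stability metrics for one community/experiment; NaN marks undefined
    values (e.g. zero-variance biomass or too few recovery samples)."""

    oev: float
    oev_abs: float
    resistance: float
    resilience: float
    temporal_stability: float
    recovery: float


def total_response_ratio(control_matrix, disturbed_matrix) -> np.ndarray:
    """tot.RR per time point from (time x species) abundance matrices."""
    con = np.asarray(control_matrix, dtype=float)
    dis = np.asarray(disturbed_matrix, dtype=float)
    if con.shape != dis.shape or con.size == 0:
        raise ValueError("control and disturbed matrices must share a non-empty shape")
    return response_ratio(dis.sum(axis=1), con.sum(axis=1))


def _abs_auc(t: np.ndarray, y: np.ndarray) -> float:
    """Area under |y| for the piecewise-linear curve through (t, y).

    Zero crossings of the interpolated curve are inserted before taking the
    trapezoidal integral, so a segment from -y0 to +y1 contributes the two
    triangle areas rather than the trapezoid of the endpoint magnitudes.
    """
    total = 0.0
    for i in range(t.size - 1):
        y0, y1 = y[i], y[i + 1]
        dt = t[i + 1] - t[i]
        if y0 * y1 < 0:  # crossing at fraction |y0|/(|y0|+|y1|)
            total += 0.5 * dt * (y0 * y0 + y1 * y1) / (abs(y0) + abs(y1))
        else:
            total += 0.5 * dt * (abs(y0) + abs(y1))
    return float(total)


def oev(times, tot_rr) -> tuple[float, float]:
    """Signed and absolute AUC of tot.RR over time normalized to [0, 1].

    The absolute variant integrates |tot.RR| along the interpolated curve
    (zero crossings contribute no spurious area), so deviations of opposite
    sign accumulate instead of cancelling.
    """
    t = normalize_times(times)
    tot_rr = np.asarray(tot_rr, dtype=float)
    return auc(t, tot_rr), _abs_auc(t, tot_rr)


def decompose(
    times,
    tot_rr,
    disturbed_totals=None,
    recovery_from: float | None = None,
) -> StabilityRecord:
    """Stability decomposition from a tot.RR series on an analysis window.

    ``recovery_from`` is the normalized time at which the recovery-phase
    regression starts (the pulse end for simulated data); ``None`` regresses
    over the whole window, the convention for empirical series where the
    pulse precedes the first post-onset sample. ``disturbed_totals`` (total
    biomass of the disturbed community per time point) feeds temporal
    stability; if omitted, temporal stability is NaN.
    """
    t = normalize_times(times)
    tot_rr = np.asarray(tot_rr, dtype=float)
    if t.size < 3:
        raise ValueError("decomposition needs at least three time points")
    signed, absolute = auc(t, tot_rr), _abs_auc(t, tot_rr)

    resistance = float(tot_rr[0])
    recovery = float(tot_rr[-1])

    start = 0.0 if recovery_from is None else float(recovery_from)
    in_phase = t >= start - 1e-12
    if in_phase.sum() >= 2:
        resilience = float(np.polyfit(t[in_phase], tot_rr[in_phase], 1)[0])
    else:
        resilience = float("nan")

    if disturbed_totals is not None:
        totals = np.asarray(disturbed_totals, dtype=float)
        sd = float(np.std(totals, ddof=1))
        temporal_stability = float(np.mean(totals) / sd) if sd > 0 else float("nan")
    else:
        temporal_stability = float("nan")

    return StabilityRecord(
        oev=signed,
        oev_abs=absolute,
        resistance=resistance,
        resilience=resilience,
        temporal_stability=temporal_stability,
        recovery=recovery,
    )


def stability_record(traj: TrajectoryPair) -> StabilityRecord:
    """OEV and decomposition for a simulated trajectory pair (analysis window
    from pulse onset to the end; recovery regression from pulse end)."""
    times = traj.window_times
    tot_rr = total_response_ratio(traj.window_control, traj.window_disturbed)
    p = traj.profile
    span = p.t_total - p.t_onset
    recovery_from = (p.t_pulse_end - p.t_onset) / span if span > 0 else 0.0
    return decompose(
        times,
        tot_rr,
        disturbed_totals=traj.window_disturbed.sum(axis=1),
        recovery_from=recovery_from,
    )
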