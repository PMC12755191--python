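"""Synthetic meta-analysis-style experiments with known ground truth.

Each synthetic experiment mimics one pulse-disturbance experiment from a
meta-analysis database: a handful of species observed at >= 3 sampling times
(normalized to [0, 1], always including 0 and 1) in a paired
control/disturbed design. Treatment series are constructed by *inverting*
the response-ratio formula,

    treatment_i(t) = control_i(t) * (1 + RR_i(t)) / (1 - RR_i(t)),

so each species' true response ratio is an exactly known profile
``RR_i(t) = delta_i * exp(-rho_i * t)`` (initial drop ``|delta| < 1``,
recovery rate ``rho >= 0``). Since |RR| < 1, treatment abundances stay
positive. Multiplicative lognormal noise is applied independently to both
arms; noise-free mode gives exact round-trips.

``generate_dataset`` additionally embeds a linear instability-vs-mean-
response relation: per experiment it draws a mean response m_e, targets a
community OEV of beta0 + beta1 * m_e + noise, and solves for species
response values and control abundances that realise both the mean and the
OEV exactly (time-constant response ratios, so the weighted-mean identity
tot.RR = sum(c_i d_i/(1-d_i)) / sum(c_i/(1-d_i)) applies). Downstream
regression can then be checked against the embedded coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EmpiricalExperiment",
    "GeneratorConfig",
    "rr_profile",
    "rr_profile_auc",
    "generate_experiment",
    "generate_dataset",
    "dataset_to_frame",
]


@dataclass
class EmpiricalExperiment:
    """One meta-analysis-style experiment with paired series.

    ``control`` and ``treatment`` are (m, S) matrices over the normalized
    sampling times; >= 3 sampling times and both arms are required.
    """

    experiment_id: str
    times: np.ndarray
    control: np.ndarray
    treatment: np.ndarray
    species: tuple[str, ...]
    response_unit: str = "abundance"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.control = np.asarray(self.control, dtype=float)
        self.treatment = np.asarray(self.treatment, dtype=float)
        if self.times.size < 3:
            raise ValueError("an experiment needs at least 3 sampling times")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("sampling times must be strictly increasing")
        m, S = self.control.shape
        if self.treatment.shape != (m, S) or m != self.times.size:
            raise ValueError("control/treatment must be (n_times, n_species)")
        if len(self.species) != S:
            raise ValueError("species names must match the matrices")
        if np.any(self.control < 0) or np.any(self.treatment < 0):
            raise ValueError("abundances must be non-negative")
        if self.response_unit not in {"abundance", "biomass"}:
            raise ValueError("response_unit must be 'abundance' or 'biomass'")

    @property
    def S(self) -> int:
        return len(self.species)


@dataclass(frozen=True)
class GeneratorConfig:
    """Conditions for the synthetic meta-analysis database.

    Defaults emulate the empirical database's shape: 134 experiments, a few
    to a dozen species and sampling times each, mostly negative mean
    responses, and a positive instability-vs-mean-response relation of slope
    ~1 on the OEV scale.
    """

    n_experiments: int = 134
    s_range: tuple[int, int] = (3, 12)
    m_range: tuple[int, int] = (3, 12)
    delta_spread: float = 0.35
    mean_response_range: tuple[float, float] = (-0.55, 0.25)
    rho_range: tuple[float, float] = (0.0, 3.0)
    drift_range: tuple[float, float] = (-0.3, 0.3)
    base_abundance_sd: float = 0.5
    noise_sd: float = 0.1
    beta0: float = 0.0
    beta1: float = 0.97
    oev_noise_sd: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_experiments < 1:
            raise ValueError("need at least one experiment")
        if not (0 < self.delta_spread < 1):
            raise ValueError("delta_spread must be in (0, 1)")
        if self.noise_sd < 0 or self.oev_noise_sd < 0:
            raise ValueError("noise sds must be non-negative")
        if self.m_range[0] < 3:
            raise ValueError("experiments need >= 3 sampling times")
        if self.s_range[0] < 2:
            raise ValueError("experiments need >= 2 species")


def rr_profile(delta: float, rho: float, t):
    """Response-ratio profile ``delta * exp(-rho * t)`` on normalized time."""
    if not abs(delta) < 1:
        raise ValueError("|delta| must be < 1")
    if rho < 0:
        raise ValueError("rho must be >= 0")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t > 1):
        raise ValueError("t must lie in [0, 1]")
    out = delta * np.exp(-rho * t)
    return float(out) if out.ndim == 0 else out


def rr_profile_auc(delta: float, rho: float) -> float:
    """Analytic integral of ``rr_profile`` over [0, 1]."""
    if rho == 0:
        return float(delta)
    return float(delta * (1.0 - np.exp(-rho)) / rho)


def _sample_times(m: int, rng: np.random.Generator) -> np.ndarray:
    """m normalized sampling times always including 0 and 1, interior uniform."""
    interior = np.sort(rng.uniform(0.0, 1.0, size=m - 2))
    # nudge any coincident interior points apart so times stay strictly increasing
    times = np.concatenate([[0.0], interior, [1.0]])
    for i in range(1, m):
        if times[i] <= times[i - 1]:
            times[i] = np.nextafter(times[i - 1], 1.0)
    return times


def generate_experiment(
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    experiment_id: str = "exp0",
    deltas: np.ndarray | None = None,
    rhos: np.ndarray | None = None,
    base_abundances: np.ndarray | None = None,
    n_times: int | None = None,
) -> tuple[EmpiricalExperiment, pd.DataFrame]:
    """Generate one experiment plus its ground-truth table.

    When ``deltas``/``rhos`` are omitted they are drawn from the config
    ranges. Control series are smooth and positive (per-species base
    abundance times a shared exponential drift), treatment series invert the
    response-ratio formula, and lognormal noise is applied to both arms if
    ``cfg.noise_sd > 0``. The truth table carries each species' analytic
    realised response and the experiment's true (noise-free) OEV and mean
    response.
    """
    if deltas is None:
        lo, hi = cfg.mean_response_range
        deltas = rng.uniform(lo - cfg.delta_spread, hi + cfg.delta_spread, size=int(rng.integers(cfg.s_range[0], cfg.s_range[1] + 1)))
        deltas = np.clip(deltas, -0.95, 0.95)
    deltas = np.asarray(deltas, dtype=float)
    if np.any(np.abs(deltas) >= 1):
        raise ValueError("|delta| must be < 1 for every species")
    S = deltas.size
    if rhos is None:
        rhos = rng.uniform(*cfg.rho_range, size=S)
    rhos = np.asarray(rhos, dtype=float)
    if np.any(rhos < 0):
        raise ValueError("rho must be >= 0")
    if base_abundances is None:
        base_abundances = np.exp(rng.normal(0.0, cfg.base_abundance_sd, size=S))
    base_abundances = np.asarray(base_abundances, dtype=float)

    m = int(n_times) if n_times is not None else int(
        rng.integers(cfg.m_range[0], cfg.m_range[1] + 1)
    )
    times = _sample_times(m, rng)

    drift = rng.uniform(*cfg.drift_range)
    trend = np.exp(drift * times)  # shared smooth control dynamics
    control = base_abundances[None, :] * trend[:, None]
    rr = np.stack([rr_profile(d, r, times) for d, r in zip(deltas, rhos)], axis=1)
    treatment = control * (1.0 + rr) / (1.0 - rr)

    # true (noise-free) community-level response ratio and OEV
    tot_rr = (treatment.sum(axis=1) - control.sum(axis=1)) / (
        treatment.sum(axis=1) + control.sum(axis=1)
    )
    true_oev = float(np.trapezoid(tot_rr, times))
    true_realised = np.array([rr_profile_auc(d, r) for d, r in zip(deltas, rhos)])

    if cfg.noise_sd > 0:
        control = control * np.exp(rng.normal(0.0, cfg.noise_sd, size=control.shape))
        treatment = treatment * np.exp(
            rng.normal(0.0, cfg.noise_sd, size=treatment.shape)
        )

    species = tuple(f"sp{i + 1}" for i in range(S))
    exp = EmpiricalExperiment(
        experiment_id=experiment_id,
        times=times,
        control=control,
        treatment=treatment,
        species=species,
    )
    truth = pd.DataFrame(
        {
            "experiment_id": experiment_id,
            "species": species,
            "delta": deltas,
            "rho": rhos,
            "true_realised": true_realised,
            "true_mean_response": float(np.mean(true_realised)),
            "true_oev": true_oev,
        }
    )
    return exp, truth


def _embedding_deltas(
    m_e: float, spread: float, S: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Response values with exact mean ``m_e`` and jittered spread.

    Built as paired deviations ``m_e +- spread*u_j`` (u ~ U(0.5, 1)), plus
    one species exactly at ``m_e`` when S is odd, so the unweighted mean is
    ``m_e`` for any S while the values stay multi-valued (dissimilarity and
    divergence vary across experiments).
    """
    k = S // 2
    u = spread * rng.uniform(0.5, 1.0, size=k)
    deltas = np.concatenate(
        [m_e + u, m_e - u, [m_e] if S % 2 else []]
    )
    groups = np.concatenate([np.ones(k, dtype=int), np.zeros(S - k, dtype=int)])
    return deltas, groups


def generate_dataset(
    cfg: GeneratorConfig,
) -> tuple[list[EmpiricalExperiment], pd.DataFrame]:
    """Generate the full synthetic database plus its ground-truth table.

    Per experiment, the true mean realised response m_e is drawn uniformly
    from ``cfg.mean_response_range`` and the true OEV is targeted at
    ``beta0 + beta1 * m_e + eps`` (eps ~ N(0, oev_noise_sd), clipped into
    the attainable span of the species responses). Species response ratios
    are time-constant (rho = 0) so both the mean and the OEV are embedded
    exactly in the noise-free series; lognormal measurement noise is then
    applied per ``cfg.noise_sd``.
    """
    rng = np.random.default_rng(cfg.seed)
    experiments: list[EmpiricalExperiment] = []
    truths: list[pd.DataFrame] = []
    for e in range(cfg.n_experiments):
        m_e = rng.uniform(*cfg.mean_response_range)
        eps = rng.normal(0.0, cfg.oev_noise_sd) if cfg.oev_noise_sd > 0 else 0.0
        target = cfg.beta0 + cfg.beta1 * m_e + eps

        S = int(rng.integers(cfg.s_range[0], cfg.s_range[1] + 1))
        # keep every response value inside (-1, 1)
        spread = min(cfg.delta_spread, 0.95 * (0.97 - abs(m_e)))
        deltas, groups = _embedding_deltas(m_e, spread, S, rng)

        # weights w_i = c_i/(1 - d_i) make the community response ratio the
        # weighted mean of the d_i; scale the upper group by f so that the
        # weighted mean equals the target OEV, which must lie strictly
        # between the two group-weighted means
        w = 1.0 / (1.0 - deltas)
        hi, lo = groups == 1, groups == 0
        A1, A0 = float((deltas * w)[hi].sum()), float(w[hi].sum())
        B1, B0 = float((deltas * w)[lo].sum()), float(w[lo].sum())
        mu_hi, mu_lo = A1 / A0, B1 / B0
        margin = 0.05 * (mu_hi - mu_lo)
        target = float(np.clip(target, mu_lo + margin, mu_hi - margin))
        f = (B1 - target * B0) / (target * A0 - A1)
        base = np.where(hi, f, 1.0)
        base = base * np.exp(rng.normal(0.0, cfg.base_abundance_sd))  # overall scale

        exp, truth = generate_experiment(
            cfg,
            rng,
            experiment_id=f"exp{e + 1}",
            deltas=deltas,
            rhos=np.zeros(S),
            base_abundances=base,
        )
        truth["target_oev"] = target
        truths.append(truth)
        experiments.append(exp)
    truth_table = pd.concat(truths, ignore_index=True)
    return experiments, truth_table


def dataset_to_frame(experiments: list[EmpiricalExperiment]) -> pd.DataFrame:
    """Long-format table (experiment_id, treatment, time, species, value)."""
    rows = []
    for exp in experiments:
        for arm, matrix in (("control", exp.control), ("disturbed", exp.treatment)):
            for j, name in enumerate(exp.species):
                for t, v in zip(exp.times, matrix[:, j]):
                    rows.append(
                        {
                            "experiment_id": exp.experiment_id,
                            "treatment": arm,
                            "time": t,
                            "species": name,
                            "value": v,
                        }
                    )
    return pd.DataFrame(rows)
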