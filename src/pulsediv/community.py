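"""Species thermal biology and randomized community assembly.

A community is a set of ``S`` competing species. Each species has a Gaussian
thermal performance curve for its birth rate and for its carrying capacity,
both centred on the species' temperature optimum ``bopt``. The intrinsic
growth rate is the temperature-dependent birth rate minus a constant death
rate and can be negative far from the optimum.

Community assembly draws temperature optima from a uniform distribution with
configurable mean and range, and interspecific competition coefficients from
a left-skewed normal distribution (shape parameter -4) whose mean and
standard deviation both equal ``alpha_sd``, clipped to [0, 1]. Intraspecific
coefficients are fixed at 1, so ``alpha_sd`` sets the average strength of
purely competitive interactions.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats

__all__ = [
    "SpeciesParams",
    "Community",
    "birth_rate",
    "carrying_capacity",
    "intrinsic_growth_rate",
    "draw_temperature_optima",
    "draw_interaction_matrix",
    "skew_normal_location_scale",
    "assemble_community",
    "SKEW_SHAPE",
]

#: Shape parameter of the left-skewed normal used for competition coefficients.
SKEW_SHAPE = -4.0

# Default thermal parameters. The death rate is small enough that the
# intrinsic growth rate stays positive for |T - bopt| up to ~12.3 degC, which
# covers every temperature/optimum combination reachable in the factorial
# design (optima in [11.5, 25] degC against 15 and 22 degC); this keeps the
# discrete-time logistic dynamics stable over the whole design.
DEFAULT_BMAX = 1.0
DEFAULT_SIGMA_B = 5.0
DEFAULT_D0 = 0.05
DEFAULT_KMAX = 1.0
DEFAULT_SIGMA_K = 10.0


@dataclass(frozen=True)
class SpeciesParams:
    """Thermal biology of one species.

    Parameters
    ----------
    bopt
        Temperature optimum for birth, degC.
    bmax
        Birth rate at the optimum, per time step.
    sigma_b
        Thermal breadth (Gaussian sd) of the birth rate, degC.
    d0
        Temperature-independent death rate, per time step.
    Kmax
        Carrying capacity at the optimum, abundance units.
    sigma_K
        Thermal breadth of the carrying capacity, degC.
    """

    bopt: float
    bmax: float = DEFAULT_BMAX
    sigma_b: float = DEFAULT_SIGMA_B
    d0: float = DEFAULT_D0
    Kmax: float = DEFAULT_KMAX
    sigma_K: float = DEFAULT_SIGMA_K

    def __post_init__(self) -> None:
        if not math.isfinite(self.bopt):
            raise ValueError("bopt must be finite")
        if not (self.bmax > self.d0 >= 0.0):
            raise ValueError(
                f"require bmax > d0 >= 0 (positive growth at optimum); "
                f"got bmax={self.bmax}, d0={self.d0}"
            )
        if self.sigma_b <= 0 or self.sigma_K <= 0:
            raise ValueError("sigma_b and sigma_K must be positive")
        if self.Kmax <= 0:
            raise ValueError("Kmax must be positive")


def birth_rate(sp: SpeciesParams, T):
    """Temperature-dependent birth rate, Gaussian in ``T`` around ``bopt``."""
    T = np.asarray(T, dtype=float)
    if not np.all(np.isfinite(T)):
        raise ValueError("temperature must be finite")
    out = sp.bmax * np.exp(-((T - sp.bopt) ** 2) / (2.0 * sp.sigma_b**2))
    return float(out) if out.ndim == 0 else out


def carrying_capacity(sp: SpeciesParams, T):
    """Temperature-dependent carrying capacity, sharing the species optimum."""
    T = np.asarray(T, dtype=float)
    if not np.all(np.isfinite(T)):
        raise ValueError("temperature must be finite")
    out = sp.Kmax * np.exp(-((T - sp.bopt) ** 2) / (2.0 * sp.sigma_K**2))
    return float(out) if out.ndim == 0 else out


def intrinsic_growth_rate(sp: SpeciesParams, T):
    """Intrinsic growth rate ``r(T) = b(T) - d0``; may be negative far from
    the optimum."""
    b = birth_rate(sp, T)
    return b - sp.d0


def draw_temperature_optima(
    S: int, bopt_mean: float, bopt_range: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``S`` temperature optima uniformly on
    ``[bopt_mean - bopt_range/2, bopt_mean + bopt_range/2]``."""
    if S <= 0:
        raise ValueError(f"S must be positive, got {S}")
    if bopt_range < 0:
        raise ValueError(f"bopt_range must be non-negative, got {bopt_range}")
    half = bopt_range / 2.0
    return rng.uniform(bopt_mean - half, bopt_mean + half, size=S)


def skew_normal_location_scale(alpha_sd: float, shape: float = SKEW_SHAPE):
    """Location and scale of a skew-normal with given ``shape`` whose mean and
    standard deviation both equal ``alpha_sd``.

    From the skew-normal moments: with ``delta = shape/sqrt(1+shape^2)``,
    ``mean = loc + scale*delta*sqrt(2/pi)`` and
    ``sd = scale*sqrt(1 - 2*delta^2/pi)``.
    """
    delta = shape / math.sqrt(1.0 + shape**2)
    scale = alpha_sd / math.sqrt(1.0 - 2.0 * delta**2 / math.pi)
    loc = alpha_sd - scale * delta * math.sqrt(2.0 / math.pi)
    return loc, scale


def draw_interaction_matrix(
    S: int, alpha_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw an ``S x S`` competition matrix.

    Diagonal entries are 1 (intraspecific). Off-diagonals are drawn from a
    left-skewed normal with mean and sd both equal to ``alpha_sd`` and clipped
    to [0, 1] (purely competitive). ``alpha_sd = 0`` yields the
    no-interactions matrix.
    """
    if S <= 0:
        raise ValueError(f"S must be positive, got {S}")
    if alpha_sd < 0:
        raise ValueError(f"alpha_sd must be non-negative, got {alpha_sd}")
    if alpha_sd == 0.0:
        alpha = np.zeros((S, S))
    else:
        loc, scale = skew_normal_location_scale(alpha_sd)
        draws = stats.skewnorm.rvs(
            SKEW_SHAPE, loc=loc, scale=scale, size=(S, S), random_state=rng
        )
        alpha = np.clip(draws, 0.0, 1.0)
    np.fill_diagonal(alpha, 1.0)
    return alpha


@dataclass
class Community:
    """One randomized community: species parameters plus interaction matrix."""

    species: tuple[SpeciesParams, ...]
    alpha: np.ndarray
    alpha_sd: float
    bopt_mean: float
    bopt_range: float
    replicate_id: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        self.species = tuple(self.species)
        self.alpha = np.asarray(self.alpha, dtype=float)
        S = len(self.species)
        if self.alpha.shape != (S, S):
            raise ValueError(
                f"alpha shape {self.alpha.shape} does not match S={S}"
            )
        if not np.allclose(np.diag(self.alpha), 1.0):
            raise ValueError("all diagonal entries of alpha must equal 1")
        off = self.alpha[~np.eye(S, dtype=bool)]
        if off.size and off.min() < 0:
            raise ValueError("off-diagonal interaction coefficients must be >= 0")
        if self.alpha_sd == 0.0 and off.size and not np.all(off == 0.0):
            raise ValueError("alpha_sd = 0 requires all off-diagonals to be 0")

    @property
    def S(self) -> int:
        return len(self.species)

    @property
    def bopt(self) -> np.ndarray:
        return np.array([sp.bopt for sp in self.species])

    def rates_at(self, T: float) -> tuple[np.ndarray, np.ndarray]:
        """Vector of intrinsic growth rates and carrying capacities at ``T``."""
        r = np.array([intrinsic_growth_rate(sp, T) for sp in self.species])
        K = np.array([carrying_capacity(sp, T) for sp in self.species])
        return r, K

    # -- JSON serialization so grid runs are resumable and auditable --------

    def to_json(self) -> str:
        payload = {
            "species": [asdict(sp) for sp in self.species],
            "alpha": self.alpha.tolist(),
            "alpha_sd": self.alpha_sd,
            "bopt_mean": self.bopt_mean,
            "bopt_range": self.bopt_range,
            "replicate_id": self.replicate_id,
            "seed": self.seed,
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "Community":
        payload = json.loads(text)
        return cls(
            species=tuple(SpeciesParams(**sp) for sp in payload["species"]),
            alpha=np.array(payload["alpha"]),
            alpha_sd=payload["alpha_sd"],
            bopt_mean=payload["bopt_mean"],
            bopt_range=payload["bopt_range"],
            replicate_id=payload["replicate_id"],
            seed=payload["seed"],
        )


def assemble_community(
    S: int,
    bopt_mean: float,
    bopt_range: float,
    alpha_sd: float,
    seed: int,
    replicate_id: int = 0,
    species_kwargs: dict | None = None,
) -> Community:
    """Draw one community (optima then interaction matrix) from ``seed``."""
    rng = np.random.default_rng(seed)
    bopts = draw_temperature_optima(S, bopt_mean, bopt_range, rng)
    alpha = draw_interaction_matrix(S, alpha_sd, rng)
    kwargs = species_kwargs or {}
    species = tuple(SpeciesParams(bopt=b, **kwargs) for b in bopts)
    return Community(
        species=species,
        alpha=alpha,
        alpha_sd=alpha_sd,
        bopt_mean=bopt_mean,
        bopt_range=bopt_range,
        replicate_id=replicate_id,
        seed=seed,
    )
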