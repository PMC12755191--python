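"""Factorial simulation design and the community-level results table.

The design crosses the interaction-strength scale ``alpha_sd`` with the mean
and range of species temperature optima, replicated with fresh community
draws. The default levels (7 x 27 x 15 x 5 replicates) enumerate 14,175
independent communities, 2,025 per interaction-strength level. Every run draws a community, simulates the paired
control/pulse trajectories, applies the rare-species filter, and records the
fundamental and realised response summaries plus the stability metrics.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .community import assemble_community
from .responses import fundamental_response, realised_responses, summarise_responses
from .simulate import (
    DEFAULT_PROFILE,
    TemperatureProfile,
    filter_rare_species,
    run_pair,
)
from .stability import stability_record

__all__ = [
    "GridDesign",
    "RunSpec",
    "build_design",
    "run_design",
    "summarize",
    "metric_rank_correlations",
    "DEFAULT_ALPHA_SD_LEVELS",
    "DEFAULT_BOPT_MEAN_LEVELS",
    "DEFAULT_BOPT_RANGE_LEVELS",
]

logger = logging.getLogger("pulsediv")

# Default factorial: 7 x 27 x 15 levels x 5 replicates = 14,175 communities
# (2,025 per interaction-strength level). Optimum means span the pulse-to-
# control temperature range; ranges span none to wide thermal spread.
DEFAULT_ALPHA_SD_LEVELS = (0.0, 0.05, 0.1, 0.15, 0.25, 0.35, 0.5)
DEFAULT_BOPT_MEAN_LEVELS = tuple(15.0 + 0.25 * i for i in range(27))  # 15..21.5
DEFAULT_BOPT_RANGE_LEVELS = tuple(0.5 * i for i in range(15))  # 0..7 degC


@dataclass(frozen=True)
class RunSpec:
    """Coordinates and derived seed of one grid run."""

    alpha_sd: float
    bopt_mean: float
    bopt_range: float
    replicate: int
    seed: int


@dataclass(frozen=True)
class GridDesign:
    """Factorial design: level lists, replicate count, and base seed."""

    alpha_sd_levels: tuple[float, ...] = DEFAULT_ALPHA_SD_LEVELS
    bopt_mean_levels: tuple[float, ...] = DEFAULT_BOPT_MEAN_LEVELS
    bopt_range_levels: tuple[float, ...] = DEFAULT_BOPT_RANGE_LEVELS
    replicates: int = 5
    base_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha_sd_levels", "bopt_mean_levels", "bopt_range_levels"):
            levels = getattr(self, name)
            object.__setattr__(self, name, tuple(float(v) for v in levels))
            if len(getattr(self, name)) == 0:
                raise ValueError(f"{name} must be non-empty")
        if any(v < 0 for v in self.alpha_sd_levels):
            raise ValueError("alpha_sd levels must be non-negative")
        if any(v < 0 for v in self.bopt_range_levels):
            raise ValueError("bopt_range levels must be non-negative")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def size(self) -> int:
        return (
            len(self.alpha_sd_levels)
            * len(self.bopt_mean_levels)
            * len(self.bopt_range_levels)
            * self.replicates
        )

    def runs(self):
        """Enumerate runs in canonical (sorted-coordinate) order with
        per-run seeds derived deterministically from the base seed."""
        for (ia, a), (im, m), (ir, r), rep in itertools.product(
            enumerate(self.alpha_sd_levels),
            enumerate(self.bopt_mean_levels),
            enumerate(self.bopt_range_levels),
            range(self.replicates),
        ):
            seq = np.random.SeedSequence((self.base_seed, ia, im, ir, rep))
            seed = int(seq.generate_state(1)[0] % (2**31))
            yield RunSpec(a, m, r, rep, seed)


def build_design(config: dict | None = None, **overrides) -> GridDesign:
    """Build a :class:`GridDesign` from a config mapping (e.g. parsed YAML).

    Recognised keys: ``alpha_sd``, ``bopt_mean``, ``bopt_range`` (level
    lists), ``replicates``, ``base_seed``. Keyword overrides win over the
    mapping; anything omitted falls back to the default factorial.
    """
    cfg = dict(config or {})
    cfg.update(overrides)
    kwargs = {}
    for key, attr in [
        ("alpha_sd", "alpha_sd_levels"),
        ("bopt_mean", "bopt_mean_levels"),
        ("bopt_range", "bopt_range_levels"),
    ]:
        if key in cfg:
            kwargs[attr] = tuple(cfg[key])
        elif attr in cfg:
            kwargs[attr] = tuple(cfg[attr])
    if "replicates" in cfg:
        kwargs["replicates"] = int(cfg["replicates"])
    if "base_seed" in cfg:
        kwargs["base_seed"] = int(cfg["base_seed"])
    return GridDesign(**kwargs)


RECORD_COLUMNS = [
    "alpha_sd",
    "bopt_mean",
    "bopt_range",
    "replicate",
    "seed",
    "n_species",
    "n_species_included",
    "fundamental_mean",
    "fundamental_dissimilarity",
    "fundamental_divergence",
    "realised_mean",
    "realised_dissimilarity",
    "realised_divergence",
    "oev",
    "oev_abs",
    "resistance",
    "resilience",
    "temporal_stability",
    "recovery",
]


def run_one(
    spec: RunSpec,
    profile: TemperatureProfile = DEFAULT_PROFILE,
    S: int = 10,
    species_kwargs: dict | None = None,
    min_entries: int = 10,
    threshold: float = 1e-3,
) -> dict:
    """Simulate one grid run and return its community record as a dict."""
    community = assemble_community(
        S=S,
        bopt_mean=spec.bopt_mean,
        bopt_range=spec.bopt_range,
        alpha_sd=spec.alpha_sd,
        seed=spec.seed,
        replicate_id=spec.replicate,
        species_kwargs=species_kwargs,
    )
    traj = run_pair(community, profile)

    fund = np.array(
        [
            fundamental_response(sp, profile.T_pulse, profile.T_control)
            for sp in community.species
        ]
    )
    fund_summary = summarise_responses(fund, "fundamental")

    mask = filter_rare_species(traj, min_entries=min_entries, threshold=threshold)
    realised = realised_responses(traj)[mask]
    real_summary = summarise_responses(realised, "realised")

    stab = stability_record(traj)

    return {
        "alpha_sd": spec.alpha_sd,
        "bopt_mean": spec.bopt_mean,
        "bopt_range": spec.bopt_range,
        "replicate": spec.replicate,
        "seed": spec.seed,
        "n_species": S,
        "n_species_included": int(mask.sum()),
        "fundamental_mean": fund_summary.mean,
        "fundamental_dissimilarity": fund_summary.dissimilarity,
        "fundamental_divergence": fund_summary.divergence,
        "realised_mean": real_summary.mean,
        "realised_dissimilarity": real_summary.dissimilarity,
        "realised_divergence": real_summary.divergence,
        "oev": stab.oev,
        "oev_abs": stab.oev_abs,
        "resistance": stab.resistance,
        "resilience": stab.resilience,
        "temporal_stability": stab.temporal_stability,
        "recovery": stab.recovery,
    }


def run_design(
    design: GridDesign,
    profile: TemperatureProfile = DEFAULT_PROFILE,
    S: int = 10,
    species_kwargs: dict | None = None,
    min_entries: int = 10,
    threshold: float = 1e-3,
    on_error: str = "skip",
) -> pd.DataFrame:
    """Run every community of the design and return the records table.

    Per-run failures are logged with their coordinates and skipped
    (``on_error="skip"``, the default) so one pathological draw cannot abort
    a grid run; ``on_error="raise"`` propagates instead.
    """
    if on_error not in {"skip", "raise"}:
        raise ValueError("on_error must be 'skip' or 'raise'")
    records = []
    for spec in design.runs():
        try:
            records.append(
                run_one(
                    spec,
                    profile=profile,
                    S=S,
                    species_kwargs=species_kwargs,
                    min_entries=min_entries,
                    threshold=threshold,
                )
            )
        except Exception:
            if on_error == "raise":
                raise
            logger.exception(
                "grid run failed at alpha_sd=%s bopt_mean=%s bopt_range=%s "
                "replicate=%s seed=%s; skipping",
                spec.alpha_sd,
                spec.bopt_mean,
                spec.bopt_range,
                spec.replicate,
                spec.seed,
            )
    return pd.DataFrame.from_records(records, columns=RECORD_COLUMNS)


_SUMMARY_METRICS = [
    "oev",
    "oev_abs",
    "fundamental_mean",
    "fundamental_dissimilarity",
    "fundamental_divergence",
    "realised_mean",
    "realised_dissimilarity",
    "realised_divergence",
]


def summarize(records: pd.DataFrame) -> pd.DataFrame:
    """Per-``alpha_sd`` stratum means of OEV, |OEV| and the response
    summaries."""
    if records.empty:
        raise ValueError("no records to summarize")
    out = records.groupby("alpha_sd")[_SUMMARY_METRICS].mean()
    out = out.rename(columns={"oev": "mean_oev", "oev_abs": "mean_oev_abs"})
    out["n_communities"] = records.groupby("alpha_sd").size()
    return out.reset_index()


def metric_rank_correlations(
    records: pd.DataFrame, columns: tuple[str, ...] | None = None
) -> pd.DataFrame:
    """Cross-community Spearman correlation matrix among metrics."""
    cols = list(columns) if columns is not None else _SUMMARY_METRICS
    sub = records[cols].dropna()
    rho = stats.spearmanr(sub.to_numpy(), axis=0).statistic
    rho = np.atleast_2d(rho)
    return pd.DataFrame(rho, index=cols, columns=cols)
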