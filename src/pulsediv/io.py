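"""Readers/writers for tidy series tables, the metrics pipeline, and config.

All tables are CSV with a schema-version comment header. The carrier format
for community time series is long/tidy:

    experiment_id, treatment, time, species, value

with ``treatment`` in {control, disturbed}, both arms present per
experiment, times sortable per experiment (raw units accepted; they are
normalized to [0, 1] internally), and non-negative values. The column
aliases ``community_id`` (for ``experiment_id``) and ``abundance``/
``biomass`` (for ``value``) are accepted on read.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .responses import response_ratio, summarise_responses
from .simulate import TrajectoryPair
from .stability import decompose, total_response_ratio
from .synthetic import EmpiricalExperiment

__all__ = [
    "SchemaError",
    "read_series",
    "write_series",
    "write_table",
    "read_table",
    "series_from_trajectory",
    "experiments_from_series",
    "analyze_series",
    "load_config",
]

SCHEMA_VERSION = "pulsediv-series v1"
REQUIRED_COLUMNS = ("experiment_id", "treatment", "time", "species", "value")
_ALIASES = {"community_id": "experiment_id", "abundance": "value", "biomass": "value"}
TREATMENTS = ("control", "disturbed")


class SchemaError(ValueError):
    """A table does not conform to the documented schema."""


def write_table(df: pd.DataFrame, path, kind: str = "table") -> None:
    """Write a CSV with a schema-version comment header."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# pulsediv-{kind} v1\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def validate_series(df: pd.DataFrame) -> pd.DataFrame:
    df = df.rename(columns=_ALIASES)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"series table is missing column(s): {missing}")
    df = df[list(REQUIRED_COLUMNS)].copy()

    bad_treat = ~df["treatment"].isin(TREATMENTS)
    if bad_treat.any():
        rows = df.index[bad_treat].tolist()[:10]
        raise SchemaError(
            f"treatment must be one of {TREATMENTS}; offending rows: {rows}"
        )
    bad_value = df["value"].isna() | (df["value"] < 0)
    if bad_value.any():
        rows = df.index[bad_value].tolist()[:10]
        raise SchemaError(f"values must be non-negative; offending rows: {rows}")
    dup = df.duplicated(subset=["experiment_id", "treatment", "time", "species"])
    if dup.any():
        rows = df.index[dup].tolist()[:10]
        raise SchemaError(
            f"duplicate (experiment_id, treatment, time, species) keys; rows: {rows}"
        )
    arms = df.groupby("experiment_id")["treatment"].agg(lambda s: frozenset(s))
    one_armed = arms[arms != frozenset(TREATMENTS)]
    if len(one_armed):
        raise SchemaError(
            "every experiment needs a disturbed treatment and an undisturbed "
            f"control; incomplete: {sorted(one_armed.index.tolist())}"
        )
    return df


def read_series(path) -> pd.DataFrame:
    """Read and validate a tidy series table."""
    df = pd.read_csv(path, comment="#")
    return validate_series(df)


def write_series(df: pd.DataFrame, path) -> None:
    write_table(validate_series(df), path, kind="series")


def series_from_trajectory(traj: TrajectoryPair, community_id: str = "community0") -> pd.DataFrame:
    """Long-format export of a simulated trajectory pair (all time steps)."""
    S = traj.community.S
    frames = []
    for arm, matrix in (("control", traj.N_control), ("disturbed", traj.N_disturbed)):
        frames.append(
            pd.DataFrame(
                {
                    "experiment_id": community_id,
                    "treatment": arm,
                    "time": np.repeat(traj.times, S),
                    "species": np.tile([f"sp{i + 1}" for i in range(S)], len(traj.times)),
                    "value": matrix.ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def experiments_from_series(df: pd.DataFrame) -> list[EmpiricalExperiment]:
    """Pivot a validated tidy table into per-experiment paired matrices."""
    out = []
    for exp_id, sub in df.groupby("experiment_id", sort=True):
        wide = sub.pivot_table(
            index="time", columns=["treatment", "species"], values="value"
        )
        if wide.isna().any().any():
            raise SchemaError(
                f"experiment {exp_id!r}: control/disturbed series do not cover "
                "the same (time, species) grid"
            )
        times = wide.index.to_numpy(dtype=float)
        species = tuple(sorted(sub["species"].unique()))
        con = wide["control"][list(species)].to_numpy(dtype=float)
        dis = wide["disturbed"][list(species)].to_numpy(dtype=float)
        span = times[-1] - times[0]
        norm_times = (times - times[0]) / span if span > 0 else times
        out.append(
            EmpiricalExperiment(
                experiment_id=str(exp_id),
                times=norm_times,
                control=con,
                treatment=dis,
                species=species,
            )
        )
    return out


def analyze_series(
    df: pd.DataFrame,
    rare_filter: bool = False,
    min_entries: int = 10,
    threshold: float = 1e-3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-experiment realised responses, response summaries, and stability.

    Returns ``(community_table, species_table)``. The realised response
    summary optionally applies the rare-species filter (the convention for
    simulated data; empirical series are used in full). Community totals are
    never filtered.
    """
    df = validate_series(df)
    community_rows, species_rows = [], []
    for exp in experiments_from_series(df):
        included = np.ones(exp.S, dtype=bool)
        if rare_filter:
            present = (exp.control > threshold) | (exp.treatment > threshold)
            included = present.sum(axis=0) >= min_entries
            if not included.any():
                raise SchemaError(
                    f"experiment {exp.experiment_id!r}: rare-species filter "
                    "excluded every species"
                )
        rr = response_ratio(exp.treatment, exp.control)
        realised = np.trapezoid(rr, exp.times, axis=0)
        for name, resp, inc in zip(exp.species, realised, included):
            species_rows.append(
                {
                    "experiment_id": exp.experiment_id,
                    "species": name,
                    "realised_response": float(resp),
                    "included": bool(inc),
                }
            )
        summary = summarise_responses(realised[included], "realised")
        tot_rr = total_response_ratio(exp.control, exp.treatment)
        stab = decompose(
            exp.times, tot_rr, disturbed_totals=exp.treatment.sum(axis=1)
        )
        community_rows.append(
            {
                "experiment_id": exp.experiment_id,
                "n_species": exp.S,
                "n_species_included": int(included.sum()),
                "mean_response": summary.mean,
                "dissimilarity": summary.dissimilarity,
                "divergence": summary.divergence,
                "oev": stab.oev,
                "oev_abs": stab.oev_abs,
                "resistance": stab.resistance,
                "resilience": stab.resilience,
                "temporal_stability": stab.temporal_stability,
                "recovery": stab.recovery,
            }
        )
    return pd.DataFrame(community_rows), pd.DataFrame(species_rows)


def load_config(path) -> dict:
    """Load a YAML config file into a dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
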