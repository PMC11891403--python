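"""Tabular serialisation: tidy TSV for trajectories, measurements and
observables.  TSV with a header row and '.' decimal is the single dialect."""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import FeedingProtocol, Trajectory
from .model import ModelSpec

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "write_table",
    "read_measurements",
]

TRAJECTORY_COLUMNS = ["time_s", "species", "concentration_uM"]


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as tidy TSV (time_s, species, concentration_uM)."""
    n_t, n_s = traj.values.shape
    frame = pd.DataFrame({
        "time_s": np.repeat(traj.times, n_s),
        "species": np.tile(traj.model.species, n_t),
        "concentration_uM": traj.values.ravel(),
    })
    frame.to_csv(path, sep="\t", index=False)


def read_trajectory(model: ModelSpec, path: str | Path,
                    protocol: FeedingProtocol | None = None) -> Trajectory:
    """Read a tidy trajectory TSV back into a Trajectory.

    Round-trips :func:`write_trajectory` losslessly.  Unknown species or
    malformed rows raise; negative concentrations produce a warning (the
    trajectory invariant allows only tiny negative solver output, which is
    clipped on write).
    """
    try:
        frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValueError(f"malformed trajectory file {path}: {exc}") from exc
    if list(frame.columns) != TRAJECTORY_COLUMNS:
        raise ValueError(
            f"expected columns {TRAJECTORY_COLUMNS}, got {list(frame.columns)}")
    if frame.empty:
        return Trajectory(model, np.array([]),
                          np.zeros((0, len(model.species))), protocol)
    unknown = set(frame["species"]) - set(model.species)
    if unknown:
        raise ValueError(f"unknown species in trajectory file: {sorted(unknown)}")
    if (frame["concentration_uM"] < 0).any():
        bad = frame[frame["concentration_uM"] < 0]
        warnings.warn(
            f"{len(bad)} negative concentrations in {path}; "
            "first offending row index "
            f"{bad.index[0] + 2} (1-based, incl. header)")
    wide = frame.pivot(index="time_s", columns="species",
                       values="concentration_uM").sort_index()
    missing = set(model.species) - set(wide.columns)
    if missing:
        raise ValueError(f"species missing from trajectory file: {sorted(missing)}")
    values = wide[model.species].to_numpy()
    return Trajectory(model, wide.index.to_numpy(), values, protocol)


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read a measurement TSV (analyte, time_s, replicate, counts,
    normalizer_counts); validates schema and non-negativity."""
    from .synthdata import MEASUREMENT_COLUMNS

    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = set(MEASUREMENT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"measurement file missing columns: {sorted(missing)}")
    if (frame["counts"] < 0).any() or (frame["normalizer_counts"] < 0).any():
        raise ValueError("counts must be non-negative")
    return frame
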