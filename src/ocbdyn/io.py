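"""Serialization: tidy trajectory CSV, grid CSV, run metadata."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .experiments import GridResult
from .model import Trajectory

__all__ = [
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_grid_csv",
    "write_run_metadata",
]


def write_trajectory_csv(traj: Trajectory, path: str | Path,
                         run_id: str = "run") -> Path:
    """Write a trajectory as tidy long CSV (run_id, time, variable, value).

    Values are written with full repr precision, so reading the file back
    reproduces every float exactly and re-writing it is byte-identical.
    """
    path = Path(path)
    long = traj.to_long(run_id)
    # shortest round-tripping repr; pandas' default %.16g can drop the
    # 17th significant digit and perturb values by 1 ulp
    for column in ("time", "value"):
        long[column] = long[column].map(lambda v: repr(float(v)))
    long.to_csv(path, index=False)
    return path


def read_trajectory_csv(path: str | Path) -> pd.DataFrame:
    """Read a tidy long trajectory CSV back into a DataFrame."""
    return pd.read_csv(path, dtype={"run_id": str}, float_precision="round_trip")


def write_grid_csv(result: GridResult, directory: str | Path,
                   stem: str = "grid") -> tuple[Path, Path]:
    """Write a grid result as a mean matrix CSV plus a long replicate CSV.

    The matrix has workloads as rows and frequencies as columns.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    matrix_path = directory / f"{stem}_mean_matrix.csv"
    long_path = directory / f"{stem}_replicates.csv"
    result.mean_matrix.to_csv(matrix_path)
    result.replicates.to_csv(long_path, index=False)
    return matrix_path, long_path


def write_run_metadata(directory: str | Path, config: dict,
                       filename: str = "run_metadata.json") -> Path:
    """Write the resolved configuration and software version next to outputs."""
    from . import __version__

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / filename
    payload = {"version": __version__, "config": config}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path
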