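"""Figure analogues: line plots for runs/sweeps, heatmaps for grids.

Plot styling is non-contractual; the numeric CSV written alongside each
figure is the artifact of record.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .experiments import GridResult
from .io import write_grid_csv, write_trajectory_csv
from .model import Trajectory

__all__ = ["render_figures"]

_RUN_FIGURES = (4, 5)
_SWEEP_FIGURES = (6, 7, 8)
_GRID_FIGURES = (9, 10, 11)
_RUN_VARIABLES = ("challenge_stressor", "job_satisfaction", "coping", "ocb")


def render_figures(results, which: int, directory: str | Path) -> list[Path]:
    """Render the analogue of one study figure and its CSV.

    ``results`` must match the figure family: a :class:`Trajectory` for
    4-5, a mapping of initial stressor -> trajectory for 6-8, and a
    :class:`GridResult` for 9-11.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if which in _RUN_FIGURES:
        if not isinstance(results, Trajectory):
            raise ValueError(f"figure {which} needs a Trajectory")
        return _render_run(results, which, directory)
    if which in _SWEEP_FIGURES:
        if not isinstance(results, dict):
            raise ValueError(f"figure {which} needs a sweep mapping S0 -> Trajectory")
        return _render_sweep(results, which, directory)
    if which in _GRID_FIGURES:
        if not isinstance(results, GridResult):
            raise ValueError(f"figure {which} needs a GridResult")
        return _render_grid(results, which, directory)
    raise ValueError(f"unknown figure id {which}; expected 4..11")


def _render_run(traj: Trajectory, which: int, directory: Path) -> list[Path]:
    csv_path = write_trajectory_csv(traj, directory / f"figure{which}.csv",
                                    run_id=f"figure{which}")
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for name in _RUN_VARIABLES:
        ax.plot(traj.times, traj.series(name), label=name.replace("_", " "))
    ax.set_xlabel("time (day)")
    ax.set_ylabel("value")
    ax.legend()
    ax.set_title(f"Figure {which} analogue: baseline run")
    png_path = directory / f"figure{which}.png"
    fig.savefig(png_path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return [png_path, csv_path]


def _render_sweep(sweep: dict, which: int, directory: Path) -> list[Path]:
    import pandas as pd

    frames = []
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for s0, traj in sorted(sweep.items()):
        ax.plot(traj.times, traj.series("ocb"), label=f"S0={s0:g}")
        frames.append(pd.DataFrame({
            "initial_stressor": s0,
            "time": traj.times,
            "ocb": traj.series("ocb"),
        }))
    csv_path = directory / f"figure{which}.csv"
    pd.concat(frames, ignore_index=True).to_csv(csv_path, index=False)
    ax.set_xlabel("time (day)")
    ax.set_ylabel("OCB rate")
    ax.legend(fontsize=7, ncol=2)
    ax.set_title(f"Figure {which} analogue: OCB by initial stressor")
    png_path = directory / f"figure{which}.png"
    fig.savefig(png_path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return [png_path, csv_path]


def _render_grid(result: GridResult, which: int, directory: Path) -> list[Path]:
    matrix_path, long_path = write_grid_csv(result, directory, stem=f"figure{which}")
    matrix = result.mean_matrix
    fig, ax = plt.subplots(figsize=(8, 4))
    im = ax.imshow(matrix.to_numpy(), aspect="auto", origin="lower",
                   extent=(min(result.frequencies), max(result.frequencies),
                           min(result.workloads), max(result.workloads)))
    fig.colorbar(im, ax=ax, label="cumulative OCB (100 days)")
    ax.set_xlabel("new-task frequency (pulses / 100 days)")
    ax.set_ylabel("new-task workload")
    ax.set_title(f"Figure {which} analogue: OCB accumulation")
    png_path = directory / f"figure{which}.png"
    fig.savefig(png_path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return [png_path, matrix_path, long_path]
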