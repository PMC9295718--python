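"""Scenario presets and sweep runners.

Reproduces the study's simulation experiments:

* the baseline run and the revised run with nonzero expectations
  (``figure4`` / ``figure5`` presets);
* four named conditions crossing the equilibrium level of job
  satisfaction (above/below the expected satisfaction of 2) with the
  importance of challenge appraisal (above/below the strain importance
  of 0.29), swept over initial stressor values;
* the task-assignment grid: cumulative OCB over 100 days as a function
  of new-task workload (1..8) and frequency (1..100 pulses per 100
  days), with per-cell seed replicates.

The grid is simulated as one vectorized batch: every cell's four stocks
live in NumPy arrays and step together through the same Euler update used
for scalar runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import RandomInputs, TimeGrid, euler_step, simulate
from .model import ModelState, ParameterSet, Trajectory

__all__ = [
    "ConditionPreset",
    "CONDITIONS",
    "GridResult",
    "run_preset_scenario",
    "run_condition",
    "stressor_sweep",
    "ocb_accumulation_grid",
    "optimal_frequency",
    "optimal_frequency_by_workload",
    "DEFAULT_SWEEP_S0",
]

#: Initial stressor values used by default in condition sweeps: the
#: integers 1..18 (covering every threshold the narrative mentions) plus
#: the baseline scale mean 2.71.
DEFAULT_SWEEP_S0: tuple[float, ...] = tuple(range(1, 19)) + (2.71,)


@dataclass(frozen=True)
class ConditionPreset:
    """One of the four named experimental conditions.

    Each condition fixes the expected satisfaction at 2 and the strain
    importance at 0.29, and varies the equilibrium level of job
    satisfaction and the challenge-appraisal importance.
    """

    id: int
    initial_equilibrium_level: float
    importance_challenge_appraisal: float
    expected_satisfaction_init: float = 2.0
    importance_strain: float = 0.29

    def to_params(self, initial_stressor: float = 0.0, **overrides) -> ParameterSet:
        return ParameterSet(
            initial_challenge_stressor=initial_stressor,
            initial_equilibrium_level=self.initial_equilibrium_level,
            importance_challenge_appraisal=self.importance_challenge_appraisal,
            importance_strain=self.importance_strain,
            expected_satisfaction_init=self.expected_satisfaction_init,
            expected_challenge_stress=0.0,
            **overrides,
        )


CONDITIONS: Mapping[int, ConditionPreset] = {
    1: ConditionPreset(1, initial_equilibrium_level=4.0, importance_challenge_appraisal=0.4),
    2: ConditionPreset(2, initial_equilibrium_level=4.0, importance_challenge_appraisal=0.2),
    3: ConditionPreset(3, initial_equilibrium_level=0.0, importance_challenge_appraisal=0.4),
    4: ConditionPreset(4, initial_equilibrium_level=0.0, importance_challenge_appraisal=0.2),
}


def run_preset_scenario(name: str, inputs: RandomInputs | None = None) -> Trajectory:
    """Run one of the two validation scenarios.

    ``figure4``: all defaults over 100 days. ``figure5``: expected
    challenge stress and expected satisfaction both raised to 2, over a
    20-day horizon.
    """
    if name == "figure4":
        return simulate(ParameterSet(), TimeGrid(), inputs)
    if name == "figure5":
        params = ParameterSet(expected_challenge_stress=2.0,
                              expected_satisfaction_init=2.0)
        return simulate(params, TimeGrid(final_time=20.0), inputs)
    raise ValueError(f"unknown preset scenario {name!r}")


def run_condition(preset: ConditionPreset, initial_stressor: float,
                  inputs: RandomInputs | None = None,
                  grid: TimeGrid | None = None) -> Trajectory:
    """Simulate one condition at a given initial stressor (no new tasks)."""
    if initial_stressor < 0:
        raise ValueError("initial stressor must be >= 0")
    params = preset.to_params(initial_stressor=initial_stressor)
    return simulate(params, grid or TimeGrid(), inputs)


def stressor_sweep(preset: ConditionPreset,
                   initial_stressors: Sequence[float] = DEFAULT_SWEEP_S0,
                   inputs: RandomInputs | None = None,
                   grid: TimeGrid | None = None) -> dict[float, Trajectory]:
    """One trajectory per initial stressor value, same seed for each.

    Re-using the same stream position for every value keeps trajectories
    comparable across the sweep.
    """
    if len(initial_stressors) == 0:
        raise ValueError("initial_stressors must be non-empty")
    inputs = inputs or RandomInputs(mode="mean")
    return {
        s0: run_condition(preset, s0, inputs.fresh(), grid)
        for s0 in initial_stressors
    }


# ---------------------------------------------------------------------------
# Workload x frequency grid
# ---------------------------------------------------------------------------

def _cell_seed(base_seed: int, workload: float, frequency: float,
               replicate: int) -> tuple[int, int, int, int]:
    """Deterministic per-cell seed entropy, independent of execution order."""
    return (int(base_seed), int(round(workload * 1e6)),
            int(round(frequency * 1e6)), int(replicate))


@dataclass(frozen=True)
class GridResult:
    """Cumulative OCB over a (workload x frequency) grid.

    ``replicates`` is tidy long data with one row per (workload,
    frequency, replicate); ``mean_matrix`` aggregates replicates into a
    workload-by-frequency matrix of means.
    """

    workloads: tuple[float, ...]
    frequencies: tuple[float, ...]
    replicates: pd.DataFrame  # columns: workload, frequency, replicate, cumulative_ocb

    @property
    def mean_matrix(self) -> pd.DataFrame:
        wide = self.replicates.pivot_table(
            index="workload", columns="frequency",
            values="cumulative_ocb", aggfunc="mean",
        )
        return wide.reindex(index=list(self.workloads), columns=list(self.frequencies))

    def summary(self) -> pd.DataFrame:
        """Per-cell mean/min/max over replicates."""
        g = self.replicates.groupby(["workload", "frequency"])["cumulative_ocb"]
        return g.agg(["mean", "min", "max"]).reset_index()

    def row(self, workload: float) -> pd.Series:
        """Mean cumulative OCB as a function of frequency at one workload."""
        return self.mean_matrix.loc[workload]


def ocb_accumulation_grid(preset: ConditionPreset,
                          workloads: Sequence[float] = tuple(range(1, 9)),
                          frequencies: Sequence[float] = tuple(range(1, 101)),
                          n_seeds: int = 20,
                          grid: TimeGrid | None = None,
                          mode: str = "stochastic",
                          base_seed: int = 0) -> GridResult:
    """Cumulative OCB over 100 days for every (workload, frequency) cell.

    Each cell runs the task-assignment regime: the stressor stock starts
    at zero and receives ``workload`` units in one-day pulses,
    ``frequency`` times per 100 days. Cumulative OCB is the left Riemann
    sum of the OCB rate over the horizon. Stochastic cells are replicated
    over ``n_seeds`` independent streams derived from
    (base_seed, workload, frequency, replicate); mean mode is
    deterministic, so a single replicate is recorded.
    """
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    grid = grid or TimeGrid()
    n_steps = grid.n_steps
    n_reps = 1 if mode == "mean" else int(n_seeds)

    cells = [(w, f, rep) for w in workloads for f in frequencies
             for rep in range(n_reps)]
    m = len(cells)
    w_vec = np.array([c[0] for c in cells], dtype=float)
    f_vec = np.array([c[1] for c in cells], dtype=float)

    if mode == "mean":
        restored = np.ones((n_steps, m))
        other = np.full((n_steps, m), 0.5)
    else:
        restored = np.empty((n_steps, m))
        other = np.empty((n_steps, m))
        for i, (w, f, rep) in enumerate(cells):
            rng = np.random.default_rng(_cell_seed(base_seed, w, f, rep))
            u = rng.random((n_steps, 2))
            restored[:, i] = 2.0 * u[:, 0]
            other[:, i] = u[:, 1]

    params = preset.to_params(
        initial_stressor=np.zeros(m),
        new_task_workload=w_vec,
        new_task_frequency=f_vec,
    )
    state = ModelState(
        challenge_stressor=np.zeros(m),
        job_satisfaction=np.full(m, preset.initial_equilibrium_level),
        resource_difference=np.zeros(m),
        expected_satisfaction=np.full(m, preset.expected_satisfaction_init),
    )
    total = np.zeros(m)
    times = grid.times
    for k in range(n_steps):
        state, record = euler_step(state, params, (restored[k], other[k]),
                                   times[k], grid.dt)
        total += np.asarray(record.ocb) * grid.dt

    replicates = pd.DataFrame({
        "workload": w_vec,
        "frequency": f_vec,
        "replicate": [c[2] for c in cells],
        "cumulative_ocb": total,
    })
    return GridResult(tuple(workloads), tuple(frequencies), replicates)


def optimal_frequency(row: pd.Series | Mapping[float, float]) -> float:
    """Frequency maximizing mean cumulative OCB; ties go to the smallest.

    ``row`` maps frequency -> cumulative OCB (e.g. one row of
    :attr:`GridResult.mean_matrix`).
    """
    series = pd.Series(dict(row)) if not isinstance(row, pd.Series) else row
    if len(series) == 0:
        raise ValueError("frequency row must be non-empty")
    series = series.sort_index()
    return float(series.index[int(np.argmax(series.to_numpy()))])


def optimal_frequency_by_workload(result: GridResult) -> pd.Series:
    """Optimal frequency at each workload of a grid result."""
    return pd.Series(
        {w: optimal_frequency(result.row(w)) for w in result.workloads},
        name="optimal_frequency",
    )
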