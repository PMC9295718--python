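"""Discrete-time stock-and-flow kernel (Euler integration).

The engine provides the primitives the model equations are built on: a
time grid, a rectangular pulse-train forcing function, per-step random
inputs (with a deterministic mean mode), a single Euler step with full
auxiliary bookkeeping, and the simulation loop.

Evaluation order within a step is fixed: all auxiliaries are computed
from the *current* stocks (the dependency graph is acyclic within a
step), then every stock is advanced as ``S(t+dt) = S(t) + dt * netflow``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Literal

import numpy as np
import pandas as pd

from .model import (
    AuxRecord,
    ModelState,
    ParameterSet,
    Trajectory,
    TRAJECTORY_COLUMNS,
    challenge_appraisal,
    coping,
    felt_obligation,
    importance_of_coping,
    importance_of_ocb,
    job_satisfaction_flow,
    ocb,
    satisfaction_discrepancy,
    strain,
    stress_discrepancy,
    task_increment,
)

__all__ = [
    "TimeGrid",
    "RandomInputs",
    "NumericalError",
    "pulse_train",
    "draw_random_inputs",
    "euler_step",
    "simulate",
]

#: Distribution means substituted in mean mode.
MEAN_RESTORED_RATE = 1.0
MEAN_OTHER_ACTIVITIES = 0.5


class NumericalError(ArithmeticError):
    """A model variable became non-finite during integration."""


@dataclass(frozen=True)
class TimeGrid:
    """Uniform simulation grid in days."""

    initial_time: float = 0.0
    final_time: float = 100.0
    dt: float = 1.0
    unit: str = "day"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.final_time <= self.initial_time:
            raise ValueError("final_time must exceed initial_time")
        n = (self.final_time - self.initial_time) / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError("(final_time - initial_time) / dt must be an integer")

    @property
    def n_steps(self) -> int:
        return int(round((self.final_time - self.initial_time) / self.dt))

    @property
    def times(self) -> np.ndarray:
        return self.initial_time + self.dt * np.arange(self.n_steps + 1)


@dataclass
class RandomInputs:
    """Per-step random resource inputs.

    ``restored_rate`` ~ Uniform(0, 2) and ``other_activities`` ~
    Uniform(0, 1), redrawn every step. In ``mean`` mode the exact
    distribution means (1.0, 0.5) are substituted, giving a fully
    deterministic run. ``seed`` may be an int or a tuple of ints (used by
    grid experiments to derive independent per-cell streams).
    """

    mode: Literal["stochastic", "mean"] = "stochastic"
    seed: int | tuple[int, ...] = 0
    _rng: np.random.Generator = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.mode not in ("stochastic", "mean"):
            raise ValueError(f"unknown random mode {self.mode!r}")
        self._rng = np.random.default_rng(self.seed)

    def fresh(self) -> "RandomInputs":
        """A copy with its stream rewound to the start (same seed)."""
        return RandomInputs(mode=self.mode, seed=self.seed)

    def draw(self) -> tuple[float, float]:
        if self.mode == "mean":
            return MEAN_RESTORED_RATE, MEAN_OTHER_ACTIVITIES
        # 2*random() / 1*random() so the scalar path consumes the stream
        # exactly like the batched runner's rng.random((n, 2)).
        return 2.0 * self._rng.random(), 1.0 * self._rng.random()


def draw_random_inputs(inputs: RandomInputs, t: float | None = None) -> tuple[float, float]:
    """Next (restored_rate, other_activities) pair from ``inputs``.

    ``t`` is accepted for interface symmetry with the other per-step
    operations; draws depend only on the stream position, not on t.
    """
    return inputs.draw()


def pulse_train(t, start, duration, repeat_time, end):
    """Rectangular pulse train: 1 during pulses, 0 otherwise.

    Pulses of length ``duration`` begin at ``start`` and recur every
    ``repeat_time`` (which may be non-integer); the train switches off at
    ``end``. Returns 1 iff some k >= 0 has
    ``start + k*repeat_time <= t < start + k*repeat_time + duration``
    and ``t < end``. Elementwise over any argument.
    """
    t = np.asarray(t, dtype=float)
    repeat_time = np.asarray(repeat_time, dtype=float)
    if np.any(np.asarray(duration, dtype=float) <= 0):
        raise ValueError("pulse duration must be positive")
    if np.any(repeat_time <= 0):
        raise ValueError("pulse repeat_time must be positive")
    if np.any(np.asarray(start, dtype=float) > np.asarray(end, dtype=float)):
        raise ValueError("pulse start must not exceed end")
    elapsed = t - start
    k = np.floor(np.where(elapsed >= 0, elapsed, 0.0) / repeat_time)
    in_window = elapsed - k * repeat_time < duration
    on = (elapsed >= 0) & (t < end) & in_window
    return on.astype(int)[()]


def _check_finite(**named_values: float) -> None:
    for name, value in named_values.items():
        if not np.all(np.isfinite(value)):
            raise NumericalError(f"non-finite value in variable {name!r}")


def evaluate_auxiliaries(state: ModelState, params: ParameterSet,
                         draws: tuple[float, float], t: float) -> dict[str, float]:
    """All auxiliary variables from the current stocks, in dependency order."""
    p = params
    restored, other = draws
    perceived = state.challenge_stressor
    disc = stress_discrepancy(perceived, p.expected_challenge_stress)
    appraisal = challenge_appraisal(disc, p.importance_challenge_appraisal)
    strain_v = strain(disc, p.importance_strain)
    w_c = importance_of_coping(state.resource_difference, p.base_importance_coping)
    w_o = importance_of_ocb(state.resource_difference, p.base_importance_ocb)
    coping_v = coping(disc, perceived, w_c)
    sat_disc = satisfaction_discrepancy(state.job_satisfaction, state.expected_satisfaction)
    obligation = felt_obligation(sat_disc, p.exchange_orientation)
    ocb_v = ocb(obligation, w_o)
    inc = task_increment(t, p.new_task_workload, p.new_task_frequency)
    return {
        "perceived_stress": perceived,
        "stress_discrepancy": disc,
        "challenge_appraisal": appraisal,
        "strain": strain_v,
        "importance_coping": w_c,
        "importance_ocb": w_o,
        "coping": coping_v,
        "satisfaction_discrepancy": sat_disc,
        "felt_obligation": obligation,
        "ocb": ocb_v,
        "task_increment": inc,
        "restored_rate": restored,
        "other_activities": other,
    }


def evaluate_flows(aux: dict[str, float], state: ModelState,
                   params: ParameterSet) -> dict[str, float]:
    """Net flow of each stock from the current auxiliaries."""
    return {
        "flow_stressor": aux["task_increment"] - aux["coping"],
        "flow_satisfaction": job_satisfaction_flow(
            aux["challenge_appraisal"], aux["strain"],
            params.initial_equilibrium_level, state.job_satisfaction,
            params.opponent_process_rate,
        ),
        "flow_resource": (aux["restored_rate"] - aux["coping"]
                          - aux["ocb"] - aux["other_activities"]),
        "flow_expected_satisfaction": aux["ocb"] * params.exchange_orientation,
    }


def euler_step(state: ModelState, params: ParameterSet,
               draws: tuple[float, float], t: float,
               dt: float = 1.0) -> tuple[ModelState, AuxRecord]:
    """One Euler step: auxiliaries from current stocks, then stock update."""
    aux = evaluate_auxiliaries(state, params, draws, t)
    _check_finite(**aux)
    flows = evaluate_flows(aux, state, params)
    _check_finite(**flows)
    next_state = ModelState(
        challenge_stressor=state.challenge_stressor + dt * flows["flow_stressor"],
        job_satisfaction=state.job_satisfaction + dt * flows["flow_satisfaction"],
        resource_difference=state.resource_difference + dt * flows["flow_resource"],
        expected_satisfaction=(state.expected_satisfaction
                               + dt * flows["flow_expected_satisfaction"]),
    )
    return next_state, AuxRecord(**aux, **flows)


def simulate(params: ParameterSet, grid: TimeGrid | None = None,
             inputs: RandomInputs | None = None,
             initial_state: ModelState | None = None) -> Trajectory:
    """Integrate the model over the grid.

    Returns a :class:`Trajectory` with ``n_steps + 1`` records. The final
    record holds a terminal auxiliary evaluation (its flows are not
    applied). ``initial_state`` overrides the stocks derived from
    ``params`` (used e.g. to displace initial job satisfaction from its
    equilibrium in closed-form checks).

    Reproducible: identical (params, grid, mode, seed) give a
    bit-identical trajectory.
    """
    grid = grid or TimeGrid()
    inputs = (inputs or RandomInputs(mode="mean")).fresh()
    state = initial_state or params.initial_state()
    times = grid.times
    rows = np.empty((grid.n_steps + 1, len(TRAJECTORY_COLUMNS)))
    for k in range(grid.n_steps):
        t = times[k]
        try:
            next_state, record = euler_step(state, params, inputs.draw(), t, grid.dt)
        except NumericalError as err:
            raise NumericalError(f"step {k} (t={t}): {err}") from err
        rows[k] = [t, *state.as_tuple(), *_aux_values(record)]
        state = next_state
    # terminal evaluation: auxiliaries of the final stocks; flows unused
    t_final = times[-1]
    aux = evaluate_auxiliaries(state, params, inputs.draw(), t_final)
    flows = evaluate_flows(aux, state, params)
    rows[-1] = [t_final, *state.as_tuple(), *_aux_values(AuxRecord(**aux, **flows))]
    frame = pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)
    return Trajectory(data=frame, dt=grid.dt)


def _aux_values(record: AuxRecord) -> list[float]:
    return [getattr(record, f.name) for f in fields(AuxRecord)]
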