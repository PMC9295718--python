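"""Equation set of the challenge-stressor / OCB feedback model.

The model couples a cybernetic stress-coping loop with a social-exchange
loop. Four stocks evolve in discrete time (Euler, daily steps):

* challenge stressor ``S`` — the external demand, reduced by coping and
  optionally replenished by a pulse train of newly assigned tasks;
* job satisfaction ``J`` — raised by challenge appraisal, lowered by
  strain, and pulled back to an equilibrium level by an opponent process;
* resource difference ``D`` — the running balance of daily restored
  resources minus resources consumed by coping, OCB and other activities;
* expected satisfaction ``E_J`` — the satisfaction level an employee has
  come to expect, ratcheted upward by their own OCB.

All auxiliary variables are instantaneous functions of the current stocks.
Every function in this module is elementwise (NumPy-broadcastable), so the
same definitions drive both the scalar Euler stepper and the vectorized
batch runner used for parameter grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "ParameterSet",
    "ModelState",
    "AuxRecord",
    "Trajectory",
    "stress_discrepancy",
    "challenge_appraisal",
    "strain",
    "coping",
    "importance_of_coping",
    "importance_of_ocb",
    "satisfaction_discrepancy",
    "felt_obligation",
    "ocb",
    "job_satisfaction_flow",
    "task_increment",
    "variable_table",
]


@dataclass(frozen=True)
class ParameterSet:
    """Model constants and initial stock values.

    Defaults are the published baseline: the initial stressor is the scale
    mean 2.71; appraisal/strain/coping/OCB importances are correlation
    coefficients taken from prior empirical studies; the opponent process
    pulls satisfaction halfway back to equilibrium each day.

    Units: the stressor and its expectation share one abstract "stressor"
    scale; satisfaction quantities share a "satisfaction" scale; resources
    are an abstract daily budget; rates are per day.
    """

    initial_challenge_stressor: float = 2.71
    expected_challenge_stress: float = 0.0
    initial_equilibrium_level: float = 0.0
    opponent_process_rate: float = 0.5
    importance_challenge_appraisal: float = 0.23
    importance_strain: float = 0.29
    base_importance_coping: float = 0.29
    base_importance_ocb: float = 0.2
    exchange_orientation: float = 0.51
    expected_satisfaction_init: float = 0.0
    new_task_workload: float = 0.0
    new_task_frequency: float = 0.0

    def __post_init__(self) -> None:
        unit = {
            "opponent_process_rate": self.opponent_process_rate,
            "importance_challenge_appraisal": self.importance_challenge_appraisal,
            "importance_strain": self.importance_strain,
            "base_importance_coping": self.base_importance_coping,
            "base_importance_ocb": self.base_importance_ocb,
            "exchange_orientation": self.exchange_orientation,
        }
        # array-safe checks: fields may carry per-run arrays in batched grids
        for name, value in unit.items():
            if np.any(np.asarray(value) < 0.0) or np.any(np.asarray(value) > 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if np.any(np.asarray(self.new_task_workload) < 0):
            raise ValueError("new_task_workload must be >= 0")
        f = np.asarray(self.new_task_frequency)
        if np.any((f != 0) & ((f < 1.0) | (f > 100.0))):
            raise ValueError(
                f"new_task_frequency must be 0 or in [1, 100], got {self.new_task_frequency}"
            )

    def evolve(self, **changes) -> "ParameterSet":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)

    @classmethod
    def for_task_assignment(cls, workload: float, frequency: float, **changes) -> "ParameterSet":
        """Parameters for the task-assignment regime.

        The stressor stock starts empty and is driven purely by the pulse
        train of new tasks (``workload`` units delivered ``frequency`` times
        per 100 days).
        """
        return cls(
            initial_challenge_stressor=0.0,
            new_task_workload=workload,
            new_task_frequency=frequency,
            **changes,
        )

    def initial_state(self) -> "ModelState":
        return ModelState(
            challenge_stressor=self.initial_challenge_stressor,
            job_satisfaction=self.initial_equilibrium_level,
            resource_difference=0.0,
            expected_satisfaction=self.expected_satisfaction_init,
        )


@dataclass(frozen=True)
class ModelState:
    """The four stocks at one instant."""

    challenge_stressor: float
    job_satisfaction: float
    resource_difference: float
    expected_satisfaction: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (
            self.challenge_stressor,
            self.job_satisfaction,
            self.resource_difference,
            self.expected_satisfaction,
        )


@dataclass(frozen=True)
class AuxRecord:
    """Every auxiliary, random draw and flow evaluated at one step."""

    perceived_stress: float
    stress_discrepancy: float
    challenge_appraisal: float
    strain: float
    importance_coping: float
    importance_ocb: float
    coping: float
    satisfaction_discrepancy: float
    felt_obligation: float
    ocb: float
    task_increment: float
    restored_rate: float
    other_activities: float
    flow_stressor: float
    flow_satisfaction: float
    flow_resource: float
    flow_expected_satisfaction: float


_STATE_COLUMNS = [f.name for f in fields(ModelState)]
_AUX_COLUMNS = [f.name for f in fields(AuxRecord)]
TRAJECTORY_COLUMNS = ["time", *_STATE_COLUMNS, *_AUX_COLUMNS]


@dataclass(frozen=True)
class Trajectory:
    """One record per grid point: time, the four stocks, all auxiliaries.

    The trajectory holds ``steps + 1`` records. Records ``0 .. steps-1``
    carry the auxiliaries and flows that produced the next state; the final
    record carries a terminal auxiliary evaluation of the final stocks (its
    flows are never applied), so every stored state has a matching
    auxiliary row.
    """

    data: pd.DataFrame
    dt: float = 1.0

    def __len__(self) -> int:
        return len(self.data)

    def __iter__(self) -> Iterator[tuple[float, ModelState, AuxRecord]]:
        for row in self.data.itertuples(index=False):
            d = row._asdict()
            yield (
                d["time"],
                ModelState(**{k: d[k] for k in _STATE_COLUMNS}),
                AuxRecord(**{k: d[k] for k in _AUX_COLUMNS}),
            )

    @property
    def times(self) -> np.ndarray:
        return self.data["time"].to_numpy()

    def series(self, name: str) -> np.ndarray:
        """Per-record values of one stock or auxiliary variable."""
        if name not in self.data.columns:
            raise KeyError(f"unknown variable {name!r}")
        return self.data[name].to_numpy()

    def to_long(self, run_id: str = "run") -> pd.DataFrame:
        """Tidy long format: columns run_id, time, variable, value."""
        long = self.data.melt(
            id_vars=["time"], var_name="variable", value_name="value"
        )
        long.insert(0, "run_id", run_id)
        return long


# ---------------------------------------------------------------------------
# Auxiliary equations. Each is elementwise and accepts scalars or arrays.
# ---------------------------------------------------------------------------

def stress_discrepancy(perceived, expected):
    """Gap between perceived and expected (maximum acceptable) stress.

    Above expectation the full gap drives coping; between zero and the
    expectation the gap is halved (coping continues with less motivation);
    once the stressor is eliminated (perceived <= 0) the discrepancy rests
    at -expected/2.
    """
    perceived = np.asarray(perceived, dtype=float)
    gap = perceived - expected
    return np.where(gap > 0, gap, np.where(perceived > 0, gap / 2.0, -np.asarray(expected, dtype=float) / 2.0))[()]


def challenge_appraisal(disc, importance):
    """Positive appraisal of the stressor, formed only above expectation."""
    disc = np.asarray(disc, dtype=float)
    return np.where(disc > 0, disc * importance, 0.0)[()]


def strain(disc, importance):
    """Psychological strain, formed only above expectation."""
    disc = np.asarray(disc, dtype=float)
    return np.where(disc > 0, disc * importance, 0.0)[()]


def coping(disc, perceived, importance):
    """Resources per day invested in reducing the stressor.

    (1 + disc) * importance above expectation, exp(disc) * importance while
    the stressor persists below expectation (continuous at disc = 0), and
    zero once the stressor is eliminated.
    """
    disc = np.asarray(disc, dtype=float)
    perceived = np.asarray(perceived, dtype=float)
    low = np.where(perceived > 0, np.exp(np.minimum(disc, 0.0)) * importance, 0.0)
    return np.where(disc > 0, (1.0 + disc) * importance, low)[()]


def importance_of_coping(resource_difference, base):
    """Weight on coping; rises toward 2*base as resources run short.

    base for a non-negative resource balance, base * (1 + (-D)/(1-D)) when
    the balance D is negative; continuous at D = 0.
    """
    d = np.asarray(resource_difference, dtype=float)
    deficit = np.minimum(d, 0.0)
    return np.where(d > 0, base, base + base * (-deficit) / (1.0 - deficit))[()]


def importance_of_ocb(resource_difference, base):
    """Weight on OCB; decays toward 0 as resources run short.

    base for a non-negative balance, base / (1 - D) when D is negative;
    continuous at D = 0.
    """
    d = np.asarray(resource_difference, dtype=float)
    deficit = np.minimum(d, 0.0)
    return np.where(d > 0, base, base / (1.0 - deficit))[()]


def satisfaction_discrepancy(satisfaction, expected):
    """Positive part of (job satisfaction - expected satisfaction)."""
    return np.maximum(np.asarray(satisfaction, dtype=float) - expected, 0.0)[()]


def felt_obligation(sat_disc, exchange_orientation):
    """Sense of owing reciprocation, scaled by exchange orientation."""
    return np.asarray(sat_disc, dtype=float)[()] * exchange_orientation


def ocb(obligation, importance):
    """Organizational citizenship behavior rate (resources per day)."""
    return np.asarray(obligation, dtype=float)[()] * importance


def job_satisfaction_flow(appraisal, strain_value, equilibrium, satisfaction, rate):
    """Net daily change of job satisfaction.

    Appraisal pushes up, strain pushes down, and an opponent process pulls
    satisfaction back toward its equilibrium level at ``rate`` per day.
    """
    return appraisal - strain_value + (equilibrium - np.asarray(satisfaction, dtype=float)[()]) * rate


def task_increment(t, workload, frequency):
    """Stressor units delivered at time t by the new-task pulse train.

    ``frequency`` pulses of one day's duration are spread over 100 days
    (repeat time 100/frequency, first pulse at day 1). frequency = 0 means
    no new tasks.
    """
    from .engine import pulse_train  # local import to avoid a cycle

    frequency = np.asarray(frequency, dtype=float)
    if np.any(frequency < 0):
        raise ValueError("new-task frequency must be >= 0")
    if np.all(frequency == 0):
        return np.zeros_like(np.asarray(t, dtype=float) * np.ones_like(frequency))[()]
    repeat = np.where(frequency > 0, 100.0 / np.where(frequency > 0, frequency, 1.0), np.inf)
    active = pulse_train(t, start=1.0, duration=1.0, repeat_time=repeat, end=100.0)
    return np.where(frequency > 0, workload * active, 0.0)[()]


def variable_table() -> pd.DataFrame:
    """Machine-readable model definition: name, kind, equation, default."""
    rows = [
        ("challenge_stressor", "stock",
         "INTEG(task_increment - coping, S0)  [S0 = 0 in task-assignment mode]", 2.71),
        ("job_satisfaction", "stock",
         "INTEG(challenge_appraisal - strain + (equilibrium - J) * opponent_rate, equilibrium)", 0.0),
        ("resource_difference", "stock",
         "INTEG(restored_rate - coping - ocb - other_activities, 0)", 0.0),
        ("expected_satisfaction", "stock",
         "INTEG(ocb * exchange_orientation, E_J0)", 0.0),
        ("perceived_stress", "auxiliary", "challenge_stressor", None),
        ("stress_discrepancy", "auxiliary",
         "P - E_s if P - E_s > 0 else ((P - E_s)/2 if P > 0 else -E_s/2)", None),
        ("challenge_appraisal", "auxiliary",
         "disc * importance_challenge_appraisal if disc > 0 else 0", None),
        ("strain", "auxiliary", "disc * importance_strain if disc > 0 else 0", None),
        ("importance_coping", "auxiliary",
         "w_c0 if D > 0 else w_c0 + w_c0 * (-D) / (1 - D)", None),
        ("importance_ocb", "auxiliary", "w_o0 if D > 0 else w_o0 / (1 - D)", None),
        ("coping", "auxiliary",
         "(1 + disc) * w_c if disc > 0 else (exp(disc) * w_c if P > 0 else 0)", None),
        ("satisfaction_discrepancy", "auxiliary", "max(J - E_J, 0)", None),
        ("felt_obligation", "auxiliary", "sat_disc * exchange_orientation", None),
        ("ocb", "auxiliary", "felt_obligation * importance_ocb", None),
        ("task_increment", "auxiliary",
         "workload * pulse_train(t, 1, 1, 100/frequency, 100)", None),
        ("restored_rate", "random", "Uniform(0, 2) per day (mean mode: 1.0)", None),
        ("other_activities", "random", "Uniform(0, 1) per day (mean mode: 0.5)", None),
        ("expected_challenge_stress", "constant", "E_s", 0.0),
        ("initial_equilibrium_level", "constant", "L", 0.0),
        ("opponent_process_rate", "constant", "r", 0.5),
        ("importance_challenge_appraisal", "constant", "c_a", 0.23),
        ("importance_strain", "constant", "c_s", 0.29),
        ("base_importance_coping", "constant", "w_c0", 0.29),
        ("base_importance_ocb", "constant", "w_o0", 0.2),
        ("exchange_orientation", "constant", "x", 0.51),
        ("new_task_workload", "constant", "W", 0.0),
        ("new_task_frequency", "constant", "f (pulses per 100 days)", 0.0),
    ]
    return pd.DataFrame(rows, columns=["name", "kind", "equation", "default"])
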