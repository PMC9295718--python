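"""Trajectory summaries and qualitative shape labels.

The study's propositions are stated in terms of curve shapes ("M shape",
"inverted N shape", ...). To make those labels reproducible, a series is
classified by run-length-encoding the signs of its consecutive
differences: differences within a tolerance are treated as plateaus and
merged into the preceding run (leading plateaus into the following one),
and the resulting +/- pattern is matched against a small set of
templates.
"""

from __future__ import annotations

from enum import Enum
from typing import Sequence

import numpy as np

from .model import Trajectory

__all__ = [
    "ShapeLabel",
    "first_zero_day",
    "classify_shape",
    "cumulative_ocb",
]

#: Default tolerance for treating a value as zero.
ZERO_TOL = 1e-9
#: Default tolerance for treating a consecutive difference as flat.
DIFF_TOL = 1e-6


class ShapeLabel(str, Enum):
    FLAT_ZERO = "flat_zero"
    MONOTONE_DECLINE = "monotone_decline"
    INVERTED_U = "inverted_U"
    M_SHAPE = "M_shape"
    INVERTED_N = "inverted_N"
    OTHER = "other"


def first_zero_day(series: Sequence[float], tol: float = ZERO_TOL) -> int | None:
    """1-based day index of the first value within ``tol`` of zero.

    Grid point i corresponds to day ``t_i/dt + 1 = i + 1``, i.e. t=0 is
    "day 1". Returns None if the series never reaches zero.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    values = np.asarray(series, dtype=float)
    if values.size == 0:
        raise ValueError("series must be non-empty")
    hits = np.flatnonzero(np.abs(values) <= tol)
    if hits.size == 0:
        return None
    return int(hits[0]) + 1


def _sign_pattern(series: np.ndarray, tol: float) -> str:
    """Run-length-encoded signs of consecutive differences.

    Near-zero differences are plateaus: merged into the preceding run, or
    into the following run when they lead the series.
    """
    diffs = np.diff(series)
    signs = np.where(diffs > tol, 1, np.where(diffs < -tol, -1, 0))
    signs = signs[signs != 0]  # plateau merge == dropping zero runs
    pattern = []
    for s in signs:
        mark = "+" if s > 0 else "-"
        if not pattern or pattern[-1] != mark:
            pattern.append(mark)
    return "".join(pattern)


def classify_shape(series: Sequence[float], tol: float = DIFF_TOL) -> ShapeLabel:
    """Qualitative shape label for a per-step series.

    flat_zero: never rises above ``tol``. monotone_decline: starts
    positive and only falls. inverted_U: starts at zero, one rise then
    one fall. M_shape: rise-fall-rise-fall (two interior maxima).
    inverted_N: starts positive, fall-rise-fall. Anything else: other.
    """
    values = np.asarray(series, dtype=float)
    if values.size < 3:
        raise ValueError("series must have at least 3 points")
    if np.max(values) <= tol:
        return ShapeLabel.FLAT_ZERO
    pattern = _sign_pattern(values, tol)
    starts_positive = values[0] > tol
    if pattern == "-" and starts_positive:
        return ShapeLabel.MONOTONE_DECLINE
    if pattern == "+-" and not starts_positive:
        return ShapeLabel.INVERTED_U
    if pattern == "+-+-":
        return ShapeLabel.M_SHAPE
    if pattern == "-+-" and starts_positive:
        return ShapeLabel.INVERTED_N
    return ShapeLabel.OTHER


def cumulative_ocb(traj: Trajectory, dt: float | None = None) -> float:
    """Accumulated OCB over the run: left Riemann sum of the OCB rate.

    The terminal record's OCB (whose flows are never applied) is
    excluded, matching Euler flow semantics.
    """
    dt = traj.dt if dt is None else dt
    rate = traj.series("ocb")[:-1]
    return float(np.sum(rate) * dt)
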