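"""Exposure designs and the shared dose-time coordinate convention.

A design is a full factorial of instilled doses and sacrifice times with
replicated treated animals per (dose, time) condition and replicated vehicle
controls per time point (controls are untreated, so they carry no dose).

All model fitting, activation-map prediction and planted synthetic surfaces
share one coordinate convention: dose and time are log10-transformed and then
min-max scaled to [0, 1] over the design range.  With geometrically spaced
levels such as 18/54/162 ug or 1/3/28 days this puts the levels near
0, 1/2, 1 on each axis.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidDesignError, OutOfRangeError

#: Polynomial term vocabulary shared by fitting and simulation.
LINEAR_TERMS: tuple[str, ...] = ("intercept", "d", "t")
QUADRATIC_TERMS: tuple[str, ...] = ("intercept", "d", "t", "d2", "t2", "dt")

TREATED = "treated"
CONTROL = "control"


@dataclass(frozen=True)
class ExposureDesign:
    """Factorial dose x time instillation design.

    Parameters
    ----------
    doses : strictly increasing positive dose levels (ug).
    times : strictly increasing positive sacrifice times (days).
    n_treated : treated animals per (dose, time) condition.
    n_control : vehicle-control animals per time point.
    seed : seed for any simulation drawn on this design.
    """

    doses: tuple[float, ...]
    times: tuple[float, ...]
    n_treated: int
    n_control: int
    seed: int

    @property
    def n_samples(self) -> int:
        return len(self.doses) * len(self.times) * self.n_treated + len(self.times) * self.n_control

    def samples(self) -> pd.DataFrame:
        """Enumerate samples as a table with columns sample_id, dose, time, group.

        Controls have dose = NaN (they are untreated; dose is undefined).
        """
        rows = []
        for time in self.times:
            for dose in self.doses:
                for r in range(1, self.n_treated + 1):
                    rows.append((f"d{dose:g}_t{time:g}_r{r}", dose, time, TREATED))
            for r in range(1, self.n_control + 1):
                rows.append((f"ctrl_t{time:g}_r{r}", np.nan, time, CONTROL))
        return pd.DataFrame(rows, columns=["sample_id", "dose", "time", "group"])


def make_design(
    doses: Sequence[float],
    times: Sequence[float],
    n_treated: int = 5,
    n_control: int = 5,
    seed: int = 0,
) -> ExposureDesign:
    """Validate and build an :class:`ExposureDesign`.

    Raises
    ------
    InvalidDesignError
        If either axis has fewer than two strictly increasing positive levels
        (the 2-D surface fit needs a genuine grid), or replicate counts are
        below two.
    """
    for name, levels in (("doses", doses), ("times", times)):
        arr = np.asarray(levels, dtype=float)
        if arr.size < 2:
            raise InvalidDesignError(f"{name} must have at least 2 levels, got {arr.size}")
        if np.any(arr <= 0):
            raise InvalidDesignError(f"{name} must be positive, got {list(arr)}")
        if np.any(np.diff(arr) <= 0):
            raise InvalidDesignError(f"{name} must be strictly increasing, got {list(arr)}")
    if n_treated < 2 or n_control < 2:
        raise InvalidDesignError(
            f"replicate counts must be >= 2, got n_treated={n_treated}, n_control={n_control}"
        )
    return ExposureDesign(
        doses=tuple(float(x) for x in doses),
        times=tuple(float(x) for x in times),
        n_treated=int(n_treated),
        n_control=int(n_control),
        seed=int(seed),
    )


def _normalize(values: np.ndarray, lo: float, hi: float, what: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if np.any(values < lo) or np.any(values > hi):
        raise OutOfRangeError(f"{what} outside design range [{lo:g}, {hi:g}]")
    return (np.log10(values) - np.log10(lo)) / (np.log10(hi) - np.log10(lo))


def to_model_coords(dose, time, design: ExposureDesign):
    """Map raw (dose, time) to normalized model coordinates (d, t) in [0, 1]^2.

    Both axes use log10 then min-max scaling over the design range; the design
    endpoints map to exactly 0 and 1.  Accepts scalars or arrays.
    """
    d = _normalize(np.asarray(dose), design.doses[0], design.doses[-1], "dose")
    t = _normalize(np.asarray(time), design.times[0], design.times[-1], "time")
    return d, t


def term_columns(d: np.ndarray, t: np.ndarray, terms: Sequence[str]) -> np.ndarray:
    """Design-matrix columns for the given polynomial terms at (d, t)."""
    d = np.asarray(d, dtype=float)
    t = np.asarray(t, dtype=float)
    table = {
        "intercept": np.ones_like(d),
        "d": d,
        "t": t,
        "d2": d * d,
        "t2": t * t,
        "dt": d * t,
    }
    return np.column_stack([table[term] for term in terms])


def eval_surface(coefficients: Mapping[str, float], d, t):
    """Evaluate a polynomial surface (term -> coefficient) at (d, t)."""
    d = np.asarray(d, dtype=float)
    t = np.asarray(t, dtype=float)
    out = np.zeros(np.broadcast(d, t).shape, dtype=float)
    table = {"intercept": 1.0, "d": d, "t": t, "d2": d * d, "t2": t * t, "dt": d * t}
    for term, coef in coefficients.items():
        if term not in table:
            raise KeyError(f"unknown polynomial term {term!r}")
        out = out + coef * table[term]
    return out


def dose_derivative(coefficients: Mapping[str, float], d, t):
    """Partial derivative of the surface along the normalized dose axis."""
    d = np.asarray(d, dtype=float)
    t = np.asarray(t, dtype=float)
    return (
        coefficients.get("d", 0.0)
        + 2.0 * coefficients.get("d2", 0.0) * d
        + coefficients.get("dt", 0.0) * t
    )
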