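"""Monotone dose-responsive regions and dynamic point-of-departure labels.

Given an activation map, each time column is scanned along the dose axis:
the finite-difference dose gradient defines the maximal contiguous run of
strictly monotone (constant, nonzero gradient sign) dose bins ending at the
top dose.  Within that run, the column's point of departure (POD) is the
lowest dose bin whose |predicted log2FC| reaches the activity threshold,
provided the top-dose bin itself is above threshold — a response that fades
below threshold at the highest dose is not a monotone dose response.  A map
with at least one column POD is dose-responsive.

The dynamic POD (dPOD) of a responsive map is its earliest responsive time
column and that column's POD dose bin ("earliest, then most sensitive").
Both axes are split into thirds to give the 3x3 label grid:
dose sensitive/intermediate/resilient, time early/middle/late.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import NotResponsiveError, ShapeError
from .foldchange import DEFAULT_FC_THRESHOLD
from .surface import ActivationMap

DOSE_SECTIONS = ("sensitive", "intermediate", "resilient")
TIME_SECTIONS = ("early", "middle", "late")

#: |log2FC| >= log2(1.5): the default activity threshold on activation maps.
DEFAULT_ACTIVITY_THRESHOLD = float(np.log2(1.5))


@dataclass
class ResponsiveRegion:
    """Detector output for one activation map.

    ``pod_dose_bin_per_time[j]`` is the 0-based POD dose bin of time column j
    or None; ``mask[i, j]`` is True from the column POD up to the top dose.
    ``direction`` is the shared gradient sign over responsive columns
    (majority on conflict, with ``mixed_direction`` set).
    """

    mask: np.ndarray
    pod_dose_bin_per_time: list[Optional[int]]
    direction: str  # "increasing" | "decreasing" | "none"
    is_responsive: bool
    mixed_direction: bool = False


def find_responsive_region(
    amap: ActivationMap,
    activity_threshold_log2: float = DEFAULT_ACTIVITY_THRESHOLD,
) -> ResponsiveRegion:
    """Locate the monotone dose-responsive area of an activation map."""
    z = np.asarray(amap.grid, dtype=float)
    if z.ndim != 2:
        raise ShapeError(f"activation map must be 2-D, got shape {z.shape}")
    nd, nt = z.shape
    grad = np.diff(z, axis=0)
    mask = np.zeros_like(z, dtype=bool)
    pods: list[Optional[int]] = []
    signs: list[int] = []
    for j in range(nt):
        g = grad[:, j]
        s = np.sign(g[-1])
        if s == 0:
            pods.append(None)
            continue
        lo = nd - 1  # lowest dose bin of the monotone run ending at the top
        for i in range(nd - 2, -1, -1):
            if np.sign(g[i]) != s:
                break
            lo = i
        # run covers bins [lo, nd-1]; needs >= 1 gradient step by construction
        if abs(z[nd - 1, j]) < activity_threshold_log2:
            pods.append(None)
            continue
        run_abs = np.abs(z[lo:, j])
        above = np.nonzero(run_abs >= activity_threshold_log2)[0]
        pod = lo + int(above[0])
        pods.append(pod)
        signs.append(int(s))
        mask[pod:, j] = True
    responsive = any(p is not None for p in pods)
    if not responsive:
        direction, mixed = "none", False
    else:
        n_up = sum(1 for s in signs if s > 0)
        n_down = len(signs) - n_up
        direction = "increasing" if n_up >= n_down else "decreasing"
        mixed = n_up > 0 and n_down > 0
    return ResponsiveRegion(
        mask=mask,
        pod_dose_bin_per_time=pods,
        direction=direction,
        is_responsive=responsive,
        mixed_direction=mixed,
    )


@dataclass(frozen=True)
class DPODLabel:
    """dPOD grid label plus the underlying 1-based POD bin coordinates."""

    dose_section: str
    time_section: str
    pod_dose_bin: int  # 1-based
    pod_time_bin: int  # 1-based


def _section(value: float, names: tuple[str, str, str]) -> str:
    if value < 1.0 / 3.0:
        return names[0]
    if value < 2.0 / 3.0:
        return names[1]
    return names[2]


def assign_dpod_label(region: ResponsiveRegion, amap: ActivationMap) -> DPODLabel:
    """Label the earliest, most sensitive activation of a responsive map.

    The POD time bin is the earliest responsive column; the POD dose bin is
    that column's POD.  Sections are thirds of the normalized axes
    (lower-inclusive boundaries at 1/3 and 2/3).
    """
    if not region.is_responsive:
        raise NotResponsiveError("cannot label a non-responsive activation map")
    j = next(i for i, p in enumerate(region.pod_dose_bin_per_time) if p is not None)
    i = region.pod_dose_bin_per_time[j]
    return DPODLabel(
        dose_section=_section(float(amap.dose_grid[i]), DOSE_SECTIONS),
        time_section=_section(float(amap.time_grid[j]), TIME_SECTIONS),
        pod_dose_bin=i + 1,
        pod_time_bin=j + 1,
    )


def tabulate_labels(labels) -> pd.DataFrame:
    """3x3 counts of dPOD labels (rows: dose sections, columns: time sections)."""
    grid = pd.DataFrame(
        np.zeros((3, 3), dtype=int),
        index=pd.Index(DOSE_SECTIONS, name="dose_section"),
        columns=pd.Index(TIME_SECTIONS, name="time_section"),
    )
    for label in labels:
        grid.loc[label.dose_section, label.time_section] += 1
    return grid


def labels_to_frame(
    labels: dict[str, DPODLabel],
    regions: dict[str, ResponsiveRegion],
    bins: int = 50,
) -> pd.DataFrame:
    """One row per responsive entity: direction, POD bins/values, sections."""
    rows = []
    for entity_id, label in labels.items():
        region = regions[entity_id]
        rows.append(
            {
                "entity_id": entity_id,
                "direction": region.direction,
                "pod_dose_bin": label.pod_dose_bin,
                "pod_dose_value": (label.pod_dose_bin - 1) / (bins - 1),
                "pod_time_bin": label.pod_time_bin,
                "pod_time_value": (label.pod_time_bin - 1) / (bins - 1),
                "dose_section": label.dose_section,
                "time_section": label.time_section,
                "mixed_direction": region.mixed_direction,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "entity_id",
            "direction",
            "pod_dose_bin",
            "pod_dose_value",
            "pod_time_bin",
            "pod_time_value",
            "dose_section",
            "time_section",
            "mixed_direction",
        ],
    )
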