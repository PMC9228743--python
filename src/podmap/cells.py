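"""Dose-time modeling of bronchoalveolar lavage (BAL) differential counts.

Counts are normalized against time-matched controls: for every treated and
control animal pair within a (dose, time) condition,

    cc = log2((count_treated + pc) / (count_control + pc))

with a half-count pseudocount pc (default 0.5) so that zero counts (common
for eosinophils) stay defined.  All pairwise comparisons are formed, exactly
as for gene fold changes.

Cell types then go through the same linear/quadratic surface fit as genes,
with one difference: a cell type is never dropped.  When neither model
passes the goodness-of-fit gate, the lower-AIC model is kept instead
(``selected_by = "aic_fallback"``).  Downstream activation maps, responsive
regions and dPOD labels reuse the gene machinery unchanged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import CONTROL, TREATED, ExposureDesign
from .errors import InvalidSpecError, MissingControlError
from .surface import FittedSurface, fit_surface

DEFAULT_PSEUDOCOUNT = 0.5


def normalize_counts(table: pd.DataFrame, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """All pairwise treated-vs-control log2 count ratios per condition.

    Parameters
    ----------
    table : columns cell_type, animal_id, dose, time, group, count.
    pseudocount : added to numerator and denominator counts.

    Returns
    -------
    DataFrame with columns cell_type, dose, time, treated_animal,
    control_animal, cc.
    """
    if pseudocount <= 0:
        raise InvalidSpecError(f"pseudocount must be positive, got {pseudocount}")
    if (table["count"] < 0).any():
        raise InvalidSpecError("counts must be nonnegative")
    controls = table[table["group"] == CONTROL]
    treated = table[table["group"] == TREATED]
    rows = []
    for cell_type, sub in treated.groupby("cell_type", sort=True):
        ctrl_cell = controls[controls["cell_type"] == cell_type]
        for (dose, time), cond in sub.groupby(["dose", "time"]):
            ctrl = ctrl_cell[ctrl_cell["time"] == time]
            if ctrl.empty:
                raise MissingControlError(
                    f"no control animals for cell type {cell_type!r} at time {time:g}"
                )
            tr_counts = cond["count"].to_numpy(dtype=float) + pseudocount
            ctrl_counts = ctrl["count"].to_numpy(dtype=float) + pseudocount
            cc = np.log2(tr_counts[:, None] / ctrl_counts[None, :])
            rows.append(
                pd.DataFrame(
                    {
                        "cell_type": cell_type,
                        "dose": dose,
                        "time": time,
                        "treated_animal": np.repeat(cond["animal_id"].to_numpy(), len(ctrl)),
                        "control_animal": np.tile(ctrl["animal_id"].to_numpy(), len(cond)),
                        "cc": cc.ravel(),
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def fit_cell_surface(
    norm: pd.DataFrame,
    design: ExposureDesign,
    cell_type: str | None = None,
    gof_alpha: float = 0.05,
) -> FittedSurface:
    """Fit and select a dose-time surface for one cell type (never rejects).

    Selection mirrors the gene pathway: lower goodness-of-fit p wins when it
    passes ``gof_alpha``.  Otherwise the lower-AIC candidate is returned with
    ``selected_by = "aic_fallback"`` (ties go to the linear model).
    """
    if cell_type is None:
        cell_type = str(norm["cell_type"].iloc[0]) if "cell_type" in norm else "cell"
    lin, quad = fit_surface(norm, design, entity_id=cell_type, value_column="cc")
    best = lin if lin.gof_pvalue <= quad.gof_pvalue else quad
    if best.gof_pvalue <= gof_alpha:
        best = FittedSurface(**{**best.__dict__})
        best.selected_by = "gof"
        return best
    best = lin if lin.aic <= quad.aic else quad
    best = FittedSurface(**{**best.__dict__})
    best.selected_by = "aic_fallback"
    return best


def fit_all_cells(
    norm: pd.DataFrame,
    design: ExposureDesign,
    gof_alpha: float = 0.05,
) -> dict[str, FittedSurface]:
    """Fit every cell type in a normalized count table."""
    return {
        str(cell_type): fit_cell_surface(sub, design, cell_type=str(cell_type), gof_alpha=gof_alpha)
        for cell_type, sub in norm.groupby("cell_type", sort=True)
    }
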