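"""Dose-time response-surface fitting and activation-map prediction.

Each entity's sample-wise log2 fold changes are regressed on the normalized
dose-time coordinates with two candidate models:

* linear:     z = b0 + b_d d + b_t t
* quadratic:  z = b0 + b_d d + b_t t + b_dd d^2 + b_tt t^2 + b_dt d t
  (the full bivariate second-order polynomial, interaction included)

Goodness of fit is the overall F-test p-value of the model against the
intercept-only model.  For genes the lower-p candidate is kept only when its
p-value passes the gate (entities failing it are dropped from the analysis);
for cell counts a fallback to the lower-AIC model applies instead (see
:mod:`podmap.cells`).  The selected model is evaluated on a 50 x 50 grid of
equally spaced normalized dose-time coordinates to form the entity's
activation map, which interpolates the response between the tested doses
and times.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .design import LINEAR_TERMS, QUADRATIC_TERMS, ExposureDesign, eval_surface, term_columns, to_model_coords
from .errors import DegenerateDesignError, InsufficientReplicationError

DEFAULT_GRID_BINS = 50

#: Residual / explained sum-of-squares below this is treated as exactly zero.
_SS_TOL = 1e-12


@dataclass
class FittedSurface:
    """A fitted polynomial dose-time model for one gene or cell type."""

    entity_id: str
    model_order: str  # "linear" | "quadratic"
    coefficients: dict[str, float]
    gof_pvalue: float
    aic: float
    selected_by: Optional[str]  # None until selection; then "gof" | "aic_fallback"
    n_obs: int


@dataclass
class ActivationMap:
    """Predicted log2FC over the normalized dose-time square.

    ``grid[i, j]`` is the model value at (dose_grid[i], time_grid[j]); rows
    run over ascending dose bins, columns over ascending time bins.
    """

    grid: np.ndarray
    dose_grid: np.ndarray
    time_grid: np.ndarray
    source: FittedSurface


def _fit_one(entity_id: str, d, t, z, terms) -> FittedSurface:
    X = term_columns(d, t, terms)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DegenerateDesignError(
            f"{entity_id}: rank-deficient design for {len(terms)}-term model "
            "(need >=2 distinct doses and times)"
        )
    with np.errstate(divide="ignore", invalid="ignore"):  # perfect fits: ssr = 0
        res = sm.OLS(z, X).fit()
        gof = float(res.f_pvalue)
        aic = float(res.aic)
    if res.ssr < _SS_TOL:
        # Perfect fit: F-test degenerates. A flat perfect fit carries no
        # evidence against the intercept-only model; a structured one is
        # infinitely significant.
        gof = 1.0 if res.ess < _SS_TOL else 0.0
    elif np.isnan(gof):
        gof = 1.0
    return FittedSurface(
        entity_id=entity_id,
        model_order="linear" if len(terms) == 3 else "quadratic",
        coefficients=dict(zip(terms, (float(b) for b in res.params))),
        gof_pvalue=gof,
        aic=aic,
        selected_by=None,
        n_obs=int(len(z)),
    )


def fit_surface(
    records: pd.DataFrame,
    design: ExposureDesign,
    entity_id: Optional[str] = None,
    value_column: str = "log2fc",
) -> tuple[FittedSurface, FittedSurface]:
    """Fit the linear and quadratic candidates for one entity.

    ``records`` needs columns dose, time and ``value_column``; all rows enter
    the regression as independent observations.

    Returns the (linear, quadratic) pair; selection is a separate step.
    """
    if entity_id is None:
        entity_id = str(records["gene_id"].iloc[0]) if "gene_id" in records else "entity"
    z = records[value_column].to_numpy(dtype=float)
    if len(z) < 7:
        raise InsufficientReplicationError(
            f"{entity_id}: need >= 7 observations for the quadratic model, got {len(z)}"
        )
    if records["dose"].nunique() < 2 or records["time"].nunique() < 2:
        raise DegenerateDesignError(f"{entity_id}: need >= 2 distinct doses and times")
    d, t = to_model_coords(records["dose"].to_numpy(), records["time"].to_numpy(), design)
    return (
        _fit_one(entity_id, d, t, z, LINEAR_TERMS),
        _fit_one(entity_id, d, t, z, QUADRATIC_TERMS),
    )


def select_model(
    linear: FittedSurface,
    quadratic: FittedSurface,
    gof_alpha: float = 0.05,
) -> Optional[FittedSurface]:
    """Pick the lower goodness-of-fit-p candidate; gate at ``gof_alpha``.

    Returns None (entity rejected, not modeled) when the better candidate's
    p-value exceeds the gate.  Ties go to the linear model.
    """
    best = linear if linear.gof_pvalue <= quadratic.gof_pvalue else quadratic
    if not (best.gof_pvalue <= gof_alpha):
        return None
    out = FittedSurface(**{**best.__dict__})
    out.selected_by = "gof"
    return out


def predict_map(surface: FittedSurface, bins: int = DEFAULT_GRID_BINS) -> ActivationMap:
    """Evaluate the fitted polynomial on a bins x bins activation grid.

    Grid values are equally spaced in [0, 1] endpoints included:
    ``grid_value[i] = i / (bins - 1)``.
    """
    axis = np.linspace(0.0, 1.0, bins)
    dd, tt = np.meshgrid(axis, axis, indexing="ij")
    grid = eval_surface(surface.coefficients, dd, tt)
    return ActivationMap(grid=grid, dose_grid=axis.copy(), time_grid=axis.copy(), source=surface)


def plot_activation_map(amap: ActivationMap, ax=None, levels: int = 20, cmap: str = "RdBu_r"):
    """Contour plot of an activation map (dose ascending on the y axis).

    Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    limit = max(abs(float(amap.grid.min())), abs(float(amap.grid.max())), 1e-9)
    cs = ax.contourf(
        amap.time_grid, amap.dose_grid, amap.grid, levels=levels, cmap=cmap,
        vmin=-limit, vmax=limit,
    )
    ax.figure.colorbar(cs, ax=ax, label="predicted log2FC")
    ax.set_xlabel("time (normalized)")
    ax.set_ylabel("dose (normalized)")
    ax.set_title(amap.source.entity_id)
    return ax


def fit_all_genes(
    fc_table: pd.DataFrame,
    design: ExposureDesign,
    gof_alpha: float = 0.05,
) -> tuple[dict[str, FittedSurface], pd.DataFrame]:
    """Fit and select surfaces for every gene in a fold-change table.

    Returns (selected surfaces by gene, audit table with both candidates'
    goodness-of-fit p and AIC for every gene).
    """
    selected: dict[str, FittedSurface] = {}
    rows = []
    for gene_id, sub in fc_table.groupby("gene_id", sort=True):
        lin, quad = fit_surface(sub, design, entity_id=str(gene_id))
        chosen = select_model(lin, quad, gof_alpha=gof_alpha)
        if chosen is not None:
            selected[str(gene_id)] = chosen
        rows.append(
            {
                "entity_id": gene_id,
                "linear_gof_p": lin.gof_pvalue,
                "quadratic_gof_p": quad.gof_pvalue,
                "linear_aic": lin.aic,
                "quadratic_aic": quad.aic,
                "selected": None if chosen is None else chosen.model_order,
            }
        )
    return selected, pd.DataFrame(rows)


def surfaces_to_frame(surfaces: dict[str, FittedSurface]) -> pd.DataFrame:
    """Serialize selected surfaces, one row per entity (TSV-friendly)."""
    rows = []
    for entity_id, s in surfaces.items():
        row = {
            "entity_id": entity_id,
            "model_order": s.model_order,
            "gof_pvalue": s.gof_pvalue,
            "aic": s.aic,
            "selected_by": s.selected_by,
            "n_obs": s.n_obs,
        }
        for term in QUADRATIC_TERMS:
            row[f"coef_{term}"] = s.coefficients.get(term, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_surfaces(frame: pd.DataFrame) -> dict[str, FittedSurface]:
    """Inverse of :func:`surfaces_to_frame`."""
    out: dict[str, FittedSurface] = {}
    for _, row in frame.iterrows():
        terms = LINEAR_TERMS if row["model_order"] == "linear" else QUADRATIC_TERMS
        out[str(row["entity_id"])] = FittedSurface(
            entity_id=str(row["entity_id"]),
            model_order=str(row["model_order"]),
            coefficients={term: float(row[f"coef_{term}"]) for term in terms},
            gof_pvalue=float(row["gof_pvalue"]),
            aic=float(row["aic"]),
            selected_by=str(row["selected_by"]),
            n_obs=int(row["n_obs"]),
        )
    return out
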