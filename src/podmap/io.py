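"""File schemas and validated loading.

On-disk formats (all plain text):

* expression matrix — TSV, genes in rows (index column ``gene_id``),
  samples in columns, log2 scale;
* sample annotation — CSV with columns sample_id, dose, time, group
  (group is ``treated`` or ``control``; controls leave dose empty);
* BAL cell counts — CSV with columns cell_type, animal_id, dose, time,
  group, count;
* gene sets — GMT (see :func:`podmap.summarize.read_gmt`).

:func:`load_inputs` validates the files against these schemas and their
cross-file consistency, naming the offending file/row in every error.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .design import CONTROL, TREATED, ExposureDesign, make_design
from .errors import SchemaError
from .summarize import read_gmt

ANNOTATION_COLUMNS = ["sample_id", "dose", "time", "group"]
COUNT_COLUMNS = ["cell_type", "animal_id", "dose", "time", "group", "count"]


def write_expression(expr: pd.DataFrame, path) -> None:
    # %.17g round-trips doubles exactly
    expr.to_csv(path, sep="\t", index_label="gene_id", float_format="%.17g")


def read_expression(path) -> pd.DataFrame:
    expr = pd.read_csv(path, sep="\t", index_col="gene_id", float_precision="round_trip")
    if expr.index.has_duplicates or expr.columns.has_duplicates:
        raise SchemaError(f"{path}: duplicate gene or sample identifiers")
    if not all(np.issubdtype(dt, np.number) for dt in expr.dtypes):
        raise SchemaError(f"{path}: non-numeric expression values")
    return expr


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, index=False)


def read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path)
    missing = set(ANNOTATION_COLUMNS) - set(ann.columns)
    if missing:
        raise SchemaError(f"{path}: missing annotation columns {sorted(missing)}")
    bad = ~ann["group"].isin([TREATED, CONTROL])
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 2  # 1-based, after header
        raise SchemaError(f"{path}:{row}: group must be '{TREATED}' or '{CONTROL}'")
    treated = ann["group"] == TREATED
    if ann.loc[treated, "dose"].isna().any() or ann.loc[treated, "time"].isna().any():
        raise SchemaError(f"{path}: treated samples need dose and time")
    if ann["sample_id"].duplicated().any():
        raise SchemaError(f"{path}: duplicate sample_id values")
    return ann[ANNOTATION_COLUMNS]


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, index=False)


def read_counts(path) -> pd.DataFrame:
    counts = pd.read_csv(path)
    missing = set(COUNT_COLUMNS) - set(counts.columns)
    if missing:
        raise SchemaError(f"{path}: missing count columns {sorted(missing)}")
    bad = counts["count"].isna() | (counts["count"] < 0) | (counts["count"] % 1 != 0)
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 2
        raise SchemaError(f"{path}:{row}: count must be a nonnegative integer")
    counts["count"] = counts["count"].astype(int)
    return counts[COUNT_COLUMNS]


@dataclass
class Dataset:
    """Validated in-memory inputs for one exposure."""

    expression: pd.DataFrame
    annotation: pd.DataFrame
    design: ExposureDesign
    counts: Optional[pd.DataFrame] = None
    gene_sets: Optional[dict[str, set[str]]] = None


def design_from_annotation(annotation: pd.DataFrame, seed: int = 0) -> ExposureDesign:
    """Recover the factorial design implied by an annotation table."""
    treated = annotation[annotation["group"] == TREATED]
    doses = sorted(treated["dose"].unique())
    times = sorted(treated["time"].unique())
    n_treated = int(treated.groupby(["dose", "time"]).size().min())
    controls = annotation[annotation["group"] == CONTROL]
    n_control = int(controls.groupby("time").size().min()) if len(controls) else 0
    return make_design(doses, times, n_treated, n_control, seed=seed)


def load_inputs(
    expression_path,
    annotation_path,
    counts_path=None,
    gmt_path=None,
    seed: int = 0,
) -> Dataset:
    """Load and cross-validate a full input bundle."""
    expr = read_expression(expression_path)
    ann = read_annotation(annotation_path)
    extra = set(expr.columns) - set(ann["sample_id"])
    if extra:
        raise SchemaError(
            f"{annotation_path}: samples present in the matrix but not annotated: "
            f"{sorted(extra)[:5]}"
        )
    unused = set(ann["sample_id"]) - set(expr.columns)
    if unused:
        raise SchemaError(
            f"{expression_path}: annotated samples missing from the matrix: {sorted(unused)[:5]}"
        )
    design = design_from_annotation(ann, seed=seed)
    counts = None
    if counts_path is not None:
        counts = read_counts(counts_path)
        treated = counts[counts["group"] == TREATED]
        expr_conditions = set(
            map(tuple, ann.loc[ann["group"] == TREATED, ["dose", "time"]].drop_duplicates().values)
        )
        count_conditions = set(map(tuple, treated[["dose", "time"]].drop_duplicates().values))
        if count_conditions - expr_conditions:
            raise SchemaError(
                f"{counts_path}: dose/time conditions absent from the expression annotation: "
                f"{sorted(count_conditions - expr_conditions)}"
            )
    gene_sets = read_gmt(gmt_path) if gmt_path is not None else None
    return Dataset(expression=expr, annotation=ann, design=design, counts=counts, gene_sets=gene_sets)
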