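"""Sample-wise log2 fold changes and a simple differential-expression screen.

Fold changes are computed between every treated sample and every vehicle
control sacrificed at the same time point, so a condition with n treated and
m control animals contributes n*m fold-change records per gene.  These
records, not per-condition averages, feed the dose-time surface fitter.

The DEG screen is a deliberately plain stand-in for a moderated linear-model
analysis: a Welch two-sample test per gene per condition, Benjamini-Hochberg
adjusted across genes within each condition, gated at |mean log2FC| > 0.58
(log2 of 1.5) and adjusted p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .design import CONTROL, TREATED
from .errors import InsufficientReplicationError, InvalidPValueError, MissingControlError

#: log2(1.5); the fold-change gate used throughout.
DEFAULT_FC_THRESHOLD = 0.58


def _split_samples(annotation: pd.DataFrame):
    """Return (treated rows, controls-by-time dict) validating control cover."""
    treated = annotation[annotation["group"] == TREATED]
    controls = annotation[annotation["group"] == CONTROL]
    by_time = {time: sub["sample_id"].tolist() for time, sub in controls.groupby("time")}
    for _, row in treated.iterrows():
        if not by_time.get(row["time"]):
            raise MissingControlError(
                f"treated sample {row['sample_id']!r} has no control at time {row['time']:g}"
            )
    return treated, by_time


def pairwise_log2fc(expr: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """All treated-vs-control log2 fold changes, matched on time point.

    Parameters
    ----------
    expr : DataFrame, genes x samples, log2 scale.
    annotation : columns sample_id, dose, time, group.

    Returns
    -------
    DataFrame with columns gene_id, dose, time, treated_sample_id,
    control_sample_id, log2fc, one row per (gene, treated, control) pair.
    """
    treated, controls_by_time = _split_samples(annotation)
    genes = expr.index.to_numpy()
    frames = []
    for (dose, time), cond in treated.groupby(["dose", "time"]):
        tr_ids = cond["sample_id"].tolist()
        ctrl_ids = controls_by_time[time]
        # genes x (n_tr * n_ctrl) difference of log2 values
        diff = (
            expr[tr_ids].to_numpy()[:, :, None] - expr[ctrl_ids].to_numpy()[:, None, :]
        ).reshape(len(genes), -1)
        tr_rep = np.repeat(tr_ids, len(ctrl_ids))
        ctrl_rep = np.tile(ctrl_ids, len(tr_ids))
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": np.repeat(genes, diff.shape[1]),
                    "dose": dose,
                    "time": time,
                    "treated_sample_id": np.tile(tr_rep, len(genes)),
                    "control_sample_id": np.tile(ctrl_rep, len(genes)),
                    "log2fc": diff.ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise InvalidPValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DEGResult:
    """Per-condition differential-expression calls plus their union.

    ``table`` has one row per (gene, dose, time) with mean log2FC, the Welch
    p-value, the within-condition BH-adjusted p-value and the significance
    flag; ``union`` is the set of genes flagged in at least one condition.
    """

    table: pd.DataFrame
    union: set[str]
    fc_threshold: float
    alpha: float


def deg_union(
    expr: pd.DataFrame,
    annotation: pd.DataFrame,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    alpha: float = 0.05,
) -> DEGResult:
    """Flag differentially expressed genes per dose-time condition.

    Within each condition a Welch two-sample test compares treated and
    time-matched control samples per gene; BH adjustment is applied across
    genes within the condition.  A gene is flagged when
    |mean log2FC| > fc_threshold and adjusted p < alpha.
    """
    treated, controls_by_time = _split_samples(annotation)
    rows = []
    for (dose, time), cond in treated.groupby(["dose", "time"]):
        tr_ids = cond["sample_id"].tolist()
        ctrl_ids = controls_by_time[time]
        if len(tr_ids) < 2 or len(ctrl_ids) < 2:
            raise InsufficientReplicationError(
                f"condition (dose={dose:g}, time={time:g}) has {len(tr_ids)} treated "
                f"and {len(ctrl_ids)} control samples; need >= 2 of each"
            )
        a = expr[tr_ids].to_numpy()
        b = expr[ctrl_ids].to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            pvals = stats.ttest_ind(a, b, axis=1, equal_var=False).pvalue
        pvals = np.where(np.isnan(pvals), 1.0, pvals)  # zero-variance genes: no evidence
        mfc = a.mean(axis=1) - b.mean(axis=1)
        adj = bh_adjust(pvals)
        rows.append(
            pd.DataFrame(
                {
                    "gene_id": expr.index,
                    "dose": dose,
                    "time": time,
                    "mean_log2fc": mfc,
                    "pvalue": pvals,
                    "adj_pvalue": adj,
                    "significant": (np.abs(mfc) > fc_threshold) & (adj < alpha),
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    union = set(table.loc[table["significant"], "gene_id"])
    return DEGResult(table=table, union=union, fc_threshold=fc_threshold, alpha=alpha)
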