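"""Region-weighted correlation of gene and cell activation maps.

For a (gene, cell type) pair the 50x50 grid is partitioned by the two
dose-responsive masks: region A where both are dose-dependent, region B where
exactly one is, region C where neither is.  Within each region both maps are
binarized against their own regional mean (1 = above the region's mean
activation) and the Pearson correlation of the two binary vectors (the phi
coefficient) is computed.  The three regional correlations are combined as a
weighted mean with weights 0.7 / 0.2 / 0.1 for A / B / C, giving most weight
to the jointly dose-dependent area; the pair is called correlated when
|combined| exceeds 0.6.

A region can be undefined: empty, or binarizing to a constant vector (phi
undefined).  By default its weight is dropped and the remaining weights
renormalized, which keeps the combined value a correlation (self-correlation
stays exactly 1).  The alternative policy ("zero") counts undefined regions
as zero contribution without renormalizing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ShapeError

DEFAULT_WEIGHTS = (0.7, 0.2, 0.1)
DEFAULT_PASS_THRESHOLD = 0.6
REGIONS = ("a", "b", "c")


@dataclass
class RegionPartition:
    """Disjoint A/B/C masks covering the whole grid."""

    region_a: np.ndarray
    region_b: np.ndarray
    region_c: np.ndarray

    def __iter__(self):
        return iter((self.region_a, self.region_b, self.region_c))


def partition_regions(gene_mask: np.ndarray, cell_mask: np.ndarray) -> RegionPartition:
    """AND / XOR / NOR partition of two dose-responsive masks."""
    gene_mask = np.asarray(gene_mask, dtype=bool)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if gene_mask.shape != cell_mask.shape:
        raise ShapeError(f"mask shapes differ: {gene_mask.shape} vs {cell_mask.shape}")
    return RegionPartition(
        region_a=gene_mask & cell_mask,
        region_b=gene_mask ^ cell_mask,
        region_c=~(gene_mask | cell_mask),
    )


def binarize_region(grid: np.ndarray, region: np.ndarray) -> np.ndarray:
    """1 where the map value strictly exceeds the regional mean, else 0.

    Cells are traversed in fixed row-major (dose-major) order.  Returns an
    empty vector for an empty region (the caller treats that as undefined).
    """
    grid = np.asarray(grid, dtype=float)
    region = np.asarray(region, dtype=bool)
    if grid.shape != region.shape:
        raise ShapeError(f"grid shape {grid.shape} != region shape {region.shape}")
    values = grid[region]  # row-major by numpy boolean indexing
    if values.size == 0:
        return np.zeros(0, dtype=int)
    return (values > values.mean()).astype(int)


def _phi(x: np.ndarray, y: np.ndarray) -> Optional[float]:
    """Pearson correlation of two equal-length binary vectors; None if undefined."""
    if x.size == 0 or np.all(x == x[0]) or np.all(y == y[0]):
        return None
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class CorrelationResult:
    """Region correlations and their weighted combination for one pair."""

    gene_id: str
    cell_type: str
    r_a: Optional[float]
    r_b: Optional[float]
    r_c: Optional[float]
    combined: Optional[float]
    passes: bool
    defined_weights: tuple[float, ...]


def weighted_map_correlation(
    gene_grid: np.ndarray,
    cell_grid: np.ndarray,
    gene_mask: np.ndarray,
    cell_mask: np.ndarray,
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
    pass_threshold: float = DEFAULT_PASS_THRESHOLD,
    undefined_region_policy: str = "renormalize",
    gene_id: str = "gene",
    cell_type: str = "cell",
) -> CorrelationResult:
    """Region-partitioned, binarized, weighted Pearson correlation of two maps."""
    gene_grid = np.asarray(gene_grid, dtype=float)
    cell_grid = np.asarray(cell_grid, dtype=float)
    if gene_grid.shape != cell_grid.shape:
        raise ShapeError(f"grid shapes differ: {gene_grid.shape} vs {cell_grid.shape}")
    if undefined_region_policy not in ("renormalize", "zero"):
        raise ValueError(f"unknown undefined_region_policy {undefined_region_policy!r}")
    partition = partition_regions(gene_mask, cell_mask)
    rs: list[Optional[float]] = []
    for region in partition:
        rs.append(_phi(binarize_region(gene_grid, region), binarize_region(cell_grid, region)))
    defined = [(w, r) for w, r in zip(weights, rs) if r is not None]
    if not defined:
        combined: Optional[float] = None
        passes = False
        used: tuple[float, ...] = ()
    else:
        used = tuple(w for w, _ in defined)
        if undefined_region_policy == "renormalize":
            combined = sum(w * r for w, r in defined) / sum(used)
        else:
            combined = sum(w * r for w, r in defined)
        passes = abs(combined) > pass_threshold
    return CorrelationResult(
        gene_id=gene_id,
        cell_type=cell_type,
        r_a=rs[0],
        r_b=rs[1],
        r_c=rs[2],
        combined=combined,
        passes=passes,
        defined_weights=used,
    )


def correlate_all(
    gene_maps: dict[str, np.ndarray],
    gene_masks: dict[str, np.ndarray],
    cell_maps: dict[str, np.ndarray],
    cell_masks: dict[str, np.ndarray],
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
    pass_threshold: float = DEFAULT_PASS_THRESHOLD,
    undefined_region_policy: str = "renormalize",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlate every responsive gene with every cell type.

    Returns (full table, per-cell summary).  The summary reports, per cell
    type, how many and what proportion of the responsive genes pass the
    |combined| threshold; a gene may pass for several cell types.
    """
    rows = []
    for gene_id in sorted(gene_maps):
        for cell_type in sorted(cell_maps):
            res = weighted_map_correlation(
                gene_maps[gene_id],
                cell_maps[cell_type],
                gene_masks[gene_id],
                cell_masks[cell_type],
                weights=weights,
                pass_threshold=pass_threshold,
                undefined_region_policy=undefined_region_policy,
                gene_id=gene_id,
                cell_type=cell_type,
            )
            rows.append(
                {
                    "gene_id": gene_id,
                    "cell_type": cell_type,
                    "r_a": np.nan if res.r_a is None else res.r_a,
                    "r_b": np.nan if res.r_b is None else res.r_b,
                    "r_c": np.nan if res.r_c is None else res.r_c,
                    "combined": np.nan if res.combined is None else res.combined,
                    "passes": res.passes,
                }
            )
    columns = ["gene_id", "cell_type", "r_a", "r_b", "r_c", "combined", "passes"]
    table = pd.DataFrame(rows, columns=columns)
    n_genes = len(gene_maps)
    summary_rows = []
    for cell_type in sorted(cell_maps):
        sub = table[table["cell_type"] == cell_type]
        n_pass = int(sub["passes"].sum())
        summary_rows.append(
            {
                "cell_type": cell_type,
                "n_genes": n_genes,
                "n_passing": n_pass,
                "proportion_passing": n_pass / n_genes if n_genes else 0.0,
            }
        )
    return table, pd.DataFrame(summary_rows)
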