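"""Cross-exposure summaries: set intersections, label-profile clustering,
combined p-values and gene-set over-representation.

These operations compare the dynamic dose-dependent gene sets obtained from
several exposures (materials): intersecting them with differential-expression
calls, extracting genes shared across exposures, clustering shared genes by
their dPOD label profiles, combining per-exposure p-values with Fisher's
sum-of-logs method, and testing gene-set over-representation with the
hypergeometric tail on GMT collections.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    EmptyInputError,
    IncompleteProfileError,
    InvalidPValueError,
    SchemaError,
    SubsetError,
)
from .foldchange import bh_adjust

_DOSE_ORDINAL = {"sensitive": 0, "intermediate": 1, "resilient": 2}
_TIME_ORDINAL = {"early": 0, "middle": 1, "late": 2}


def intersect_deg_dpod(deg_set, dpod_set):
    """Intersection of DEG and dPOD gene sets with the three cardinalities.

    Returns (intersection, n_deg, n_dpod, n_overlap).
    """
    deg_set, dpod_set = set(deg_set), set(dpod_set)
    overlap = deg_set & dpod_set
    return overlap, len(deg_set), len(dpod_set), len(overlap)


def shared_genes(dpod_sets: Sequence[set], min_conditions: int) -> set:
    """Genes present in at least ``min_conditions`` of the given sets."""
    if min_conditions > len(dpod_sets):
        raise ValueError(
            f"min_conditions={min_conditions} exceeds number of sets {len(dpod_sets)}"
        )
    counts = Counter()
    for s in dpod_sets:
        counts.update(set(s))
    return {gene for gene, n in counts.items() if n >= min_conditions}


@dataclass(frozen=True)
class SharedGeneCluster:
    """A shared gene, its per-condition dPOD labels, and its cluster id."""

    gene_id: str
    labels: tuple[tuple[str, str], ...]  # (dose_section, time_section) per condition
    cluster_id: int


def encode_label_profile(labels: Sequence[tuple[str, str]]) -> np.ndarray:
    """Ordinal encoding of a dPOD label vector.

    sensitive/early -> 0, intermediate/middle -> 1, resilient/late -> 2;
    pairs are concatenated across conditions.
    """
    out = []
    for dose_section, time_section in labels:
        out.append(_DOSE_ORDINAL[dose_section])
        out.append(_TIME_ORDINAL[time_section])
    return np.asarray(out, dtype=float)


def _complete_linkage_cut(X: np.ndarray, k: int) -> np.ndarray:
    """Agglomerative clustering, Manhattan distance, complete linkage, cut at k.

    Deterministic: on equal merge heights the pair with the lowest
    lexicographic (i, j) index over the current cluster list is merged.
    Zero-height merges (identical profiles) are always performed, so k larger
    than the number of distinct profiles yields one cluster per profile.
    """
    n = len(X)
    clusters: list[list[int]] = [[i] for i in range(n)]
    pointdist = np.abs(X[:, None, :] - X[None, :, :]).sum(axis=2)

    def linkage(a: list[int], b: list[int]) -> float:
        return float(pointdist[np.ix_(a, b)].max())

    target = min(k, n)
    while len(clusters) > 1:
        best = None
        best_h = np.inf
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                h = linkage(clusters[i], clusters[j])
                if h < best_h:
                    best_h, best = h, (i, j)
        # zero-height merges (identical profiles) happen regardless of target
        if best_h > 0.0 and len(clusters) <= target:
            break
        i, j = best
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    assignment = np.zeros(n, dtype=int)
    for cid, members in enumerate(clusters, start=1):
        for m in members:
            assignment[m] = cid
    return assignment


def cluster_shared_genes(
    label_vectors: Mapping[str, Sequence[tuple[str, str]]],
    k: int = 7,
) -> list[SharedGeneCluster]:
    """Cluster shared genes by their per-condition dPOD label profiles.

    Profiles are encoded ordinally and clustered agglomeratively (Manhattan
    distance, complete linkage) into at most ``k`` groups; identical profiles
    always share a cluster.  Cluster ids are renumbered by first gene
    appearance so the partition is invariant to input order up to relabeling.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    genes = list(label_vectors)
    if not genes:
        return []
    n_conditions = len(label_vectors[genes[0]])
    profiles = []
    for gene in genes:
        labels = label_vectors[gene]
        if len(labels) != n_conditions or any(pair is None for pair in labels):
            raise IncompleteProfileError(f"gene {gene!r} lacks a label for some condition")
        profiles.append(encode_label_profile(labels))
    X = np.vstack(profiles)
    # canonical processing order: sort by profile then gene id, for order invariance
    order = sorted(range(len(genes)), key=lambda i: (tuple(X[i]), genes[i]))
    raw = _complete_linkage_cut(X[order], k)
    assignment = np.zeros(len(genes), dtype=int)
    for pos, idx in enumerate(order):
        assignment[idx] = raw[pos]
    # renumber clusters by first appearance in input order
    remap: dict[int, int] = {}
    out = []
    for i, gene in enumerate(genes):
        cid = assignment[i]
        if cid not in remap:
            remap[cid] = len(remap) + 1
        out.append(
            SharedGeneCluster(
                gene_id=gene,
                labels=tuple(tuple(pair) for pair in label_vectors[gene]),
                cluster_id=remap[cid],
            )
        )
    return out


def fisher_combine(pvalues: Sequence[float]) -> float:
    """Fisher's sum-of-logs combined p-value.

    X = -2 sum(ln p_i) is referred to a chi-square distribution with 2k
    degrees of freedom; the upper tail is the combined p.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise EmptyInputError("fisher_combine needs at least one p-value")
    if np.any(p <= 0) or np.any(p > 1):
        raise InvalidPValueError("p-values must lie in (0, 1]")
    x = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(x, df=2 * p.size))


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT gene-set collection: name <TAB> description <TAB> members...

    The description field is ignored; empty member fields are dropped.
    """
    collection: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise SchemaError(f"{path}:{lineno}: GMT line needs name, description, members")
            name = fields[0]
            if name in collection:
                raise SchemaError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            collection[name] = {g for g in fields[2:] if g}
    return collection


def ora_gmt(
    query: set,
    universe: set,
    collection: Mapping[str, set],
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query set against a collection.

    Each collection set is intersected with the universe; the upper-tail
    hypergeometric p of the observed overlap is computed and BH-adjusted
    across sets.  Rows are sorted by p-value.
    """
    query, universe = set(query), set(universe)
    if not query <= universe:
        raise SubsetError("query gene set must be a subset of the universe")
    m = len(universe)
    n_query = len(query)
    rows = []
    for name, members in collection.items():
        members = set(members) & universe
        overlap = len(members & query)
        p = float(stats.hypergeom.sf(overlap - 1, m, len(members), n_query))
        rows.append(
            {
                "set_name": name,
                "overlap": overlap,
                "set_size": len(members),
                "query_size": n_query,
                "universe_size": m,
                "pvalue": min(p, 1.0),
            }
        )
    table = pd.DataFrame(
        rows, columns=["set_name", "overlap", "set_size", "query_size", "universe_size", "pvalue"]
    )
    if len(table):
        table["adj_pvalue"] = bh_adjust(table["pvalue"].to_numpy())
        table = table.sort_values(["pvalue", "set_name"], kind="stable").reset_index(drop=True)
    else:
        table["adj_pvalue"] = []
    return table
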