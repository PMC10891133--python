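"""Median-centered hierarchical clustering of protein expression signatures:
complete linkage on the 1 - Pearson correlation distance, cut into a fixed
number of flat clusters (default 20), with per-cluster significance
summaries and an optional hypergeometric over-representation utility."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .differential import bh_adjust

__all__ = ["ClusterAssignment", "median_center", "pearson_distance_matrix",
           "cluster", "summarize_clusters", "cluster_enrichment"]

#: distance assigned against zero-variance rows (Pearson undefined)
MAX_DISTANCE = 2.0


@dataclass
class ClusterAssignment:
    assignment: pd.Series    # protein -> cluster id (1..k)
    linkage: np.ndarray      # scipy linkage matrix
    dropped: list[str]       # rows with too few observations to place
    k: int

    def members(self, cluster_id: int) -> list[str]:
        return sorted(self.assignment.index[self.assignment == cluster_id])


def median_center(levels: pd.DataFrame) -> pd.DataFrame:
    """Subtract each protein row's median (over observed values); missing
    values are preserved and re-centering is idempotent."""
    return levels.sub(levels.median(axis=1, skipna=True), axis=0)


def pearson_distance_matrix(levels: pd.DataFrame, min_overlap: int = 3
                            ) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise-complete 1 - Pearson distances between rows.

    Rows whose pairwise-complete overlap with every other row falls below
    ``min_overlap`` are dropped (reported).  Zero-variance rows get the
    maximal distance 2 to all others so they remain placeable.
    """
    x = levels.to_numpy(float)
    n = x.shape[0]
    obs = np.isfinite(x)
    dist = np.zeros((n, n))
    usable = np.zeros((n, n), dtype=bool)
    for i in range(n):
        usable[i, i] = True
        for j in range(i + 1, n):
            both = obs[i] & obs[j]
            if both.sum() < min_overlap:
                continue
            usable[i, j] = usable[j, i] = True
            xi, xj = x[i, both], x[j, both]
            si, sj = xi.std(), xj.std()
            if si == 0 or sj == 0:
                d = MAX_DISTANCE
            else:
                d = 1.0 - float(np.corrcoef(xi, xj)[0, 1])
            dist[i, j] = dist[j, i] = d
    keep = usable.sum(axis=1) == n  # row comparable with every kept row
    # relax greedily: drop the least-connected rows until fully comparable
    while not keep.all():
        conn = usable.sum(axis=1) + np.where(keep, 0, -n)
        worst = int(np.argmin(np.where(keep, conn, np.inf)))
        keep[worst] = False
        sub = usable[np.ix_(keep, keep)]
        if sub.all():
            break
    idx = np.flatnonzero(keep)
    kept = levels.index[idx]
    dropped = [p for p in levels.index if p not in set(kept)]
    return pd.DataFrame(dist[np.ix_(idx, idx)], index=kept, columns=kept), dropped


def cluster(centered: pd.DataFrame, k: int = 20, min_overlap: int = 3
            ) -> ClusterAssignment:
    """Agglomerative complete-linkage clustering on 1 - Pearson distance,
    cut into exactly ``k`` flat clusters."""
    dist, dropped = pearson_distance_matrix(centered, min_overlap=min_overlap)
    n = dist.shape[0]
    if k < 1 or k > n:
        raise ValueError(f"k={k} outside [1, {n}]")
    condensed = squareform(np.clip(dist.to_numpy(), 0.0, None), checks=False)
    link = hierarchy.linkage(condensed, method="complete")
    flat = hierarchy.fcluster(link, t=k, criterion="maxclust")
    # renumber clusters deterministically by first-member row order
    order: dict[int, int] = {}
    for label in flat:
        if label not in order:
            order[label] = len(order) + 1
    assignment = pd.Series([order[l] for l in flat], index=dist.index,
                           name="cluster")
    return ClusterAssignment(assignment=assignment, linkage=link,
                             dropped=dropped, k=k)


def summarize_clusters(assignment: ClusterAssignment,
                       differential: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster member count, significant-member counts per tier and the
    dominant direction of change among significant members."""
    rows = []
    for cid in range(1, assignment.k + 1):
        members = assignment.members(cid)
        sub = differential.reindex(members)
        primary = sub.index[sub["tier"] == "primary"]
        extended = sub.index[sub["tier"] == "extended"]
        sig = sub.loc[list(primary) + list(extended)]
        if len(sig):
            direction = "up" if (sig["log10_fc"] > 0).mean() >= 0.5 else "down"
        else:
            direction = "none"
        rows.append((cid, len(members), len(primary), len(extended),
                     len(primary) > 0 or len(extended) > 0, direction,
                     ";".join(members)))
    return pd.DataFrame(rows, columns=["cluster", "n_members", "n_primary",
                                       "n_extended", "contains_significant",
                                       "direction", "members"])


def cluster_enrichment(members: list[str], gene_sets: dict[str, set[str]],
                       universe: list[str]) -> pd.DataFrame:
    """Hypergeometric over-representation of gene sets in one cluster,
    BH-adjusted across sets (stand-alone utility for cluster annotation)."""
    uni = set(universe)
    mem = set(members) & uni
    rows = []
    for name, genes in gene_sets.items():
        g = genes & uni
        overlap = len(g & mem)
        p = float(stats.hypergeom.sf(overlap - 1, len(uni), len(g), len(mem)))
        rows.append((name, len(g), overlap, p))
    out = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p"])
    out["p_adj"] = bh_adjust(out["p"])
    return out.sort_values(["p_adj", "set"]).reset_index(drop=True)
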