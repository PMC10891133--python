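"""Preranked gene-set enrichment and the Jaccard-linked enrichment map.

Proteins are ranked by their directed adjusted p-value (+/-(1 - p_adj),
sign from the fold change).  Enrichment uses the weighted Kolmogorov-
Smirnov running-sum statistic (weight exponent 1 on |directed value|) with
a permutation null (random member positions, shared per set size), NES
normalization by the mean same-sign null, and a pooled-null FDR estimator
with monotonicity enforcement.  Significant sets become graph nodes; edges
join sets whose member overlap has Jaccard index >= 0.80.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .normalize import EmptyResultError

__all__ = ["read_gmt", "write_gmt", "rank_list", "filter_sets",
           "enrichment_score", "preranked_enrichment", "build_graph",
           "jaccard", "EnrichmentResult"]


@dataclass
class EnrichmentResult:
    table: pd.DataFrame            # set, size, es, nes, p, q, leading_edge
    sets: dict[str, set[str]]      # universe-intersected member sets
    n_perm: int
    seed: int


def read_gmt(path) -> dict[str, set[str]]:
    """GMT gene-set file: one set per line (name, description, members);
    duplicate members are removed, empty sets rejected."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            members = {m for m in parts[2:] if m}
            if not members:
                raise ValueError(f"gene set {parts[0]!r} has no members")
            sets[parts[0]] = members
    return sets


def write_gmt(sets: dict[str, set[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            fh.write("\t".join([name, description, *sorted(sets[name])]) + "\n")


def rank_list(differential: pd.DataFrame) -> pd.DataFrame:
    """Ordered (protein, directed) list: descending directed value, ties
    broken by protein identifier."""
    sub = differential.dropna(subset=["directed"]).reset_index()
    col = "protein" if "protein" in sub.columns else sub.columns[0]
    sub = sub.rename(columns={col: "protein"})
    sub = sub.sort_values(["directed", "protein"],
                          ascending=[False, True], kind="mergesort")
    return sub[["protein", "directed"]].reset_index(drop=True)


def filter_sets(sets: dict[str, set[str]], universe: list[str] | set[str],
                min_size: int = 3, max_size: int = 300
                ) -> dict[str, set[str]]:
    """Intersect each set with the ranked universe and keep sets whose
    intersection size lies in [min_size, max_size] (inclusive)."""
    uni = set(universe)
    out = {name: members & uni for name, members in sets.items()}
    out = {n: m for n, m in out.items() if min_size <= len(m) <= max_size}
    if not out:
        raise EmptyResultError(
            f"no gene set has between {min_size} and {max_size} members "
            "in the ranked universe")
    return out


def _es_batch(hits: np.ndarray, weights: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray]:
    """ES for a batch of hit-indicator rows over one ranked weight vector.

    Returns (es, extremum_position).  Hit steps are w_i / sum(hit weights)
    (equal steps if all hit weights are zero); miss steps are -1/(N - h).
    A set covering every item carries no information and scores 0.
    """
    hits = np.atleast_2d(hits).astype(bool)
    n = weights.size
    h = hits.sum(axis=1)
    es = np.zeros(hits.shape[0])
    pos = np.zeros(hits.shape[0], dtype=int)
    full = h == n
    nr = (hits * weights).sum(axis=1)
    zero_nr = (nr == 0) & ~full
    inc = np.where(hits, weights[None, :], 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        inc = inc / np.where(nr == 0, 1.0, nr)[:, None]
    if zero_nr.any():  # degenerate all-zero weights: equal hit steps
        inc[zero_nr] = hits[zero_nr] / h[zero_nr, None]
    miss = np.zeros_like(inc)
    denom = np.where(full, 1.0, n - h).astype(float)
    miss[:] = np.where(hits, 0.0, -1.0 / denom[:, None])
    running = np.cumsum(inc + miss, axis=1)
    idx = np.argmax(np.abs(running), axis=1)
    es = running[np.arange(hits.shape[0]), idx]
    es[full] = 0.0
    pos = idx
    return es, pos


def enrichment_score(ranked: pd.DataFrame, members: set[str],
                     weight_exponent: float = 1.0) -> float:
    """ES of one set against a ranked (protein, directed) list."""
    weights = np.abs(ranked["directed"].to_numpy(float)) ** weight_exponent
    hit = ranked["protein"].isin(members).to_numpy()
    es, _ = _es_batch(hit[None, :], weights)
    return float(es[0])


def preranked_enrichment(ranked: pd.DataFrame, sets: dict[str, set[str]],
                         n_perm: int = 1000, seed: int = 0,
                         weight_exponent: float = 1.0) -> EnrichmentResult:
    """Permutation-null preranked enrichment over a filtered collection.

    Null ES values come from random member positions (``n_perm`` draws,
    shared across sets of the same size).  p is the same-sign null tail
    probability with add-one smoothing; NES = ES / mean |same-sign null|;
    FDR q uses the pooled normalized null with monotonicity enforcement.
    """
    rng = np.random.default_rng(seed)
    proteins = ranked["protein"].to_list()
    weights = np.abs(ranked["directed"].to_numpy(float)) ** weight_exponent
    n = len(proteins)
    index = {p: i for i, p in enumerate(proteins)}

    names = sorted(sets)
    sizes = {name: len(sets[name]) for name in names}
    null_by_size: dict[int, np.ndarray] = {}
    for h in sorted(set(sizes.values())):
        hits = np.zeros((n_perm, n), dtype=bool)
        for r in range(n_perm):
            hits[r, rng.choice(n, size=h, replace=False)] = True
        null_by_size[h], _ = _es_batch(hits, weights)

    rows = []
    pooled_pos: list[np.ndarray] = []
    pooled_neg: list[np.ndarray] = []
    obs_nes = {}
    for name in names:
        hit = np.zeros(n, dtype=bool)
        hit[[index[p] for p in sets[name]]] = True
        es, pos = _es_batch(hit[None, :], weights)
        es, pos = float(es[0]), int(pos[0])
        null = null_by_size[sizes[name]]
        same = null[null >= 0] if es >= 0 else null[null < 0]
        p = (1.0 + float((np.abs(same) >= abs(es)).sum())) / (1.0 + same.size)
        mean_same = float(np.abs(same).mean()) if same.size else np.nan
        nes = es / mean_same if mean_same and np.isfinite(mean_same) else np.nan
        # normalized null for the pooled FDR estimator
        mean_pos = float(null[null >= 0].mean()) if (null >= 0).any() else np.nan
        mean_neg = float(np.abs(null[null < 0]).mean()) if (null < 0).any() else np.nan
        null_nes = np.full(null.shape, np.nan)
        pos_side = null >= 0
        if np.isfinite(mean_pos) and mean_pos > 0:
            null_nes[pos_side] = null[pos_side] / mean_pos
        if np.isfinite(mean_neg) and mean_neg > 0:
            null_nes[~pos_side] = null[~pos_side] / mean_neg
        null_nes = null_nes[np.isfinite(null_nes)]
        pooled_pos.append(null_nes[null_nes >= 0])
        pooled_neg.append(null_nes[null_nes < 0])
        obs_nes[name] = nes
        if es >= 0:
            lead = [proteins[i] for i in range(pos + 1) if hit[i]]
        else:
            lead = [proteins[i] for i in range(pos, n) if hit[i]]
        rows.append({"set": name, "size": sizes[name], "es": es, "nes": nes,
                     "p": p, "leading_edge": ";".join(lead)})

    table = pd.DataFrame(rows)
    pool_pos = np.concatenate(pooled_pos) if pooled_pos else np.array([])
    pool_neg = np.concatenate(pooled_neg) if pooled_neg else np.array([])
    nes_obs = table["nes"].to_numpy(float)
    q = np.full(len(table), np.nan)
    pos_mask = np.isfinite(nes_obs) & (nes_obs >= 0)
    neg_mask = np.isfinite(nes_obs) & (nes_obs < 0)
    n_obs_pos, n_obs_neg = int(pos_mask.sum()), int(neg_mask.sum())
    for i in np.flatnonzero(pos_mask):
        null_frac = ((pool_pos >= nes_obs[i]).sum() / pool_pos.size
                     if pool_pos.size else np.nan)
        obs_frac = (nes_obs[pos_mask] >= nes_obs[i]).sum() / n_obs_pos
        q[i] = min(null_frac / obs_frac, 1.0) if obs_frac > 0 else np.nan
    for i in np.flatnonzero(neg_mask):
        null_frac = ((pool_neg <= nes_obs[i]).sum() / pool_neg.size
                     if pool_neg.size else np.nan)
        obs_frac = (nes_obs[neg_mask] <= nes_obs[i]).sum() / n_obs_neg
        q[i] = min(null_frac / obs_frac, 1.0) if obs_frac > 0 else np.nan
    # monotonicity: q must not decrease as |NES| decreases
    for mask, sign in ((pos_mask, 1.0), (neg_mask, -1.0)):
        idx = np.flatnonzero(mask)
        if idx.size:
            order = idx[np.argsort(-sign * nes_obs[idx], kind="mergesort")]
            q[order] = np.minimum.accumulate(q[order][::-1])[::-1]
    table["q"] = q
    table = table[["set", "size", "es", "nes", "p", "q", "leading_edge"]]
    return EnrichmentResult(table=table, sets=dict(sets), n_perm=n_perm,
                            seed=seed)


def jaccard(a: set[str], b: set[str]) -> float:
    union = a | b
    return len(a & b) / len(union) if union else 0.0


def build_graph(result: EnrichmentResult, fdr_cutoff: float = 0.01,
                jaccard_min: float = 0.80) -> nx.Graph:
    """Enrichment map: nodes are sets with q < cutoff (size attribute =
    member count, nes/q attached); edges join node pairs with Jaccard
    index >= threshold (inclusive), carrying the index as weight."""
    table = result.table
    keep = table[table["q"] < fdr_cutoff]
    graph = nx.Graph()
    for _, row in keep.iterrows():
        graph.add_node(row["set"], size=int(row["size"]),
                       nes=float(row["nes"]), q=float(row["q"]))
    names = list(keep["set"])
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            j = jaccard(result.sets[a], result.sets[b])
            if j >= jaccard_min:
                graph.add_edge(a, b, weight=j)
    return graph
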