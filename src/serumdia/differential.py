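"""Paired case-vs-control differential abundance with BH-FDR control,
significance tiers and the directed +/-(1 - p_adj) ranking value."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["paired_test", "bh_adjust", "directed_transform", "tier",
           "differential_analysis", "volcano_table", "pair_frame"]

#: smallest p emitted for zero-variance difference vectors (flagged)
P_FLOOR = float(np.finfo(float).tiny)

ALPHA_PRIMARY = 0.05
ALPHA_EXTENDED = 0.20


def pair_frame(metadata: pd.DataFrame) -> pd.DataFrame:
    """(pair_id, case_run, control_run) from run-level metadata."""
    subj = metadata[metadata["cohort"].isin(["control", "convalescent"])]
    rows = []
    for pid, grp in subj.groupby("pair_id"):
        cohorts = set(grp["cohort"])
        if len(grp) != 2 or cohorts != {"control", "convalescent"}:
            raise ValueError(f"pair {pid!r} is not one case + one control")
        case = grp.index[grp["cohort"] == "convalescent"][0]
        control = grp.index[grp["cohort"] == "control"][0]
        rows.append((pid, case, control))
    return pd.DataFrame(rows, columns=["pair_id", "case_run", "control_run"]
                        ).sort_values("pair_id").reset_index(drop=True)


def paired_test(levels: pd.DataFrame, pairs: pd.DataFrame,
                min_pairs: int = 3) -> pd.DataFrame:
    """Two-tailed paired t-test per protein on log10 levels.

    d_i = level(case_i) - level(control_i) over pairs where both members are
    observed; t = mean(d) / (sd(d)/sqrt(n)), p from Student t with n-1 df.
    Proteins with fewer than ``min_pairs`` complete pairs get missing
    results.  Zero-variance difference vectors are flagged and their p is
    floored at the smallest positive float instead of an exact zero.
    """
    case = levels[pairs["case_run"]].to_numpy(float)
    ctrl = levels[pairs["control_run"]].to_numpy(float)
    d = case - ctrl
    out = []
    for i, protein in enumerate(levels.index):
        di = d[i][np.isfinite(d[i])]
        n = di.size
        if n < min_pairs:
            out.append((protein, n, np.nan, np.nan, False))
            continue
        mean = float(di.mean())
        sd = float(di.std(ddof=1))
        if sd == 0.0:
            p = 1.0 if mean == 0.0 else P_FLOOR
            out.append((protein, n, mean, p, mean != 0.0))
            continue
        t = mean / (sd / np.sqrt(n))
        p = 2.0 * float(stats.t.sf(abs(t), df=n - 1))
        out.append((protein, n, mean, p, False))
    return pd.DataFrame(out, columns=["protein", "n_pairs_used", "log10_fc",
                                      "p", "zero_variance"]
                        ).set_index("protein")


def bh_adjust(pvals: pd.Series | np.ndarray) -> pd.Series:
    """Benjamini-Hochberg step-up adjustment; missing entries are excluded
    from the family and restored as missing."""
    s = pd.Series(np.asarray(pvals, float),
                  index=getattr(pvals, "index", None))
    obs = s.dropna()
    if ((obs < 0) | (obs > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    adj = s.copy()
    if len(obs):
        adj.loc[obs.index] = multipletests(obs.to_numpy(), method="fdr_bh")[1]
    return adj


def directed_transform(p_adj: float, log10_fc: float) -> float:
    """Signed (1 - p_adj): positive fold change -> +(1-p), negative -> -(1-p),
    exactly zero fold change -> 0."""
    if not np.isfinite(p_adj) or not np.isfinite(log10_fc):
        return np.nan
    if log10_fc == 0.0:
        return 0.0
    return (1.0 - p_adj) if log10_fc > 0 else -(1.0 - p_adj)


def tier(p_adj: float, alpha: float = ALPHA_PRIMARY,
         alpha_extended: float = ALPHA_EXTENDED) -> str:
    if not np.isfinite(p_adj):
        return "ns"
    if p_adj < alpha:
        return "primary"
    if p_adj < alpha_extended:
        return "extended"
    return "ns"


def differential_analysis(levels: pd.DataFrame, metadata: pd.DataFrame,
                          min_pairs: int = 3, alpha: float = ALPHA_PRIMARY,
                          alpha_extended: float = ALPHA_EXTENDED
                          ) -> pd.DataFrame:
    """Full per-protein paired comparison: fold change, p, BH-adjusted p,
    directed value and significance tier."""
    pairs = pair_frame(metadata)
    res = paired_test(levels, pairs, min_pairs=min_pairs)
    res["p_adj"] = bh_adjust(res["p"])
    res["directed"] = [directed_transform(pa, fc)
                       for pa, fc in zip(res["p_adj"], res["log10_fc"])]
    res["tier"] = [tier(pa, alpha, alpha_extended) for pa in res["p_adj"]]
    return res


def volcano_table(results: pd.DataFrame,
                  reliability: pd.Series | None = None) -> pd.DataFrame:
    """Volcano-ready table: fold change, -log10 adjusted p, tier and the
    QC reliability flag carried through from the QC report."""
    with np.errstate(divide="ignore"):
        neglog = -np.log10(results["p_adj"])
    out = pd.DataFrame({"log10_fc": results["log10_fc"],
                        "neg_log10_p_adj": neglog,
                        "tier": results["tier"]})
    out["reliable"] = (reliability.reindex(results.index)
                       if reliability is not None else True)
    return out
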