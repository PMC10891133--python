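"""Post-translational modification occupancy from paired modified/unmodified
peptide intensities: modification level log2(mod / (mod + unmod)),
missingness filter, and a paired cohort test with BH correction."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import ModifiedPeptideTable
from .differential import ALPHA_EXTENDED, ALPHA_PRIMARY, bh_adjust, \
    directed_transform, pair_frame, paired_test, tier
from .normalize import EmptyResultError

__all__ = ["modification_level", "modification_level_table",
           "filter_peptides", "test_occupancy"]


def modification_level(mod: float, unmod: float) -> float:
    """log2 of the modified fraction, log2(mod / (mod + unmod)).

    Defined only where both intensities are observed and their sum is
    positive; a zero modified intensity is indistinguishable from a
    detection failure in DIA, so it yields missing rather than -inf.
    """
    if not (np.isfinite(mod) and np.isfinite(unmod)):
        return np.nan
    if mod < 0 or unmod < 0:
        raise ValueError("intensities must be >= 0")
    if mod == 0 or mod + unmod == 0:
        return np.nan
    return float(np.log2(mod / (mod + unmod)))


def modification_level_table(table: ModifiedPeptideTable) -> pd.DataFrame:
    """Per-peptide, per-run modification levels (vectorized)."""
    mod = table.modified.to_numpy(float)
    unmod = table.unmodified.to_numpy(float)
    ok = np.isfinite(mod) & np.isfinite(unmod) & (mod > 0) & (mod + unmod > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        levels = np.where(ok, np.log2(mod / (mod + unmod)), np.nan)
    return pd.DataFrame(levels, index=table.modified.index,
                        columns=table.modified.columns)


def filter_peptides(levels: pd.DataFrame, max_missing_frac: float = 0.20
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove peptides whose modification level is missing in more than
    ``max_missing_frac`` of the runs (boundary exclusive); returns the
    filtered table and a removal log."""
    frac = levels.isna().mean(axis=1)
    keep = frac <= max_missing_frac
    log = pd.DataFrame({"peptide": levels.index, "missing_frac": frac.to_numpy(),
                        "removed": (~keep).to_numpy()})
    if not keep.any():
        raise EmptyResultError(
            f"all peptides missing in more than {max_missing_frac:.0%} of runs")
    return levels.loc[keep], log


def test_occupancy(levels: pd.DataFrame, metadata: pd.DataFrame,
                   min_pairs: int = 3, alpha: float = ALPHA_PRIMARY,
                   alpha_extended: float = ALPHA_EXTENDED) -> pd.DataFrame:
    """Paired t-test of modification levels (convalescent - control) per
    peptide, BH-adjusted across peptides."""
    pairs = pair_frame(metadata)
    res = paired_test(levels, pairs, min_pairs=min_pairs)
    res = res.rename(columns={"log10_fc": "log2_fc"})
    res["p_adj"] = bh_adjust(res["p"])
    res["directed"] = [directed_transform(pa, fc)
                       for pa, fc in zip(res["p_adj"], res["log2_fc"])]
    res["tier"] = [tier(pa, alpha, alpha_extended) for pa in res["p_adj"]]
    return res.rename_axis("peptide")
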