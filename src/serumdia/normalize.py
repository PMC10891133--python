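"""Fragment-to-protein preprocessing: missingness filter, log2 transform,
per-batch Gaussian-kernel drift correction, cross-batch median equalization,
correlation-ranked fragment selection and sum rollup to log10 protein levels.

The chain is fixed and auditable: filter -> log2 -> fit/correct drift per
batch -> equalize medians -> back-transform -> select -> rollup -> log10.
Missingness is preserved at every step (no imputation).  The fragment
selection + rollup stage is a transparent stand-in for black-box rollup
tools: fragments are ranked by the Pearson correlation of their log2 profile
with the protein's median fragment profile and the top k are summed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import FragmentTable

__all__ = [
    "EmptyResultError",
    "DriftModel",
    "FragmentSelection",
    "ProteinMatrix",
    "filter_fragments",
    "log2_transform",
    "fit_drift",
    "correct_drift",
    "equalize_medians",
    "back_transform",
    "select_fragments",
    "rollup_proteins",
    "preprocess",
]


class EmptyResultError(RuntimeError):
    """A filtering step removed every row."""


@dataclass
class DriftModel:
    """Per-fragment, per-batch Nadaraya-Watson trend at each observed run.

    ``trend`` is aligned with the log2 table it was fitted on (same index and
    columns); entries are NaN where no trend is defined (fragment unobserved
    in the whole batch).
    """

    trend: pd.DataFrame
    kernel_sd: float
    batches: pd.Series  # run_id -> batch


@dataclass
class FragmentSelection:
    """Quality-ranked fragment subsets per protein."""

    selected: dict[str, list[str]]
    scores: pd.DataFrame  # fragment_id, protein, score, rank, selected
    low_fragment_proteins: set[str] = field(default_factory=set)


@dataclass
class ProteinMatrix:
    """Protein x sample log10 abundance matrix after normalization/rollup.

    Subject runs live in ``levels``; QC runs are kept in the parallel
    ``qc_levels`` matrix so the analysis matrix never contains QC columns.
    """

    levels: pd.DataFrame
    qc_levels: pd.DataFrame
    low_fragment_proteins: set[str] = field(default_factory=set)
    reliability: pd.Series | None = None  # filled in by quality control

    @property
    def proteins(self) -> pd.Index:
        return self.levels.index


def filter_fragments(table: FragmentTable,
                     max_missing_frac: float = 0.5
                     ) -> tuple[FragmentTable, pd.DataFrame]:
    """Drop fragments missing in more than ``max_missing_frac`` of all runs.

    The boundary is exclusive: a fragment missing in exactly half of the
    runs is retained.  Returns the filtered table and a removal log.
    """
    if len(table.fragments) == 0:
        raise EmptyResultError("fragment table is empty")
    frac = table.intensities.isna().mean(axis=1)
    keep = frac <= max_missing_frac
    log = pd.DataFrame({"fragment_id": table.fragments,
                        "missing_frac": frac.to_numpy(),
                        "removed": (~keep).to_numpy()})
    if not keep.any():
        raise EmptyResultError(
            f"all fragments missing in more than {max_missing_frac:.0%} of runs")
    filtered = FragmentTable(annotations=table.annotations.loc[keep],
                             intensities=table.intensities.loc[keep])
    return filtered, log


def log2_transform(intensities: pd.DataFrame) -> pd.DataFrame:
    """log2 of linear intensities; nonpositive values become missing."""
    vals = intensities.where(intensities > 0)
    return np.log2(vals)


def fit_drift(log2_table: pd.DataFrame, metadata: pd.DataFrame,
              kernel_sd: float = 5.0) -> DriftModel:
    """Gaussian-kernel (Nadaraya-Watson) run-order trend per fragment, per batch.

    trend(t) = sum_j w_j(t) x_j / sum_j w_j(t),
    w_j(t) = exp(-(t - t_j)^2 / (2 kernel_sd^2)),
    over the observed runs j of that fragment within the batch; the kernel
    has full support (no truncation) and is evaluated at every run position.
    """
    if kernel_sd <= 0:
        raise ValueError("kernel_sd must be > 0")
    trend = pd.DataFrame(np.nan, index=log2_table.index,
                         columns=log2_table.columns)
    for _, runs in metadata.groupby("batch").groups.items():
        runs = [r for r in runs if r in log2_table.columns]
        if not runs:
            continue
        t = metadata.loc[runs, "run_order"].to_numpy(float)
        x = log2_table[runs].to_numpy(float)
        m = np.isfinite(x)
        w = np.exp(-((t[:, None] - t[None, :]) ** 2) / (2.0 * kernel_sd**2))
        num = np.where(m, x, 0.0) @ w
        den = m.astype(float) @ w
        with np.errstate(invalid="ignore", divide="ignore"):
            trend.loc[:, runs] = np.where(den > 0, num / den, np.nan)
    return DriftModel(trend=trend, kernel_sd=kernel_sd,
                      batches=metadata["batch"])


def correct_drift(log2_table: pd.DataFrame, drift: DriftModel,
                  metadata: pd.DataFrame) -> pd.DataFrame:
    """Subtract the fitted trend, re-centered per fragment and batch.

    value' = value - trend(run) + mean(trend over the fragment's observed
    runs in the batch), so drift removal does not itself shift the batch's
    average level; batch alignment is left to median equalization.
    Missing stays missing.
    """
    out = log2_table.copy()
    for _, runs in metadata.groupby("batch").groups.items():
        runs = [r for r in runs if r in log2_table.columns]
        if not runs:
            continue
        x = log2_table[runs].to_numpy(float)
        tr = drift.trend[runs].to_numpy(float)
        obs = np.isfinite(x) & np.isfinite(tr)
        n_obs = obs.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            center = np.where(obs, tr, 0.0).sum(axis=1) \
                / np.where(n_obs > 0, n_obs, np.nan)
        corrected = x - tr + center[:, None]
        out.loc[:, runs] = np.where(np.isfinite(x) & np.isfinite(corrected),
                                    corrected, np.where(np.isfinite(x), x, np.nan))
    return out


def equalize_medians(log2_table: pd.DataFrame, metadata: pd.DataFrame
                     ) -> pd.DataFrame:
    """Shift each batch (log2 scale) so its median over all observed values
    equals the grand median of the pre-shift batch medians."""
    groups = {b: [r for r in runs if r in log2_table.columns]
              for b, runs in metadata.groupby("batch").groups.items()}
    medians = {b: np.nanmedian(log2_table[runs].to_numpy(float))
               for b, runs in groups.items() if runs}
    grand = float(np.median(list(medians.values())))
    out = log2_table.copy()
    for b, runs in groups.items():
        if runs:
            out.loc[:, runs] = log2_table[runs] + (grand - medians[b])
    return out


def back_transform(log2_table: pd.DataFrame) -> pd.DataFrame:
    """Return to the linear intensity scale."""
    return np.power(2.0, log2_table)


def select_fragments(table: FragmentTable, min_fragments: int = 2,
                     max_fragments: int = 5) -> FragmentSelection:
    """Rank each protein's fragments by profile agreement and keep the top k.

    The quality score is the Pearson correlation of the fragment's log2
    profile with the protein's median fragment profile, over runs observed
    in both (>= 3 required, else the score is undefined and ranks last).
    Proteins with fewer than ``min_fragments`` fragments keep all of them
    and are flagged.
    """
    log2 = log2_transform(table.intensities)
    records = []
    selected: dict[str, list[str]] = {}
    low: set[str] = set()
    for protein, ann in table.annotations.groupby("protein", sort=True):
        frags = list(ann.index)
        sub = log2.loc[frags]
        consensus = sub.median(axis=0, skipna=True)
        scores = {}
        for f in frags:
            x = sub.loc[f]
            both = x.notna() & consensus.notna()
            if both.sum() >= 3 and x[both].std() > 0 and consensus[both].std() > 0:
                scores[f] = float(np.corrcoef(x[both], consensus[both])[0, 1])
            else:
                scores[f] = np.nan
        order = sorted(frags, key=lambda f: (-(scores[f] if np.isfinite(scores[f])
                                               else -np.inf), f))
        keep = order[:max_fragments]
        if len(frags) < min_fragments:
            low.add(protein)
            keep = order
        selected[protein] = keep
        for rank, f in enumerate(order, start=1):
            records.append((f, protein, scores[f], rank, f in keep))
    scores_df = pd.DataFrame(records, columns=["fragment_id", "protein",
                                               "score", "rank", "selected"])
    return FragmentSelection(selected=selected, scores=scores_df,
                             low_fragment_proteins=low)


def rollup_proteins(table: FragmentTable, selection: FragmentSelection,
                    metadata: pd.DataFrame) -> ProteinMatrix:
    """Protein level per run = log10(sum of selected fragments' linear
    intensities present in that run); all selected fragments missing -> missing.
    QC runs are split into a parallel matrix."""
    runs = list(table.intensities.columns)
    proteins = sorted(selection.selected)
    levels = np.full((len(proteins), len(runs)), np.nan)
    for i, prot in enumerate(proteins):
        sub = table.intensities.loc[selection.selected[prot]].to_numpy(float)
        obs = np.isfinite(sub)
        total = np.where(obs, sub, 0.0).sum(axis=0)
        any_obs = obs.any(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            levels[i] = np.where(any_obs & (total > 0), np.log10(total), np.nan)
    mat = pd.DataFrame(levels, index=proteins, columns=runs)
    is_qc = metadata.reindex(runs)["cohort"] == "qc"
    return ProteinMatrix(levels=mat.loc[:, list(mat.columns[~is_qc])],
                         qc_levels=mat.loc[:, list(mat.columns[is_qc])],
                         low_fragment_proteins=selection.low_fragment_proteins)


def preprocess(table: FragmentTable, metadata: pd.DataFrame,
               kernel_sd: float = 5.0, max_fragments: int = 5,
               min_fragments: int = 2, max_missing_frac: float = 0.5
               ) -> tuple[ProteinMatrix, list[dict]]:
    """Run the full preprocessing chain; returns the protein matrix and a
    provenance record (one entry per step with its parameters)."""
    provenance: list[dict] = []
    filtered, removal = filter_fragments(table, max_missing_frac)
    provenance.append({"step": "filter_fragments",
                       "max_missing_frac": max_missing_frac,
                       "n_in": len(table.fragments),
                       "n_out": len(filtered.fragments)})
    log2 = log2_transform(filtered.intensities)
    provenance.append({"step": "log2_transform"})
    drift = fit_drift(log2, metadata, kernel_sd=kernel_sd)
    corrected = correct_drift(log2, drift, metadata)
    provenance.append({"step": "drift_correction", "kernel_sd": kernel_sd})
    equalized = equalize_medians(corrected, metadata)
    provenance.append({"step": "equalize_medians"})
    linear = back_transform(equalized)
    provenance.append({"step": "back_transform"})
    normalized = FragmentTable(annotations=filtered.annotations,
                               intensities=linear)
    selection = select_fragments(normalized, min_fragments=min_fragments,
                                 max_fragments=max_fragments)
    provenance.append({"step": "select_fragments",
                       "min_fragments": min_fragments,
                       "max_fragments": max_fragments})
    matrix = rollup_proteins(normalized, selection, metadata)
    provenance.append({"step": "rollup_log10",
                       "n_proteins": len(matrix.proteins),
                       "n_subject_runs": matrix.levels.shape[1],
                       "n_qc_runs": matrix.qc_levels.shape[1]})
    return matrix, provenance
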