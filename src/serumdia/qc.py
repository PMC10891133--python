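"""Measurement reliability from interleaved pooled-QC runs, plus cohort
overview ordinations (PCA and PLS-DA)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA

from .cohort import FragmentTable
from .normalize import ProteinMatrix

__all__ = ["QCReport", "compute_cov", "qc_correlations", "ordination",
           "OrdinationResult"]


@dataclass
class QCReport:
    """Per-protein coefficient-of-variance summary over QC runs.

    CoV is sd/mean of the *linear-scale* QC protein levels within a batch,
    in percent, with the sample (n-1) standard deviation; the average CoV
    pools the batches with a defined CoV.  A protein is flagged unreliable
    when its average CoV exceeds the threshold (strictly).
    """

    cov_per_batch: pd.DataFrame      # protein x batch, percent
    average_cov: pd.Series           # protein -> percent
    reliable: pd.Series              # protein -> bool (avg CoV <= threshold)
    median_cov_per_batch: pd.Series  # batch -> percent
    threshold_pct: float

    @property
    def unreliable_proteins(self) -> list[str]:
        return sorted(self.reliable.index[~self.reliable])


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame        # sample x 2 components
    explained_variance_pct: np.ndarray
    method: str
    n_proteins_used: int
    n_proteins_dropped: int


def compute_cov(matrix: ProteinMatrix, metadata: pd.DataFrame,
                threshold_pct: float = 50.0) -> QCReport:
    """QC coefficient of variance per protein per batch on linear levels.

    Batches with fewer than two observed QC levels for a protein contribute
    no CoV for it; the average is over batches with a defined CoV.
    """
    qc = matrix.qc_levels
    if qc.shape[1] == 0:
        raise ValueError("protein matrix has no QC runs")
    linear = np.power(10.0, qc)
    batches = metadata.reindex(qc.columns)["batch"]
    cov_cols = {}
    for b in sorted(batches.unique()):
        sub = linear.loc[:, list(qc.columns[batches == b])]
        n = sub.notna().sum(axis=1)
        mean = sub.mean(axis=1, skipna=True)
        sd = sub.std(axis=1, ddof=1, skipna=True)
        cov = 100.0 * sd / mean
        cov[n < 2] = np.nan
        cov_cols[b] = cov
    cov_df = pd.DataFrame(cov_cols)
    avg = cov_df.mean(axis=1, skipna=True)
    reliable = ~(avg > threshold_pct)  # NaN average -> not flagged
    return QCReport(cov_per_batch=cov_df, average_cov=avg, reliable=reliable,
                    median_cov_per_batch=cov_df.median(axis=0, skipna=True),
                    threshold_pct=threshold_pct)


def qc_correlations(table: FragmentTable, metadata: pd.DataFrame
                    ) -> pd.DataFrame:
    """Pearson correlations between all QC run pairs on raw linear fragment
    intensities (pairwise-complete); undefined pairs are NaN."""
    qc_runs = [r for r in table.intensities.columns
               if metadata.loc[r, "cohort"] == "qc"]
    if len(qc_runs) < 2:
        raise ValueError("need at least two QC runs")
    sub = table.intensities[qc_runs]
    corr = pd.DataFrame(np.nan, index=qc_runs, columns=qc_runs)
    for i, a in enumerate(qc_runs):
        corr.loc[a, a] = 1.0
        for b in qc_runs[i + 1:]:
            both = sub[a].notna() & sub[b].notna()
            if both.sum() >= 3 and sub.loc[both, a].std() > 0 \
                    and sub.loc[both, b].std() > 0:
                r = float(np.corrcoef(sub.loc[both, a], sub.loc[both, b])[0, 1])
                corr.loc[a, b] = corr.loc[b, a] = r
    return corr


def _fix_signs(coords: np.ndarray, loadings: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray]:
    # reproducible orientation: largest-|loading| entry of each axis positive
    for k in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            coords[:, k] *= -1
    return coords, loadings


def ordination(levels: pd.DataFrame, labels: pd.Series | None = None,
               method: str = "pca", n_components: int = 2
               ) -> OrdinationResult:
    """2-component sample ordination of a protein x sample log10 matrix.

    Proteins with any missing value across the used samples are dropped
    (count reported).  ``pca`` is unsupervised; ``plsda`` regresses on a
    0/1 encoding of ``labels`` (e.g. cohort) and reports the X-variance
    captured per component.  Axis signs are fixed by forcing the
    largest-magnitude loading positive.
    """
    if levels.shape[1] < 3:
        raise ValueError("need at least 3 samples for ordination")
    complete = levels.dropna(axis=0)
    dropped = levels.shape[0] - complete.shape[0]
    x = complete.to_numpy(float).T  # samples x proteins
    xc = x - x.mean(axis=0)
    total_var = float((xc**2).sum())
    if method == "pca":
        model = PCA(n_components=n_components, svd_solver="full")
        coords = model.fit_transform(xc)
        loadings = model.components_.T.copy()
        expl = model.explained_variance_ratio_ * 100.0
    elif method == "plsda":
        if labels is None:
            raise ValueError("plsda requires labels")
        y = pd.get_dummies(labels.reindex(levels.columns)).to_numpy(float)[:, :1]
        model = PLSRegression(n_components=n_components, scale=False)
        model.fit(xc, y - y.mean(axis=0))
        coords = model.x_scores_.copy()
        loadings = model.x_weights_.copy()
        # X variance captured by each PLS component
        expl = np.array([
            float((np.outer(model.x_scores_[:, k], model.x_loadings_[:, k])**2
                   ).sum()) / total_var * 100.0
            for k in range(n_components)])
    else:
        raise ValueError(f"unknown ordination method {method!r}")
    coords, _ = _fix_signs(coords, loadings)
    cdf = pd.DataFrame(coords, index=levels.columns,
                       columns=[f"comp{k + 1}" for k in range(n_components)])
    return OrdinationResult(coordinates=cdf, explained_variance_pct=expl,
                            method=method, n_proteins_used=complete.shape[0],
                            n_proteins_dropped=dropped)
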