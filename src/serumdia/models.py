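"""Six-family linear-regression framework for demographic effects on protein
levels: univariate and multivariate ordinary least squares on (i) healthy
controls, (ii) convalescents and (iii) the paired log10 case/control ratios.

Antibody titer is never a model covariate (it is collinear with symptoms and
days since diagnosis); control-cohort models carry the matched case's
Symptoms and DaysSinceDiagnosis as negative-control covariates; the RATIO
multivariate model additionally includes the Age x Sex interaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .differential import ALPHA_EXTENDED, ALPHA_PRIMARY, bh_adjust, \
    directed_transform, pair_frame, tier
from .normalize import ProteinMatrix

__all__ = ["ModelSpec", "Datasets", "default_model_specs", "build_datasets",
           "fit_models", "significance_grid", "VARIABLES"]

VARIABLES = ("Age", "Sex", "Race", "Symptoms", "DaysSinceDiagnosis")


@dataclass(frozen=True)
class ModelSpec:
    dataset: str  # CONTROL | COVID | RATIO
    form: str     # univariate | multivariate
    variables: tuple[str, ...] = VARIABLES
    interactions: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.dataset not in {"CONTROL", "COVID", "RATIO"}:
            raise ValueError(f"unknown dataset {self.dataset!r}")
        if "Titer" in self.variables:
            raise ValueError("Titer is excluded from modeling")

    @property
    def model_id(self) -> str:
        return f"{self.dataset}_{self.form}"


def default_model_specs() -> list[ModelSpec]:
    """The three univariate and three multivariate model families."""
    specs = [ModelSpec(ds, "univariate") for ds in ("CONTROL", "COVID", "RATIO")]
    specs += [ModelSpec("CONTROL", "multivariate"),
              ModelSpec("COVID", "multivariate"),
              ModelSpec("RATIO", "multivariate",
                        interactions=(("Age", "Sex"),))]
    return specs


@dataclass
class Datasets:
    """Response matrices and aligned covariate frames per model dataset."""

    levels: dict[str, pd.DataFrame]      # dataset -> protein x unit
    covariates: dict[str, pd.DataFrame]  # dataset -> unit x variables


def build_datasets(matrix: ProteinMatrix, metadata: pd.DataFrame) -> Datasets:
    """Split the protein matrix into CONTROL / COVID / RATIO datasets.

    RATIO[protein, pair] is the log10 difference case - control.  CONTROL
    covariate rows are annotated with the matched case's Symptoms and
    DaysSinceDiagnosis.
    """
    pairs = pair_frame(metadata)
    missing = [c for c in pd.concat([pairs["case_run"], pairs["control_run"]])
               if c not in matrix.levels.columns]
    if missing:
        raise ValueError(f"runs missing from protein matrix: {missing}")

    def cov_frame(runs: pd.Series) -> pd.DataFrame:
        sub = metadata.loc[runs]
        case = metadata.loc[pairs["case_run"]]
        return pd.DataFrame({
            "Age": sub["age"].to_numpy(float),
            "Sex": sub["sex"].to_numpy(),
            "Race": sub["race"].to_numpy(),
            "Symptoms": case["symptoms"].to_numpy(),
            "DaysSinceDiagnosis": case["days_since_diagnosis"].to_numpy(float),
        }, index=list(runs))

    control = matrix.levels[pairs["control_run"]]
    covid = matrix.levels[pairs["case_run"]]
    ratio = pd.DataFrame(covid.to_numpy(float) - control.to_numpy(float),
                         index=matrix.levels.index,
                         columns=list(pairs["pair_id"]))
    cov_ratio = cov_frame(pairs["case_run"]).set_axis(list(pairs["pair_id"]))
    return Datasets(
        levels={"CONTROL": control, "COVID": covid, "RATIO": ratio},
        covariates={"CONTROL": cov_frame(pairs["control_run"]),
                    "COVID": cov_frame(pairs["case_run"]),
                    "RATIO": cov_ratio})


def _encode(cov: pd.DataFrame, variables: tuple[str, ...],
            interactions: tuple[tuple[str, str], ...]
            ) -> tuple[pd.DataFrame, dict[str, str]]:
    """Design-matrix columns and a term -> variable map.

    Sex and Symptoms become 0/1 indicators; Race becomes indicator contrasts
    against its most frequent level (all levels retained); Age and
    DaysSinceDiagnosis enter untransformed.
    """
    cols: dict[str, np.ndarray] = {}
    term_var: dict[str, str] = {}

    def add(term: str, var: str, values: np.ndarray) -> None:
        cols[term] = values.astype(float)
        term_var[term] = var

    for var in variables:
        if var in ("Age", "DaysSinceDiagnosis"):
            add(var, var, cov[var].to_numpy(float))
        elif var == "Sex":
            add("Sex[male]", "Sex", (cov["Sex"] == "male").to_numpy())
        elif var == "Symptoms":
            add("Symptoms", "Symptoms",
                cov["Symptoms"].astype(float).to_numpy())
        elif var == "Race":
            ref = cov["Race"].mode().iloc[0]
            for level in sorted(set(cov["Race"]) - {ref}):
                add(f"Race[{level}]", "Race",
                    (cov["Race"] == level).to_numpy())
        else:
            raise ValueError(f"unknown variable {var!r}")
    for a, b in interactions:
        if {a, b} == {"Age", "Sex"}:
            add("Age:Sex[male]", "Age:Sex",
                cov["Age"].to_numpy(float)
                * (cov["Sex"] == "male").to_numpy(float))
        else:
            raise ValueError(f"unsupported interaction {(a, b)!r}")
    x = pd.DataFrame(cols, index=cov.index)
    return x, term_var


def fit_models(datasets: Datasets,
               specs: list[ModelSpec] | None = None) -> pd.DataFrame:
    """OLS fits per protein for every model spec; coefficient p-values from
    two-tailed t-tests, BH-adjusted within each (model, term) family across
    proteins.  Rank-deficient designs (after per-protein row dropping) are
    skipped with a logged reason.
    """
    if specs is None:
        specs = default_model_specs()
    rows = []
    for spec in specs:
        levels = datasets.levels[spec.dataset]
        cov = datasets.covariates[spec.dataset]
        var_groups: list[tuple[tuple[str, ...], tuple[tuple[str, str], ...]]]
        if spec.form == "univariate":
            var_groups = [((v,), ()) for v in spec.variables]
        else:
            var_groups = [(spec.variables, spec.interactions)]
        for variables, interactions in var_groups:
            x_full, term_var = _encode(cov, variables, interactions)
            cov_ok = x_full.notna().all(axis=1)
            x_full = x_full.loc[cov_ok]
            for protein in levels.index:
                y = levels.loc[protein, x_full.index]
                obs = y.notna()
                n = int(obs.sum())
                x = x_full.loc[obs.to_numpy()]
                design = sm.add_constant(x.to_numpy(float), has_constant="add")
                if n < design.shape[1] + 1 or \
                        np.linalg.matrix_rank(design) < design.shape[1]:
                    for term, var in term_var.items():
                        rows.append((protein, spec.model_id, spec.dataset,
                                     spec.form, var, term, np.nan, np.nan, n,
                                     "rank_deficient_or_too_few_rows"))
                    continue
                fit = sm.OLS(y[obs].to_numpy(float), design).fit()
                for k, term in enumerate(x.columns, start=1):
                    rows.append((protein, spec.model_id, spec.dataset,
                                 spec.form, term_var[term], term,
                                 float(fit.params[k]), float(fit.pvalues[k]),
                                 n, ""))
    fits = pd.DataFrame(rows, columns=["protein", "model", "dataset", "form",
                                       "variable", "term", "coefficient",
                                       "p", "n_samples_used", "note"])
    fits["p_adj"] = np.nan
    for _, idx in fits.groupby(["model", "term"]).groups.items():
        fits.loc[idx, "p_adj"] = bh_adjust(fits.loc[idx, "p"]).to_numpy()
    return fits


def significance_grid(fits: pd.DataFrame, differential: pd.DataFrame,
                      alpha: float = ALPHA_PRIMARY,
                      alpha_extended: float = ALPHA_EXTENDED
                      ) -> pd.DataFrame:
    """Display grid of directed +/-(1 - p_adj) values per protein: the
    overall paired comparison plus each variable's multivariate coefficient
    in the CONTROL and COVID cohorts.  For multi-term variables (Race) the
    smallest-p_adj term represents the variable."""
    proteins = differential.index
    grid = pd.DataFrame(index=proteins)
    grid["Overall"] = differential["directed"]
    multi = fits[fits["form"] == "multivariate"]
    for dataset in ("CONTROL", "COVID"):
        sub = multi[multi["dataset"] == dataset]
        for var in VARIABLES:
            cells = []
            vsub = sub[sub["variable"] == var]
            by_prot = dict(tuple(vsub.groupby("protein")))
            for protein in proteins:
                rows = by_prot.get(protein)
                if rows is None or rows["p_adj"].isna().all():
                    cells.append(np.nan)
                    continue
                best = rows.loc[rows["p_adj"].idxmin()]
                cells.append(directed_transform(best["p_adj"],
                                                best["coefficient"]))
            grid[f"{var}({dataset})"] = cells
    tiers = grid.apply(lambda col: [tier(1.0 - abs(v), alpha, alpha_extended)
                                    if np.isfinite(v) else "ns" for v in col])
    tiers.columns = [f"{c}_tier" for c in tiers.columns]
    return pd.concat([grid, tiers], axis=1)
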