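"""Covariate regression framework: dataset construction, OLS against the
normal-equations oracle, exact recovery and the significance grid."""

import numpy as np
import pandas as pd
import pytest

from serumdia.models import (VARIABLES, Datasets, ModelSpec, build_datasets,
                             default_model_specs, fit_models,
                             significance_grid)
from serumdia.normalize import preprocess


def _normal_equations(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    xtx = x.T @ x
    return np.linalg.solve(xtx, x.T @ y)


@pytest.fixture(scope="module")
def datasets(small_matrix):
    matrix, meta = small_matrix
    return build_datasets(matrix, meta), matrix, meta


class TestDatasets:
    def test_ratio_is_log_difference(self, datasets):
        ds, matrix, meta = datasets
        from serumdia.differential import pair_frame
        pairs = pair_frame(meta)
        for _, row in pairs.iterrows():
            expected = (matrix.levels[row["case_run"]]
                        - matrix.levels[row["control_run"]])
            got = ds.levels["RATIO"][row["pair_id"]]
            assert np.allclose(got.dropna(), expected.dropna())

    def test_simple_ratio_values(self):
        from serumdia.normalize import ProteinMatrix
        levels = pd.DataFrame({"case1": [3.0], "ctrl1": [2.5]}, index=["P"])
        meta = pd.DataFrame({
            "cohort": ["convalescent", "control"], "pair_id": ["p1", "p1"],
            "age": [40.0, 40.0], "sex": ["male", "male"],
            "race": ["white", "white"], "symptoms": [True, None],
            "days_since_diagnosis": [30.0, None]},
            index=["case1", "ctrl1"])
        mat = ProteinMatrix(levels=levels, qc_levels=levels.iloc[:, :0])
        ds = build_datasets(mat, meta)
        assert ds.levels["RATIO"].loc["P", "p1"] == pytest.approx(0.5)

    def test_controls_carry_matched_case_covariates(self, datasets):
        ds, _, meta = datasets
        ctrl_cov = ds.covariates["CONTROL"]
        assert ctrl_cov["Symptoms"].notna().all()
        assert ctrl_cov["DaysSinceDiagnosis"].notna().all()

    def test_identical_cohorts_ratio_zero(self):
        from serumdia.normalize import ProteinMatrix
        levels = pd.DataFrame({"case1": [3.0, 2.0], "ctrl1": [3.0, 2.0]},
                              index=["P1", "P2"])
        meta = pd.DataFrame({
            "cohort": ["convalescent", "control"], "pair_id": ["p1", "p1"],
            "age": [40.0, 40.0], "sex": ["female", "female"],
            "race": ["black", "black"], "symptoms": [False, None],
            "days_since_diagnosis": [20.0, None]},
            index=["case1", "ctrl1"])
        mat = ProteinMatrix(levels=levels, qc_levels=levels.iloc[:, :0])
        ds = build_datasets(mat, meta)
        assert (ds.levels["RATIO"] == 0).all().all()


class TestFits:
    def test_exact_linear_recovery(self):
        """A response built as 2*Age is recovered exactly with p ~ 0."""
        rng = np.random.default_rng(0)
        n = 24
        cov = pd.DataFrame({
            "Age": rng.uniform(22, 61, n), "Sex": rng.choice(
                ["male", "female"], n),
            "Race": rng.choice(["white", "black"], n),
            "Symptoms": rng.choice([True, False], n),
            "DaysSinceDiagnosis": rng.uniform(9, 70, n)},
            index=[f"s{i}" for i in range(n)])
        levels = pd.DataFrame([2.0 * cov["Age"].to_numpy()], index=["P"],
                              columns=cov.index)
        ds = Datasets(levels={"COVID": levels}, covariates={"COVID": cov})
        fits = fit_models(ds, [ModelSpec("COVID", "univariate",
                                         variables=("Age",))])
        row = fits[fits["term"] == "Age"].iloc[0]
        assert row["coefficient"] == pytest.approx(2.0, abs=1e-9)
        assert row["p"] < 1e-12

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        n = 20
        cov = pd.DataFrame({
            "Age": rng.uniform(22, 61, n),
            "Sex": rng.choice(["male", "female"], n),
            "Race": rng.choice(["white", "black", "asian"], n),
            "Symptoms": rng.choice([True, False], n),
            "DaysSinceDiagnosis": rng.uniform(9, 70, n)},
            index=[f"s{i}" for i in range(n)])
        y = rng.normal(size=n)
        levels = pd.DataFrame([y], index=["P"], columns=cov.index)
        ds = Datasets(levels={"RATIO": levels}, covariates={"RATIO": cov})
        spec = ModelSpec("RATIO", "multivariate",
                         interactions=(("Age", "Sex"),))
        fits = fit_models(ds, [spec]).set_index("term")
        # rebuild the same design by hand and solve the normal equations
        ref = cov["Race"].mode().iloc[0]
        x = np.column_stack([
            np.ones(n), cov["Age"],
            (cov["Sex"] == "male").astype(float),
            *[(cov["Race"] == lv).astype(float)
              for lv in sorted(set(cov["Race"]) - {ref})],
            cov["Symptoms"].astype(float), cov["DaysSinceDiagnosis"],
            cov["Age"] * (cov["Sex"] == "male")])
        beta = _normal_equations(x, y)
        assert fits.loc["Age", "coefficient"] == pytest.approx(beta[1],
                                                               abs=1e-9)
        assert fits.loc["Age:Sex[male]", "coefficient"] == pytest.approx(
            beta[-1], abs=1e-9)

    def test_univariate_equals_multivariate_when_orthogonal(self):
        """With mutually orthogonal (mean-centered, uncorrelated) covariates
        the univariate and multivariate coefficients coincide."""
        n = 8
        age = np.array([-3., -1., 1., 3., -3., -1., 1., 3.]) + 40
        days = np.array([-2., 2., -2., 2., 2., -2., 2., -2.]) + 30
        assert abs(np.corrcoef(age, days)[0, 1]) < 1e-12
        cov = pd.DataFrame({"Age": age, "DaysSinceDiagnosis": days},
                           index=[f"s{i}" for i in range(n)])
        y = 0.5 * age + 0.2 * days + np.linspace(-0.1, 0.1, n)
        levels = pd.DataFrame([y], index=["P"], columns=cov.index)
        ds = Datasets(levels={"COVID": levels}, covariates={"COVID": cov})
        uni = fit_models(ds, [ModelSpec(
            "COVID", "univariate",
            variables=("Age", "DaysSinceDiagnosis"))]).set_index("term")
        multi = fit_models(ds, [ModelSpec(
            "COVID", "multivariate",
            variables=("Age", "DaysSinceDiagnosis"))]).set_index("term")
        for term in ("Age", "DaysSinceDiagnosis"):
            assert uni.loc[term, "coefficient"] == pytest.approx(
                multi.loc[term, "coefficient"], abs=1e-9)

    def test_rank_deficient_design_skipped_with_reason(self):
        cov = pd.DataFrame({"Age": [40.0] * 5,
                            "Sex": ["male"] * 5},
                           index=[f"s{i}" for i in range(5)])
        levels = pd.DataFrame([np.arange(5.0)], index=["P"],
                              columns=cov.index)
        ds = Datasets(levels={"COVID": levels}, covariates={"COVID": cov})
        fits = fit_models(ds, [ModelSpec("COVID", "multivariate",
                                         variables=("Age", "Sex"))])
        assert (fits["note"] != "").all()
        assert fits["coefficient"].isna().all()

    def test_six_default_families(self, datasets):
        ds, _, _ = datasets
        fits = fit_models(ds, default_model_specs())
        assert set(fits["model"].unique()) == {
            "CONTROL_univariate", "COVID_univariate", "RATIO_univariate",
            "CONTROL_multivariate", "COVID_multivariate",
            "RATIO_multivariate"}
        # the Age x Sex interaction only exists in the RATIO multivariate
        inter = fits[fits["variable"] == "Age:Sex"]
        assert set(inter["model"].unique()) == {"RATIO_multivariate"}
        assert (fits["p_adj"].dropna() >= fits["p"].reindex(
            fits["p_adj"].dropna().index) - 1e-12).all()


class TestGrid:
    def test_grid_shape_and_tiers(self, datasets):
        ds, matrix, meta = datasets
        from serumdia.differential import differential_analysis
        fits = fit_models(ds, default_model_specs())
        diff = differential_analysis(matrix.levels, meta)
        grid = significance_grid(fits, diff)
        value_cols = [c for c in grid.columns if not c.endswith("_tier")]
        assert value_cols[0] == "Overall"
        assert len(value_cols) == 1 + 2 * len(VARIABLES)
        assert len(grid) == len(diff)

    @pytest.mark.parametrize("p_adj,coef,value,expected_tier", [
        (0.10, 1.0, 0.90, "extended"), (0.50, -1.0, -0.50, "ns"),
        (0.01, -2.0, -0.99, "primary")])
    def test_cell_transform(self, p_adj, coef, value, expected_tier):
        from serumdia.differential import directed_transform, tier
        v = directed_transform(p_adj, coef)
        assert v == pytest.approx(value)
        assert tier(1.0 - abs(v)) == expected_tier
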