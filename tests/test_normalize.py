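"""Preprocessing chain: missingness filter, kernel drift model, median
equalization, fragment selection and protein rollup, against closed-form
and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from serumdia.cohort import CohortDesign, FragmentTable, generate_fragments, \
    generate_metadata, metadata_to_frame
from serumdia.normalize import (EmptyResultError, back_transform,
                                correct_drift, equalize_medians,
                                filter_fragments, fit_drift, log2_transform,
                                preprocess, rollup_proteins, select_fragments)
from conftest import brute_force_nw


def _table(values: dict[str, list], runs: list[str],
           protein: str = "P1") -> FragmentTable:
    ann = pd.DataFrame({"peptide": [f"{protein}_pep" for _ in values],
                        "protein": protein},
                       index=pd.Index(values, name="fragment_id"))
    intens = pd.DataFrame(values, index=runs).T
    return FragmentTable(annotations=ann, intensities=intens)


def _meta(runs, batches=None, cohorts=None) -> pd.DataFrame:
    n = len(runs)
    batches = batches or [1] * n
    order, seen = [], {}
    for b in batches:
        seen[b] = seen.get(b, 0) + 1
        order.append(seen[b])
    return pd.DataFrame({"batch": batches, "run_order": order,
                         "cohort": cohorts or ["control"] * n}, index=runs)


class TestFilter:
    def test_majority_missing_removed_half_retained(self):
        runs = [f"r{i}" for i in range(74)]
        vals_38 = [np.nan] * 38 + [100.0] * 36   # 38/74 > 1/2 -> removed
        vals_37 = [np.nan] * 37 + [100.0] * 37   # exactly half -> retained
        table = _table({"f38": vals_38, "f37": vals_37}, runs)
        filtered, log = filter_fragments(table)
        assert list(filtered.fragments) == ["f37"]
        assert log.set_index("fragment_id").loc["f38", "removed"]

    def test_complete_table_unchanged(self):
        runs = ["a", "b"]
        table = _table({"f1": [1.0, 2.0]}, runs)
        filtered, _ = filter_fragments(table)
        pd.testing.assert_frame_equal(filtered.intensities, table.intensities)

    def test_all_removed_raises_with_threshold(self):
        runs = [f"r{i}" for i in range(4)]
        table = _table({"f1": [np.nan, np.nan, np.nan, 1.0]}, runs)
        with pytest.raises(EmptyResultError, match="50%"):
            filter_fragments(table)


class TestDriftModel:
    def test_constant_series_trend_is_constant(self):
        runs = [f"r{i}" for i in range(6)]
        log2 = pd.DataFrame([[3.0] * 6], index=["f1"], columns=runs)
        model = fit_drift(log2, _meta(runs))
        assert np.allclose(model.trend.loc["f1"], 3.0)

    def test_two_points_midway_is_mean(self):
        runs = ["r1", "r2", "r3"]
        meta = _meta(runs)
        log2 = pd.DataFrame([[2.0, np.nan, 6.0]], index=["f1"], columns=runs)
        model = fit_drift(log2, meta)
        assert model.trend.loc["f1", "r2"] == pytest.approx(4.0)

    def test_matches_brute_force_everywhere(self):
        """The fitted trend equals direct summation of the weighted-average
        formula at every run position, including with missing values."""
        rng = np.random.default_rng(0)
        runs = [f"r{i}" for i in range(15)]
        meta = _meta(runs)
        x = rng.normal(10, 2, size=(4, 15))
        x[rng.random(x.shape) < 0.25] = np.nan
        x[:, 0] = np.nan
        log2 = pd.DataFrame(x, index=[f"f{i}" for i in range(4)], columns=runs)
        model = fit_drift(log2, meta, kernel_sd=5.0)
        t = meta["run_order"].to_numpy(float)
        for i, frag in enumerate(log2.index):
            obs = np.isfinite(x[i])
            for j, run in enumerate(runs):
                expected = brute_force_nw(t[j], t[obs], x[i, obs], 5.0)
                assert model.trend.loc[frag, run] == pytest.approx(
                    expected, abs=1e-12)

    def test_invalid_kernel_sd(self):
        runs = ["r1", "r2"]
        log2 = pd.DataFrame([[1.0, 2.0]], index=["f"], columns=runs)
        with pytest.raises(ValueError):
            fit_drift(log2, _meta(runs), kernel_sd=0.0)


class TestDriftCorrection:
    def test_drift_free_data_nearly_unchanged(self):
        rng = np.random.default_rng(1)
        runs = [f"r{i}" for i in range(20)]
        meta = _meta(runs)
        x = 12.0 + rng.normal(0, 0.05, size=(3, 20))
        log2 = pd.DataFrame(x, index=list("abc"), columns=runs)
        corrected = correct_drift(log2, fit_drift(log2, meta), meta)
        assert np.abs(corrected.to_numpy() - x).max() < 0.1

    def test_linear_drift_noise_free_matches_closed_form(self):
        """Correcting a monotone linear series equals the closed-form kernel
        evaluation exactly and strongly flattens the series."""
        n = 61
        runs = [f"r{i}" for i in range(n)]
        meta = _meta(runs)
        t = np.arange(n, dtype=float)
        x = 10.0 + 0.2 * t
        log2 = pd.DataFrame([x], index=["f"], columns=runs)
        corrected = correct_drift(log2, fit_drift(log2, meta), meta)
        trend = np.array([brute_force_nw(ti, t + 1, x, 5.0) for ti in t + 1])
        expected = x - trend + trend.mean()
        assert np.allclose(corrected.to_numpy()[0], expected, atol=1e-12)
        # points further than ~3 kernel sds from the edges are flattened
        assert np.ptp(corrected.to_numpy()[0][15:-15]) < 0.05 * np.ptp(x[15:-15])

    def test_injected_drift_reduces_qc_variance(self):
        design = CohortDesign(n_pairs=8, n_batches=2, n_proteins=15,
                              drift_amplitude=1.5, noise_sd_log2=0.1,
                              missing_rate=0.0, seed=13)
        records = generate_metadata(design)
        meta = metadata_to_frame(records)
        frags, _ = generate_fragments(design, records)
        log2 = log2_transform(frags.intensities)
        corrected = correct_drift(log2, fit_drift(log2, meta), meta)
        qc_runs = meta.index[meta["cohort"] == "qc"]
        for batch in meta["batch"].unique():
            cols = [r for r in qc_runs if meta.loc[r, "batch"] == batch]
            before = log2[cols].var(axis=1, ddof=1).median()
            after = corrected[cols].var(axis=1, ddof=1).median()
            assert after < before

    def test_missingness_preserved(self, small_cohort):
        _, meta, frags, _ = small_cohort
        log2 = log2_transform(frags.intensities)
        corrected = correct_drift(log2, fit_drift(log2, meta), meta)
        assert corrected.isna().equals(log2.isna())


class TestMedianEqualization:
    def test_single_batch_unchanged(self):
        runs = ["r1", "r2", "r3"]
        log2 = pd.DataFrame([[1.0, 2.0, 3.0]], index=["f"], columns=runs)
        out = equalize_medians(log2, _meta(runs))
        pd.testing.assert_frame_equal(out, log2)

    def test_two_batches_meet_at_grand_median(self):
        runs = ["a1", "a2", "b1", "b2"]
        meta = _meta(runs, batches=[1, 1, 2, 2])
        log2 = pd.DataFrame([[10.0, 10.0, 12.0, 12.0]], index=["f"],
                            columns=runs)
        out = equalize_medians(log2, meta)
        assert np.nanmedian(out[["a1", "a2"]]) == pytest.approx(11.0)
        assert np.nanmedian(out[["b1", "b2"]]) == pytest.approx(11.0)

    def test_batch_medians_equal_after_and_idempotent(self, small_cohort):
        _, meta, frags, _ = small_cohort
        log2 = log2_transform(frags.intensities)
        once = equalize_medians(log2, meta)
        medians = [np.nanmedian(once[[r for r in meta.index
                                      if meta.loc[r, "batch"] == b]])
                   for b in meta["batch"].unique()]
        assert np.allclose(medians, medians[0])
        twice = equalize_medians(once, meta)
        pd.testing.assert_frame_equal(twice, once)


class TestSelectionAndRollup:
    def test_identical_profiles_all_selected_score_one(self):
        runs = [f"r{i}" for i in range(6)]
        prof = [100.0, 200.0, 150.0, 300.0, 250.0, 120.0]
        table = _table({f"f{i}": prof for i in range(3)}, runs)
        sel = select_fragments(table, max_fragments=3)
        assert sorted(sel.selected["P1"]) == ["f0", "f1", "f2"]
        assert np.allclose(sel.scores["score"], 1.0)

    def test_anticorrelated_fragment_ranked_last(self):
        rng = np.random.default_rng(2)
        runs = [f"r{i}" for i in range(10)]
        base = rng.normal(10, 1, size=10)
        vals = {f"f{i}": list(2.0 ** (base + rng.normal(0, 0.05, 10)))
                for i in range(5)}
        vals["f_anti"] = list(2.0 ** (20 - base))
        table = _table(vals, runs)
        sel = select_fragments(table, max_fragments=6)
        ranks = sel.scores.set_index("fragment_id")["rank"]
        assert ranks["f_anti"] == 6

    def test_scores_match_brute_force_correlation(self):
        rng = np.random.default_rng(3)
        runs = [f"r{i}" for i in range(12)]
        vals = {f"f{i}": list(2.0 ** rng.normal(10, 1, 12)) for i in range(4)}
        table = _table(vals, runs)
        sel = select_fragments(table)
        log2 = np.log2(table.intensities)
        consensus = log2.median(axis=0)
        for frag in table.fragments:
            expected = np.corrcoef(log2.loc[frag], consensus)[0, 1]
            got = sel.scores.set_index("fragment_id").loc[frag, "score"]
            assert got == pytest.approx(expected, abs=1e-12)

    def test_rollup_log10_of_sum(self):
        runs = ["r1"]
        meta = _meta(runs)
        one = _table({"f1": [1000.0]}, runs)
        sel = select_fragments(one, min_fragments=1)
        mat = rollup_proteins(one, sel, meta)
        assert mat.levels.loc["P1", "r1"] == pytest.approx(3.0)
        two = _table({"f1": [100.0], "f2": [900.0]}, runs)
        mat2 = rollup_proteins(two, select_fragments(two), meta)
        assert mat2.levels.loc["P1", "r1"] == pytest.approx(3.0)

    def test_rollup_missing_when_all_fragments_missing(self):
        runs = ["r1", "r2"]
        table = _table({"f1": [np.nan, 10.0], "f2": [np.nan, 30.0]}, runs)
        mat = rollup_proteins(table, select_fragments(table), _meta(runs))
        assert np.isnan(mat.levels.loc["P1", "r1"])
        assert mat.levels.loc["P1", "r2"] == pytest.approx(np.log10(40.0))


class TestFullChain:
    def test_dimension_contract_and_qc_split(self, default_cohort):
        design, _, meta, frags, _ = default_cohort
        matrix, provenance = preprocess(frags, meta)
        # a protein can drop out only if the missingness filter removed all
        # of its fragments; otherwise the full panel is quantified
        assert matrix.levels.shape[1] == 58
        assert matrix.levels.shape[0] >= 0.97 * design.n_proteins
        assert matrix.qc_levels.shape[1] == int((meta["cohort"] == "qc").sum())
        steps = [p["step"] for p in provenance]
        assert steps == ["filter_fragments", "log2_transform",
                         "drift_correction", "equalize_medians",
                         "back_transform", "select_fragments", "rollup_log10"]

    def test_back_transform_roundtrip(self):
        x = pd.DataFrame([[1.5, np.nan]], index=["f"], columns=["a", "b"])
        pd.testing.assert_frame_equal(log2_transform(back_transform(x)), x)
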