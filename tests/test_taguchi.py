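import numpy as np
import pandas as pd
import pytest
from importlib import resources

from climexsa import (
    DATE_PALM,
    FactorTable,
    build_design,
    default_factor_table,
    load_orthogonal_array,
    main_effects,
    sensitivity_plot_data,
    sn_larger_better,
)
from climexsa.taguchi import TABLE_ORDER, construct_l54, resolve_run, validate_orthogonal_array


@pytest.fixture(scope="module")
def array():
    return load_orthogonal_array()


@pytest.fixture(scope="module")
def design(array):
    return build_design(array)


class TestOrthogonalArray:
    def test_shape_and_level_sets(self, array):
        assert array.shape == (54, 26)
        assert set(np.unique(array[:, 0])) == {1, 2}
        assert set(np.unique(array[:, 1:])) == {1, 2, 3}

    def test_two_level_column_balanced(self, array):
        counts = np.bincount(array[:, 0])[1:]
        assert counts.tolist() == [27, 27]

    def test_three_level_columns_balanced(self, array):
        for j in range(1, 26):
            counts = np.bincount(array[:, j])[1:]
            assert counts.tolist() == [18, 18, 18]

    def test_strength_two_pair_balance_exhaustive(self, array):
        three = array[:, 1:]
        for i in range(25):
            for j in range(i + 1, 25):
                pairs = np.bincount((three[:, i] - 1) * 3 + (three[:, j] - 1), minlength=9)
                assert (pairs == 6).all(), f"columns {i + 1},{j + 1}"

    def test_fixture_matches_construction(self, array):
        np.testing.assert_array_equal(array, construct_l54())

    def test_corrupted_array_detected(self, array):
        bad = array.copy()
        bad[0, 3] = bad[1, 3]  # break balance
        with pytest.raises(ValueError):
            validate_orthogonal_array(bad)
        with pytest.raises(ValueError):
            validate_orthogonal_array(array[:, :-1])


class TestFactorTable:
    def test_default_levels_and_order(self):
        t = default_factor_table()
        assert t.codes == TABLE_ORDER
        assert t.levels["DV2"] == (30.0, 39.0, 45.0)
        assert t.levels["SM3"] == (0.6, 0.9, 1.0)
        assert t.levels["THCS"] == (-0.05, -0.01, 0.0)

    def test_level_2_equals_baseline(self):
        t = default_factor_table()
        for code in t.codes:
            assert t.value(code, 2) == getattr(DATE_PALM, code)

    def test_csv_round_trip(self, tmp_path):
        t = default_factor_table()
        path = tmp_path / "factors.csv"
        t.to_csv(path)
        assert FactorTable.from_csv(path).levels == t.levels

    def test_wrong_level_count_rejected(self):
        with pytest.raises(ValueError):
            FactorTable(levels={"DV0": (1.0, 2.0)})


class TestBuildDesign:
    def test_54_resolved_runs(self, design):
        assert design.n_runs == 54
        assert len(design.runs) == 54

    def test_all_level_two_run_equals_baseline(self, design):
        # every factor at level 2 reproduces the baseline parameter set
        params, repairs = resolve_run(
            {c: design.factors.value(c, 2) for c in design.factors.codes}
        )
        assert params == DATE_PALM
        assert repairs == []

    def test_ordering_repairs_logged_and_valid(self, design):
        assert set(design.repairs["code"]) <= {"DV1", "DV2", "DV3", "SM1", "SM2", "SM3"}
        for p in design.runs:
            p.validate()  # every materialised run satisfies the invariants
        # the known infeasible combinations are repaired as degenerate ramps
        row = design.levels.query("DV2 == 3 and DV3 == 1")
        assert not row.empty
        run = design.runs[row.index[0] - 1]
        assert run.DV3 == pytest.approx(run.DV2 + 0.1)

    def test_single_factor_toy_design_varies_only_that_factor(self):
        toy = np.hstack(
            [np.array([[1, 1, 1]]).T, np.array([[1, 2, 3]]).T]
        )  # 3 runs, one 3-level column
        # bypass the full L54 validation: resolve rows directly
        table = FactorTable(levels={"DV2": (30.0, 39.0, 45.0)})
        runs = []
        for r in range(3):
            vals = {"DV2": table.value("DV2", int(toy[r, 1]))}
            params, _ = resolve_run(vals)
            runs.append(params)
        assert [p.DV2 for p in runs] == [30.0, 39.0, 45.0]
        for code in set(TABLE_ORDER) - {"DV2", "DV3"}:
            assert len({getattr(p, code) for p in runs}) == 1

    def test_sample_run_patterns_resolve_to_valid_parameters(self):
        # published sample level patterns (runs 1-12) all materialise; the
        # run-2 pattern pins the moisture knots at baseline values
        with resources.files("climexsa.data").joinpath("date_palm_sample_runs.csv").open() as fh:
            sample = pd.read_csv(fh)
        table = default_factor_table()
        for _, row in sample.iterrows():
            vals = {c: table.value(c, int(row[c])) for c in TABLE_ORDER}
            params, _ = resolve_run(vals)
            params.validate()
        run2 = sample.iloc[1]
        vals = {c: table.value(c, int(run2[c])) for c in TABLE_ORDER}
        params, repairs = resolve_run(vals)
        assert (params.SM0, params.SM1, params.SM2, params.SM3) == (0.007, 0.013, 0.81, 0.9)
        assert (params.DV2, params.DV3) == (39.0, 46.0)
        assert params.TTCS == 2.0 and params.TTHS == 40.0
        assert repairs == []


class TestSignalToNoise:
    def test_analytic_values(self):
        assert sn_larger_better([1.0]) == pytest.approx(0.0, abs=1e-12)
        assert sn_larger_better([10.0, 10.0]) == pytest.approx(20.0, abs=1e-12)
        assert sn_larger_better([1.0, 2.0, 4.0]) == pytest.approx(
            -10.0 * np.log10(0.4375), rel=1e-12
        )

    def test_single_replicate_reduces_to_20log10(self, rng):
        for y in rng.uniform(0.1, 1e7, 50):
            assert sn_larger_better([y]) == pytest.approx(20 * np.log10(y), rel=1e-12)

    def test_matches_direct_formula_on_random_vectors(self, rng):
        for _ in range(1000):
            y = rng.uniform(0.01, 1e6, rng.integers(1, 8))
            direct = -10.0 * np.log10(np.mean(1.0 / y**2))
            assert sn_larger_better(y) == pytest.approx(direct, rel=1e-12, abs=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            sn_larger_better([1.0, 0.0])
        with pytest.raises(ValueError):
            sn_larger_better([])


def synthetic_results(design, sn):
    return pd.DataFrame(
        {"sn_db": sn, "floored": np.zeros(len(sn), dtype=bool)},
        index=design.levels.index,
    )


class TestMainEffects:
    def test_identical_sn_gives_zero_deltas(self, design):
        report = main_effects(design, synthetic_results(design, np.full(54, 7.0)))
        assert (report.table["delta"] == 0).all()
        assert sorted(report.table["rank"]) == list(range(1, 15))

    def test_level_index_response_isolates_its_factor(self, design):
        # SN equal to DV2's level index: delta 2 dB for DV2, 0 for the rest
        sn = design.levels["DV2"].to_numpy(dtype=float)
        report = main_effects(design, synthetic_results(design, sn))
        assert report.table.loc["DV2", "delta"] == pytest.approx(2.0)
        others = report.table.drop("DV2")["delta"]
        np.testing.assert_allclose(others.to_numpy(), 0.0, atol=1e-12)
        assert report.table.loc["DV2", "rank"] == 1
        assert report.table.loc["DV2", "optimum_level"] == 3

    def test_level_means_conserve_total_sn(self, design, rng):
        sn = rng.normal(0, 3, 54)
        report = main_effects(design, synthetic_results(design, sn))
        total = sn.sum()
        for code in design.factors.codes:
            level_sum = 18.0 * sum(
                report.table.loc[code, f"mean_sn_L{l}"] for l in (1, 2, 3)
            )
            assert level_sum == pytest.approx(total, rel=1e-9)

    def test_constant_shift_leaves_deltas_and_ranks_unchanged(self, design, rng):
        sn = rng.normal(0, 3, 54)
        a = main_effects(design, synthetic_results(design, sn))
        b = main_effects(design, synthetic_results(design, sn + 11.5))
        np.testing.assert_allclose(a.table["delta"], b.table["delta"], atol=1e-10)
        assert (a.table["rank"] == b.table["rank"]).all()
        np.testing.assert_allclose(
            b.table["mean_sn_L1"] - a.table["mean_sn_L1"], 11.5, atol=1e-10
        )

    def test_degenerate_factor_has_exactly_zero_delta(self, array, rng):
        levels = dict(default_factor_table().levels)
        levels["HWS"] = (0.022, 0.022, 0.022)
        design = build_design(array, FactorTable(levels=levels))
        # response depends on parameters only through HWS -> constant
        sn = np.array([p.HWS for p in design.runs], dtype=float)
        report = main_effects(design, synthetic_results(design, sn))
        assert report.table.loc["HWS", "delta"] == 0.0

    def test_rank_ties_broken_by_factor_order(self, design):
        report = main_effects(design, synthetic_results(design, np.zeros(54)))
        assert report.ranking == list(design.factors.codes)

    def test_missing_runs_rejected(self, design, rng):
        short = synthetic_results(design, np.zeros(54)).iloc[:50]
        with pytest.raises(ValueError):
            main_effects(design, short)


class TestPlotData:
    def test_series_shapes_and_flatness(self, design, rng):
        sn = design.levels["SM0"].to_numpy(dtype=float) * 1.5
        report = main_effects(design, synthetic_results(design, sn))
        data = sensitivity_plot_data(report)
        assert set(data) == set(design.factors.codes)
        for code, series in data.items():
            assert [lv for lv, _ in series] == [1, 2, 3]
        assert [m for _, m in data["SM0"]] == pytest.approx([1.5, 3.0, 4.5])
        flat = [m for _, m in data["DV0"]]
        assert max(flat) - min(flat) == pytest.approx(0.0, abs=1e-12)
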