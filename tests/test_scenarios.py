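"""Scenario grid: structure, cross-age comparisons, MM-vs-full agreement."""

import numpy as np
import pandas as pd
import pytest

import pedtmdd as pt

AGE_ORDER = ["2y", "6y", "12y", "18y"]
FAMILY = ["target_policy", "dose_policy", "nominal_dose", "target_level", "model_kind"]


class TestGridStructure:
    def test_default_axis_product(self):
        spec = pt.default_grid()
        assert spec.n_cells() == 1120  # 2*2*5*7*4 scenario cells x 2 model kinds
        assert 1.74 in spec.target_concentrations
        assert 4.87 in spec.target_amounts

    def test_one_record_per_key_and_no_failures(self, full_table):
        keys = FAMILY + ["age_label"]
        assert len(full_table) == 1120
        assert not full_table.duplicated(subset=keys).any()
        assert (full_table["error"] == "").all()

    def test_reference_age_ratio_is_100(self, full_table):
        ref_rows = full_table[full_table["age_label"] == "18y"]
        assert ref_rows["auc_ratio_vs_18y"].to_numpy() == pytest.approx(
            np.full(len(ref_rows), 100.0), rel=1e-12
        )


class TestCrossAgeComparisons:
    def test_fixed_dose_cmax_decreases_with_age(self, full_table):
        fixed = full_table[
            (full_table["dose_policy"] == "fixed") & (full_table["model_kind"] == "tmdd")
        ]
        for _, group in fixed.groupby(["target_policy", "nominal_dose", "target_level"]):
            cmax = group.set_index("age_label")["cmax"].reindex(AGE_ORDER).to_numpy()
            assert np.all(np.diff(cmax) < 0.0)

    def test_cl_fraction_decreases_with_dose(self, full_table):
        tmdd = full_table[full_table["model_kind"] == "tmdd"]
        for _, group in tmdd.groupby(["target_policy", "dose_policy", "target_level", "age_label"]):
            frac = group.sort_values("nominal_dose")["cl_fraction"].to_numpy()
            assert np.all(np.diff(frac) <= 1e-9)

    def test_occupancy_duration_increases_with_dose(self, full_table):
        tmdd = full_table[full_table["model_kind"] == "tmdd"]
        for _, group in tmdd.groupby(["target_policy", "dose_policy", "target_level", "age_label"]):
            dur = group.sort_values("nominal_dose")["occupancy_duration"].to_numpy()
            assert np.all(np.diff(dur) >= -1e-9)

    def test_twelve_year_olds_closer_to_adults_than_two_year_olds(self, full_table):
        tmdd = full_table[
            (full_table["model_kind"] == "tmdd") & full_table["age_label"].isin(["2y", "12y"])
        ]
        for _, group in tmdd.groupby(["target_policy", "dose_policy", "nominal_dose", "target_level"]):
            ratio = group.set_index("age_label")["auc_ratio_vs_18y"]
            assert abs(ratio["12y"] - 100.0) <= abs(ratio["2y"] - 100.0) + 1e-9

    def test_bw_dosing_same_concentration_ratio_approaches_unity(self, full_table):
        """Child/adult exposure converges to 100% with rising target level and
        falling dose under mg/kg dosing at equal target concentrations."""
        sel = full_table[
            (full_table["target_policy"] == "same_concentration")
            & (full_table["dose_policy"] == "per_kg")
            & (full_table["model_kind"] == "tmdd")
            & (full_table["age_label"] == "2y")
        ]
        pivot = sel.pivot_table(
            index="target_level", columns="nominal_dose", values="auc_ratio_vs_18y"
        ).sort_index()
        values = pivot.to_numpy()
        assert np.all(values < 100.0)
        # weakly increasing in target level (rows) and decreasing in dose (columns)
        assert np.all(np.diff(values, axis=0) >= -1e-6)
        assert np.all(np.diff(values, axis=1) <= 1e-6)


class TestExactlyLinearCase:
    def test_proportional_clearance_gives_equal_exposure(self, ref_params):
        """With no binding and CL proportional to BW, mg/kg dosing yields
        identical AUC in every age group (dose and clearance both scale as BW)."""
        linear = ref_params.with_(kon=0.0, koff=0.0, kint=0.0)
        spec = pt.ScenarioSpec(
            per_kg_doses=(0.5, 4.5),
            target_concentrations=(1.74,),
            target_policies=("same_concentration",),
            dose_policies=("per_kg",),
            model_kinds=("tmdd",),
        )
        policy = pt.ScalingPolicy(cl_exponent=1.0)
        table = pt.run_grid(spec, linear, policy)
        assert (table["error"] == "").all()
        assert table["auc_ratio_vs_18y"].to_numpy() == pytest.approx(
            np.full(len(table), 100.0), rel=2e-3
        )


class TestMMComparison:
    def test_mm_tracks_full_model_in_linear_regime(self, full_table):
        # highest dose, lowest target level: both models are near-linear
        for dose_policy, dose in (("per_kg", 4.5), ("fixed", 315.0)):
            for target_policy, level in (
                ("same_concentration", 0.0017),
                ("same_amount", 0.005),
            ):
                sel = full_table[
                    (full_table["target_policy"] == target_policy)
                    & (full_table["dose_policy"] == dose_policy)
                    & (full_table["nominal_dose"] == dose)
                    & (full_table["target_level"] == level)
                    & (full_table["model_kind"] == "mm")
                ]
                assert len(sel) == 4
                assert np.all(np.abs(sel["mm_vs_full_ratio"] - 100.0) < 5.0)

    def test_compare_table_structure_and_flags(self, full_table):
        comparison = pt.compare_mm_full(full_table)
        assert len(comparison) == 560
        change = comparison["mm_vs_full_auc_ratio_change"]
        assert change.notna().all()
        assert (comparison["flagged"] == ((change - 100.0).abs() > 25.0)).all()
        # agreement in the high-dose / low-target corner
        corner = comparison[
            (comparison["nominal_dose"].isin([4.5, 315.0]))
            & (comparison["target_level"].isin([0.0017, 0.005]))
        ]
        assert not corner["flagged"].any()

    def test_identical_model_kinds_give_100(self, full_table):
        doubled = full_table.copy()
        doubled.loc[doubled["model_kind"] == "mm", "auc_ratio_vs_18y"] = doubled.loc[
            doubled["model_kind"] == "tmdd", "auc_ratio_vs_18y"
        ].to_numpy()
        comparison = pt.compare_mm_full(doubled)
        assert comparison["mm_vs_full_auc_ratio_change"].to_numpy() == pytest.approx(
            np.full(560, 100.0)
        )


class TestDeterminism:
    def test_rerun_writes_byte_identical_csv(self, ref_params, tmp_path):
        spec = pt.ScenarioSpec(
            per_kg_doses=(2.0,),
            fixed_doses=(140.0,),
            target_concentrations=(1.74,),
            target_amounts=(4.87,),
            ages=("2y", "18y"),
        )
        paths = []
        for name in ("a.csv", "b.csv"):
            table = pt.run_grid(spec, ref_params)
            paths.append(pt.write_table(table, tmp_path / name))
        assert paths[0].read_bytes() == paths[1].read_bytes()
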