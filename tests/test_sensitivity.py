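"""Saltelli sampling and Sobol index estimation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from avibind import (
    ParameterRange,
    default_ranges,
    evaluate_outputs,
    sample_parameters,
    sobol_indices,
    sensitivity_experiment,
)


def _toy_design(n=1024, seed=3, names=("z1", "z2", "z3"), second_order=False):
    ranges = {name: ParameterRange(0.0, 1.0, "linear") for name in names}
    return sample_parameters(ranges, n=n, seed=seed, second_order=second_order)


class TestSampling:
    def test_samples_within_bounds(self):
        design = sample_parameters(default_ranges(), n=256, seed=0)
        matrix = design.matrix
        for j, name in enumerate(design.names):
            r = design.ranges[name]
            assert matrix[:, j].min() >= r.lower
            assert matrix[:, j].max() <= r.upper

    def test_fixed_seed_reproduces_design(self):
        a = sample_parameters(default_ranges(), n=128, seed=11).matrix
        b = sample_parameters(default_ranges(), n=128, seed=11).matrix
        np.testing.assert_array_equal(a, b)
        c = sample_parameters(default_ranges(), n=128, seed=12).matrix
        assert not np.array_equal(a, c)

    def test_design_size(self):
        d = len(default_ranges())
        full = sample_parameters(default_ranges(), n=64, seed=0, second_order=True)
        assert full.matrix.shape == (64 * (2 * d + 2), d)
        slim = sample_parameters(default_ranges(), n=64, seed=0, second_order=False)
        assert slim.matrix.shape == (64 * (d + 2), d)

    def test_non_power_of_two_rejected(self):
        with pytest.raises(ValueError):
            sample_parameters(default_ranges(), n=1000, seed=0)

    def test_log_scaled_marginals_uniform_in_log10(self):
        design = sample_parameters(default_ranges(), n=2048, seed=1)
        matrix = design.a
        for j, name in enumerate(design.names):
            r = design.ranges[name]
            if r.scale != "log":
                continue
            logs = np.log10(matrix[:, j])
            lo, hi = np.log10(r.lower), np.log10(r.upper)
            stat = kstest(logs, "uniform", args=(lo, hi - lo))
            assert stat.pvalue > 0.01, name

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            ParameterRange(2.0, 1.0)
        with pytest.raises(ValueError):
            ParameterRange(-1.0, 1.0, "log")


class TestEvaluation:
    def test_dummy_column_is_inert(self):
        design = sample_parameters(default_ranges(), n=32, seed=2, second_order=False)
        i_dummy = design.names.index("dummy")
        out_a = evaluate_outputs(design.a, design.names, 1e-9)
        out_ab = evaluate_outputs(design.ab(i_dummy), design.names, 1e-9)
        pd.testing.assert_frame_equal(out_a, out_ab)

    def test_identical_rows_have_zero_variance(self):
        design = _toy_design(n=64)
        outputs = np.ones(len(design.matrix))
        result = sobol_indices(design, outputs)
        assert result["0"].zero_variance
        assert result["0"].table["ST"].isna().all()


class TestEstimators:
    def test_single_factor_model(self):
        design = _toy_design(n=1024, seed=8)
        y = design.matrix[:, 0]
        res = sobol_indices(design, y).popitem()[1].table
        assert res.loc["z1", "S1"] == pytest.approx(1.0, abs=0.05)
        assert res.loc["z1", "ST"] == pytest.approx(1.0, abs=0.05)
        for other in ("z2", "z3"):
            assert abs(res.loc[other, "S1"]) < 0.05
            assert res.loc[other, "ST"] < 0.05

    def test_additive_model_matches_closed_form(self):
        # Y = a Z1 + b Z2, Z uniform(0,1): S_i = c_i^2 / (a^2 + b^2)
        a, b = 2.0, 1.0
        design = _toy_design(n=1024, seed=8)
        y = a * design.matrix[:, 0] + b * design.matrix[:, 1]
        res = sobol_indices(design, y).popitem()[1].table
        expected_1 = a**2 / (a**2 + b**2)
        expected_2 = b**2 / (a**2 + b**2)
        assert res.loc["z1", "S1"] == pytest.approx(expected_1, abs=0.05)
        assert res.loc["z2", "S1"] == pytest.approx(expected_2, abs=0.05)
        assert res.loc["z1", "ST"] == pytest.approx(expected_1, abs=0.05)
        assert res.loc["z3", "ST"] < 0.03

    def test_second_order_vanishes_for_additive_model(self):
        design = _toy_design(n=1024, seed=9, second_order=True)
        y = design.matrix[:, 0] + design.matrix[:, 1]
        res = sobol_indices(design, y, second_order=True).popitem()[1]
        assert np.abs(res.second_order["S2"]).max() < 0.08

    def test_interaction_model_total_exceeds_first_order(self):
        design = _toy_design(n=1024, seed=10)
        y = design.matrix[:, 0] * design.matrix[:, 1]
        res = sobol_indices(design, y).popitem()[1].table
        assert res.loc["z1", "ST"] > res.loc["z1", "S1"]


@pytest.fixture(scope="module")
def model_result():
    design = sample_parameters(default_ranges(), n=256, seed=0, second_order=False)
    outputs = evaluate_outputs(design.matrix, design.names, 1e-10)
    return sobol_indices(design, outputs, n_boot=100, boot_seed=0)


class TestModelIndices:
    def test_sobol_identities(self, model_result):
        for res in model_result.values():
            t = res.table
            assert (t["S1"] <= t["ST"] + 3 * (t["S1_err"] + t["ST_err"])).all()
            assert t["S1"].sum() <= 1.0 + 3 * t["S1_err"].sum()

    def test_dummy_below_noise_threshold(self, model_result):
        for res in model_result.values():
            assert res.table.loc["dummy", "ST"] < 0.05

    def test_low_dose_occupancy_driven_by_antigen_density(self, model_result):
        table = model_result["occupancy"].table
        assert table["ST"].idxmax() == "rtot"

    def test_doubling_sample_size_stays_within_bootstrap_width(self):
        small = sample_parameters(default_ranges(), n=256, seed=1, second_order=False)
        large = sample_parameters(default_ranges(), n=512, seed=1, second_order=False)
        res = {}
        for key, design in (("small", small), ("large", large)):
            outputs = evaluate_outputs(design.matrix, design.names, 1e-10)
            res[key] = sobol_indices(design, outputs, n_boot=100)["occupancy"].table
        for param in small.names:
            diff = abs(res["small"].loc[param, "ST"] - res["large"].loc[param, "ST"])
            width = 3 * (res["small"].loc[param, "ST_err"] + res["large"].loc[param, "ST_err"])
            assert diff <= max(width, 0.02), param


class TestExperiment:
    def test_long_format_table(self):
        table = sensitivity_experiment([1e-10, 1e-8], n=64, seed=0, n_boot=10)
        assert set(table.columns) == {
            "output", "ainit", "parameter", "S1", "ST", "S1_err", "ST_err", "N", "seed"
        }
        assert len(table) == 2 * 3 * 5  # doses x outputs x parameters
        assert set(table["output"]) == {"occupancy", "bound_ratio", "total_bound"}
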