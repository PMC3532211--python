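"""Length-weight allometry, stage averaging and the shipped-table validation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from mixedfishery import (
    LengthWeightRule,
    ParameterError,
    annual_survival,
    benthos_to_volumetric,
    length_at_weight,
    stage_average_weight,
    validate_params,
    weight_at_length,
    z_ratio,
)

SOLE = LengthWeightRule(a=0.0091, b=3.077)
PLAICE = LengthWeightRule(a=0.0089, b=3.0353)


class TestWeightAtLength:
    @pytest.mark.parametrize(
        "rule, L, expected, rel",
        [
            (SOLE, 24.0, 160.676, 1e-4),   # table adult sole weight 160.7
            (SOLE, 0.0, 0.0, 0.0),
            (PLAICE, 10.0, 9.65362, 1e-4),
        ],
    )
    def test_values(self, rule, L, expected, rel):
        assert weight_at_length(L, rule) == pytest.approx(expected, rel=rel, abs=1e-12)

    def test_inverse_round_trip(self):
        for L in (0.85, 5.0, 27.0):
            W = weight_at_length(L, PLAICE)
            assert length_at_weight(W, PLAICE) == pytest.approx(L, rel=1e-12)

    def test_negative_length_rejected(self):
        with pytest.raises(ParameterError):
            weight_at_length(-1.0, SOLE)


class TestStageAverageWeight:
    def test_closed_form_example(self):
        # logarithmic mean of (1, e) is e - 1
        assert stage_average_weight(1.0, math.e) == pytest.approx(math.e - 1.0, rel=1e-12)

    def test_sole_juvenile_bounds_reproduce_table(self):
        W0 = weight_at_length(0.85, SOLE)
        W1 = weight_at_length(12.0, SOLE)
        assert stage_average_weight(W0, W1) == pytest.approx(2.33671, rel=1e-4)

    def test_degenerate_limit_is_lower_bound(self):
        assert stage_average_weight(5.0, 5.0) == 5.0

    def test_ordering_violation_rejected(self):
        with pytest.raises(ParameterError):
            stage_average_weight(2.0, 1.0)

    @settings(max_examples=100, derandomize=True)
    @given(
        W_min=st.floats(1e-3, 1e3),
        ratio=st.floats(1.001, 1e4),
    )
    def test_matches_quadrature_oracle_and_brackets(self, W_min, ratio):
        # the 1/W-weighted mean over [W_min, W_max]:
        # (integral of dW) / (integral of dW/W)
        W_max = W_min * ratio
        avg = stage_average_weight(W_min, W_max)
        denom, _ = quad(lambda w: 1.0 / w, W_min, W_max)
        assert avg == pytest.approx((W_max - W_min) / denom, rel=1e-6)
        assert W_min < avg < W_max


class TestZRatio:
    @pytest.mark.parametrize(
        "L0, L1, rule, expected",
        [
            (12.0, 24.0, SOLE, 0.118503),     # table 0.118
            (0.85, 12.0, SOLE, 2.89855e-4),   # table 0.0003
        ],
    )
    def test_table_values(self, L0, L1, rule, expected):
        assert z_ratio(L0, L1, rule) == pytest.approx(expected, rel=1e-4)

    def test_degenerate_stage(self):
        assert z_ratio(5.0, 5.0, SOLE) == 1.0

    @settings(max_examples=50, derandomize=True)
    @given(a=st.floats(1e-4, 1.0))
    def test_independent_of_allometric_coefficient(self, a):
        rule = LengthWeightRule(a=a, b=3.077)
        assert z_ratio(12.0, 24.0, rule) == pytest.approx(
            z_ratio(12.0, 24.0, SOLE), rel=1e-12
        )

    def test_ordering_violation_rejected(self):
        with pytest.raises(ParameterError):
            z_ratio(24.0, 12.0, SOLE)


class TestUnitConversions:
    def test_background_mortality_gives_70pct_annual_survival(self):
        assert annual_survival(0.001) == pytest.approx(0.69420, rel=1e-4)

    def test_survival_limits(self):
        assert annual_survival(0.0) == 1.0
        assert annual_survival(0.01) == pytest.approx(0.025991, rel=1e-4)

    @pytest.mark.parametrize(
        "areal, depth, frac, expected",
        [
            (10.1, 0.1, 1.0 / 3.0, 0.303),
            (10.1, 0.1, 1.0, 0.101),
            (1.0, 1.0, 1.0, 0.001),
        ],
    )
    def test_benthos_density_conversion(self, areal, depth, frac, expected):
        assert benthos_to_volumetric(areal, depth, frac) == pytest.approx(
            expected, rel=1e-9
        )

    def test_zero_depth_rejected(self):
        with pytest.raises(ParameterError):
            benthos_to_volumetric(10.1, 0.0, 1.0)


class TestDefaultParamsValidation:
    def test_all_entries_within_tolerance(self, params):
        report = validate_params(params)
        assert len(report) == 14
        bad = report[~report["ok"]]
        assert bad.empty, bad.to_string()

    def test_sole_entries_tight(self, params):
        sp = params.sole
        rule = LengthWeightRule(sp.lw_a, sp.lw_b)
        assert z_ratio(12.0, 24.0, rule) == pytest.approx(0.118, rel=0.01)
        assert weight_at_length(24.0, rule) == pytest.approx(160.7, rel=0.005)

    def test_resource_maxima_ratio(self, params):
        assert params.resources.K_p / params.resources.K_m == pytest.approx(1.0 / 0.3)

    def test_corrupted_entry_is_flagged(self, params):
        import dataclasses

        sp = params.plaice
        stages = dict(sp.stages)
        stages["J"] = dataclasses.replace(stages["J"], W_avg=3.0)
        broken = dataclasses.replace(
            params, plaice=dataclasses.replace(sp, stages=stages)
        )
        report = validate_params(broken)
        flagged = report[(report["species"] == "plaice")
                         & (report["parameter"] == "W_avg_J")]
        assert not flagged["ok"].iloc[0]

    def test_plaice_weights_documentedly_loose(self, params):
        # the printed plaice adult weight is ~6% above its own allometry;
        # the validator must report the discrepancy without failing
        report = validate_params(params)
        row = report[(report["species"] == "plaice")
                     & (report["parameter"] == "W_avg_A")].iloc[0]
        assert row["rel_diff"] > 0.02
        assert row["ok"]
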