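"""Rate functions, the nine-dimensional RHS and the fishery metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mixedfishery import (
    ParameterError,
    SystemState,
    fishery_metrics,
    fishing_mortality,
    ingestion,
    maturation_rate,
    net_production,
    rhs,
    split_resource_maxima,
)
from mixedfishery.model import PackedParams, default_seed_state


class TestSplitResourceMaxima:
    @pytest.mark.parametrize(
        "omega, expected",
        [
            (0.0, (0.3, 0.0)),   # no overlap: sole keeps the full maximum
            (1.0, (0.0, 0.3)),   # complete overlap: everything shared
            (0.5, (0.15, 0.15)),
        ],
    )
    def test_endpoints_and_midpoint(self, omega, expected):
        assert split_resource_maxima(0.3, omega) == pytest.approx(expected)

    @settings(max_examples=100, derandomize=True)
    @given(omega=st.floats(0.0, 1.0), K_m=st.floats(1e-6, 1e3))
    def test_conserves_total(self, omega, K_m):
        K_s, K_sh = split_resource_maxima(K_m, omega)
        assert K_s + K_sh == pytest.approx(K_m, rel=1e-12)
        assert K_s >= 0 and K_sh >= 0

    @pytest.mark.parametrize("omega", [-0.1, 1.5])
    def test_domain_errors(self, omega):
        with pytest.raises(ParameterError):
            split_resource_maxima(0.3, omega)


class TestIngestion:
    def test_half_saturation(self):
        total, _, _ = ingestion(0.01, 0.0, 0.05, 0.01)
        assert total == pytest.approx(0.025)

    def test_no_food(self):
        assert ingestion(0.0, 0.0, 0.05, 0.01) == (0.0, 0.0, 0.0)

    def test_two_resource_arithmetic(self):
        total, f_own, f_sh = ingestion(0.01, 0.01, 0.05, 0.01)
        assert total == pytest.approx(0.05 * 0.02 / 0.03)
        assert f_own == pytest.approx(0.5)
        assert f_own + f_sh == pytest.approx(1.0)

    def test_negative_resource_rejected(self):
        with pytest.raises(ParameterError):
            ingestion(-0.01, 0.0, 0.05, 0.01)


class TestNetProduction:
    def test_break_even(self):
        assert net_production(0.0032 / 0.36, 0.36, 0.0032) == pytest.approx(0.0)

    def test_pure_maintenance_loss(self):
        assert net_production(0.0, 0.36, 0.0032) == pytest.approx(-0.0032)

    def test_hand_value(self):
        assert net_production(0.02, 0.36, 0.0032) == pytest.approx(0.0040)


class TestMaturationRate:
    def test_starvation_shuts_maturation_off(self):
        assert maturation_rate(-0.001, 0.002, 0.118) == 0.0
        assert maturation_rate(0.0, 0.0, 0.5) == 0.0

    def test_zero_mortality_reduction(self):
        assert maturation_rate(0.01, 0.0, 0.5) == pytest.approx(0.02)

    def test_hand_value(self):
        assert maturation_rate(0.01, 0.001, 0.118) == pytest.approx(
            0.0105401, rel=1e-5
        )

    def test_continuous_across_removable_singularity(self):
        # the formula is singular at nu = mu; its limit is -nu/ln(z)
        nu = 0.004
        z = 0.118
        limit = -nu / math.log(z)
        assert maturation_rate(nu, nu, z) == pytest.approx(limit, rel=1e-12)
        for eps in (-1e-10, -1e-13, 1e-13, 1e-10):
            val = maturation_rate(nu, nu + eps, z)
            assert val == pytest.approx(limit, abs=1e-8)
        # no jump on a mortality grid straddling nu = mu: consecutive
        # differences stay comparable to the median slope step
        grid = np.linspace(0.5 * nu, 1.5 * nu, 201)
        vals = np.array([maturation_rate(nu, mu, z) for mu in grid])
        diffs = np.abs(np.diff(vals))
        assert diffs.max() < 3.0 * np.median(diffs)

    def test_tiny_positive_nu_underflows_to_zero(self):
        assert maturation_rate(1e-12, 0.01, 0.5) == pytest.approx(0.0, abs=1e-15)

    @pytest.mark.parametrize("z", [0.0, 1.0, 1.5])
    def test_z_domain_errors(self, z):
        with pytest.raises(ParameterError):
            maturation_rate(0.01, 0.001, z)


class TestFishingMortality:
    def test_table_catchability_at_unit_effort(self):
        assert fishing_mortality(0.001455, 1.0) == pytest.approx(0.001455)

    def test_no_fishing(self):
        assert fishing_mortality(0.5, 0.0) == 0.0

    def test_linearity(self):
        assert fishing_mortality(5e-5, 2.0) == pytest.approx(1e-4)

    def test_negative_effort_rejected(self):
        with pytest.raises(ParameterError):
            fishing_mortality(0.001, -1.0)


class TestRhs:
    def test_consumer_free_saturated_resources_is_fixed_point(self, params):
        p = PackedParams(params, 0.4)
        y = np.zeros(9)
        y[:3] = p.K
        d = rhs(y, params, E=0.0, omega=0.4)
        assert np.max(np.abs(d)) < 1e-15

    def test_empty_system_regrows_resources_only(self, params):
        d = rhs(np.zeros(9), params, E=0.0, omega=0.4)
        p = PackedParams(params, 0.4)
        assert d[:3] == pytest.approx(p.r * p.K)
        assert np.all(d[3:] == 0.0)

    @pytest.mark.parametrize("bad", [np.full(9, np.nan), -np.ones(9)])
    def test_invalid_state_rejected(self, params, bad):
        with pytest.raises(ParameterError):
            rhs(bad, params, E=0.0)

    def test_flow_balance_bookkeeping(self, params):
        """Independent accounting of every biomass flow.

        For each species, the change of total consumer biomass must equal
        assimilated intake minus maintenance, background mortality,
        fishing removals and what the stage equations route through
        maturation (which is conservative).  The intake flux is rebuilt
        from the ingestion function, independently of the RHS internals;
        resource drains must mirror the consumers' intake exactly.
        """
        rng = np.random.default_rng(7)
        for _ in range(50):
            omega = rng.uniform(0, 1)
            E = rng.uniform(0, 20)
            y = rng.uniform(0, 1, size=9) * np.array(
                [1.0, 0.3, 0.3, 0.5, 2, 2, 0.5, 2, 2]
            )
            d = rhs(y, params, E=E, omega=omega)
            R = {"plaice": y[0], "sole": y[1]}
            total_intake = {"plaice": 0.0, "sole": 0.0}
            for i, name in enumerate(("plaice", "sole")):
                sp = params.species(name)
                B = y[3 + 3 * i: 6 + 3 * i]
                dB = d[3 + 3 * i: 6 + 3 * i]
                gain = 0.0
                for j, st_name in enumerate(("J", "LJ", "A")):
                    stage = sp.stages[st_name]
                    IR, _, _ = ingestion(
                        R[name], y[2], stage.I_max, params.resources.R_h
                    )
                    total_intake[name] += IR * B[j]
                    nu = sp.delta * IR - sp.T
                    mu_tot = sp.mu + stage.f * E
                    gain += (nu - mu_tot) * B[j]
                assert dB.sum() == pytest.approx(gain, rel=1e-9, abs=1e-15)
            # resource drains mirror total consumer intake
            p = PackedParams(params, omega)
            supply = p.r * (p.K - y[:3])
            drained = supply - d[:3]
            assert drained.sum() == pytest.approx(
                total_intake["plaice"] + total_intake["sole"], rel=1e-9, abs=1e-15
            )

    def test_forward_invariant_nonnegativity(self, params):
        from scipy.integrate import solve_ivp

        from mixedfishery.model import _rhs_packed

        rng = np.random.default_rng(3)
        p = PackedParams(params, 0.6)
        for _ in range(5):
            y0 = rng.uniform(0, 1, 9) * 0.5
            sol = solve_ivp(
                lambda t, y: _rhs_packed(y, p, 5.0), (0, 5000), y0,
                method="LSODA", rtol=1e-8, atol=1e-12,
            )
            assert sol.y.min() > -1e-10


class TestFisheryMetrics:
    def test_no_effort_no_flows(self, params):
        state = default_seed_state(params, 0.0, consumer_density=0.5)
        m = fishery_metrics(state, params, E=0.0)
        assert m.revenue_total == 0.0
        for s in ("plaice", "sole"):
            assert m.catch(s).landings == 0.0
            assert m.catch(s).discards == 0.0

    def test_revenue_hand_value(self, params):
        # 1 g/L of adult sole at unit effort: price 10.06 EUR/kg,
        # f_A = 0.001455 -> 10.06 * 0.001455 / 1000 EUR/L/d
        y = np.zeros(9)
        y[8] = 1.0  # A_s
        m = fishery_metrics(y, params, E=1.0)
        assert m.sole.revenue == pytest.approx(1.46373e-5, rel=1e-5)

    def test_discard_ratio_zero_without_large_juveniles(self, params):
        y = np.zeros(9)
        y[5] = 1.0  # adult plaice only
        m = fishery_metrics(y, params, E=1.0)
        assert m.plaice.discard_ratio == 0.0

    def test_discard_ratio_flagged_when_landings_vanish(self, params):
        y = np.zeros(9)
        y[4] = 1.0  # large-juvenile plaice, no adults
        m = fishery_metrics(y, params, E=1.0)
        assert math.isnan(m.plaice.discard_ratio)

    def test_negative_effort_rejected(self, params):
        with pytest.raises(ParameterError):
            fishery_metrics(np.zeros(9), params, E=-1.0)


class TestSystemState:
    def test_component_order_and_accessors(self):
        s = SystemState(np.arange(9, dtype=float))
        assert s.R_p == 0.0 and s.R_sh == 2.0 and s.A_s == 8.0
        assert s.species_total("plaice") == 3.0 + 4.0 + 5.0

    def test_negative_component_rejected(self):
        with pytest.raises(ValueError):
            SystemState([-1.0] + [0.0] * 8)
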