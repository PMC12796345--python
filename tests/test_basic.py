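"""Generic two- and three-component assembly models: orderings, optima, metrics."""

import numpy as np
import pytest

from necrosim.basic import (
    AssemblyModel,
    BasicRateParameters,
    ResponseCurve,
    StoichiometryConfig,
    optimal_mid_assembly,
    response_curve,
    sensitivity_coefficient,
    simulate_three_component,
    simulate_two_component,
    three_component_reference,
    two_component_reference,
    THREE_COMPONENT_INITIAL_B,
    THREE_COMPONENT_INITIAL_C,
    THREE_COMPONENT_INPUT,
)
from necrosim.network import ValidationError, simulate_fixed_step


class TestStoichiometryConfig:
    @pytest.mark.parametrize("bad", [{"m": 0, "n": 1}, {"m": 1, "n": -2},
                                     {"m": 1, "n": 1, "h": 0}, {"m": 1.5, "n": 1}])
    def test_invalid_multiplicities_rejected(self, bad):
        with pytest.raises(ValidationError):
            StoichiometryConfig(**bad)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValidationError):
            BasicRateParameters(k1=-0.1, k_minus1=0.0, kappa1=0.0)


class TestTwoComponent:
    def test_no_upstream_signal_no_activation(self):
        """With A absent, B is never activated."""
        traj = simulate_two_component(two_component_reference(),
                                      StoichiometryConfig(1, 2), 0.0, 20.0, 100.0)
        assert np.all(traj.series("Bstar") == 0.0)

    def test_matches_closed_form_irreversible_binding(self):
        """m=n=1, no unbinding/activation: complex follows kt/(1+kt)."""
        params = BasicRateParameters(k1=1.0, k_minus1=0.0, kappa1=0.0)
        traj = simulate_two_component(params, StoichiometryConfig(1, 1), 1.0, 1.0, 10.0)
        expected = traj.times / (1.0 + traj.times)
        assert np.allclose(traj.series("AmBn"), expected, atol=1e-6)

    def test_downstream_assembly_amplifies_output(self):
        """Terminal activated B increases with the B assembly degree (n=4>2>1)."""
        params = two_component_reference()
        outs = {n: simulate_two_component(params, StoichiometryConfig(1, n),
                                          1.0, 20.0, 100.0).terminal("Bstar")
                for n in (1, 2, 4)}
        assert outs[4] > outs[2] > outs[1]

    def test_upstream_assembly_attenuates_output(self):
        """Higher-order upstream A (m=4) yields lower output at every input."""
        params = two_component_reference()
        grid = np.linspace(0.25, 2.5, 6)
        model1 = AssemblyModel(params, StoichiometryConfig(1, 1))
        model4 = AssemblyModel(params, StoichiometryConfig(4, 1))
        out1 = response_curve(model1, grid).outputs
        out4 = response_curve(model4, grid).outputs
        assert np.all(out1 > out4)

    def test_monomeric_response_is_linear(self):
        """m=n=1 input-output curve is linear in the low-input regime (R2>=0.99)."""
        model = AssemblyModel(two_component_reference(), StoichiometryConfig(1, 1))
        grid = np.linspace(0.05, 1.0, 8)
        curve = response_curve(model, grid)
        coeffs = np.polyfit(curve.input_levels, curve.outputs, 1)
        fitted = np.polyval(coeffs, curve.input_levels)
        ss_res = np.sum((curve.outputs - fitted) ** 2)
        ss_tot = np.sum((curve.outputs - curve.outputs.mean()) ** 2)
        assert 1.0 - ss_res / ss_tot >= 0.99


class TestThreeComponent:
    def test_no_downstream_pool_no_output(self):
        traj = simulate_three_component(three_component_reference(),
                                        StoichiometryConfig(1, 2, 3),
                                        3.5, 8.0, 0.0, 100.0)
        assert np.all(traj.series("Cstar") == 0.0)

    def test_output_rises_with_downstream_assembly(self):
        """At m=n=1, terminal C* increases with C's assembly degree h."""
        params = three_component_reference()
        outs = [simulate_three_component(params, StoichiometryConfig(1, 1, h),
                                         THREE_COMPONENT_INPUT,
                                         THREE_COMPONENT_INITIAL_B,
                                         THREE_COMPONENT_INITIAL_C,
                                         100.0).terminal("Cstar")
                for h in (1, 2, 3, 4)]
        assert np.all(np.diff(outs) > 0)

    def test_agrees_with_fixed_step_oracle(self):
        """Adaptive three-component run matches Euler at dt=1e-4 within 0.1%."""
        from necrosim.basic import three_component_network
        from necrosim.network import simulate

        params = three_component_reference()
        net = three_component_network(params, StoichiometryConfig(1, 2, 3))
        init = {"A": 3.5, "B": 8.0, "C": 5.5}
        fine = simulate_fixed_step(net, init, 30.0, dt=1e-4, n_saved=4)
        adaptive = simulate(net, init, 30.0, t_eval=fine.times)
        c_fine = fine.series("Cstar")[1:]
        c_adaptive = adaptive.series("Cstar")[1:]
        assert np.max(np.abs(c_adaptive - c_fine) / c_fine) < 1e-3

    def test_midstream_optimum_is_dimer(self):
        """Varying n at m=1, h=3: output peaks at n=2."""
        assert optimal_mid_assembly(three_component_reference(),
                                    {"m": 1, "h": 3}, "n", range(1, 7)) == 2

    def test_upstream_optimum_is_dimer(self):
        """Varying m at n=1, h=3: output peaks at m=2."""
        assert optimal_mid_assembly(three_component_reference(),
                                    {"n": 1, "h": 3}, "m", range(1, 7)) == 2

    def test_downstream_optimum_tops_range(self):
        """At m=n=1 the output is monotone in h, so the optimum is the top."""
        assert optimal_mid_assembly(three_component_reference(),
                                    {"m": 1, "n": 1}, "h", range(1, 5)) == 4

    def test_amplify_then_attenuate_decomposition(self):
        """Terminal activated B rises with n while terminal C* peaks inside."""
        params = three_component_reference()
        bstar, cstar = [], []
        for n in range(1, 7):
            traj = simulate_three_component(params, StoichiometryConfig(1, n, 3),
                                            THREE_COMPONENT_INPUT,
                                            THREE_COMPONENT_INITIAL_B,
                                            THREE_COMPONENT_INITIAL_C, 100.0)
            bstar.append(traj.terminal("Bstar") + n * traj.terminal("BnCh"))
            cstar.append(traj.terminal("Cstar"))
        assert np.all(np.diff(bstar) >= -1e-6)
        peak = int(np.argmax(cstar))
        assert 0 < peak < len(cstar) - 1
        assert cstar[-1] < cstar[peak]

    def test_validation(self):
        with pytest.raises(ValidationError):
            optimal_mid_assembly(three_component_reference(), {"m": 1}, "n", [1, 2])
        with pytest.raises(ValidationError):
            optimal_mid_assembly(three_component_reference(), {"m": 1, "h": 3}, "n", [])


class TestResponseCurveOps:
    def test_all_zero_inputs_zero_outputs(self):
        model = AssemblyModel(two_component_reference(), StoichiometryConfig(1, 2))
        curve = response_curve(model, [0.0])
        assert np.all(curve.outputs == 0.0)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValidationError):
            ResponseCurve(np.array([1.0, 2.0]), np.array([1.0]))

    def test_decreasing_inputs_rejected(self):
        with pytest.raises(ValidationError):
            ResponseCurve(np.array([2.0, 1.0]), np.array([1.0, 2.0]))


class TestSensitivityCoefficient:
    def test_step_curve_near_zero(self):
        """An ideal switch needs almost no stimulus reduction: coefficient ~ grid step."""
        x = np.linspace(0, 10, 101)
        y = np.where(x >= 5.0, 20.0, 0.0)
        assert sensitivity_coefficient(ResponseCurve(x, y)) <= 0.1 + 1e-12

    def test_linear_curve_gives_half_span(self):
        x = np.linspace(0, 10, 101)
        assert sensitivity_coefficient(ResponseCurve(x, 2 * x)) == pytest.approx(5.0)

    def test_hill_sharpening_reduces_coefficient(self):
        """The coefficient strictly decreases as the Hill exponent rises 1..4."""
        x = np.linspace(0, 10, 401)
        k = 5.0
        coeffs = [sensitivity_coefficient(
            ResponseCurve(x, x ** h / (x ** h + k ** h))) for h in (1, 2, 3, 4)]
        assert np.all(np.diff(coeffs) < 0)

    def test_non_monotone_curve_rejected(self):
        x = np.linspace(0, 10, 11)
        y = np.sin(x)
        with pytest.raises(ValidationError, match="monotone"):
            sensitivity_coefficient(ResponseCurve(x, np.maximum(y, 0)))

    def test_unreached_fraction_returns_span_with_flag(self):
        x = np.linspace(0, 10, 11)
        y = np.full_like(x, 7.0)  # flat positive curve never falls to half-max
        value, flagged = sensitivity_coefficient(ResponseCurve(x, y), return_flag=True)
        assert flagged and value == pytest.approx(10.0)
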