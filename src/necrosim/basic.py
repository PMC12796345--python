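"""Generic higher-order assembly models with two or three components.

The two-component scheme couples an upstream species A and a downstream
species B through an assembled intermediate:

    m A + n B  <=>[k1, k-1]  AmBn  -->[kappa1]  m A + n B*

A is recycled on activation (it is a scaffold/catalyst); each activation event
releases n activated B.  The three-component extension recruits a downstream
species C through activated B:

    n B* + h C  <=>[k2, k-2]  Bn*Ch  -->[kappa2]  n B* + h C*

The integer multiplicities (m, n, h) are the assembly degrees of A, B and C
within one binding subunit.  "Output" is the terminal activated species at the
end of the horizon; reference horizons are long enough that the output changes
by less than ~1% over the last 10% of the run.

Concentrations are in arbitrary units (a.u.) on the scale used for the
response-curve analyses, where the maximal output is ~20 a.u.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .network import (
    Reaction,
    ReactionNetwork,
    Trajectory,
    ValidationError,
    simulate,
)

__all__ = [
    "StoichiometryConfig",
    "BasicRateParameters",
    "ResponseCurve",
    "AssemblyModel",
    "two_component_network",
    "three_component_network",
    "simulate_two_component",
    "simulate_three_component",
    "response_curve",
    "sensitivity_coefficient",
    "optimal_mid_assembly",
    "two_component_reference",
    "three_component_reference",
]


@dataclass(frozen=True)
class StoichiometryConfig:
    """Integer assembly multiplicities of a complex-forming subunit."""

    m: int
    n: int
    h: int | None = None

    def __post_init__(self):
        for label, value in (("m", self.m), ("n", self.n), ("h", self.h)):
            if value is None:
                continue
            if not isinstance(value, (int, np.integer)) or value < 1:
                raise ValidationError(f"{label} must be a positive integer, got {value!r}")


@dataclass(frozen=True)
class BasicRateParameters:
    """Rate constants of the two-stage assembly scheme.

    k1/k_minus1 bind and unbind A with B; kappa1 irreversibly activates B in
    the complex.  k2/k_minus2/kappa2 play the same roles for the B*-C stage.
    Association constants have units 1/(a.u.^(order-1) * time); the others are
    first order (1/time).
    """

    k1: float
    k_minus1: float
    kappa1: float
    k2: float = 0.0
    k_minus2: float = 0.0
    kappa2: float = 0.0

    def __post_init__(self):
        for name, value in self.__dict__.items():
            if value < 0:
                raise ValidationError(f"rate {name} must be non-negative, got {value}")


@dataclass
class ResponseCurve:
    """Stimulus grid with one terminal-output value per input level."""

    input_levels: np.ndarray
    outputs: np.ndarray
    max_output: float = 20.0

    def __post_init__(self):
        self.input_levels = np.asarray(self.input_levels, dtype=float)
        self.outputs = np.asarray(self.outputs, dtype=float)
        if self.input_levels.shape != self.outputs.shape:
            raise ValidationError("input and output sequences differ in length")
        if self.input_levels.size and np.any(np.diff(self.input_levels) <= 0):
            raise ValidationError("input levels must be strictly increasing")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"input": self.input_levels, "output": self.outputs})


def two_component_network(params: BasicRateParameters,
                          stoich: StoichiometryConfig) -> ReactionNetwork:
    m, n = stoich.m, stoich.n
    species = ["A", "B", "AmBn", "Bstar"]
    reactions = [
        Reaction("bind_AB", {"A": m, "B": n}, {"AmBn": 1}, "k1", "association"),
        Reaction("unbind_AB", {"AmBn": 1}, {"A": m, "B": n}, "k_minus1", "dissociation"),
        Reaction("activate_B", {"AmBn": 1}, {"A": m, "Bstar": n}, "kappa1", "catalytic"),
    ]
    parameters = {"k1": params.k1, "k_minus1": params.k_minus1, "kappa1": params.kappa1}
    classes = {"k1": "kinetic", "k_minus1": "kinetic", "kappa1": "catalytic"}
    return ReactionNetwork(species, reactions, parameters, classes)


def three_component_network(params: BasicRateParameters,
                            stoich: StoichiometryConfig) -> ReactionNetwork:
    if stoich.h is None:
        raise ValidationError("three-component model requires h")
    n, h = stoich.n, stoich.h
    base = two_component_network(params, stoich)
    species = base.species + ["C", "BnCh", "Cstar"]
    reactions = base.reactions + [
        Reaction("bind_BC", {"Bstar": n, "C": h}, {"BnCh": 1}, "k2", "association"),
        Reaction("unbind_BC", {"BnCh": 1}, {"Bstar": n, "C": h}, "k_minus2", "dissociation"),
        Reaction("activate_C", {"BnCh": 1}, {"Bstar": n, "Cstar": h}, "kappa2", "catalytic"),
    ]
    parameters = dict(base.parameters)
    parameters.update({"k2": params.k2, "k_minus2": params.k_minus2, "kappa2": params.kappa2})
    classes = dict(base.parameter_classes)
    classes.update({"k2": "kinetic", "k_minus2": "kinetic", "kappa2": "catalytic"})
    return ReactionNetwork(species, reactions, parameters, classes)


def simulate_two_component(params: BasicRateParameters, stoich: StoichiometryConfig,
                           initial_A: float, initial_B: float, horizon: float,
                           **kwargs) -> Trajectory:
    """Integrate the A+B scheme; returns species {A, B, AmBn, Bstar}."""
    if initial_A < 0 or initial_B < 0:
        raise ValidationError("initial concentrations must be non-negative")
    net = two_component_network(params, stoich)
    return simulate(net, {"A": initial_A, "B": initial_B}, horizon, **kwargs)


def simulate_three_component(params: BasicRateParameters, stoich: StoichiometryConfig,
                             initial_A: float, initial_B: float, initial_C: float,
                             horizon: float, **kwargs) -> Trajectory:
    """Integrate the A+B+C scheme; adds species {C, BnCh, Cstar}."""
    if min(initial_A, initial_B, initial_C) < 0:
        raise ValidationError("initial concentrations must be non-negative")
    net = three_component_network(params, stoich)
    return simulate(net, {"A": initial_A, "B": initial_B, "C": initial_C}, horizon, **kwargs)


# ---------------------------------------------------------------------------
# reference parameterizations (reconstructed operating regimes)
# ---------------------------------------------------------------------------

#: default horizon (a.u. of time) for the basic models
DEFAULT_HORIZON = 100.0

#: default initial amounts for the two-component response analyses
TWO_COMPONENT_INITIAL_B = 20.0

#: default initial amounts for the three-component optimum analyses
THREE_COMPONENT_INITIAL_B = 8.0
THREE_COMPONENT_INITIAL_C = 5.5
THREE_COMPONENT_INPUT = 3.5


def two_component_reference() -> BasicRateParameters:
    """Reference rates for the A+B response-curve regime (B abundant, ~20 a.u.)."""
    return BasicRateParameters(k1=0.02, k_minus1=0.05, kappa1=0.02)


def three_component_reference() -> BasicRateParameters:
    """Reference rates for the A+B+C optimum-stoichiometry regime.

    The regime is tuned so that the midstream assembly degree has an interior
    optimum: stage-1 association is fast but loose (large k_minus1) and both
    activation steps are slow, so the downstream output at the observation
    horizon balances midstream amplification against midstream-imposed
    attenuation of the second binding stage.
    """
    return BasicRateParameters(k1=0.15, k_minus1=3.3, kappa1=0.007,
                               k2=0.6, k_minus2=0.006, kappa2=0.025)


@dataclass
class AssemblyModel:
    """A runnable model specification mapping input intensity -> trajectory.

    "Input intensity" scales the initial amount of the upstream species A
    (upstream abundance), matching the observation that modulating the input
    and the upstream component act alike.
    """

    params: BasicRateParameters
    stoich: StoichiometryConfig
    initial_B: float = TWO_COMPONENT_INITIAL_B
    initial_C: float | None = None
    horizon: float = DEFAULT_HORIZON
    output_species: str = ""

    def __post_init__(self):
        if not self.output_species:
            self.output_species = "Cstar" if self.stoich.h is not None else "Bstar"

    def simulate(self, input_level: float, **kwargs) -> Trajectory:
        if self.stoich.h is not None:
            c0 = THREE_COMPONENT_INITIAL_C if self.initial_C is None else self.initial_C
            return simulate_three_component(self.params, self.stoich, input_level,
                                            self.initial_B, c0, self.horizon, **kwargs)
        return simulate_two_component(self.params, self.stoich, input_level,
                                      self.initial_B, self.horizon, **kwargs)

    def terminal_output(self, input_level: float, **kwargs) -> float:
        return self.simulate(input_level, **kwargs).terminal(self.output_species)


def response_curve(model: AssemblyModel, input_grid) -> ResponseCurve:
    """Terminal output for each stimulus intensity on ``input_grid``."""
    grid = np.asarray(input_grid, dtype=float)
    if grid.size == 0:
        raise ValidationError("input grid must be non-empty")
    outputs = np.array([model.terminal_output(x) for x in grid])
    return ResponseCurve(grid, outputs)


def sensitivity_coefficient(curve: ResponseCurve, fraction: float = 0.5,
                            monotone_tol: float = 1e-6,
                            return_flag: bool = False):
    """Stimulus reduction needed to pull output down to ``fraction`` of maximum.

    Starting from the input level attaining the maximal output, the coefficient
    is the decrease in stimulus required for the output to fall to
    ``fraction * max``; small values mean a switch-like (threshold) response,
    large values a graded one.  If the output never falls to the target on the
    grid, the full input span is returned and the flag is set.
    """
    x, y = curve.input_levels, curve.outputs
    if x.size < 2:
        raise ValidationError("need at least two grid points")
    scale = max(y.max(), 1.0) * monotone_tol
    if np.any(np.diff(y) < -scale):
        raise ValidationError("response curve must be monotone non-decreasing")
    i_max = int(np.argmax(y))
    target = fraction * y[i_max]
    below = np.nonzero(y[: i_max + 1] <= target)[0]
    if below.size == 0 or y[i_max] == 0:
        value = float(x[-1] - x[0])
        return (value, True) if return_flag else value
    i = int(below[-1])  # last grid point at or below the target
    if i == i_max:
        x_target = x[i_max]
    else:
        # linear interpolation between the bracketing grid points
        y0, y1 = y[i], y[i + 1]
        x_target = x[i] if y1 == y0 else x[i] + (target - y0) * (x[i + 1] - x[i]) / (y1 - y0)
    value = float(x[i_max] - x_target)
    return (value, False) if return_flag else value


def optimal_mid_assembly(params: BasicRateParameters, fixed: dict[str, int],
                         vary: str, candidates,
                         input_level: float = THREE_COMPONENT_INPUT,
                         initial_B: float = THREE_COMPONENT_INITIAL_B,
                         initial_C: float = THREE_COMPONENT_INITIAL_C,
                         horizon: float = DEFAULT_HORIZON) -> int:
    """Multiplicity in ``candidates`` maximizing terminal downstream output.

    ``fixed`` supplies two of {m, n, h}; ``vary`` names the third.  Ties break
    toward the smallest candidate.
    """
    candidates = sorted(int(c) for c in candidates)
    if not candidates:
        raise ValidationError("candidate set must be non-empty")
    if vary not in ("m", "n", "h") or set(fixed) != {"m", "n", "h"} - {vary}:
        raise ValidationError("fixed must supply exactly the two multiplicities not varied")
    best, best_out = candidates[0], -np.inf
    for c in candidates:
        stoich = StoichiometryConfig(**{**fixed, vary: c})
        traj = simulate_three_component(params, stoich, input_level, initial_B,
                                        initial_C, horizon)
        out = traj.terminal("Cstar")
        if out > best_out + 1e-12:
            best, best_out = c, out
    return best
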