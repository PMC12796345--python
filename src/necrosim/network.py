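"""Mass-action reaction networks and their ODE integration.

A :class:`ReactionNetwork` is a list of named species plus reactions with
integer stoichiometries.  Every reaction carries a rate-law kind (association,
dissociation, catalytic, degradation or synthesis) and the name of its rate
constant; the rate of each reaction is the mass-action law

    r_j = k_j * prod_i [X_i]**p_ij

where ``p_ij`` is the multiplicity of species ``i`` on the reactant side of
reaction ``j`` (concentrations are raised to the stoichiometric power, with no
statistical-factor corrections).  The network compiles to the ODE system

    d[X_i]/dt = sum_j nu_ij * r_j

with ``nu_ij`` the net stoichiometric coefficient.  Integration uses a
stiff-capable adaptive solver (LSODA); high stoichiometric powers make these
systems stiff.  A fixed-step explicit Euler integrator is provided as an
independent verification oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.integrate import solve_ivp

RATE_LAW_KINDS = ("association", "dissociation", "catalytic", "degradation", "synthesis")

#: parameter classes used for ensemble sampling bounds
PARAMETER_CLASSES = ("kinetic", "catalytic", "degradation")

#: default solver tolerances (high powers create stiffness)
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


class ValidationError(ValueError):
    """Raised for invalid model configuration (negative rates, bad stoichiometry...)."""


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries the last valid state."""

    def __init__(self, message: str, last_time: float | None = None,
                 last_state: np.ndarray | None = None):
        super().__init__(message)
        self.last_time = last_time
        self.last_state = last_state


@dataclass(frozen=True)
class Reaction:
    """One elementary reaction with integer stoichiometries.

    ``reactants`` and ``products`` map species name -> multiplicity.  Catalysts
    appear on both sides.  ``rate_constant`` names an entry of the network's
    parameter mapping.
    """

    name: str
    reactants: dict[str, int]
    products: dict[str, int]
    rate_constant: str
    kind: str

    def __post_init__(self):
        if self.kind not in RATE_LAW_KINDS:
            raise ValidationError(f"unknown rate-law kind {self.kind!r}")
        for side in (self.reactants, self.products):
            for sp, coef in side.items():
                if not isinstance(coef, (int, np.integer)) or coef < 1:
                    raise ValidationError(
                        f"stoichiometric coefficient of {sp!r} in {self.name!r} "
                        f"must be a positive integer, got {coef!r}")


@dataclass
class Trajectory:
    """Time grid with per-species concentration series from one integration."""

    times: np.ndarray
    species_names: list[str]
    concentrations: np.ndarray  # shape (len(times), n_species)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("trajectory times must be strictly increasing")
        if self.concentrations.shape != (self.times.size, len(self.species_names)):
            raise ValidationError("concentration matrix shape mismatch")

    def series(self, species: str) -> np.ndarray:
        return self.concentrations[:, self.species_names.index(species)]

    def terminal(self, species: str) -> float:
        return float(self.concentrations[-1, self.species_names.index(species)])

    def value_at(self, species: str, t: float) -> float:
        """Linear interpolation of one species at time t."""
        return float(np.interp(t, self.times, self.series(species)))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.concentrations, columns=self.species_names,
                            index=pd.Index(self.times, name="time"))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


class ReactionNetwork:
    """Species + mass-action reactions; compiles to an ODE right-hand side."""

    def __init__(self, species: list[str], reactions: list[Reaction],
                 parameters: dict[str, float],
                 parameter_classes: dict[str, str] | None = None):
        self.species = list(species)
        self.reactions = list(reactions)
        self.parameters = dict(parameters)
        self.parameter_classes = dict(parameter_classes or {})
        self._validate()
        self._compiled = None

    def _validate(self) -> None:
        sset = set(self.species)
        if len(sset) != len(self.species):
            raise ValidationError("duplicate species names")
        for rx in self.reactions:
            for sp in list(rx.reactants) + list(rx.products):
                if sp not in sset:
                    raise ValidationError(f"reaction {rx.name!r} references unknown species {sp!r}")
            if rx.rate_constant not in self.parameters:
                raise ValidationError(
                    f"reaction {rx.name!r} references missing rate constant {rx.rate_constant!r}")
        for name, value in self.parameters.items():
            if value < 0:
                raise ValidationError(f"rate constant {name!r} is negative ({value})")
        for name, cls in self.parameter_classes.items():
            if cls not in PARAMETER_CLASSES:
                raise ValidationError(f"unknown parameter class {cls!r} for {name!r}")

    # -- compilation -------------------------------------------------------

    def compile(self):
        """Build (reactant-order matrix P, net stoichiometry S, k index) arrays."""
        if self._compiled is None:
            ns, nr = len(self.species), len(self.reactions)
            index = {sp: i for i, sp in enumerate(self.species)}
            P = np.zeros((ns, nr), dtype=np.int64)
            S = np.zeros((ns, nr), dtype=np.int64)
            knames = []
            for j, rx in enumerate(self.reactions):
                for sp, coef in rx.reactants.items():
                    P[index[sp], j] = coef
                    S[index[sp], j] -= coef
                for sp, coef in rx.products.items():
                    S[index[sp], j] += coef
                knames.append(rx.rate_constant)
            self._compiled = (P, S, knames)
        return self._compiled

    def rate_vector(self, overrides: dict[str, float] | None = None) -> np.ndarray:
        """Per-reaction rate constants, optionally overriding parameter values."""
        params = self.parameters if overrides is None else {**self.parameters, **overrides}
        _, _, knames = self.compile()
        return np.array([params[k] for k in knames], dtype=float)

    def initial_vector(self, initial: dict[str, float]) -> np.ndarray:
        y0 = np.zeros(len(self.species))
        for sp, conc in initial.items():
            if sp not in self.species:
                raise ValidationError(f"initial concentration for unknown species {sp!r}")
            if conc < 0:
                raise ValidationError(f"negative initial concentration for {sp!r}")
            y0[self.species.index(sp)] = conc
        return y0

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "reactions": [
                {
                    "name": rx.name,
                    "reactants": rx.reactants,
                    "products": rx.products,
                    "rate_constant": rx.rate_constant,
                    "kind": rx.kind,
                }
                for rx in self.reactions
            ],
            "parameters": self.parameters,
            "parameter_classes": self.parameter_classes,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReactionNetwork":
        reactions = [
            Reaction(r["name"], {k: int(v) for k, v in r["reactants"].items()},
                     {k: int(v) for k, v in r["products"].items()},
                     r["rate_constant"], r["kind"])
            for r in d["reactions"]
        ]
        return cls(d["species"], reactions, d["parameters"], d.get("parameter_classes"))

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source: str) -> "ReactionNetwork":
        return cls.from_dict(json.loads(source))


@njit(cache=True)
def _rhs(y, P, S, k):
    ns = y.shape[0]
    nr = k.shape[0]
    out = np.zeros(ns)
    for j in range(nr):
        r = k[j]
        for i in range(ns):
            p = P[i, j]
            if p > 0:
                yi = y[i] if y[i] > 0.0 else 0.0
                for _ in range(p):
                    r *= yi
        if r != 0.0:
            for i in range(ns):
                s = S[i, j]
                if s != 0:
                    out[i] += s * r
    return out


@njit(cache=True)
def _euler_path(y0, P, S, k, dt, n_steps, save_stride):
    n_save = n_steps // save_stride + 1
    ns = y0.shape[0]
    ys = np.empty((n_save, ns))
    ys[0] = y0
    y = y0.copy()
    isave = 1
    for step in range(1, n_steps + 1):
        dy = _rhs(y, P, S, k)
        for i in range(ns):
            y[i] += dt * dy[i]
            if y[i] < 0.0:
                y[i] = 0.0
        if step % save_stride == 0:
            ys[isave] = y
            isave += 1
    return ys


def simulate(network: ReactionNetwork, initial: dict[str, float], horizon: float,
             t_eval: np.ndarray | None = None, n_points: int = 201,
             rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL,
             min_step: float = 0.0, max_nfev: int | None = None,
             parameter_overrides: dict[str, float] | None = None) -> Trajectory:
    """Integrate the network ODEs from ``initial`` over ``[0, horizon]``.

    Raises :class:`IntegrationError` with the last valid state on solver
    failure.  Concentrations are clipped to zero inside the rate law, so small
    negative solver excursions cannot feed back into the dynamics.
    ``max_nfev`` caps right-hand-side evaluations (an ensemble throughput
    guard against pathologically stiff parameter draws).
    """
    if horizon <= 0:
        raise ValidationError("horizon must be positive")
    P, S, _ = network.compile()
    k = network.rate_vector(parameter_overrides)
    y0 = network.initial_vector(initial)
    if t_eval is None:
        t_eval = np.linspace(0.0, horizon, n_points)
    else:
        t_eval = np.asarray(t_eval, dtype=float)

    nfev = 0

    class _BudgetExceeded(Exception):
        pass

    def fun(t, y):
        nonlocal nfev
        nfev += 1
        if max_nfev is not None and nfev > max_nfev:
            raise _BudgetExceeded
        return _rhs(y, P, S, k)

    try:
        sol = solve_ivp(fun, (0.0, float(horizon)), y0, method="LSODA", t_eval=t_eval,
                        rtol=rtol, atol=atol, min_step=min_step)
    except _BudgetExceeded:
        raise IntegrationError(
            f"ODE integration exceeded the evaluation budget ({max_nfev} RHS calls)")
    if not sol.success:
        last_t = float(sol.t[-1]) if sol.t.size else 0.0
        last_y = sol.y[:, -1] if sol.t.size else y0
        raise IntegrationError(f"ODE integration failed: {sol.message}",
                               last_time=last_t, last_state=last_y)
    return Trajectory(sol.t, network.species, sol.y.T)


def simulate_fixed_step(network: ReactionNetwork, initial: dict[str, float],
                        horizon: float, dt: float = 1e-4,
                        n_saved: int = 201,
                        parameter_overrides: dict[str, float] | None = None) -> Trajectory:
    """Fixed-step explicit Euler integration (verification oracle).

    Deliberately naive: no adaptivity, no error control.  Used to cross-check
    the adaptive solver on small instances; far too slow for production runs.
    """
    P, S, _ = network.compile()
    k = network.rate_vector(parameter_overrides)
    y0 = network.initial_vector(initial)
    n_steps = int(round(horizon / dt))
    save_stride = max(1, n_steps // (n_saved - 1))
    # trim so the saved grid lands exactly on multiples of save_stride * dt
    n_steps = (n_steps // save_stride) * save_stride
    ys = _euler_path(y0, P, S, k, dt, n_steps, save_stride)
    times = np.arange(ys.shape[0]) * (save_stride * dt)
    return Trajectory(times, network.species, ys)


def conserved_total(traj: Trajectory, weights: dict[str, int]) -> np.ndarray:
    """Multiplicity-weighted total of a conserved moiety along a trajectory."""
    total = np.zeros(traj.times.size)
    for sp, w in weights.items():
        total += w * traj.series(sp)
    return total
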