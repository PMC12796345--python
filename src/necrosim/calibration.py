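"""Goodness-of-fit and parameter estimation against phosphorylation time courses.

The fit criterion is the coefficient of determination between observed and
simulated series,

    R^2 = 1 - sum_i (x_i^obs - x_i^sim)^2 / sum_i (x_i^obs - mean(x^obs))^2,

which may be negative for fits worse than the observed mean.  Densitometry is
relative, so each observable is normalized by its own mean before comparison.
With several observables the objective is the mean of per-observable R^2.

The optimizer is a bounded global-then-local strategy: a Latin-Hypercube
multistart in log-parameter space followed by Nelder-Mead refinement of the
best starts.  Results are reproducible bit-for-bit for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from scipy.stats import qmc

from .network import ReactionNetwork, ValidationError, IntegrationError
from .necrosome import (
    InitialState,
    NecrosomeRateParameters,
    build_reference_network,
    reference_parameters,
    simulate_necrosome,
)

__all__ = [
    "TimeCourseDataset",
    "FitResult",
    "r_squared",
    "observable_series",
    "fit",
    "calibrate_reference",
    "DEFAULT_FREE_PARAMETERS",
]

#: observables understood by the necrosome model, mapped to trajectory readouts
OBSERVABLES = ("p-RIP3", "p-MLKL", "cleaved-C8")

#: core kinetic constants left free in the reference calibration
DEFAULT_FREE_PARAMETERS = ("k1", "kappa2", "k3", "k_minus3", "kappa4")


@dataclass
class TimeCourseDataset:
    """Observed (or synthetic) phosphorylation measurements at discrete times.

    ``observables`` maps an observable name to one value per time point
    (relative densitometry, a.u.).  ``condition`` is the initial state the
    measurements were taken under; ``provenance`` records origin metadata
    (for synthetic data: the generator seed and ground-truth id).
    """

    times: np.ndarray
    observables: dict[str, np.ndarray]
    condition: InitialState = field(default_factory=InitialState)
    provenance: dict = field(default_factory=lambda: {"kind": "experimental"})

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        clean = {}
        for name, values in self.observables.items():
            values = np.asarray(values, dtype=float)
            if values.shape != self.times.shape:
                raise ValidationError(f"observable {name!r}: one value per time required")
            if np.any(values < 0):
                raise ValidationError(f"observable {name!r} has negative values")
            clean[name] = values
        self.observables = clean

    def n_points(self) -> int:
        return int(self.times.size)

    def to_frame(self):
        import pandas as pd

        rows = [
            {"time": t, "observable": name, "value": v}
            for name, values in self.observables.items()
            for t, v in zip(self.times, values)
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path, condition_id: str = "") -> None:
        frame = self.to_frame()
        frame["condition_id"] = condition_id or self.provenance.get("truth_id", "")
        frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, condition: InitialState | None = None) -> "TimeCourseDataset":
        import pandas as pd

        frame = pd.read_csv(path)
        times = np.sort(frame["time"].unique())
        observables = {}
        for name, group in frame.groupby("observable"):
            series = group.set_index("time")["value"].reindex(times)
            observables[str(name)] = series.to_numpy()
        return cls(times, observables, condition or InitialState(),
                   provenance={"kind": "csv", "path": str(path)})


@dataclass
class FitResult:
    parameters: NecrosomeRateParameters
    r_squared: float
    n_evaluations: int
    converged: bool
    per_observable: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        import json

        return json.dumps({
            "parameters": self.parameters.as_dict(),
            "r_squared": self.r_squared,
            "n_evaluations": self.n_evaluations,
            "converged": self.converged,
            "per_observable": self.per_observable,
        }, indent=1)


def r_squared(observed, simulated) -> float:
    """Coefficient of determination of ``simulated`` against ``observed``."""
    observed = np.asarray(observed, dtype=float)
    simulated = np.asarray(simulated, dtype=float)
    if observed.shape != simulated.shape or observed.ndim != 1:
        raise ValidationError("observed and simulated must be 1-d of equal length")
    if observed.size < 2:
        raise ValidationError("need at least two data points")
    tss = float(np.sum((observed - observed.mean()) ** 2))
    if tss == 0.0:
        raise ValidationError("observed values are all identical; R^2 undefined")
    rss = float(np.sum((observed - simulated) ** 2))
    return 1.0 - rss / tss


def observable_series(traj, name: str, times, n_rip3: int) -> np.ndarray:
    """Model counterpart (nM) of a measured observable at the given times."""
    if name == "p-RIP3":
        free = np.interp(times, traj.times, traj.series("RIP3_pho"))
        if "RIP3phon_MLKL2" in traj.species_names:
            free = free + n_rip3 * np.interp(times, traj.times, traj.series("RIP3phon_MLKL2"))
        return free
    if name == "p-MLKL":
        return np.interp(times, traj.times, traj.series("MLKL_pho"))
    if name == "cleaved-C8":
        return np.interp(times, traj.times, traj.series("C8_active"))
    raise ValidationError(f"unknown observable {name!r}; expected one of {OBSERVABLES}")


def _scaled(values: np.ndarray) -> np.ndarray:
    # densitometry is relative: normalize each observable by its own mean.
    # The mean is used rather than the maximum because a noisy maximum biases
    # the whole normalized curve low, which shape-only fits absorb as
    # systematically slower kinetics.
    center = values.mean()
    return values / center if center > 0 else values


def _objective(dataset: TimeCourseDataset, n_rip3: int, include_caspase8: bool,
               horizon: float, sim_kwargs: dict):
    names = sorted(dataset.observables)

    def evaluate(params: NecrosomeRateParameters):
        net = build_reference_network(n_rip3, include_caspase8=include_caspase8,
                                      params=params)
        traj = simulate_necrosome(net, dataset.condition, horizon, **sim_kwargs)
        per = {}
        for name in names:
            sim = observable_series(traj, name, dataset.times, n_rip3)
            per[name] = r_squared(_scaled(dataset.observables[name]), _scaled(sim))
        return float(np.mean(list(per.values()))), per

    return evaluate


def fit(dataset: TimeCourseDataset,
        bounds: dict[str, tuple[float, float]],
        n_rip3: int = 3,
        include_caspase8: bool = False,
        base_params: NecrosomeRateParameters | None = None,
        seed: int = 0,
        n_starts: int = 24,
        n_refine: int = 3,
        max_evals_local: int = 150,
        horizon: float = 480.0,
        **sim_kwargs) -> FitResult:
    """Maximize the mean per-observable R^2 over the free parameters in ``bounds``.

    ``bounds`` maps parameter names (fields of
    :class:`NecrosomeRateParameters`) to (low, high) intervals searched in
    log-space.  Parameters not listed stay at ``base_params``.  Raises a
    fitting error if every evaluation fails.
    """
    if dataset.n_points() < 2:
        raise ValidationError("dataset too short to fit")
    names = sorted(bounds)
    if not names:
        raise ValidationError("bounds must cover at least one free parameter")
    for name, (lo, hi) in bounds.items():
        if not 0 < lo < hi:
            raise ValidationError(f"invalid bounds for {name!r}: ({lo}, {hi})")
    base = base_params or reference_parameters()
    sim_kwargs.setdefault("rtol", 1e-6)
    sim_kwargs.setdefault("atol", 1e-9)
    evaluate = _objective(dataset, n_rip3, include_caspase8, horizon, sim_kwargs)
    lo = np.log10([bounds[n][0] for n in names])
    hi = np.log10([bounds[n][1] for n in names])

    n_evals = 0

    def loss(x):
        nonlocal n_evals
        n_evals += 1
        x = np.clip(x, lo, hi)
        params = replace(base, **dict(zip(names, 10.0 ** x)))
        try:
            value, _ = evaluate(params)
        except (IntegrationError, ValidationError):
            return 1e6
        return -value

    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    starts = lo + sampler.random(n_starts) * (hi - lo)
    start_losses = np.array([loss(x) for x in starts])
    if np.all(start_losses >= 1e6):
        raise IntegrationError("all fit evaluations failed")
    order = np.argsort(start_losses)

    best_x, best_loss, converged = None, np.inf, False
    for idx in order[:n_refine]:
        res = minimize(loss, starts[idx], method="Nelder-Mead",
                       options=dict(maxfev=max_evals_local, xatol=1e-4, fatol=1e-6))
        if res.fun < best_loss:
            best_loss, best_x, converged = res.fun, np.clip(res.x, lo, hi), bool(res.success)

    params = replace(base, **dict(zip(names, 10.0 ** best_x)))
    value, per = evaluate(params)
    return FitResult(parameters=params, r_squared=value, n_evaluations=n_evals,
                     converged=converged, per_observable=per)


def default_bounds(free=DEFAULT_FREE_PARAMETERS, span: float = 30.0,
                   base_params: NecrosomeRateParameters | None = None):
    """Log-symmetric bounds around the reference values (factor ``span``)."""
    base = (base_params or reference_parameters()).as_dict()
    return {name: (base[name] / span, base[name] * span) for name in free}


def calibrate_reference(dataset: TimeCourseDataset,
                        free=DEFAULT_FREE_PARAMETERS,
                        seed: int = 0, **kwargs) -> FitResult:
    """Calibrate the core cascade constants against a p-RIP3 (and optionally
    p-MLKL) time course taken under caspase-blocked stimulation.

    Requires at least four time points.  Returns the best parameters found
    with the achieved R^2; ``converged`` is False when the local refinement
    hit its evaluation budget without meeting its tolerances.
    """
    if dataset.n_points() < 4:
        raise ValidationError("reference calibration needs >= 4 time points")
    bounds = kwargs.pop("bounds", None) or default_bounds(free)
    return fit(dataset, bounds, include_caspase8=False, seed=seed, **kwargs)
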