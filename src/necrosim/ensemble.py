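"""Latin-Hypercube stochastic ensembles over kinetic parameters and chain length.

To capture cell-to-cell variability, kinetic constants are perturbed log-
uniformly within per-class physiological ranges using stratified Latin
Hypercube Sampling, and the RIP3 chain length is drawn discrete-uniformly
from {1..8}.  The kinetic ([0.1, 10]) and catalytic ([1e-3, 1e2]) class
ranges are fold-changes applied to the calibrated reference constants --
the unit-invariant reading of a physiological prior, since absolute rate
constants are tied to an arbitrary unit system; degradation and synthesis
rates ([1e-2, 1] per minute) are sampled as absolute first-order rates.  For every sampled model the
MLKL phosphorylation efficiency

    eta = [p-MLKL](T) / [MLKL_total]

is evaluated at the readout time T across all chain lengths, the per-model
optimal chain length n* = argmax_n eta(n) is recorded, and the top fraction
alpha of models by peak efficiency is selected for statistics.  Condition
sweeps repeat the procedure at fixed TNF / RIP3 / MLKL levels and report the
shift in the distribution of n*.

Models are independent: results are identical regardless of execution order
or worker count because all randomness is drawn up-front from the master
seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import qmc

from .network import IntegrationError, ValidationError, Trajectory
from .necrosome import (
    CHAIN_LENGTHS,
    EfficiencyPhaseMap,
    InitialState,
    build_reference_network,
    reference_parameters,
    simulate_necrosome,
    DEFAULT_READOUT_MIN,
)

__all__ = [
    "SamplingRanges",
    "EnsembleResult",
    "EfficiencyPhaseMap",
    "lhs_sample",
    "efficiency",
    "run_ensemble",
    "select_top",
    "optimal_chain_length",
    "condition_sweep",
    "sweep_summary",
    "results_to_jsonl",
    "results_from_jsonl",
]

#: per-class log-uniform sampling ranges (physiological priors)
DEFAULT_CLASS_BOUNDS = {
    "kinetic": (0.1, 10.0),
    "catalytic": (1e-3, 1e2),
    "degradation": (1e-2, 1.0),
}


@dataclass
class SamplingRanges:
    """Sampling specification for the stochastic ensemble."""

    n_samples: int = 1000
    seed: int = 0
    kinetic_bounds: tuple[float, float] = DEFAULT_CLASS_BOUNDS["kinetic"]
    catalytic_bounds: tuple[float, float] = DEFAULT_CLASS_BOUNDS["catalytic"]
    degradation_bounds: tuple[float, float] = DEFAULT_CLASS_BOUNDS["degradation"]
    chain_lengths: tuple[int, ...] = CHAIN_LENGTHS

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")
        for name in ("kinetic_bounds", "catalytic_bounds", "degradation_bounds"):
            lo, hi = getattr(self, name)
            if not 0 < lo < hi:
                raise ValidationError(f"{name} must satisfy 0 < low < high")
        if not self.chain_lengths:
            raise ValidationError("chain_lengths must be non-empty")

    def bounds_for_class(self, cls: str) -> tuple[float, float]:
        return {
            "kinetic": self.kinetic_bounds,
            "catalytic": self.catalytic_bounds,
            "degradation": self.degradation_bounds,
        }[cls]


def lhs_sample(ranges: SamplingRanges, parameter_classes: dict[str, str]):
    """Stratified log-uniform parameter draws plus discrete-uniform chain lengths.

    Returns ``(names, theta, chains)`` where ``theta`` has shape
    ``(n_samples, n_parameters)``; every continuous dimension places exactly
    one sample in each of ``n_samples`` equal log-space bins.
    """
    names = sorted(parameter_classes)
    if not names:
        raise ValidationError("no parameters to sample")
    lo = np.array([np.log10(ranges.bounds_for_class(parameter_classes[n])[0]) for n in names])
    hi = np.array([np.log10(ranges.bounds_for_class(parameter_classes[n])[1]) for n in names])
    sampler = qmc.LatinHypercube(d=len(names), seed=ranges.seed)
    unit = sampler.random(ranges.n_samples)
    theta = 10.0 ** (lo + unit * (hi - lo))
    rng = np.random.default_rng(ranges.seed + 1)
    chains = rng.choice(np.asarray(ranges.chain_lengths, dtype=int), size=ranges.n_samples)
    return names, theta, chains


def efficiency(trajectory: Trajectory, mlkl_total: float,
               t: float = DEFAULT_READOUT_MIN) -> float:
    """MLKL phosphorylation efficiency eta = p-MLKL(t)/MLKL_total, in [0, 1]."""
    if mlkl_total <= 0:
        raise ValidationError("MLKL total must be positive; efficiency undefined")
    if t > trajectory.times[-1] + 1e-9:
        raise ValidationError("trajectory does not cover the readout time")
    eta = trajectory.value_at("MLKL_pho", t) / mlkl_total
    return float(min(max(eta, 0.0), 1.0))


@dataclass
class EnsembleResult:
    """One sampled model: parameters, efficiency profile and optimum."""

    model_id: int
    parameters: dict[str, float]
    efficiency_profile: dict[int, float]  # chain length -> eta (NaN = failed)
    sampled_chain: int = 0
    selected: bool = False

    @property
    def eta_star(self) -> float:
        vals = [v for v in self.efficiency_profile.values() if np.isfinite(v)]
        return max(vals) if vals else float("nan")

    @property
    def n_star(self) -> int:
        return optimal_chain_length(self.efficiency_profile)

    @property
    def failed(self) -> bool:
        return not any(np.isfinite(v) for v in self.efficiency_profile.values())


def optimal_chain_length(profile: dict[int, float]) -> int:
    """argmax_n eta(n); ties break toward the smallest chain length."""
    if not profile:
        raise ValidationError("empty efficiency profile")
    finite = {n: v for n, v in profile.items() if np.isfinite(v)}
    if not finite:
        raise ValidationError("all-failed efficiency profile")
    best = max(finite.values())
    return min(n for n, v in finite.items() if v >= best - 1e-15)


def run_ensemble(ranges: SamplingRanges,
                 conditions: InitialState | None = None,
                 chain_lengths=None,
                 include_caspase8: bool = False,
                 include_turnover: bool = True,
                 readout: float = DEFAULT_READOUT_MIN,
                 horizon: float | None = None,
                 rtol: float = 1e-6, atol: float = 1e-9,
                 min_step: float = 1e-6, max_nfev: int = 20000,
                 max_failure_fraction: float = 0.5) -> list[EnsembleResult]:
    """Evaluate the efficiency profile of every sampled model.

    Each sampled parameter vector overrides the class-tagged rate constants of
    the reference network; the efficiency is evaluated for every chain length
    in ``chain_lengths`` (default: the full {1..8} grid).  Failed integrations
    are recorded as NaN and excluded from statistics; the run aborts if more
    than ``max_failure_fraction`` of models fail everywhere.
    """
    conditions = conditions or InitialState()
    chain_grid = tuple(int(n) for n in (chain_lengths or ranges.chain_lengths))
    horizon = horizon if horizon is not None else readout
    mlkl_total = conditions.total_mlkl_nm()
    if mlkl_total <= 0:
        raise ValidationError("conditions give zero total MLKL")

    # one compiled network per chain length, shared across samples
    networks = {
        n: build_reference_network(n, include_caspase8=include_caspase8,
                                   include_turnover=include_turnover)
        for n in sorted(set(chain_grid))
    }
    template = networks[chain_grid[0]]
    # synthesis constants are not free: each balances its sampled degradation
    # rate at the condition's own amounts (homeostatic turnover)
    classes = {k: v for k, v in template.parameter_classes.items()
               if not k.startswith("ksyn_")}
    names, theta, chains = lhs_sample(ranges, classes)
    # kinetic/catalytic draws are fold-changes on the reference constants;
    # degradation-class draws are absolute first-order rates
    reference = template.parameters
    scale = np.array([reference[n] if classes[n] != "degradation" else 1.0
                      for n in names])
    theta = theta * scale[None, :]
    from .necrosome import NM_PER_UNIT

    amounts = conditions.amounts_nm()
    syn_targets = {k: amounts.get(k[5:], 0.0) / NM_PER_UNIT
                   for k in template.parameters if k.startswith("ksyn_")}

    results: list[EnsembleResult] = []
    t_eval = np.array([0.0, horizon]) if horizon <= readout else np.array(
        [0.0, readout, horizon])
    for i in range(ranges.n_samples):
        overrides = dict(zip(names, theta[i]))
        for ksyn, target in syn_targets.items():
            overrides[ksyn] = overrides[f"kdeg_{ksyn[5:]}"] * target
        profile: dict[int, float] = {}
        for n in chain_grid:
            try:
                traj = simulate_necrosome(networks[n], conditions, horizon,
                                          t_eval=t_eval, rtol=rtol, atol=atol,
                                          min_step=min_step, max_nfev=max_nfev,
                                          parameter_overrides=overrides)
                profile[n] = efficiency(traj, mlkl_total, readout)
            except (IntegrationError, ValidationError):
                profile[n] = float("nan")
        results.append(EnsembleResult(model_id=i, parameters=overrides,
                                      efficiency_profile=profile,
                                      sampled_chain=int(chains[i])))
    n_failed = sum(r.failed for r in results)
    if n_failed > max_failure_fraction * len(results):
        raise IntegrationError(
            f"{n_failed}/{len(results)} ensemble models failed integration")
    return results


def select_top(results: list[EnsembleResult], alpha: float = 0.05) -> list[EnsembleResult]:
    """The fraction ``alpha`` of models with the highest peak efficiency.

    Ties at the selection threshold break by model id for determinism; failed
    models are never selected.  Marks ``selected`` on the returned members.
    """
    if not results:
        raise ValidationError("empty ensemble")
    if not 0 < alpha <= 1:
        raise ValidationError("alpha must lie in (0, 1]")
    usable = [r for r in results if not r.failed]
    if not usable:
        raise ValidationError("no usable ensemble members")
    k = max(1, int(round(alpha * len(results))))
    k = min(k, len(usable))
    ranked = sorted(usable, key=lambda r: (-r.eta_star, r.model_id))
    chosen = ranked[:k]
    for r in chosen:
        r.selected = True
    return chosen


def sweep_summary(top: list[EnsembleResult]) -> dict[str, float]:
    """Box-plot-ready statistics of n* among selected models."""
    stars = np.array([r.n_star for r in top], dtype=float)
    q1, med, q3 = np.percentile(stars, [25, 50, 75])
    iqr = q3 - q1
    lo_whisk = stars[stars >= q1 - 1.5 * iqr].min()
    hi_whisk = stars[stars <= q3 + 1.5 * iqr].max()
    return {
        "n": int(stars.size),
        "mean": float(stars.mean()),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(lo_whisk),
        "whisker_high": float(hi_whisk),
    }


def condition_sweep(ranges: SamplingRanges, condition: str, condition_values,
                    alpha: float = 0.05,
                    base_state: InitialState | None = None,
                    **run_kwargs):
    """Distribution of n* among top-alpha models per condition value.

    ``condition`` is TNF, RIP3 or MLKL; values are nM.  Kinetic parameters are
    resampled identically (same seed) for every condition value, so shifts in
    the n* distribution are attributable to the condition alone.  Returns
    ``(summaries, distributions)``.
    """
    values = list(condition_values)
    if len(values) < 2:
        raise ValidationError("need at least two condition values")
    if condition not in ("TNF", "RIP3", "MLKL"):
        raise ValidationError("condition must be TNF, RIP3 or MLKL")
    base = base_state or InitialState()
    summaries, distributions = [], {}
    for value in values:
        if condition == "TNF":
            state = replace(base, tnf=float(value))
        else:
            state = replace(base, concentrations={**base.concentrations,
                                                  condition: float(value)})
        results = run_ensemble(ranges, conditions=state, **run_kwargs)
        top = select_top(results, alpha)
        stats = sweep_summary(top)
        stats.update({"condition": condition, "value": float(value)})
        summaries.append(stats)
        distributions[float(value)] = [r.n_star for r in top]
    return summaries, distributions


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def results_to_jsonl(results: list[EnsembleResult], path) -> None:
    with open(path, "w") as fh:
        for r in results:
            fh.write(json.dumps({
                "model_id": r.model_id,
                "parameters": r.parameters,
                "efficiency_profile": {str(n): (v if np.isfinite(v) else None)
                                       for n, v in r.efficiency_profile.items()},
                "sampled_chain": r.sampled_chain,
                "selected": r.selected,
            }) + "\n")


def results_from_jsonl(path) -> list[EnsembleResult]:
    out = []
    with open(path) as fh:
        for line in fh:
            d = json.loads(line)
            profile = {int(n): (float("nan") if v is None else float(v))
                       for n, v in d["efficiency_profile"].items()}
            out.append(EnsembleResult(model_id=d["model_id"], parameters=d["parameters"],
                                      efficiency_profile=profile,
                                      sampled_chain=d.get("sampled_chain", 0),
                                      selected=d.get("selected", False)))
    return out
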