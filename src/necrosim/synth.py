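"""Synthetic phosphorylation time courses from known ground-truth networks.

Stands in for immunoblot densitometry series: trajectories of a known
parameterization of the necrosome network are sampled at a handful of time
points and corrupted with measurement noise.  Densitometry noise is
intensity-proportional, so the default noise model is multiplicative
log-normal at 10% coefficient of variation; additive Gaussian noise (also
scaled to the signal) is available as an alternative.  All randomness flows
from explicit seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .network import ValidationError
from .necrosome import (
    InitialState,
    NecrosomeRateParameters,
    build_reference_network,
    reference_parameters,
    simulate_necrosome,
)
from .calibration import TimeCourseDataset, observable_series

__all__ = [
    "NoiseModel",
    "GroundTruth",
    "DEFAULT_SAMPLING_TIMES",
    "generate_timecourse",
    "generate_condition_series",
    "write_manifest",
]

#: default sampling grid (minutes), bracketing the 0-8 h stimulation window
DEFAULT_SAMPLING_TIMES = (0.0, 60.0, 120.0, 180.0, 240.0, 360.0, 480.0)

NOISE_KINDS = ("multiplicative-lognormal", "additive-gaussian")


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise specification.

    ``scale`` is the relative noise amplitude (coefficient of variation for
    the log-normal kind; standard deviation relative to the signal for the
    Gaussian kind).  Both kinds scale with the signal, so zero signal stays
    exactly zero and sample means are unbiased.
    """

    kind: str = "multiplicative-lognormal"
    scale: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if self.kind not in NOISE_KINDS:
            raise ValidationError(f"unknown noise kind {self.kind!r}")
        if self.scale < 0:
            raise ValidationError("noise scale must be >= 0")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.scale == 0:
            return values.copy()
        if self.kind == "additive-gaussian":
            noisy = values * (1.0 + self.scale * rng.standard_normal(values.shape))
            return np.clip(noisy, 0.0, None)
        sigma = np.sqrt(np.log1p(self.scale ** 2))  # CV -> log-sd
        factors = rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma, size=values.shape)
        return values * factors


@dataclass
class GroundTruth:
    """A simulable known-truth model: network configuration + parameters + state."""

    params: NecrosomeRateParameters = field(default_factory=reference_parameters)
    init: InitialState = field(default_factory=InitialState)
    n_rip3: int = 3
    include_caspase8: bool = False
    truth_id: str = "reference"

    def network(self):
        return build_reference_network(self.n_rip3,
                                       include_caspase8=self.include_caspase8,
                                       params=self.params)

    def simulate(self, horizon: float, **kwargs):
        kwargs.setdefault("rtol", 1e-8)
        kwargs.setdefault("atol", 1e-10)
        return simulate_necrosome(self.network(), self.init, horizon, **kwargs)

    def as_manifest(self) -> dict:
        return {
            "truth_id": self.truth_id,
            "n_rip3": self.n_rip3,
            "include_caspase8": self.include_caspase8,
            "parameters": self.params.as_dict(),
            "tnf_nm": self.init.tnf,
            "scalings": {
                "RIP1": self.init.scale_rip1,
                "RIP3": self.init.scale_rip3,
                "MLKL": self.init.scale_mlkl,
            },
            "concentration_overrides": dict(self.init.concentrations),
        }


def generate_timecourse(truth: GroundTruth,
                        times=DEFAULT_SAMPLING_TIMES,
                        observables=("p-RIP3",),
                        noise: NoiseModel | None = None,
                        replicates: int = 1) -> TimeCourseDataset:
    """Noisy observations of ``truth`` at the given times.

    With ``replicates`` > 1 the dataset records the per-time replicate mean
    (as densitometry series from repeated blots would be averaged); the raw
    replicate draws stay available in the provenance for dispersion checks.
    """
    times = np.asarray(sorted(times), dtype=float)
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    noise = noise or NoiseModel()
    horizon = max(times[-1], 1.0)
    traj = truth.simulate(horizon)
    missing = [name for name in observables
               if name == "cleaved-C8" and "C8_active" not in traj.species_names]
    if missing:
        raise ValidationError(f"observable(s) {missing} absent from the truth network")
    rng = np.random.default_rng(noise.seed)
    clean, noisy = {}, {}
    for name in observables:
        series = observable_series(traj, name, times, truth.n_rip3)
        draws = np.stack([noise.apply(series, rng) for _ in range(replicates)])
        clean[name] = series
        noisy[name] = draws.mean(axis=0)
    return TimeCourseDataset(
        times=times,
        observables=noisy,
        condition=truth.init,
        provenance={
            "kind": "synthetic",
            "truth_id": truth.truth_id,
            "seed": noise.seed,
            "noise_kind": noise.kind,
            "noise_scale": noise.scale,
            "replicates": replicates,
            "noiseless": {k: v.tolist() for k, v in clean.items()},
        },
    )


def generate_condition_series(truth: GroundTruth, condition: str, values,
                              noise: NoiseModel | None = None,
                              times=DEFAULT_SAMPLING_TIMES,
                              observables=("p-RIP3", "p-MLKL"),
                              replicates: int = 1) -> list[TimeCourseDataset]:
    """One dataset per condition value (dose / expression series), shared truth.

    ``condition`` is TNF (dose, nM), RIP1/RIP3/MLKL (expression scaling if
    <= 1, otherwise absolute nM).
    """
    if condition not in ("TNF", "RIP1", "RIP3", "MLKL"):
        raise ValidationError("condition must be one of TNF, RIP1, RIP3, MLKL")
    noise = noise or NoiseModel()
    datasets = []
    for j, value in enumerate(values):
        value = float(value)
        if value < 0:
            raise ValidationError("condition values must be non-negative")
        if condition == "TNF":
            init = replace(truth.init, tnf=value)
        elif value <= 1.0:
            init = replace(truth.init, **{f"scale_{condition.lower()}": value})
        else:
            init = replace(truth.init,
                           concentrations={**truth.init.concentrations, condition: value})
        variant = replace(truth, init=init,
                          truth_id=f"{truth.truth_id}/{condition}={value:g}")
        datasets.append(generate_timecourse(variant, times, observables,
                                            replace(noise, seed=noise.seed + j),
                                            replicates))
    return datasets


def write_manifest(truths, path) -> None:
    """Manifest JSON recording ground-truth parameters for recovery scoring."""
    if isinstance(truths, GroundTruth):
        truths = [truths]
    with open(path, "w") as fh:
        json.dump([t.as_manifest() for t in truths], fh, indent=1)
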