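"""The TNF-induced necrosome assembly network.

The reference network implements six modules of TNF-driven necroptotic
signaling as elementary mass-action reactions:

1. TNF binding to TNFR1 and recruitment of TRADD and RIP1 into complex I;
2. activation of RIP1 and its release from complex I (the receptor, TRADD and
   the activated RIP1 are recycled);
3. necrosome nucleation: one active RIP1 binds ``n`` RIP3 molecules
   (``n`` = RIP3 assembly degree, the central control variable; the measured
   reference stoichiometry is RIP1:RIP3:MLKL = 1:3:2) and phosphorylates them,
   releasing ``n`` p-RIP3 per catalytic event;
4. MLKL activation: ``n`` p-RIP3 bind two MLKL and phosphorylate both;
5. mutual inhibition between the RIP3 and caspase-8 branches: active
   caspase-8 cleaves active RIP1 and disassembles necrosomes by cleaving
   their complexed RIP3 (bilinear catalytic removal into inert cleavage
   products), while p-RIP3 disassembles the caspase-8 activation complex
   before the protease can mature;
6. the caspase-8 branch itself: FADD bridges caspase-8 to active RIP1 at 1:1,
   TRADD provides a weak RIP1-independent activation route, and c-FLIP
   sequesters the caspase-8 precursor.  Active RIP1 has a finite catalytic
   lifetime (first-order inactivation), which bounds the signaling budget a
   given RIP1 pool can deliver.

With every module enabled the reference network has exactly 23 reactions.
Optional first-order synthesis/degradation ("turnover") of the core proteins
adds reactions beyond the reference set; conservation of the RIP1/RIP3/MLKL
moieties holds exactly when turnover is off because cleavage products are
explicit species.

Units
-----
Public interfaces take concentrations in nM and times in minutes.  Rate laws
operate on scaled concentrations (one model unit = ``NM_PER_UNIT`` nM); the
scale is part of the calibrated reference model and sets the concentration
regime in which higher-order association terms switch between amplifying and
attenuating.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .network import (
    Reaction,
    ReactionNetwork,
    Trajectory,
    ValidationError,
    IntegrationError,
    simulate,
)

__all__ = [
    "NM_PER_UNIT",
    "REFERENCE_NM",
    "NecrosomeRateParameters",
    "InitialState",
    "EfficiencyPhaseMap",
    "build_reference_network",
    "reference_parameters",
    "reference_initial_state",
    "simulate_necrosome",
    "terminal_readout",
    "efficiency_profile",
    "activation_threshold",
    "rip1_titration",
    "breakpoint_level",
    "caspase8_recruitment",
    "biphasic_scan",
    "phase_diagram",
]

#: concentration scale of the rate laws (nM per model unit)
NM_PER_UNIT = 9.0

#: reference initial amounts (nM) of the inactive core proteins
REFERENCE_NM = {
    "TNFR1": 12.5,
    "TRADD": 25.0,
    "RIP1": 25.0,
    "RIP3": 62.5,
    "MLKL": 45.0,
    "FADD": 25.0,
    "C8": 25.0,
    "cFLIP": 12.5,
}

#: reference TNF dose (nM) for strong ("TSZ-like") stimulation
DEFAULT_TNF_NM = 100.0

#: default simulation horizon and efficiency readout time (minutes)
DEFAULT_HORIZON_MIN = 480.0
DEFAULT_READOUT_MIN = 240.0

#: chain lengths the network accepts for the RIP3 assembly degree
CHAIN_LENGTHS = tuple(range(1, 9))

#: core proteins subject to optional first-order turnover
TURNOVER_SPECIES = ("RIP1", "RIP3", "MLKL", "C8", "cFLIP")


@dataclass(frozen=True)
class NecrosomeRateParameters:
    """Rate constants of the necrosome network (model units, per minute).

    The core cascade constants follow the reaction naming R1-R4: ``k1`` /
    ``k_minus1`` bind and unbind active RIP1 with n RIP3; ``kappa2``
    phosphorylates RIP3 in the complex; ``k3`` / ``k_minus3`` bind p-RIP3 with
    MLKL; ``kappa4`` phosphorylates MLKL.  Upstream, caspase-8-branch and
    turnover constants are named by what they do.
    """

    # upstream: TNF receptor engagement and complex I
    k_tnf_on: float = 0.05
    k_tnf_off: float = 2.17
    k_tradd_on: float = 1.0
    k_rip1_on: float = 1.0
    k_act: float = 1.54
    # core necrosome cascade (R1-R4)
    k_rip1a_decay: float = 0.022
    k1: float = 2.36e-4
    k_minus1: float = 0.07
    kappa2: float = 1.96
    k3: float = 100.0
    k_minus3: float = 0.064
    kappa4: float = 1.24e-3
    # caspase-8 branch
    k_fadd_on: float = 0.01
    k_fadd_off: float = 1.0
    k_c8_on: float = 1.0
    k_c8_off: float = 1.0
    kappa_c8: float = 0.1
    k_tradd_c8: float = 5e-6
    k_cleave: float = 0.015
    k_block: float = 0.005
    k_flip_on: float = 1.0
    k_flip_off: float = 0.1
    # optional first-order turnover
    deg: float = 0.01
    syn_scale: float = 1.0  # synthesis balances degradation at reference amounts

    def __post_init__(self):
        for name, value in self.__dict__.items():
            if value < 0:
                raise ValidationError(f"rate {name} must be non-negative, got {value}")

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


@dataclass
class InitialState:
    """Initial condition: TNF dose, reference amounts and expression scalings.

    All proteins start in their inactive, unbound forms.  ``concentrations``
    overrides reference amounts (nM) per species; the scalings multiply the
    RIP1/RIP3/MLKL amounts (knockdown < 1 < overexpression) and must lie in
    [0, 10].
    """

    tnf: float = DEFAULT_TNF_NM
    concentrations: dict[str, float] = field(default_factory=dict)
    scale_rip1: float = 1.0
    scale_rip3: float = 1.0
    scale_mlkl: float = 1.0

    def __post_init__(self):
        if self.tnf < 0:
            raise ValidationError("TNF dose must be non-negative")
        for name in ("scale_rip1", "scale_rip3", "scale_mlkl"):
            value = getattr(self, name)
            if not 0.0 <= value <= 10.0:
                raise ValidationError(f"{name} must lie in [0, 10], got {value}")
        for sp, conc in self.concentrations.items():
            if conc < 0:
                raise ValidationError(f"negative initial concentration for {sp!r}")

    def amounts_nm(self) -> dict[str, float]:
        """Initial amounts in nM for every seeded species."""
        amounts = dict(REFERENCE_NM)
        amounts.update(self.concentrations)
        amounts["RIP1"] = amounts["RIP1"] * self.scale_rip1
        amounts["RIP3"] = amounts["RIP3"] * self.scale_rip3
        amounts["MLKL"] = amounts["MLKL"] * self.scale_mlkl
        amounts["TNF"] = self.tnf
        return amounts

    def total_mlkl_nm(self) -> float:
        return self.amounts_nm()["MLKL"]


def reference_parameters() -> NecrosomeRateParameters:
    """The calibrated reference parameterization."""
    return NecrosomeRateParameters()


def reference_initial_state(**kwargs) -> InitialState:
    return InitialState(**kwargs)


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def build_reference_network(n_rip3: int = 3, include_caspase8: bool = True,
                            mutual_inhibition: bool = True,
                            include_turnover: bool = False,
                            params: NecrosomeRateParameters | None = None,
                            ) -> ReactionNetwork:
    """Assemble the necrosome network with ``n_rip3`` RIP3 per RIP1 subunit.

    With all modules on (and turnover off) the network has exactly 23
    reactions.  ``mutual_inhibition`` controls the caspase-8/RIP3 crosstalk
    reactions and requires ``include_caspase8``.
    """
    if n_rip3 not in CHAIN_LENGTHS:
        raise ValidationError(f"n_rip3 must be in {{1..8}}, got {n_rip3}")
    if mutual_inhibition and not include_caspase8:
        mutual_inhibition = False
    p = params or reference_parameters()
    n = int(n_rip3)

    species = [
        "TNF", "TNFR1", "TNF_TNFR1", "TRADD", "CI_TRADD", "CI",
        "RIP1", "RIP1_active", "RIP1_spent", "RIP3", "RIP1a_RIP3n", "RIP3_pho",
        "MLKL", "RIP3phon_MLKL2", "MLKL_pho",
    ]
    reactions = [
        # module 1-2: receptor engagement, complex I, RIP1 activation
        Reaction("tnf_binding", {"TNF": 1, "TNFR1": 1}, {"TNF_TNFR1": 1},
                 "k_tnf_on", "association"),
        Reaction("tnf_unbinding", {"TNF_TNFR1": 1}, {"TNF": 1, "TNFR1": 1},
                 "k_tnf_off", "dissociation"),
        # complex I nucleates on a pair of ligated receptors (TNF cross-links
        # receptors, so signaling-competent complex I engages cooperatively)
        Reaction("tradd_recruitment", {"TNF_TNFR1": 2, "TRADD": 1}, {"CI_TRADD": 1},
                 "k_tradd_on", "association"),
        Reaction("rip1_recruitment", {"CI_TRADD": 1, "RIP1": 1}, {"CI": 1},
                 "k_rip1_on", "association"),
        Reaction("rip1_activation", {"CI": 1},
                 {"TNF_TNFR1": 2, "TRADD": 1, "RIP1_active": 1},
                 "k_act", "catalytic"),
        # active RIP1 has a finite catalytic lifetime (kinase inactivation)
        Reaction("rip1a_decay", {"RIP1_active": 1}, {"RIP1_spent": 1},
                 "k_rip1a_decay", "degradation"),
        # module 3: R1/R2 — RIP1-RIP3 assembly and RIP3 phosphorylation
        Reaction("R1_bind", {"RIP1_active": 1, "RIP3": n}, {"RIP1a_RIP3n": 1},
                 "k1", "association"),
        Reaction("R1_unbind", {"RIP1a_RIP3n": 1}, {"RIP1_active": 1, "RIP3": n},
                 "k_minus1", "dissociation"),
        Reaction("R2_phosphorylate_rip3", {"RIP1a_RIP3n": 1},
                 {"RIP1_active": 1, "RIP3_pho": n}, "kappa2", "catalytic"),
        # module 4: R3/R4 — MLKL recruitment and phosphorylation
        Reaction("R3_bind", {"RIP3_pho": n, "MLKL": 2}, {"RIP3phon_MLKL2": 1},
                 "k3", "association"),
        Reaction("R3_unbind", {"RIP3phon_MLKL2": 1}, {"RIP3_pho": n, "MLKL": 2},
                 "k_minus3", "dissociation"),
        Reaction("R4_phosphorylate_mlkl", {"RIP3phon_MLKL2": 1},
                 {"RIP3_pho": n, "MLKL_pho": 2}, "kappa4", "catalytic"),
    ]
    parameters = {
        "k_tnf_on": p.k_tnf_on, "k_tnf_off": p.k_tnf_off,
        "k_tradd_on": p.k_tradd_on, "k_rip1_on": p.k_rip1_on, "k_act": p.k_act,
        "k_rip1a_decay": p.k_rip1a_decay,
        "k1": p.k1, "k_minus1": p.k_minus1, "kappa2": p.kappa2,
        "k3": p.k3, "k_minus3": p.k_minus3, "kappa4": p.kappa4,
    }
    classes = {
        "k_tnf_on": "kinetic", "k_tnf_off": "kinetic", "k_tradd_on": "kinetic",
        "k_rip1_on": "kinetic", "k_act": "catalytic",
        "k_rip1a_decay": "degradation",
        "k1": "kinetic", "k_minus1": "kinetic", "kappa2": "catalytic",
        "k3": "kinetic", "k_minus3": "kinetic", "kappa4": "catalytic",
    }

    if include_caspase8:
        species += ["FADD", "RIP1a_FADD", "C8", "RIP1a_FADD_C8", "C8_active",
                    "cFLIP", "C8_cFLIP"]
        reactions += [
            # module 6: FADD-bridged 1:1 recruitment and activation of caspase-8
            Reaction("fadd_bind", {"RIP1_active": 1, "FADD": 1}, {"RIP1a_FADD": 1},
                     "k_fadd_on", "association"),
            Reaction("fadd_unbind", {"RIP1a_FADD": 1}, {"RIP1_active": 1, "FADD": 1},
                     "k_fadd_off", "dissociation"),
            Reaction("c8_recruit", {"RIP1a_FADD": 1, "C8": 1}, {"RIP1a_FADD_C8": 1},
                     "k_c8_on", "association"),
            Reaction("c8_release", {"RIP1a_FADD_C8": 1}, {"RIP1a_FADD": 1, "C8": 1},
                     "k_c8_off", "dissociation"),
            Reaction("c8_activation", {"RIP1a_FADD_C8": 1},
                     {"RIP1_active": 1, "FADD": 1, "C8_active": 1},
                     "kappa_c8", "catalytic"),
            Reaction("tradd_c8_activation", {"TRADD": 1, "C8": 1},
                     {"TRADD": 1, "C8_active": 1}, "k_tradd_c8", "catalytic"),
            # c-FLIP sequesters the caspase-8 precursor; RIP1-dependent synthesis
            Reaction("flip_bind", {"cFLIP": 1, "C8": 1}, {"C8_cFLIP": 1},
                     "k_flip_on", "association"),
            Reaction("flip_unbind", {"C8_cFLIP": 1}, {"cFLIP": 1, "C8": 1},
                     "k_flip_off", "dissociation"),
        ]
        parameters.update({
            "k_fadd_on": p.k_fadd_on, "k_fadd_off": p.k_fadd_off,
            "k_c8_on": p.k_c8_on, "k_c8_off": p.k_c8_off,
            "kappa_c8": p.kappa_c8, "k_tradd_c8": p.k_tradd_c8,
            "k_flip_on": p.k_flip_on, "k_flip_off": p.k_flip_off,
        })
        classes.update({
            "k_fadd_on": "kinetic", "k_fadd_off": "kinetic",
            "k_c8_on": "kinetic", "k_c8_off": "kinetic",
            "kappa_c8": "catalytic", "k_tradd_c8": "catalytic",
            "k_flip_on": "kinetic", "k_flip_off": "kinetic",
        })

    if mutual_inhibition:
        species += ["RIP3_cleaved", "RIP1_cleaved"]
        reactions += [
            # module 5: caspase-8 cleaves RIP3 and RIP1 (shared rate constant);
            # p-RIP3 disassembles the caspase-8 activation complex
            # caspase-8 disassembles necrosomes: cleaves the complexed RIP3,
            # releasing the bound (unphosphorylated) MLKL
            Reaction("c8_cleaves_rip3", {"C8_active": 1, "RIP3phon_MLKL2": 1},
                     {"C8_active": 1, "RIP3_cleaved": n, "MLKL": 2},
                     "k_cleave", "catalytic"),
            Reaction("c8_cleaves_rip1", {"C8_active": 1, "RIP1_active": 1},
                     {"C8_active": 1, "RIP1_cleaved": 1}, "k_cleave", "catalytic"),
            Reaction("prip3_blocks_c8", {"RIP3_pho": 1, "RIP1a_FADD_C8": 1},
                     {"RIP3_pho": 1, "RIP1a_FADD": 1, "C8": 1}, "k_block", "catalytic"),
        ]
        parameters["k_cleave"] = p.k_cleave
        parameters["k_block"] = p.k_block
        classes["k_cleave"] = "catalytic"
        classes["k_block"] = "catalytic"

    if include_turnover:
        turnover = [sp for sp in TURNOVER_SPECIES if sp in species]
        for sp in turnover:
            ref_units = REFERENCE_NM[sp] / NM_PER_UNIT
            reactions.append(Reaction(f"syn_{sp}", {}, {sp: 1}, f"ksyn_{sp}", "synthesis"))
            reactions.append(Reaction(f"deg_{sp}", {sp: 1}, {}, f"kdeg_{sp}", "degradation"))
            parameters[f"ksyn_{sp}"] = p.deg * ref_units * p.syn_scale
            parameters[f"kdeg_{sp}"] = p.deg
            classes[f"ksyn_{sp}"] = "degradation"
            classes[f"kdeg_{sp}"] = "degradation"

    return ReactionNetwork(species, reactions, parameters, classes)


# ---------------------------------------------------------------------------
# simulation and readouts
# ---------------------------------------------------------------------------

def simulate_necrosome(network: ReactionNetwork, init: InitialState,
                       horizon: float = DEFAULT_HORIZON_MIN,
                       **kwargs) -> Trajectory:
    """Integrate the network from ``init``; trajectory concentrations in nM."""
    amounts = init.amounts_nm()
    initial_units = {sp: amounts[sp] / NM_PER_UNIT
                     for sp in network.species if sp in amounts}
    traj = simulate(network, initial_units, horizon, **kwargs)
    return Trajectory(traj.times, traj.species_names,
                      traj.concentrations * NM_PER_UNIT)


def terminal_readout(traj: Trajectory, species: str,
                     t: float = DEFAULT_READOUT_MIN) -> float:
    """Concentration (nM) of ``species`` at the readout time."""
    return traj.value_at(species, t)


def efficiency_profile(n_grid=CHAIN_LENGTHS, init: InitialState | None = None,
                       params: NecrosomeRateParameters | None = None,
                       include_caspase8: bool = False,
                       readout: float = DEFAULT_READOUT_MIN,
                       horizon: float = DEFAULT_HORIZON_MIN,
                       **sim_kwargs) -> dict[int, float]:
    """MLKL phosphorylation efficiency eta = p-MLKL(T)/MLKL_total per chain length.

    The default drops the caspase-8 branch, matching stimulation conditions in
    which caspase activity is pharmacologically blocked.
    """
    init = init or reference_initial_state()
    mlkl_total = init.total_mlkl_nm()
    if mlkl_total <= 0:
        raise ValidationError("MLKL total must be positive for an efficiency readout")
    profile = {}
    for n in n_grid:
        net = build_reference_network(n, include_caspase8=include_caspase8,
                                      params=params)
        traj = simulate_necrosome(net, init, horizon, **sim_kwargs)
        eta = terminal_readout(traj, "MLKL_pho", readout) / mlkl_total
        profile[int(n)] = float(min(max(eta, 0.0), 1.0))
    return profile


def activation_threshold(n_grid=CHAIN_LENGTHS, fraction: float = 0.5,
                         init: InitialState | None = None,
                         params: NecrosomeRateParameters | None = None,
                         readout: float = DEFAULT_READOUT_MIN,
                         **sim_kwargs) -> int:
    """Smallest chain length whose terminal p-RIP3 reaches ``fraction`` of the max."""
    init = init or reference_initial_state()
    outputs = {}
    for n in n_grid:
        net = build_reference_network(n, include_caspase8=False, params=params)
        traj = simulate_necrosome(net, init, DEFAULT_HORIZON_MIN, **sim_kwargs)
        outputs[int(n)] = terminal_readout(traj, "RIP3_pho", readout) + \
            int(n) * terminal_readout(traj, "RIP3phon_MLKL2", readout)
    top = max(outputs.values())
    for n in sorted(outputs):
        if outputs[n] >= fraction * top:
            return n
    return max(outputs)  # pragma: no cover - unreachable, max satisfies fraction<=1


def total_prip3(traj: Trajectory, n_rip3: int, t: float = DEFAULT_READOUT_MIN) -> float:
    """Total phosphorylated RIP3 (free + MLKL-complexed), nM, at time t."""
    return traj.value_at("RIP3_pho", t) + n_rip3 * traj.value_at("RIP3phon_MLKL2", t)


# ---------------------------------------------------------------------------
# scans
# ---------------------------------------------------------------------------

#: default log-spaced RIP1 titration grid (fractions of reference expression),
#: fine below 0.3 where the threshold collapse is expected
DEFAULT_RIP1_LEVELS = (
    0.05, 0.0625, 0.08, 0.1, 0.125, 0.15, 0.2, 0.25, 0.3, 0.4, 0.5, 0.65, 0.8, 1.0,
)


def breakpoint_level(levels, outputs) -> float:
    """Level below which the output drops sharply.

    On an ascending level grid, the breakpoint is the upper level of the
    adjacent pair with the largest output drop (normalized by the curve
    maximum, so a plateau followed by a collapse yields the knee, not the
    tail).
    """
    levels = np.asarray(levels, dtype=float)
    outputs = np.asarray(outputs, dtype=float)
    if levels.size < 2:
        raise ValidationError("need at least two levels")
    top = outputs.max()
    if top <= 0:
        raise ValidationError("all outputs are zero; breakpoint undefined")
    drops = np.diff(outputs) / top
    return float(levels[int(np.argmax(drops)) + 1])


def rip1_titration(levels=DEFAULT_RIP1_LEVELS,
                   n_rip3: int = 3,
                   init: InitialState | None = None,
                   params: NecrosomeRateParameters | None = None,
                   include_caspase8: bool = False,
                   mutual_inhibition: bool = False,
                   readout: float = DEFAULT_READOUT_MIN,
                   **sim_kwargs):
    """Terminal p-RIP3 versus RIP1 expression level (fractions of reference).

    Returns ``(curve, breakpoint)`` where the breakpoint is the level with the
    maximal drop per grid step.  The default emulates caspase-blocked
    stimulation (caspase-8 branch off).
    """
    levels = sorted(float(x) for x in levels)
    if any(not 0.0 <= x <= 1.0 for x in levels):
        raise ValidationError("RIP1 levels must lie in [0, 1]")
    base = init or reference_initial_state()
    net = build_reference_network(n_rip3, include_caspase8=include_caspase8,
                                  mutual_inhibition=mutual_inhibition, params=params)
    outputs = []
    for f in levels:
        state = replace(base, scale_rip1=f)
        traj = simulate_necrosome(net, state, **sim_kwargs)
        outputs.append(total_prip3(traj, n_rip3, readout))
    from .basic import ResponseCurve

    curve = ResponseCurve(np.asarray(levels), np.asarray(outputs),
                          max_output=float(np.max(outputs)))
    return curve, breakpoint_level(levels, outputs)


def caspase8_recruitment(levels=DEFAULT_RIP1_LEVELS,
                         init: InitialState | None = None,
                         params: NecrosomeRateParameters | None = None,
                         readout: float = DEFAULT_READOUT_MIN,
                         **sim_kwargs):
    """Caspase-8 recruited into the RIP1 complex versus RIP1 level.

    Run under RIP3 depletion (scale_rip3 = 0), where the caspase-8 branch
    responds linearly to RIP1 abundance.
    """
    levels = sorted(float(x) for x in levels)
    base = init or reference_initial_state()
    net = build_reference_network(3, include_caspase8=True,
                                  mutual_inhibition=False, params=params)
    outputs = []
    for f in levels:
        state = replace(base, scale_rip1=f, scale_rip3=0.0)
        traj = simulate_necrosome(net, state, **sim_kwargs)
        recruited = traj.value_at("RIP1a_FADD_C8", readout) + \
            traj.value_at("C8_active", readout)
        outputs.append(recruited)
    from .basic import ResponseCurve

    return ResponseCurve(np.asarray(levels), np.asarray(outputs),
                         max_output=float(np.max(outputs)))


def biphasic_scan(levels=DEFAULT_RIP1_LEVELS,
                  n_rip3: int = 3,
                  init: InitialState | None = None,
                  params: NecrosomeRateParameters | None = None,
                  mutual_inhibition: bool = True,
                  readout: float = DEFAULT_READOUT_MIN,
                  **sim_kwargs):
    """Terminal p-RIP3 versus RIP1 level with the caspase-8 branch engaged.

    With mutual inhibition on, caspase-8 activation grows linearly with RIP1
    while the RIP3 branch responds with a threshold, producing a biphasic
    p-RIP3 response: an interior maximum at intermediate RIP1.  Returns
    ``(curve, level_at_maximum)``.
    """
    levels = sorted(float(x) for x in levels)
    base = init or reference_initial_state()
    net = build_reference_network(n_rip3, include_caspase8=True,
                                  mutual_inhibition=mutual_inhibition, params=params)
    outputs = []
    for f in levels:
        state = replace(base, scale_rip1=f)
        traj = simulate_necrosome(net, state, **sim_kwargs)
        outputs.append(total_prip3(traj, n_rip3, readout))
    from .basic import ResponseCurve

    curve = ResponseCurve(np.asarray(levels), np.asarray(outputs),
                          max_output=float(np.max(outputs)))
    peak_level = float(levels[int(np.argmax(outputs))])
    return curve, peak_level


@dataclass
class EfficiencyPhaseMap:
    """Efficiency grid over (condition value, RIP3 chain length)."""

    condition: str
    condition_values: np.ndarray  # nM (or RIP1 fraction)
    chain_lengths: np.ndarray
    values: np.ndarray  # shape (len(condition_values), len(chain_lengths)); NaN = failed
    effective_fraction: float = 1.0 / 3.0

    def optimal_n(self) -> np.ndarray:
        """Chain length maximizing efficiency for each condition value."""
        vals = np.where(np.isnan(self.values), -np.inf, self.values)
        return self.chain_lengths[np.argmax(vals, axis=1)]

    def minimal_effective_n(self) -> np.ndarray:
        """Smallest chain length reaching ``effective_fraction`` of the map maximum.

        Conditions where no chain length is effective report -1.
        """
        threshold = self.effective_fraction * np.nanmax(self.values)
        out = np.full(self.condition_values.size, -1, dtype=int)
        for i in range(self.condition_values.size):
            ok = np.nonzero(self.values[i] >= threshold)[0]
            if ok.size:
                out[i] = int(self.chain_lengths[ok[0]])
        return out

    def to_frame(self):
        import pandas as pd

        rows = [
            {"condition": self.condition, "value": v, "n": int(n), "efficiency": e}
            for i, v in enumerate(self.condition_values)
            for n, e in zip(self.chain_lengths, self.values[i])
        ]
        return pd.DataFrame(rows)


_CONDITIONS = ("TNF", "RIP1", "RIP3", "MLKL")


def phase_diagram(condition: str, condition_grid, n_grid=CHAIN_LENGTHS,
                  init: InitialState | None = None,
                  params: NecrosomeRateParameters | None = None,
                  include_caspase8: bool = False,
                  readout: float = DEFAULT_READOUT_MIN,
                  effective_fraction: float = 1.0 / 3.0,
                  **sim_kwargs) -> EfficiencyPhaseMap:
    """Efficiency eta over a (condition, chain length) grid.

    ``condition`` is one of TNF / RIP1 / RIP3 / MLKL; its grid is in nM
    (RIP1/RIP3/MLKL set the total expression) except RIP1 which may also be
    given as fractions if values are <= 1.  Failed integrations are flagged
    as NaN, not fatal.
    """
    if condition not in _CONDITIONS:
        raise ValidationError(f"condition must be one of {_CONDITIONS}")
    grid = np.asarray(list(condition_grid), dtype=float)
    n_grid = np.asarray(list(n_grid), dtype=int)
    if grid.size == 0 or n_grid.size == 0:
        raise ValidationError("grids must be non-empty")
    base = init or reference_initial_state()
    values = np.full((grid.size, n_grid.size), np.nan)
    for j, n in enumerate(n_grid):
        net = build_reference_network(int(n), include_caspase8=include_caspase8,
                                      params=params)
        for i, v in enumerate(grid):
            state = _condition_state(base, condition, float(v))
            mlkl_total = state.total_mlkl_nm()
            try:
                traj = simulate_necrosome(net, state, **sim_kwargs)
            except IntegrationError:
                continue
            eta = traj.value_at("MLKL_pho", readout) / mlkl_total
            values[i, j] = min(max(eta, 0.0), 1.0)
    return EfficiencyPhaseMap(condition, grid, n_grid, values, effective_fraction)


def _condition_state(base: InitialState, condition: str, value: float) -> InitialState:
    if condition == "TNF":
        return replace(base, tnf=value)
    if condition == "RIP1":
        if value <= 1.0:  # fraction of reference expression
            return replace(base, scale_rip1=value)
        return replace(base, concentrations={**base.concentrations, "RIP1": value})
    key = condition if condition != "MLKL" else "MLKL"
    return replace(base, concentrations={**base.concentrations, key: value})
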