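# necrosim

Mass-action kinetic modeling of necrosome assembly: how the integer
stoichiometry of a supramolecular signaling complex — the number of RIP3
kinases recruited per RIP1 in the TNF-induced necrosome — controls signal
amplification, threshold behavior, and ultimately the efficiency of MLKL
phosphorylation that commits a cell to necroptosis.

The package is for systems biologists who want to simulate, calibrate and
interrogate higher-order assembly models: it provides

- a generic mass-action reaction-network engine (integer stoichiometries,
  stiff-capable integration, JSON serialization, conservation checks);
- generic two-component (mA + nB ⇌ AmBn → mA + nB\*) and three-component
  (nB\* + hC ⇌ Bn\*Ch → nB\* + hC\*) assembly models with response-curve
  characterization (amplification, linearity, sensitivity coefficient,
  optimal assembly degree);
- the TNF → RIP1 → RIP3 → MLKL necrosome network (23 elementary reactions,
  configurable RIP3 chain length n ∈ {1..8}, caspase-8 branch with mutual
  inhibition, optional protein turnover);
- R²-based calibration against phosphorylation time courses;
- Latin-Hypercube stochastic ensembles with top-5% selection and
  condition sweeps over TNF dose and RIP3/MLKL expression;
- a synthetic-data generator that emulates densitometry time courses from
  known ground-truth parameterizations.

## The model in brief

Every reaction is elementary mass action: a reaction j with reactant
multiset {X_i : p_ij} proceeds at rate r_j = k_j ∏_i [X_i]^{p_ij}, and
species evolve as d[X_i]/dt = Σ_j ν_ij r_j.  The core necrosome cascade is

    R1:  RIP1* + n·RIP3            ⇌  RIP1*·RIP3_n          (k1, k-1)
    R2:  RIP1*·RIP3_n              →  RIP1* + n·p-RIP3      (κ2)
    R3:  n·p-RIP3 + 2·MLKL         ⇌  p-RIP3_n·MLKL_2       (k3, k-3)
    R4:  p-RIP3_n·MLKL_2           →  n·p-RIP3 + 2·p-MLKL   (κ4)

with the RIP3 chain length n as the central control variable, upstream TNF
receptor engagement supplying active RIP1, and MLKL phosphorylation
efficiency η = [p-MLKL](T)/[MLKL_total] at T = 4 h as the output statistic.
The [RIP3]^n and [p-RIP3]^n association terms make the assembly degree a
genuine control parameter: higher-order recruitment amplifies flux per
binding event but demands higher-order collisions and sequesters more
subunits per complex, so η(n) has an interior optimum.

## Worked example

```python
from necrosim import efficiency_profile, activation_threshold, rip1_titration

# MLKL phosphorylation efficiency versus RIP3 chain length, strong TNF
profile = efficiency_profile()
print({n: round(eta, 3) for n, eta in profile.items()})
print("optimal RIP3:RIP1 =", max(profile, key=profile.get))

# smallest chain length that achieves appreciable RIP3 phosphorylation
print("activation threshold n =", activation_threshold())

# robustness of p-RIP3 to RIP1 knockdown
curve, breakpoint = rip1_titration()
print(f"p-RIP3 collapses below {100 * breakpoint:.0f}% RIP1")
```

prints

```
{1: 0.018, 2: 0.092, 3: 0.159, 4: 0.149, 5: 0.127, 6: 0.109, 7: 0.094, 8: 0.083}
optimal RIP3:RIP1 = 3
activation threshold n = 3
p-RIP3 collapses below 20% RIP1
```

— the efficiency profile peaks at three RIP3 per RIP1 (the necrosome's
measured stoichiometry), at least three RIP3 per RIP1 are needed to switch
RIP3 phosphorylation on, and p-RIP3 stays on a plateau until RIP1 falls to
roughly a fifth of its reference expression.

The command line mirrors the library:

```
necrosim ensemble --n-samples 1000 --seed 1 --tnf 10
necrosim sweep --condition TNF --values 10,20,70 --seed 1
necrosim reproduce fig4g
```

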