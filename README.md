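# halosynergy

Quantitative analysis of **synergistic carboxylate–cation–water
interactions** in halophilic proteins.

Proteins from organisms that live in multimolar KCl are crowded with
surface aspartates and glutamates.  Whether two neighboring acidic
residues repel, as plain electrostatics suggests, or *stabilize each
other* through shared potassium/water networks can be decided
thermodynamically.  This package implements that analysis for
computational biophysicists working with alchemical free-energy and
umbrella-sampling output:

* **Thermodynamic integration** — per-λ ∂V/∂λ time series → leg and total
  mutation free energies ΔG_XaY = ΔG_decharge + ΔG_vdW + ΔG_charge, with
  natural-cubic-spline quadrature and propagated standard errors.
* **The ΔΔG synergy statistic** — for a residue pair (a, b),
  ΔΔG = ΔG(0)_XaY − ΔG(−)_XaY: the cost of neutralizing residue *a* next
  to a neutral versus a charged neighbor.  ΔΔG ≤ −0.5 kcal/mol ⇒
  synergistic, ≥ +0.5 ⇒ interfering, |ΔΔG| < 0.5 ⇒ negligible; the
  statistic decomposes leg-wise into components that sum to it exactly.
* **WHAM** — 1D/2D potentials of mean force from harmonically biased
  umbrella windows (log-space self-consistent iteration, honest
  convergence and overlap diagnostics, bootstrap uncertainties).
* **Distance-resolved synergy** — the combination
  ΔΔG(ξ) = g_DD + g_NN − 2·g_DN of side-chain-mimic PMFs, with the curve
  triple anchored at ξ = 15 Å against the Debye–Hückel screened Coulomb
  interaction of the charged pair.
* **Structural observables** — Shrake–Rupley SASA, selection of
  solvent-exposed acidic pairs (SASA ≥ 50 Å², carboxylate-carbon distance
  < 7 Å), carboxylate distance histograms, and 2D (d, cos θ) histograms
  of water→carboxylate hydrogen-bond geometry.
* **Synthetic generators** — seeded, truth-recording stand-ins for the
  MD stages (noisy ∂V/∂λ with known integrals, Metropolis-sampled
  umbrella windows on known pair potentials, toy structures with waters
  at exact hydrogen-bond geometries), so the whole pipeline is testable
  offline.

Estimators follow a model/results idiom: build
`ThermodynamicIntegration(windows)` or `WHAM(windows)` from data, call
`.fit()`, and read estimates, uncertainties and `summary()` off the
result.

## Worked example

A pair with a built-in synergistic interaction: the decharge leg of the
E41Q mutation is 1 kcal/mol cheaper when the neighboring D38 is charged.

```python
from halosynergy import (DvdlProfile, MutationPair, ThermodynamicIntegration,
                         delta_delta_g, gen_dvdl, mutation_free_energy)

contexts = {}
for j, (state, offset) in enumerate((("charged", 1.0), ("neutral", 0.0))):
    legs = {}
    for i, (leg, coeff) in enumerate((("decharge", (2.0 + offset, 3.0)),
                                      ("vdw", (0.5, 0.0)),
                                      ("charge", (1.0, -2.0)))):
        windows, _ = gen_dvdl(DvdlProfile(leg=leg, coefficients=coeff,
                                          seed=40 + 10 * j + i))
        res = ThermodynamicIntegration(windows, t_eq=0).fit("spline")
        legs[leg] = res.legs[leg]
    contexts[state] = mutation_free_energy(
        legs["decharge"], legs["vdw"], legs["charge"],
        site="E41", neighbor_state=state)

pair = MutationPair(site_a="E41", site_b="D38", protein="protein_L",
                    salt_molality=2.0,
                    g_charged_neighbor=contexts["charged"],
                    g_neutral_neighbor=contexts["neutral"])
result = delta_delta_g(pair)
print(f"ddG = {result.ddg:+.3f} +/- {result.ddg_sem:.3f} kcal/mol -> {result.label}")
for leg, value in result.components.items():
    print(f"  {leg:>9s} component: {value:+.3f} kcal/mol")
```

Output:

```
ddG = -1.007 +/- 0.027 kcal/mol -> synergistic
   decharge component: -1.006 kcal/mol
        vdw component: +0.003 kcal/mol
     charge component: -0.005 kcal/mol
```

The recovered ΔΔG matches the constructed −1 kcal/mol within its
propagated error; the effect sits entirely in the decharge component, the
signature of a solvent-mediated electrostatic interaction between the two
acidic groups, and the pair is classified synergistic under the
±0.5 kcal/mol rule.

## Command line

```sh
halosynergy simulate umbrella --label dd --seed 1 --out scratch/dd
halosynergy wham --manifest scratch/dd/manifest_DD.yaml --out scratch/pmf_dd.csv
halosynergy pmf-synergy --dd pmf_dd.csv --nn pmf_nn.csv --dn pmf_dn.csv \
    --salt-molality 2 --out ddg_xi.csv
halosynergy pair-select --structure protein.pdb --sasa-min 50 --dmax 7 --out pairs.csv
halosynergy run --config pipeline.yaml   # whole alchemical or pmf pipeline
```

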