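# Methods

## The synergy statistic

Halophilic proteins carry unusually many surface aspartates and
glutamates.  Whether two neighboring acidic residues *a* and *b* attract
(via shared potassium/water networks) or repel is decided
thermodynamically: neutralize residue *a* alchemically (D→N or E→Q) twice,
once with the native charged neighbor and once after the neighbor has been
replaced by its neutral analog, and form

ΔΔG = ΔG(0)_XaY − ΔG(−)_XaY.

ΔΔG < 0 means the mutation is harder with the acidic neighbor present — a
synergistic (mutually stabilizing) interaction; ΔΔG > 0 means ordinary
electrostatic interference.  Values with |ΔΔG| < 0.5 kcal/mol are
classified negligible; the boundary value itself belongs to the
significant class, so a pair at exactly −0.5 kcal/mol counts as (weakly)
synergistic.  An opt-in variant additionally requires |ΔΔG| to exceed one
standard error; the plain threshold rule is the default
(`halosynergy.synergy.classify`).

Each mutation free energy is the sum of three alchemical legs — decharge
(remove the charges of X), vdW (morph the uncharged residue), charge
(reinstate the charges of Y) — so ΔΔG decomposes leg-wise into components
that sum to it exactly.  Uncertainties propagate in quadrature throughout;
the two neighbor contexts are independent simulation campaigns, so their
total SEMs combine quadratically.

## Thermodynamic integration

Leg free energies are ΔG = ∫₀¹ ⟨∂V/∂λ⟩ dλ.  The default estimator
interpolates the per-λ means with a **natural cubic spline** (second
derivative zero at λ = 0, 1) and integrates it; a composite trapezoid rule
is available for cross-checking.  Both rules are linear in the ordinates,
so exact quadrature weights exist per grid and the per-λ SEMs propagate
through them in quadrature (windows assumed independent).

Choices and defaults:

* equilibration discard `t_eq` = 1000 ps, overridable per run;
* per-window SEM from 5-block averaging by default; when several
  independent replicate windows exist at the same (leg, λ), the replicate
  spread is used instead and is authoritative;
* a λ-grid missing either endpoint is a hard error — extrapolated
  alchemical endpoints are a classic source of silent bias;
* a single block or replicate yields SEM = NaN with a warning, never a
  silent zero;
* λ schedules are free: the manifest accepts arbitrary ascending grids.

## WHAM

Umbrella windows (harmonic biases ½k(ξ−c)², k in kcal·mol⁻¹·Å⁻²) are
combined by iterating the standard WHAM self-consistency equations to a
fixed point, accumulating in log space to survive strongly biased windows.
Defaults: bin width 0.1 Å (1D) / 0.2 Å (2D), convergence when the largest
per-window offset change is below 10⁻⁷ k_BT, at most 10⁵ iterations,
temperature 298 K.  Unvisited bins stay NaN; the `converged` flag is
honest, and adjacent windows that share no occupied bin trigger a warning,
an entry in the curve's diagnostics and `converged=False`.  No
autocorrelation correction is applied inside WHAM — subsampling stride is
the caller's knob.  Per-bin uncertainties come from an ordinary bootstrap
over windows on a fixed bin grid, aligned at the best-sampled bin.

## Distance-resolved synergy and curve alignment

For side-chain mimic pairs the analog of ΔΔG as a function of separation
is ΔΔG(ξ) = g_DD(ξ) + g_NN(ξ) − 2·g_DN(ξ).  WHAM curves float by
arbitrary constants, so the triple is anchored first: D-N and N-N are
zeroed at ξ_ref = 15 Å (where dipolar interactions are negligible), and
D-D is offset from N-N at ξ_ref by the analytic Coulomb interaction of two
point charges.  That anchor uses **Debye–Hückel screened** electrostatics,

U(r) = 332.0637·z₁z₂/(ε_r·r)·exp(−κr),

with ε_r = 78.4 and κ from the ionic strength at the stated temperature
(κ⁻¹ ≈ 2.15 Å at 2 mol/dm³, 298 K); an unscreened mode is exposed because
at 15 Å and high salt both conventions shift the curve by well under
10⁻³ kcal/mol, and some analyses quote the bare Coulomb value.  Salt
molality converts to ionic strength assuming solution density
1 kg/dm³ — adequate at the near-zero interaction energies involved.  The
water-model permittivity (~82 for common 3-site models) versus the
experimental 78.4 is a genuine ambiguity; 78.4 is the default and the
parameter is configurable.  Alignment evaluates the *bin containing*
ξ_ref rather than interpolating, to avoid inventing smoothness at curve
tails.

The PMFs exclude the ideal-gas radial term −2k_BT·ln ξ; `jacobian_term`
adds or removes it explicitly and records the state.

## Structural observables

* **SASA** — Shrake–Rupley with Bondi radii, probe 1.4 Å and a
  deterministic 960-point golden-spiral point set per atom, summed per
  residue.  Determinism makes the value reproducible bit-for-bit;
  accuracy is limited only by the point count (isolated atoms are exact
  by construction).  SASA ignores periodic images (solutes are assumed
  centered); all distance observables apply the orthorhombic
  minimum-image convention whenever a box is present.
* **Pair selection** — acidic residues with SASA ≥ 50 Å² whose
  carboxylate carbons (CG for Asp, CD for Glu) are closer than 7 Å in the
  reference frame, each unordered pair reported once.
* **Hydrogen-bond geometry** — for every water hydrogen, the nearest
  carboxylate oxygen is paired (both oxygens eligible); an event is
  recorded when the heavy-atom distance d = |O_w−O_c| is within 3.5 Å
  *and* the hydrogen is closer to the acceptor than its own oxygen is
  (i.e., it actually points at the acceptor).  θ is measured **at the
  hydrogen** between H→O_w and H→O_c, so a linear bond gives cos θ = −1.
  This angle convention is a package choice (documented here prominently
  because other conventions exist); it is configurable through the
  recorded axes and the generator.  Default bins: 0.05 Å × 0.05 (cos θ)
  for the 2D maps, 0.25 Å for 1D distance histograms.

## Synthetic data

The generators replace cluster-scale MD and define the package's test
conditions:

* `gen_dvdl` — AR(1) Gaussian noise (default sd 0.5 kcal/mol, lag-1
  coefficient 0.8, 2000 samples/window at 1 ps, 11-point λ-grid) around a
  polynomial mean with closed-form integral.  The autocorrelation is there
  so block averaging is actually exercised; blocks of 400 samples dwarf
  the ~5-sample correlation time.
* `gen_umbrella` — Metropolis sampling of ξ under a mimic potential plus
  bias, all windows advanced as one vectorized chain.  Default schedule:
  centers 3–16 Å every 0.5 Å, k = 10 kcal·mol⁻¹·Å⁻² (window width
  √(k_BT/k) ≈ 0.24 Å, giving healthy adjacent-window overlap at 298 K),
  5·10⁴ steps/window, Gaussian proposals of 0.3 Å.  Sampling is plain 1D —
  the ξ² Jacobian is deliberately absent, matching the PMF convention
  above.  Acceptance rates are logged and near-zero acceptance is an
  error.
* mimic potentials — screened Coulomb between the group charge centers
  (−1/−1, 0/0, −1/0 for DD/NN/DN) plus a 12-6 well (depth 0.5 kcal/mol,
  contact 4.5 Å) reproducing the short-range attractive contact of real
  side-chain mimics.  With identical short-range terms across the triple,
  the analytic ΔΔG(ξ) reduces exactly to the DD screened-Coulomb
  repulsion — nonnegative everywhere, which is the behavior expected of
  the two-body system.
* `gen_toy_structures` / `gen_hbond_frames` — minimal Asp-like residues
  (stub backbone + CG/OD1/OD2) and rigid waters placed at exact
  (d, cos θ); the non-donating hydrogen is oriented away from the
  acceptor so generator truth and counted events agree one-to-one.

Every generator is bit-reproducible for a fixed seed and writes a
machine-readable truth record next to its data files.

What the generators do **not** emulate: explicit solvent and ions,
force-field detail, conformational coupling between residues, and
correlated errors across λ-windows.  Tests passing on synthetic data
therefore validate the estimators and their error models, not force-field
accuracy on real proteins.

## The bundled ΔΔG compilation

`halosynergy.datasets.ddg_compilation()` ships a **synthetic** per-pair
table (see the CSV header) constructed to satisfy the published summary
constraints for the three halophilic proteins: 18 folded pairs at
2 mol/kg KCl with 5 synergistic, 3 fully shielded and 10 interfering;
one weakly synergistic site (−0.5 kcal/mol) at 0.15 mol/kg; synergistic
magnitudes in −0.5…−2 kcal/mol; overall range −3…+3; synergy most
frequent in protein L; an unfolded protein-L set that is almost entirely
synergistic.  Individual values are constructed, not simulated — the
table exists to exercise classification and summary machinery end to end.

## Problem sizes and numerical tolerances

The repetition study uses 100 seeds; WHAM oracles use 5×10⁴ Metropolis
steps per window; hydrogen-bond recovery uses 400 placed waters; the
pair-selection property check uses 100 random toy structures.  At these
sizes the observed accuracies are ~0.05 kcal/mol RMS for the harmonic
WHAM oracle and ~0.05–0.11 kcal/mol RMS for the end-to-end ΔΔG(ξ)
recovery, with 2×SEM coverage of the TI estimator at ~95 %.

## Known limitations

* WHAM assumes decorrelated samples; heavily autocorrelated input will
  understate bootstrap uncertainties.
* The three-body (2D reaction coordinate) machinery stops at the 2D PMF
  and its marginals; no three-body synergy statistic is defined.
* The SASA implementation targets desk-scale structures (thousands of
  atoms); it is O(n·m) in atoms × sphere points.
* Alignment at a bin (not an interpolated point) quantizes the reference
  by up to half a bin width; with the 0.1 Å default this is negligible
  against sampling noise.
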