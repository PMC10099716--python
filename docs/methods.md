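# Methods

## Scope and model

The package treats two linked questions about a homodimeric
DNA/lamin-binding protein and its Gly16Arg variant: (i) how restricted is
the conformational ensemble of the N-terminal arm (residues 1–12, with the
transient helix α1 at 5–12), and (ii) what does that restriction do to the
binding thermodynamics. The ensemble side consumes trajectories (real or
synthetic); the thermodynamics side consumes integrated ITC heats (real or
simulated). Neither side depends on the other at run time; the pipeline
merely sequences them.

## Superposition and region RMSD

Frames are rigid-body fitted on the reference structure by minimizing the
Cα RMSD of the core — by default the last four HELIX-annotated helices of
the chain, standing for the stable α3–α6 bundle (the exact residue spans
are a property of the input structure's annotations, not hard-coded).
Weights are unit by default, since the quantity minimized is a plain Cα
RMSD; mass weighting is available but off. The Kabsch SVD solution is used
with the reflection branch corrected; degenerate inputs (fewer than three
pairs, collinear sets) are rejected rather than silently pseudo-solved.

Region RMSD is evaluated after the core fit **without re-fitting** on the
region, so it measures arm displacement relative to the rigidly held core.
Chains are superposed and evaluated independently and pooled, so a
symmetric dimer contributes two monomer samples per frame; per-chain
output is available by calling `region_rmsd_series` directly. A
configurable leading fraction of frames (default 2%) is dropped as
equilibration.

Distributions are density-normalized histograms (default bin 0.1 Å) with
the median reported. Modes come from a Gaussian KDE with Silverman
bandwidth; local maxima with prominence below 10% of the peak density are
discarded. These are deterministic stand-ins for reading peaks off a
plotted histogram; both thresholds are arguments.

## Salt bridges

A bridge is scored formed at donor-N–acceptor-O distance ≤ 4.0 Å, the
conventional structural criterion (the underlying study states none). The
default group distance is the minimum over donor × acceptor atom pairs,
which is robust to the two-fold symmetry of a guanidinium group; centroid
distance is available, and the chosen method is logged and recorded on the
trace because the convention used in the original distance plots is not
documented. "Stable" is reported at occupancy ≥ 0.9. Both chain orderings
of the symmetric dimer are traced independently.

## Quasi-harmonic entropy

The mass-weighted covariance σᵢⱼ = √(mᵢmⱼ)⟨ΔxᵢΔxⱼ⟩ is built from frames
already superposed on the reference core (superposition is a precondition,
not a side effect, so the caller controls which fit removed rigid-body
motion). Each eigenvalue λ (amu·Å²) defines a mode frequency
ω = √(k_BT/λ) and the entropy is the quantum harmonic-oscillator sum in
cal·mol⁻¹·K⁻¹ via R. Eigenvalues at or below a floor of 1e-8 amu·Å² are
discarded and counted — these are the ~6 near-null rigid-body modes plus
numerical noise — and the discarded count is always reported. Temperature
defaults to 310 K, the thermostat setting of the simulations the analysis
is designed for. Constants are CODATA-2018 and echoed in every summary.
Convergence is assessed by recomputing S on growing frame prefixes; the
converged flag requires the last two checkpoints to agree within 1%
relative. The series is monotone only in expectation; sampling noise may
produce small dips, which is why the flag uses the final pair rather than
global monotonicity.

## One-set-of-sites ITC model

Bound complex concentration is the exact quadratic root of the 1:n
equilibrium at post-injection totals. Displacement bookkeeping: each dV
injection into the constant-volume cell (default 1.4 mL, the nominal
VP-ITC cell — the instrument's effective volume is calibration-specific
and configurable) multiplies both totals by (1 − dV/V₀) before fresh
titrant is added. The measured heat is the change in cell heat content
Q = V₀·ΔH·[MX] plus the standard half-step term
(dV/V₀)·(Qᵢ+Qᵢ₋₁)/2 for material expelled mid-injection, plus a constant
per-injection dilution offset. Commercial packages implement closely
related but not identically documented corrections; this one is stated
here formulaically so fits are reproducible.

Fitting is `scipy.optimize.least_squares` (TRF, bounded) over
(log₁₀ Kd, ΔH, n, offset), with n fixable — 0.5 encodes one ligand per
dimer with the cell concentration counted in monomer units — and
multi-starts over Kd decades from 1 pM to 1 mM; the lowest-cost local
optimum wins. Heats marked NaN (the optional first-injection discard,
which is universal ITC practice though not part of the underlying study's
stated processing) stay in the concentration bookkeeping but leave the
residuals. Flat isotherms raise an unidentifiability error instead of
returning a boundary Kd; c-values outside 1–1000 log a warning.
ΔG = RT ln Kd (R = 1.98720425×10⁻³ kcal·mol⁻¹·K⁻¹, natural log, 1 M
standard state); the entropic penalty is −TΔS = ΔG − ΔH, and every fit
satisfies |ΔG − ΔH − (−TΔS)| < 10⁻⁶ kcal/mol by construction. Energies
are per mole of injectant, the convention of the standard instrument
software. Fold changes report Kd(ref)/Kd(alt) plus the nearest integer
fold (of the inverse when the ratio is below 1).

A design note on identifiability: a 29 × 10 µL program of 33 µM titrant
into a 10 µM cell crosses the equivalence point only if the stoichiometry
is below ~0.75 sites per cell molecule. Noiseless round trips recover Kd
regardless (the partial curve still pins the model exactly), but noisy
recovery of a nanomolar Kd requires the step region to be sampled, which
is why the stochastic-recovery validation uses n = 0.3 — several protein
copies per 22-bp duplex, the regime in which such a titration design is
informative.

## Synthetic ensembles

The generator emulates the *statistics* the analyses consume, not protein
geometry. A toy dimer places one Cα per residue on an ideal helical trace
(1.5 Å rise, 100° twist), two antiparallel chains 11 Å apart, with proxy
guanidinium nitrogens on residue 16 and carboxylate oxygens on the
C-terminal residue; HELIX annotations mirror a six-helix monomer so the
default core selection works unchanged.

Frames are i.i.d. draws: core atoms get isotropic Gaussian jitter
(default σ = 0.3 Å); per frame and chain a basin is drawn from the mixture
weights and the residues-5–12 block is rigidly translated along a random
unit direction by a distance ~N(center, σ_basin) clipped at zero — a rigid
translation of the block equals its region RMSD when the core is aligned,
and the analysis code re-measures it rather than trusting the
construction. Residues 1–4 get independent large displacements
(|N(6.0, 1.5)| Å plus per-atom scatter) in **every** regime, emulating
termini that stay disordered in all variants. Defaults encode the study
conditions: 6000 frames, basin centers 3.0/5.0 Å with equal weights for
the open regime (the equal split is a generator default; the underlying
bimodal observation does not quantify occupancies), a single 3.0 Å basin
for the restricted regime, σ_basin = 0.4 Å (read off the width of the
reported distributions), and a 2.0 Å basin for the phosphorylated-like
closed regime. When a bridge is enforced, the donor group is placed at
target + truncated-Gaussian noise (±2.5σ, so held frames provably stay
within target + 3·jitter) from the acceptor centroid with the configured
hold probability, per ordering.

Because frames are independent, the generator does not emulate kinetics,
autocorrelation, anisotropic collective motions, force-field energetics or
solvent effects. Passing tests therefore demonstrate that the analysis
chain recovers known distributional structure — basin locations, weights,
occupancies, covariance spectra — from trajectory-shaped data; they do not
validate conclusions about real MD force fields or sampling.

## Numerical choices and edge cases

- Kabsch collinearity is detected from the singular-value spectrum
  (second value below 1e-10 of the first).
- KDE mode search pads the grid by 4 bandwidths; a monotone density
  (e.g. a half-Gaussian against zero) falls back to the density argmax so
  a mode is always reported for non-degenerate input.
- Near-constant RMSD samples (range below one bin) short-circuit to a
  single-bin distribution to keep histogramming well-posed.
- Covariance uses the population normalization (1/F); at the frame counts
  involved the 1/(F−1) difference is far below the 2% entropy-recovery
  tolerance.
- Fit tolerances are 1e-13 with any finite-cost local optimum accepted as
  a candidate, because with noisy heats the tight tolerances hit the
  iteration cap before scipy's formal success flag.
- The acceptance script runs the two Kd round trips at the study's
  schedules and the two 6000-frame ensembles; everything completes in
  seconds on one CPU, and test-suite ensembles use 150–6000 frames chosen
  per test as the smallest size that exercises the statistic.

## Known limitations

- The toy dimer's reference bridge distance (~24 Å) means enforced-bridge
  frames teleport the donor proxy rather than bending the arm; occupancy
  statistics are exercised, arm–bridge coupling is not.
- The two-state NMR projection is a geometric descriptor in scaled
  (¹H, ¹⁵N/0.14) shift space; it deliberately fits no exchange model, and
  its fraction is invariant under uniform, not anisotropic, rescaling.
- Multi-model PDB parsing takes the topology from the first model and
  checks only atom counts (not atom identity) across frames.
- The entropy implementation is the mass-weighted Cartesian quasi-harmonic
  variant only; Schlitter's formula and anharmonic corrections are out of
  scope.
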