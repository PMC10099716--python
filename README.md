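# bafdyn

Analysis toolkit for studying how a point mutation reshapes the
conformational ensemble and binding thermodynamics of barrier-to-
autointegration factor (BAF), a small homodimeric protein that tethers
chromatin to the nuclear lamina by binding dsDNA and the lamin A/C IgFold
domain. The disease variant Gly16Arg introduces an inter-monomer salt
bridge (Arg16 guanidinium to the partner chain's Leu89 C-terminal
carboxylate) that pre-orders the flexible N-terminal arm carrying the
transient helix α1 (residues 5–12); the package quantifies both the
ensemble restriction and its thermodynamic consequence — a reduced entropic
penalty of DNA binding.

It is aimed at structural biologists and molecular modellers who have (or
simulate) dimer trajectories and ITC titrations and want the full analysis
chain as tested, scriptable components rather than instrument-vendor or
in-house one-offs.

## What it computes

**Ensemble side** (per trajectory frame, per monomer):

- Kabsch least-squares superposition on the rigid four-helix core
  (α3–α6), minimizing the Cα RMSD;
- region RMSD distributions for the N-terminal arm (residues 1–12, 1–4,
  5–12) in density mode with medians and KDE-detected modes — an open
  (wild-type-like) arm is bimodal with peaks near 3.0 and 5.0 Å, a
  restricted (Gly16Arg-like) arm unimodal near 3.0 Å;
- salt-bridge traces: min donor-N/acceptor-O distance per frame, occupancy
  at a 4.0 Å cutoff, for both chain orderings of the symmetric dimer;
- quasi-harmonic configurational entropy: eigenvalues λᵢ of the
  mass-weighted covariance of superposed fluctuations define mode
  frequencies ωᵢ = √(k_B T / λᵢ), and

  S = R Σᵢ [ uᵢ/(e^{uᵢ}−1) − ln(1−e^{−uᵢ}) ],  uᵢ = ħωᵢ/(k_B T),

  with a convergence-versus-sampling series as the completeness check.

**Thermodynamics side** (one-set-of-sites ITC):

- isotherm simulation with exact quadratic bound-fraction solution and
  perfusion-cell displacement/half-step heat corrections;
- nonlinear least-squares fitting (multi-start in log Kd) with optional
  fixed stoichiometry (n = 0.5 encodes one IgFold per BAF dimer counted in
  monomer units);
- ΔG = RT ln Kd, the entropic penalty −TΔS = ΔG − ΔH, and affinity fold
  changes between variants.

A synthetic-ensemble generator (`build_toy_dimer`, `sample_ensemble`)
produces dimer trajectories with prescribed basin structure, core jitter
and enforced bridges, standing in for microsecond MD so every stage is
testable at desk scale.

## Worked example

```python
>>> import bafdyn as b
>>> # thermodynamic decomposition from measured dissociation constants
>>> dg_wt  = b.gibbs_from_kd(117e-9, 288.0)    # wild type vs dsDNA
>>> dg_var = b.gibbs_from_kd(16.3e-9, 288.0)   # Gly16Arg vs dsDNA
>>> round(dg_wt, 2), round(dg_var, 2)
(-9.13, -10.26)
>>> round(b.decompose(dg_wt, -49.5), 2)        # -TdS, wild type
40.37
>>> round(b.decompose(dg_var, -18.1), 2)       # -TdS, variant
7.84
>>> b.affinity_fold_change(117e-9, 16.3e-9)
(7.177914110429448, 7)
```

The variant pays a 7.8 kcal/mol entropic penalty to bind DNA where the
wild type pays 40.4: its pre-ordered arm costs far less entropy to clamp
onto DNA, and despite a much smaller binding enthalpy it ends up binding
sevenfold tighter.

```python
>>> from bafdyn.synthetic import core_ranges
>>> ref = b.build_toy_dimer(89)
>>> traj = b.sample_ensemble(ref, b.open_recipe(n_frames=6000, seed=1))
>>> vals = b.pooled_monomer_rmsd(traj, ref, core_ranges(ref), (5, 12))
>>> dist = b.make_distribution(vals)
>>> [round(loc, 2) for loc, height in dist.modes]
[3.02, 5.02]
```

The open-mode ensemble's helix-α1 RMSD distribution shows the two basins
at 3.0 and 5.0 Å; the restricted recipe gives a single mode at 3.0 Å and a
salt-bridge occupancy of 1.0.

A `bafdyn` console script exposes the same stages
(`generate`, `rmsd`, `bridge`, `entropy`, `itc simulate|fit`, `noe`,
`run`); `bafdyn run --seed 0 --out outdir` executes the whole pipeline and
writes a JSON report with the qualitative contrast checks.

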