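"""Synthetic dimer ensembles with the statistical structure of the BAF study.

The generator does not attempt atomistic realism.  It builds a toy two-chain
dimer whose residues sit on an idealized helical trace, then draws i.i.d.
frames in which:

* core atoms (residues 13 onward) jitter isotropically about the reference,
* the helix-alpha-1 arm (residues 5-12) is displaced rigidly so that its
  realized core-superposed RMSD is Gaussian about a basin center — one basin
  for a "restricted" (Gly16Arg-like) ensemble, two for an "open"
  (wild-type-like) one,
* the extreme N-terminus (residues 1-4) receives large displacements in every
  mode, emulating termini that stay highly flexible in all variants,
* optionally, a donor proxy atom on residue 16 of one chain is pinned near
  the C-terminal acceptor proxy of the other chain, emulating the
  Arg16-Leu89 inter-monomer salt bridge.

Frames are independent draws rather than autocorrelated dynamics: every
downstream statistic here (histograms, medians, occupancies, quasi-harmonic
entropy) is distributional, so temporal correlation is unnecessary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .structures import (
    AtomRecord,
    StructureModel,
    TrajectoryEnsemble,
    element_mass,
    select_atoms,
    select_calpha,
    RegionSpec,
)

#: Residue ranges of the toy dimer's helices; the last four are the rigid core.
TOY_HELICES: tuple[tuple[int, int], ...] = ((5, 12), (14, 22), (25, 39), (42, 54), (57, 69), (72, 86))
#: Flexible-arm region definitions shared with the analysis stages.
NTERM_RANGE = (1, 12)
NTERM_TIP_RANGE = (1, 4)
HELIX1_RANGE = (5, 12)
DONOR_RESIDUE = 16
DONOR_ATOMS = ("NH1", "NH2")  # guanidinium-nitrogen proxies
ACCEPTOR_ATOMS = ("O", "OXT")  # C-terminal carboxylate-oxygen proxies


class RecipeError(ValueError):
    pass


@dataclass(frozen=True)
class SaltBridgePair:
    """Donor and acceptor atom groups, each (chain, residue number, atom names)."""

    donor: tuple[str, int, tuple[str, ...]]
    acceptor: tuple[str, int, tuple[str, ...]]

    def __post_init__(self) -> None:
        if self.donor[0] == self.acceptor[0]:
            raise ValueError("inter-monomer bridge requires donor and acceptor on different chains")

    def swapped(self) -> "SaltBridgePair":
        """The mirror-image bridge (other chain ordering of a symmetric dimer)."""
        d_chain, d_res, d_names = self.donor
        a_chain, a_res, a_names = self.acceptor
        return SaltBridgePair((a_chain, d_res, d_names), (d_chain, a_res, a_names))


def arg16_leu89_bridge(donor_chain: str = "A", acceptor_chain: str = "B", c_terminal_residue: int = 89) -> SaltBridgePair:
    """The inter-monomer Arg16 guanidinium to Leu89 C-terminal carboxylate pair."""
    return SaltBridgePair(
        donor=(donor_chain, DONOR_RESIDUE, DONOR_ATOMS),
        acceptor=(acceptor_chain, c_terminal_residue, ACCEPTOR_ATOMS),
    )


@dataclass
class EnsembleRecipe:
    """Everything needed to draw a reproducible synthetic ensemble.

    ``basin_centers`` are target region-RMSD values (Å) for residues 5-12
    after core superposition; ``basin_weights`` their mixture probabilities;
    ``basin_width`` the Gaussian sigma of the realized RMSD about its basin
    center.  ``mode`` is a label only ("open", "restricted", "closed"); the
    basins define the statistics.
    """

    mode: str = "open"
    n_frames: int = 6000
    basin_centers: tuple[float, ...] = (3.0, 5.0)
    basin_weights: tuple[float, ...] = (0.5, 0.5)
    basin_width: float = 0.4
    salt_bridge: SaltBridgePair | None = None
    bridge_target: float = 3.0
    bridge_hold_probability: float = 1.0
    bridge_jitter: float = 0.1
    core_jitter: float = 0.3
    tip_center: float = 6.0
    tip_width: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise RecipeError("n_frames must be >= 1")
        if len(self.basin_centers) != len(self.basin_weights):
            raise RecipeError("basin_centers and basin_weights length mismatch")
        if any(c < 0 for c in self.basin_centers):
            raise RecipeError("basin centers must be non-negative RMSD targets")
        if abs(sum(self.basin_weights) - 1.0) > 1e-9 or any(w < 0 for w in self.basin_weights):
            raise RecipeError("basin_weights must be non-negative and sum to 1")
        if self.basin_width < 0 or self.core_jitter < 0:
            raise RecipeError("widths must be non-negative")


def open_recipe(**overrides) -> EnsembleRecipe:
    """Wild-type-like ensemble: arm RMSD bimodal at 3.0 and 5.0 Å, no bridge."""
    return EnsembleRecipe(
        mode="open", basin_centers=(3.0, 5.0), basin_weights=(0.5, 0.5), **overrides
    )


def restricted_recipe(with_bridge: bool = True, **overrides) -> EnsembleRecipe:
    """Gly16Arg-like ensemble: unimodal arm at 3.0 Å, inter-chain bridge held."""
    bridge = arg16_leu89_bridge() if with_bridge else None
    return EnsembleRecipe(
        mode="restricted",
        basin_centers=(3.0,),
        basin_weights=(1.0,),
        salt_bridge=bridge,
        **overrides,
    )


def closed_recipe(**overrides) -> EnsembleRecipe:
    """Di-phosphorylated-like ensemble: arm pinned tighter, around 2.0 Å."""
    return EnsembleRecipe(mode="closed", basin_centers=(2.0,), basin_weights=(1.0,), **overrides)


def build_toy_dimer(residues_per_chain: int = 89) -> StructureModel:
    """Idealized two-chain dimer with per-residue C-alpha plus proxy atoms.

    Each chain traces an alpha-helical spiral (1.5 Å rise, 100 deg twist per
    residue); the chains run antiparallel, offset by ~11 Å, which places the
    residue-16 donor proxy of each chain within reach of the other chain's
    C-terminal acceptor proxy.  Residue 16 carries two guanidinium-nitrogen
    proxies, the terminal residue a backbone O and a terminal OXT.  HELIX
    annotations mirror a six-helix monomer so the default core selection
    (last four helices) works unchanged.
    """
    if residues_per_chain < 16:
        raise RecipeError(
            f"residues_per_chain must be >= 16 (got {residues_per_chain}): the dimer must "
            "contain residue 16 and a C-terminal residue"
        )
    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    rise, twist, radius = 1.5, np.deg2rad(100.0), 2.3
    for chain, offset in (("A", 0.0), ("B", 11.0)):
        for resnum in range(1, residues_per_chain + 1):
            theta = twist * resnum
            # chains run antiparallel over the same z span, keeping the dimer compact
            z_index = resnum if chain == "A" else residues_per_chain + 1 - resnum
            ca = np.array(
                [
                    radius * np.cos(theta) + offset,
                    radius * np.sin(theta),
                    rise * z_index,
                ]
            )
            resname = "ARG" if resnum == DONOR_RESIDUE else ("LEU" if resnum == residues_per_chain else "ALA")
            atoms.append(AtomRecord("CA", resname, resnum, chain, element_mass("C"), "C"))
            coords.append(ca)
            if resnum == DONOR_RESIDUE:
                # side-chain proxies point toward the partner chain
                toward_partner = 2.0 if chain == "A" else -2.0
                for k, name in enumerate(DONOR_ATOMS):
                    atoms.append(AtomRecord(name, resname, resnum, chain, element_mass("N"), "N"))
                    coords.append(ca + np.array([toward_partner, 0.8 * k, 0.0]))
            if resnum == residues_per_chain:
                for k, name in enumerate(ACCEPTOR_ATOMS):
                    atoms.append(AtomRecord(name, resname, resnum, chain, element_mass("O"), "O"))
                    coords.append(ca + np.array([0.0, 1.2 * (k + 1), 0.0]))
    helices = [
        (chain, start, min(end, residues_per_chain))
        for chain in ("A", "B")
        for start, end in TOY_HELICES
        if start <= residues_per_chain
    ]
    return StructureModel(atoms, np.array(coords), helices)


def _arm_indices(ref: StructureModel, chain: str) -> tuple[np.ndarray, np.ndarray]:
    """All-atom index arrays for the flexible arm: (residues 5-12, residues 1-4)."""
    helix1 = np.array(
        [
            i
            for i, a in enumerate(ref.atoms)
            if a.chain_id == chain and HELIX1_RANGE[0] <= a.residue_number <= HELIX1_RANGE[1]
        ]
    )
    tip = np.array(
        [
            i
            for i, a in enumerate(ref.atoms)
            if a.chain_id == chain and NTERM_TIP_RANGE[0] <= a.residue_number <= NTERM_TIP_RANGE[1]
        ]
    )
    return helix1, tip


def sample_ensemble(ref: StructureModel, recipe: EnsembleRecipe) -> TrajectoryEnsemble:
    """Draw a reproducible trajectory realizing the recipe's statistics.

    Core atoms get isotropic Gaussian jitter (sigma ``core_jitter``).  For
    each frame and each chain a basin is drawn from ``basin_weights`` and the
    residues-5-12 block is rigidly translated along a random unit vector by a
    distance drawn N(center, basin_width) (clipped at zero), which by
    construction equals the block's RMSD from the reference when the core is
    aligned; the analysis stages re-measure it rather than trusting the
    construction.  Residues 1-4 get independent, larger displacements in
    every mode.  When a salt bridge is set, the donor proxy group is placed
    at ``bridge_target`` (Å, plus jitter) from the acceptor group with
    probability ``bridge_hold_probability`` — both chain orderings of the
    symmetric dimer are constrained.
    """
    rng = np.random.default_rng(recipe.seed)
    chains = ref.chains()
    n_atoms = ref.n_atoms
    centers = np.asarray(recipe.basin_centers)
    weights = np.asarray(recipe.basin_weights)

    arm = {c: _arm_indices(ref, c) for c in chains}
    arm_all = np.concatenate([np.concatenate(v) for v in arm.values()]) if chains else np.array([], int)
    core_mask = np.ones(n_atoms, dtype=bool)
    core_mask[arm_all] = False

    bridges: list[tuple[np.ndarray, np.ndarray]] = []
    if recipe.salt_bridge is not None:
        for pair in (recipe.salt_bridge, recipe.salt_bridge.swapped()):
            d_chain, d_res, d_names = pair.donor
            a_chain, a_res, a_names = pair.acceptor
            bridges.append(
                (
                    select_atoms(ref, d_chain, d_res, d_names),
                    select_atoms(ref, a_chain, a_res, a_names),
                )
            )

    frames = np.empty((recipe.n_frames, n_atoms, 3))
    for k in range(recipe.n_frames):
        frame = ref.coords.copy()
        if recipe.core_jitter > 0:
            frame[core_mask] += rng.normal(0.0, recipe.core_jitter, (int(core_mask.sum()), 3))
        for chain in chains:
            helix1, tip = arm[chain]
            basin = rng.choice(len(centers), p=weights)
            dist = max(0.0, rng.normal(centers[basin], recipe.basin_width))
            frame[helix1] += dist * _random_unit(rng)
            tip_dist = abs(rng.normal(recipe.tip_center, recipe.tip_width))
            frame[tip] += tip_dist * _random_unit(rng)
            # extra per-atom scatter keeps the 1-4 tip visibly disordered
            frame[tip] += rng.normal(0.0, recipe.tip_width / 2, (len(tip), 3))
        for donor_idx, acceptor_idx in bridges:
            if rng.random() <= recipe.bridge_hold_probability:
                acc_centroid = frame[acceptor_idx].mean(axis=0)
                direction = _random_unit(rng)
                # noise truncated at 2.5 sigma so held frames never stray past
                # target + 3*jitter even in the far tail
                noise = float(
                    np.clip(
                        rng.normal(0.0, recipe.bridge_jitter),
                        -2.5 * recipe.bridge_jitter,
                        2.5 * recipe.bridge_jitter,
                    )
                )
                d = abs(recipe.bridge_target + noise)
                anchor = acc_centroid + d * direction
                group = frame[donor_idx]
                frame[donor_idx] = group - group.mean(axis=0) + anchor
        frames[k] = frame
    return TrajectoryEnsemble(ref.with_coords(ref.coords), frames)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def core_ranges(ref: StructureModel, chain: str = "A") -> list[tuple[int, int]]:
    """Residue ranges of the last four annotated helices of ``chain``."""
    chain_helices = [h for h in ref.helices if h[0] == chain]
    return [(h[1], h[2]) for h in chain_helices[-4:]]
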