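"""Structure and trajectory data model with PDB / XYZ readers and writers.

The analyte throughout this package is a two-chain protein dimer, so every
residue reference is chain-qualified and residue numbering is 1-based and
inclusive, following PDB conventions.  Trajectories are plain-text only:
multi-model PDB or whitespace-delimited XYZ frame streams (one block per
frame: atom-count line, comment line, then ``element x y z`` rows).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger("bafdyn")

# Atomic masses (amu) for the elements that occur in protein heavy-atom and
# toy-model structures.  Unknown elements fall back to carbon with a warning;
# masses only influence the quasi-harmonic entropy stage.
ELEMENT_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "SE": 78.971,
    "FE": 55.845,
    "ZN": 65.38,
    "MG": 24.305,
}
DEFAULT_MASS = 12.0


class PDBParseError(ValueError):
    """Malformed record in a PDB or XYZ file (message carries the line number)."""


class StructureError(ValueError):
    """Structurally inconsistent input (empty structure, ragged frames...)."""


class SelectionError(KeyError):
    """A region or atom-group selection resolved to nothing."""


def element_mass(element: str) -> float:
    key = element.strip().upper()
    if key in ELEMENT_MASSES:
        return ELEMENT_MASSES[key]
    logger.warning("unknown element %r: assigning default mass %.1f amu", element, DEFAULT_MASS)
    return DEFAULT_MASS


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the shared topology table."""

    atom_name: str
    residue_name: str
    residue_number: int
    chain_id: str
    mass: float
    element: str

    def __post_init__(self) -> None:
        if self.residue_number < 1:
            raise ValueError(f"residue_number must be >= 1, got {self.residue_number}")
        if self.mass <= 0:
            raise ValueError(f"mass must be positive, got {self.mass}")


@dataclass
class StructureModel:
    """Atoms plus one set of Cartesian coordinates in Angstrom.

    ``helices`` holds (chain_id, start_residue, end_residue) triples taken
    from HELIX records when the structure was read from a PDB file; they feed
    the default core-superposition selection.
    """

    atoms: list[AtomRecord]
    coords: np.ndarray
    helices: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.atoms), 3):
            raise StructureError(
                f"coords shape {self.coords.shape} does not match {len(self.atoms)} atoms"
            )
        if len(self.atoms) and not np.isfinite(self.coords).all():
            raise StructureError("non-finite coordinates in structure")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def with_coords(self, coords: np.ndarray) -> "StructureModel":
        return StructureModel(self.atoms, np.asarray(coords, dtype=float), list(self.helices))


@dataclass
class TrajectoryEnsemble:
    """Ordered coordinate frames sharing one topology.

    ``frame_times`` (ns) is optional; when present it must be strictly
    increasing.
    """

    topology: StructureModel
    frames: np.ndarray
    frame_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1:] != (self.topology.n_atoms, 3):
            raise StructureError(
                f"frames shape {self.frames.shape} incompatible with "
                f"{self.topology.n_atoms}-atom topology"
            )
        if self.frame_times is not None:
            self.frame_times = np.asarray(self.frame_times, dtype=float)
            if len(self.frame_times) != len(self.frames):
                raise StructureError("frame_times length does not match frame count")
            if np.any(np.diff(self.frame_times) <= 0):
                raise StructureError("frame_times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def __len__(self) -> int:
        return self.n_frames


@dataclass(frozen=True)
class RegionSpec:
    """A chain-qualified inclusive residue range, e.g. helix alpha-1 = (A, 5, 12)."""

    name: str
    chain_id: str
    residue_range: tuple[int, int]

    def __post_init__(self) -> None:
        start, end = self.residue_range
        if start > end:
            raise ValueError(f"region {self.name}: start {start} > end {end}")

    def on_chain(self, chain_id: str) -> "RegionSpec":
        return replace(self, chain_id=chain_id)


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int) -> tuple[AtomRecord, np.ndarray]:
    try:
        atom_name = line[12:16].strip()
        residue_name = line[17:20].strip()
        chain_id = line[21].strip() or " "
        residue_number = int(line[22:26])
        xyz = np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])])
        element = line[76:78].strip() if len(line) >= 77 else ""
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"malformed ATOM record at line {lineno}: {exc}") from exc
    if not element:
        # wwPDB element column absent: fall back to the leading letter of the name
        element = atom_name.lstrip("0123456789")[:1]
    record = AtomRecord(
        atom_name=atom_name,
        residue_name=residue_name,
        residue_number=residue_number,
        chain_id=chain_id,
        mass=element_mass(element),
        element=element,
    )
    return record, xyz


def read_pdb(path: str | Path) -> StructureModel:
    """Read a single-model PDB file (first MODEL if several are present).

    ATOM and HETATM records populate the atom table in file order; HELIX
    records populate ``helices``.  Malformed coordinate fields raise
    :class:`PDBParseError` naming the offending line.
    """
    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    helices: list[tuple[str, int, int]] = []
    in_model = 0
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        rec = line[:6]
        if rec == "MODEL ":
            in_model += 1
            if in_model > 1:
                break
        elif rec == "HELIX ":
            try:
                helices.append((line[19].strip(), int(line[21:25]), int(line[33:37])))
            except (ValueError, IndexError) as exc:
                raise PDBParseError(f"malformed HELIX record at line {lineno}: {exc}") from exc
        elif rec in ("ATOM  ", "HETATM"):
            record, xyz = _parse_atom_line(line, lineno)
            atoms.append(record)
            coords.append(xyz)
    if not atoms:
        raise StructureError(f"{path}: no ATOM records found")
    return StructureModel(atoms, np.array(coords), helices)


def write_pdb(structure: StructureModel, path: str | Path) -> None:
    """Write a single-model PDB with HELIX records (fixed-column, 3-decimal Å)."""
    Path(path).write_text("".join(_pdb_lines(structure)) + "END\n")


def _pdb_lines(structure: StructureModel) -> Iterable[str]:
    for i, (chain, start, end) in enumerate(structure.helices, start=1):
        yield (
            f"HELIX  {i:>3} {i:>3} ALA {chain}{start:>5}  ALA {chain}{end:>5} "
            f" 1{'':>30}{end - start + 1:>6}\n"
        )
    for serial, (atom, xyz) in enumerate(zip(structure.atoms, structure.coords), start=1):
        name = atom.atom_name if len(atom.atom_name) == 4 else f" {atom.atom_name:<3}"
        yield (
            f"ATOM  {serial % 100000:>5} {name}{'':1}{atom.residue_name:>3} "
            f"{atom.chain_id}{atom.residue_number:>4}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"{'':10}{atom.element:>2}\n"
        )


# ---------------------------------------------------------------------------
# Trajectory reading / writing
# ---------------------------------------------------------------------------

def read_trajectory(path: str | Path, format: str = "multi-model-pdb") -> TrajectoryEnsemble:
    """Read a plain-text trajectory.

    ``format`` is ``"multi-model-pdb"`` (MODEL/ENDMDL blocks, topology taken
    from the first model) or ``"xyz-frames"`` (concatenated XYZ blocks).
    Frames must share a constant atom count; a ragged frame raises
    :class:`StructureError` naming its index.
    """
    if format == "multi-model-pdb":
        return _read_multi_model_pdb(path)
    if format == "xyz-frames":
        return _read_xyz_frames(path)
    raise ValueError(f"unknown trajectory format {format!r}")


def _read_multi_model_pdb(path: str | Path) -> TrajectoryEnsemble:
    frames: list[list[np.ndarray]] = []
    atoms: list[AtomRecord] = []  # topology, taken from the first model
    helices: list[tuple[str, int, int]] = []
    current: list[np.ndarray] | None = None
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        rec = line[:6]
        if rec == "MODEL ":
            current = []
        elif rec == "ENDMDL":
            if current is None:
                raise PDBParseError(f"ENDMDL without MODEL at line {lineno}")
            frames.append(current)
            current = None
        elif rec == "HELIX " and not frames:
            helices.append((line[19].strip(), int(line[21:25]), int(line[33:37])))
        elif rec in ("ATOM  ", "HETATM"):
            record, xyz = _parse_atom_line(line, lineno)
            if current is None:  # tolerate model-less single-frame files
                current = []
            if not frames:
                atoms.append(record)
            current.append(xyz)
    if current:
        frames.append(current)
    if not frames:
        raise StructureError(f"{path}: no frames found")
    n0 = len(frames[0])
    for i, fr in enumerate(frames):
        if len(fr) != n0:
            raise StructureError(f"frame {i} has {len(fr)} atoms, expected {n0}")
    topology = StructureModel(atoms[:n0], np.array(frames[0]), helices)
    return TrajectoryEnsemble(topology, np.array(frames))


def _read_xyz_frames(path: str | Path) -> TrajectoryEnsemble:
    lines = Path(path).read_text().splitlines()
    frames: list[np.ndarray] = []
    elements: list[str] = []
    i = 0
    frame_idx = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise PDBParseError(f"expected atom count at line {i + 1}: {exc}") from exc
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise StructureError(f"frame {frame_idx} truncated: {len(block)} of {n} atoms")
        coords = np.empty((n, 3))
        frame_elements: list[str] = []
        for j, row in enumerate(block):
            parts = row.split()
            if len(parts) < 4:
                raise PDBParseError(f"malformed XYZ row at line {i + 3 + j}")
            frame_elements.append(parts[0])
            try:
                coords[j] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError as exc:
                raise PDBParseError(f"malformed XYZ row at line {i + 3 + j}: {exc}") from exc
        if not frames:
            elements = frame_elements
        elif len(frame_elements) != len(elements):
            raise StructureError(f"frame {frame_idx} atom count mismatch")
        frames.append(coords)
        i += 2 + n
        frame_idx += 1
    if not frames:
        raise StructureError(f"{path}: no frames found")
    atoms = [
        AtomRecord(
            atom_name=el,
            residue_name="UNK",
            residue_number=k + 1,
            chain_id="A",
            mass=element_mass(el),
            element=el,
        )
        for k, el in enumerate(elements)
    ]
    topology = StructureModel(atoms, frames[0])
    return TrajectoryEnsemble(topology, np.array(frames))


def write_trajectory(traj: TrajectoryEnsemble, path: str | Path, format: str = "multi-model-pdb") -> None:
    if format == "multi-model-pdb":
        out: list[str] = []
        for k in range(traj.n_frames):
            out.append(f"MODEL {k + 1:>8}\n")
            out.append("".join(_pdb_lines(traj.topology.with_coords(traj.frames[k]))))
            out.append("ENDMDL\n")
        out.append("END\n")
        Path(path).write_text("".join(out))
    elif format == "xyz-frames":
        out = []
        for k in range(traj.n_frames):
            out.append(f"{traj.topology.n_atoms}\nframe {k}\n")
            for atom, xyz in zip(traj.topology.atoms, traj.frames[k]):
                out.append(f"{atom.element or 'C'} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}\n")
        Path(path).write_text("".join(out))
    else:
        raise ValueError(f"unknown trajectory format {format!r}")


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

def select_calpha(structure: StructureModel, regions: Sequence[RegionSpec]) -> np.ndarray:
    """Indices of C-alpha atoms covered by ``regions``.

    Sorted by (chain, residue number); one atom per residue; duplicated
    coverage across regions is deduplicated.  A region resolving to zero
    C-alpha atoms raises :class:`SelectionError`.
    """
    picked: dict[tuple[str, int], int] = {}
    for region in regions:
        start, end = region.residue_range
        found = False
        for idx, atom in enumerate(structure.atoms):
            if (
                atom.chain_id == region.chain_id
                and atom.atom_name == "CA"
                and start <= atom.residue_number <= end
            ):
                picked.setdefault((atom.chain_id, atom.residue_number), idx)
                found = True
        if not found:
            raise SelectionError(
                f"region {region.name} ({region.chain_id} {start}-{end}) selects no C-alpha atoms"
            )
    keys = sorted(picked)
    return np.array([picked[k] for k in keys], dtype=int)


def select_atoms(
    structure: StructureModel, chain_id: str, residue_number: int, atom_names: Sequence[str]
) -> np.ndarray:
    """Indices of the named atoms of one residue (for salt-bridge groups)."""
    names = set(atom_names)
    idx = [
        i
        for i, a in enumerate(structure.atoms)
        if a.chain_id == chain_id and a.residue_number == residue_number and a.atom_name in names
    ]
    if not idx:
        raise SelectionError(
            f"no atoms {sorted(names)} in residue {chain_id}:{residue_number}"
        )
    return np.array(idx, dtype=int)


def default_core_regions(structure: StructureModel, chain_id: str) -> list[RegionSpec]:
    """Core-superposition regions for one chain: its last four HELIX records.

    BAF's superposition core is the bundle of helices alpha-3..alpha-6; when a
    structure carries HELIX annotations, the last four helices of the chain
    are taken as that core.  Explicit :class:`RegionSpec` lists override this.
    """
    chain_helices = [h for h in structure.helices if h[0] == chain_id]
    if len(chain_helices) < 4:
        raise SelectionError(
            f"chain {chain_id} has {len(chain_helices)} HELIX records; need >= 4 "
            "to derive the core, or pass explicit core regions"
        )
    return [
        RegionSpec(name=f"core_helix_{i + 1}", chain_id=chain_id, residue_range=(h[1], h[2]))
        for i, h in enumerate(chain_helices[-4:])
    ]
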