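"""Multi-model PDB reading/writing and the in-memory trajectory model.

A trajectory is stored as one immutable atom table (the *topology*) shared by
all frames plus a ``(n_frames, n_atoms, 3)`` coordinate array.  Every frame of
a multi-model PDB file must contain the same atoms in the same order; this is
validated on read and is what makes per-frame metric series well defined.

Waters (HOH/TIP3/SOL/WAT, case-insensitive) are retained and flagged so that
hydration metrics can select them cheaply.  Files without hydrogens are
first-class inputs: all downstream analyses are defined on heavy atoms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import gemmi
import numpy as np

from .exceptions import PDBFormatError, PDBParseError, StructureError

logger = logging.getLogger(__name__)

#: Residue names recognised as water (compared upper-case).  "TIP" covers
#: CHARMM-style TIP3 names whose fourth character falls outside the 3-column
#: residue-name field.
WATER_RESNAMES = frozenset({"HOH", "TIP3", "TIP", "SOL", "WAT"})

#: Two-letter element symbols that may appear as full atom names (ions etc.).
_TWO_LETTER_ELEMENTS = frozenset({"CL", "NA", "MG", "ZN", "FE", "BR", "MN", "CU", "CA2"})

# PDB %8.3f coordinate columns can represent this closed interval only.
_COORD_MIN = -999.999
_COORD_MAX = 9999.999


def infer_element(atom_name: str) -> str:
    """Guess the element from a PDB atom name when the element column is blank.

    Water oxygens (``OW``/``OH2``) map to O; otherwise the first alphabetic
    character is used, with a short list of monoatomic-ion names special-cased.
    """
    stripped = "".join(c for c in atom_name if c.isalpha()).upper()
    if not stripped:
        raise PDBParseError(f"cannot infer element from atom name {atom_name!r}")
    if stripped in ("OW", "OH"):
        return "O"
    if stripped in _TWO_LETTER_ELEMENTS:
        return stripped.capitalize()
    return stripped[0]


def atomic_mass(element: str) -> float:
    """Standard atomic mass (u) for an element symbol."""
    el = gemmi.Element(element)
    weight = el.weight
    if not weight or weight <= 0:
        raise PDBParseError(f"unknown element {element!r}")
    return float(weight)


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity, residue, chain, element, coordinates, mass."""

    serial: int
    atom_name: str
    residue_name: str
    chain_id: str
    residue_number: int
    element: str
    coords: np.ndarray
    mass: float
    is_water: bool = False
    het: bool = False

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.atom_name}")
        if self.mass <= 0:
            raise ValueError(f"non-positive mass for atom {self.atom_name}")

    @property
    def key(self) -> tuple:
        return (self.chain_id, self.residue_number, self.atom_name)


class Topology:
    """Column-oriented atom table shared by all frames of a trajectory."""

    def __init__(
        self,
        serial: np.ndarray,
        atom_name: np.ndarray,
        residue_name: np.ndarray,
        chain_id: np.ndarray,
        residue_number: np.ndarray,
        element: np.ndarray,
        mass: np.ndarray,
        het: np.ndarray,
    ) -> None:
        self.serial = np.asarray(serial, dtype=np.int64)
        self.atom_name = np.asarray(atom_name, dtype=object)
        self.residue_name = np.asarray(residue_name, dtype=object)
        self.chain_id = np.asarray(chain_id, dtype=object)
        self.residue_number = np.asarray(residue_number, dtype=np.int64)
        self.element = np.asarray(element, dtype=object)
        self.mass = np.asarray(mass, dtype=np.float64)
        self.het = np.asarray(het, dtype=bool)
        self.is_water = np.array(
            [str(r).upper() in WATER_RESNAMES for r in self.residue_name], dtype=bool
        )
        if np.any(self.mass <= 0):
            raise ValueError("all atomic masses must be positive")
        keys = list(zip(self.chain_id, self.residue_number, self.atom_name))
        if len(set(keys)) != len(keys):
            seen: set = set()
            for k in keys:
                if k in seen:
                    raise StructureError(
                        f"duplicate atom identity (chain, residue, name) = {k}"
                    )
                seen.add(k)

    @property
    def n_atoms(self) -> int:
        return len(self.serial)

    def identity(self) -> list[tuple]:
        """Ordered (chain, residue number, residue name, atom name) tuples."""
        return list(
            zip(self.chain_id, self.residue_number, self.residue_name, self.atom_name)
        )

    def record(self, index: int, coords: np.ndarray) -> AtomRecord:
        return AtomRecord(
            serial=int(self.serial[index]),
            atom_name=str(self.atom_name[index]),
            residue_name=str(self.residue_name[index]),
            chain_id=str(self.chain_id[index]),
            residue_number=int(self.residue_number[index]),
            element=str(self.element[index]),
            coords=np.asarray(coords, dtype=float),
            mass=float(self.mass[index]),
            is_water=bool(self.is_water[index]),
            het=bool(self.het[index]),
        )


@dataclass
class Frame:
    """One coordinate snapshot of a trajectory."""

    topology: Topology
    coords: np.ndarray  # (n_atoms, 3), Å
    frame_index: int = 0
    time_ps: float = 0.0

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms

    def atoms(self, indices: Optional[Iterable[int]] = None) -> list[AtomRecord]:
        idx = range(self.n_atoms) if indices is None else indices
        return [self.topology.record(i, self.coords[i]) for i in idx]


@dataclass
class Trajectory:
    """An ordered frame sequence with shared topology and time metadata."""

    topology: Topology
    coords: np.ndarray  # (n_frames, n_atoms, 3), Å
    dt_ps: float = 1.0
    source: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("a trajectory needs at least one frame")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise StructureError("coordinate array does not match topology size")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms

    @property
    def times_ps(self) -> np.ndarray:
        return np.arange(self.n_frames, dtype=float) * self.dt_ps

    def frame(self, k: int) -> Frame:
        if not 0 <= k < self.n_frames:
            raise IndexError(f"frame index {k} out of range [0, {self.n_frames})")
        return Frame(self.topology, self.coords[k], frame_index=k, time_ps=k * self.dt_ps)

    def __len__(self) -> int:
        return self.n_frames

    def __iter__(self) -> Iterator[Frame]:
        for k in range(self.n_frames):
            yield self.frame(k)

    def sliced(self, start: int = 0, stop: Optional[int] = None) -> "Trajectory":
        """Sub-trajectory over a frame range (frame times restart at zero)."""
        stop = self.n_frames if stop is None else stop
        if not (0 <= start < stop <= self.n_frames):
            raise IndexError(f"invalid frame range [{start}, {stop})")
        return Trajectory(self.topology, self.coords[start:stop], self.dt_ps, self.source)


def select(
    obj: "Frame | Trajectory | Topology",
    chain: Optional[str] = None,
    residue_numbers: Optional[Iterable[int]] = None,
    atom_names: Optional[Iterable[str]] = None,
    water_only: bool = False,
) -> np.ndarray:
    """Indices of atoms matching the conjunction of the provided filters.

    Filters apply to the shared topology, so a selection made on one frame is
    valid for every frame of the same trajectory.  An empty result is legal.
    """
    top = obj if isinstance(obj, Topology) else obj.topology
    mask = np.ones(top.n_atoms, dtype=bool)
    if chain is not None:
        mask &= np.array([c == chain for c in top.chain_id])
    if residue_numbers is not None:
        wanted = set(int(r) for r in residue_numbers)
        mask &= np.array([int(r) in wanted for r in top.residue_number])
    if atom_names is not None:
        names = set(atom_names)
        mask &= np.array([n in names for n in top.atom_name])
    if water_only:
        mask &= top.is_water
    return np.nonzero(mask)[0]


def water_oxygen_indices(top: Topology) -> np.ndarray:
    """One index per water molecule: its oxygen atom (the paper counts molecules)."""
    return np.nonzero(top.is_water & (top.element == "O"))[0]


def n_recorded_positions(duration_ns: float, interval_ps: float = 1.0) -> int:
    """Number of positions recorded over ``duration_ns`` at one per ``interval_ps``.

    A 100-ns production run sampled every 1 ps yields 100,000 records.
    """
    if duration_ns <= 0 or interval_ps <= 0:
        raise ValueError("duration and interval must be positive")
    return int(round(duration_ns * 1000.0 / interval_ps))


# ---------------------------------------------------------------------------
# PDB reading


def _validate_pdb_lines(path: str) -> None:
    """Check fixed-column coordinate fields before handing the file to gemmi.

    gemmi tolerates malformed numbers silently; metric code must not, so
    ATOM/HETATM coordinate columns are float-checked here with line numbers.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise PDBParseError(
                    f"{path}: line {lineno}: truncated coordinate record"
                )
            for lo, hi, label in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                text = line[lo:hi]
                try:
                    float(text)
                except ValueError:
                    raise PDBParseError(
                        f"{path}: line {lineno}: malformed {label} coordinate "
                        f"field {text!r}"
                    ) from None


def read_pdb_models(path: str, dt_ps: float = 1.0) -> Trajectory:
    """Read a multi-model PDB file into a :class:`Trajectory`.

    Each MODEL/ENDMDL block becomes one frame; a file without MODEL records is
    a single-frame trajectory.  ATOM and HETATM records are both parsed; altloc
    identifiers other than blank or 'A' are dropped with a warning.  All models
    must contain the same atoms in the same order.

    ``dt_ps`` is trajectory metadata supplied by the caller (the format does
    not carry it).
    """
    _validate_pdb_lines(path)
    try:
        structure = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi detail
        raise PDBParseError(f"{path}: {exc}") from exc
    if len(structure) == 0:
        raise PDBParseError(f"{path}: no models/atoms found")

    frames_ids: list[list[tuple]] = []
    frames_coords: list[np.ndarray] = []
    topology: Optional[Topology] = None
    dropped_altloc = 0

    for model in structure:
        serials, names, resnames, chains, resnums, elements, masses, het = (
            [], [], [], [], [], [], [], [],
        )
        coords = []
        for chain in model:
            for residue in chain:
                for atom in residue:
                    if atom.altloc not in ("", "A", "\x00"):
                        dropped_altloc += 1
                        continue
                    serials.append(atom.serial)
                    names.append(atom.name)
                    resnames.append(residue.name)
                    chains.append(chain.name)
                    resnums.append(residue.seqid.num)
                    el = atom.element.name
                    if not el or el == "X":
                        el = infer_element(atom.name)
                    elements.append(el)
                    masses.append(atomic_mass(el))
                    het.append(residue.het_flag == "H")
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
        ids = list(zip(chains, resnums, resnames, names))
        frames_ids.append(ids)
        frames_coords.append(np.asarray(coords, dtype=float))
        if topology is None:
            topology = Topology(
                np.asarray(serials), np.asarray(names, dtype=object),
                np.asarray(resnames, dtype=object), np.asarray(chains, dtype=object),
                np.asarray(resnums), np.asarray(elements, dtype=object),
                np.asarray(masses), np.asarray(het),
            )

    if dropped_altloc:
        logger.warning("%s: dropped %d alternate-location atoms", path, dropped_altloc)

    first = frames_ids[0]
    for k, ids in enumerate(frames_ids[1:], start=1):
        if ids != first:
            raise StructureError(
                f"{path}: model {k + 1} atom set differs from model 1 "
                f"({len(ids)} vs {len(first)} atoms or mismatched identities)"
            )

    assert topology is not None
    coords3 = np.stack(frames_coords, axis=0)
    return Trajectory(topology, coords3, dt_ps=dt_ps, source=str(path))


# ---------------------------------------------------------------------------
# PDB writing


def write_pdb_models(traj: Trajectory, path: str) -> str:
    """Write a trajectory as a multi-model PDB file (one MODEL per frame).

    Round-trip contract: reading the written file reproduces atom names,
    residues, chains and coordinates to 3 decimals (the PDB column precision).
    """
    if traj.n_frames < 1 or traj.n_atoms < 1:
        raise PDBFormatError("cannot write an empty trajectory")
    if np.any(traj.coords < _COORD_MIN) or np.any(traj.coords > _COORD_MAX):
        bad = traj.coords[(traj.coords < _COORD_MIN) | (traj.coords > _COORD_MAX)]
        raise PDBFormatError(
            f"coordinate {bad.flat[0]:.3f} exceeds fixed-column PDB range "
            f"[{_COORD_MIN}, {_COORD_MAX}]"
        )

    top = traj.topology
    structure = gemmi.Structure()
    structure.name = "hexchan"
    for k in range(traj.n_frames):
        model = gemmi.Model(k + 1)
        chain = None
        residue = None
        prev_chain = None
        prev_res = None
        for i in range(top.n_atoms):
            cid = str(top.chain_id[i])
            rkey = (cid, int(top.residue_number[i]), str(top.residue_name[i]))
            if cid != prev_chain:
                chain = gemmi.Chain(cid)
                model.add_chain(chain)
                chain = model[len(model) - 1]
                prev_chain = cid
                prev_res = None
            if rkey != prev_res:
                res = gemmi.Residue()
                res.name = str(top.residue_name[i])
                res.seqid = gemmi.SeqId(int(top.residue_number[i]), " ")
                res.het_flag = "H" if top.het[i] else "A"
                chain.add_residue(res)
                residue = chain[len(chain) - 1]
                prev_res = rkey
            atom = gemmi.Atom()
            atom.name = str(top.atom_name[i])
            atom.element = gemmi.Element(str(top.element[i]))
            atom.b_iso = 0.0
            atom.occ = 1.0
            x, y, z = traj.coords[k, i]
            atom.pos = gemmi.Position(float(x), float(y), float(z))
            residue.add_atom(atom)
        structure.add_model(model)
    structure.setup_entities()
    structure.write_pdb(str(path))
    return str(path)
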