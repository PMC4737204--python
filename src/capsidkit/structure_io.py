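"""PDB-format structure and ensemble I/O.

Reads and writes the fixed-column PDB dialect, keeping the crystallographic
records (CRYST1 / ORIGXn / SCALEn) that the symmetry expansion depends on.
Multi-model files are treated as conformational ensembles in which every
MODEL may carry its own CRYST1 record — each frame of a constant-pressure
trajectory has its own unit cell, so the nearest preceding CRYST1 is
attached to each frame.

Hand-written on purpose: general readers collapse per-model cells into one,
and the writer here guarantees SCALEn consistent with the cell it emits.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from .constants import (ATOMIC_MASSES, RESIDUE_MASSES, WATER_MASS,
                        WATER_RESNAMES)

logger = logging.getLogger(__name__)


class PDBParseError(ValueError):
    """Malformed PDB content (carries the offending line number)."""


class StructureError(ValueError):
    """Structural inconsistency (mismatched frames, bad partitions...)."""


# --- domain types ---------------------------------------------------------


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray          # shape (3,), angstrom
    occupancy: float = 1.0
    b_factor: float = 0.0
    is_water: bool = False
    altloc: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coords must be 3 finite values")
        if not self.element:
            raise ValueError(f"atom {self.name}: element must be non-empty")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"

    @property
    def mass(self) -> float:
        return ATOMIC_MASSES.get(self.element.upper(), 12.011)

    def copy(self) -> "Atom":
        return replace(self, coords=self.coords.copy())


@dataclass
class Residue:
    name: str                   # 3-letter code
    number: int                 # author numbering, 1-based
    atoms: list = field(default_factory=list)
    insertion_code: str = ""

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def is_water(self) -> bool:
        return self.name in WATER_RESNAMES

    def heavy_atoms(self) -> list:
        return [a for a in self.atoms if not a.is_hydrogen]

    def sidechain_heavy_atoms(self) -> list:
        backbone = {"N", "CA", "C", "O", "OXT"}
        return [a for a in self.atoms
                if not a.is_hydrogen and a.name not in backbone]

    def copy(self) -> "Residue":
        return Residue(self.name, self.number,
                       [a.copy() for a in self.atoms], self.insertion_code)


@dataclass
class Chain:
    id: str
    residues: list = field(default_factory=list)

    def residue(self, number: int) -> Optional[Residue]:
        for r in self.residues:
            if r.number == number:
                return r
        return None

    def atoms(self) -> Iterator[Atom]:
        for r in self.residues:
            yield from r.atoms

    def heavy_coords(self) -> np.ndarray:
        pts = [a.coords for a in self.atoms() if not a.is_hydrogen]
        return np.array(pts) if pts else np.empty((0, 3))

    @property
    def operator_index(self) -> Optional[int]:
        """Symmetry-operator tag if this chain is an expanded copy (id like 'A_3')."""
        if "_" in self.id:
            tail = self.id.rsplit("_", 1)[1]
            if tail.isdigit():
                return int(tail)
        return None

    def sequence_mass(self) -> float:
        """Chain molecular weight (Da) from the residue sequence.

        Sequence-based so it is exact even for reduced (e.g. CA-only)
        coordinate sets; one water is added back for the termini.
        """
        m = sum(RESIDUE_MASSES.get(r.name, 110.0)
                for r in self.residues if not r.is_water)
        return m + WATER_MASS if m > 0 else 0.0

    def copy(self) -> "Chain":
        return Chain(self.id, [r.copy() for r in self.residues])


@dataclass
class UnitCell:
    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0 < ang < 180:
                raise ValueError("cell angles must be in (0, 180)")

    def orthogonalization_matrix(self) -> np.ndarray:
        """Fractional -> orthogonal (angstrom) transform, PDB convention."""
        al = math.radians(self.alpha)
        be = math.radians(self.beta)
        ga = math.radians(self.gamma)
        ca, cb, cg = math.cos(al), math.cos(be), math.cos(ga)
        sg = math.sin(ga)
        v = math.sqrt(1 - ca * ca - cb * cb - cg * cg + 2 * ca * cb * cg)
        return np.array([
            [self.a, self.b * cg, self.c * cb],
            [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
            [0.0, 0.0, self.c * v / sg],
        ])

    def fractionalization_matrix(self) -> np.ndarray:
        return np.linalg.inv(self.orthogonalization_matrix())

    def volume(self) -> float:
        return float(abs(np.linalg.det(self.orthogonalization_matrix())))

    def scaled(self, factor: float) -> "UnitCell":
        return UnitCell(self.a * factor, self.b * factor, self.c * factor,
                        self.alpha, self.beta, self.gamma)


@dataclass
class StructureModel:
    chains: list = field(default_factory=list)
    unit_cell: Optional[UnitCell] = None
    space_group: Optional[str] = None
    waters: list = field(default_factory=list)   # list of Atom (water O and H)

    def __post_init__(self):
        ids = [c.id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError("chain ids must be unique")

    def chain(self, chain_id: str) -> Optional[Chain]:
        for c in self.chains:
            if c.id == chain_id:
                return c
        return None

    def atoms(self) -> Iterator[Atom]:
        for c in self.chains:
            yield from c.atoms()

    def n_atoms(self, include_waters: bool = True) -> int:
        n = sum(1 for _ in self.atoms())
        return n + (len(self.waters) if include_waters else 0)

    def heavy_coords(self) -> np.ndarray:
        pts = [a.coords for a in self.atoms() if not a.is_hydrogen]
        return np.array(pts) if pts else np.empty((0, 3))

    def center_of_mass(self) -> np.ndarray:
        """Mass-weighted center over protein heavy atoms (waters excluded)."""
        coords, masses = [], []
        for a in self.atoms():
            if not a.is_hydrogen:
                coords.append(a.coords)
                masses.append(a.mass)
        if not coords:
            raise StructureError("no heavy atoms")
        coords = np.array(coords)
        masses = np.array(masses)
        return coords.T @ masses / masses.sum()

    def protein_mass(self) -> float:
        """Total protein mass in Da, from residue sequences."""
        return sum(c.sequence_mass() for c in self.chains)

    def copy(self) -> "StructureModel":
        return StructureModel([c.copy() for c in self.chains],
                              self.unit_cell, self.space_group,
                              [w.copy() for w in self.waters])

    def subset(self, chain_ids: Sequence[str]) -> "StructureModel":
        wanted = set(chain_ids)
        chains = [c for c in self.chains if c.id in wanted]
        if len(chains) != len(wanted):
            missing = wanted - {c.id for c in chains}
            raise StructureError(f"chains not found: {sorted(missing)}")
        return StructureModel([c.copy() for c in chains],
                              self.unit_cell, self.space_group, [])


@dataclass
class TrajectoryFrame:
    index: int
    structure: StructureModel
    cell: UnitCell

    def __post_init__(self):
        if self.cell is None:
            raise ValueError("every trajectory frame needs a unit cell")


# --- parsing ---------------------------------------------------------------


def _parse_cryst1(line: str) -> tuple:
    cell = UnitCell(float(line[6:15]), float(line[15:24]), float(line[24:33]),
                    float(line[33:40]), float(line[40:47]), float(line[47:54]))
    sg = line[55:66].strip() or None
    return cell, sg


def _guess_element(name: str, resname: str) -> str:
    """Element from the atom-name columns when columns 77-78 are blank."""
    stripped = name.strip()
    if len(name) >= 4 and name[0] not in " 1234567890":
        # 4-char names starting in column 13: two-letter element (e.g. FE)
        cand = stripped[:2].upper()
        if cand in ATOMIC_MASSES:
            return cand
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot deduce element for atom '{name}' in {resname}")


def _parse_atom_line(line: str, lineno: int) -> tuple:
    try:
        serial = int(line[6:11])
        name = line[12:16]
        altloc = line[16].strip()
        resname = line[17:20].strip()
        chain_id = line[21].strip() or "A"
        resnum = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ = float(line[54:60]) if line[54:60].strip() else 1.0
        bf = float(line[60:66]) if line[60:66].strip() else 0.0
        segid = line[72:76].strip() if len(line) >= 73 else ""
        element = line[76:78].strip().upper() if len(line) >= 77 else ""
        if not element:
            element = _guess_element(name, resname)
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"malformed ATOM/HETATM record at line {lineno}: "
                            f"{exc}") from None
    # expanded symmetry copies store their operator index in the segid
    # columns, reconstructing the reversible 'id_opindex' chain naming
    if segid.isdigit():
        chain_id = f"{chain_id}_{int(segid)}"
    atom = Atom(serial=serial, name=name.strip(), element=element,
                coords=np.array([x, y, z]),
                occupancy=min(max(occ, 0.0), 1.0), b_factor=bf,
                is_water=resname in WATER_RESNAMES, altloc=altloc)
    return atom, resname, chain_id, resnum, icode


class _ModelBuilder:
    """Accumulates atom records into a StructureModel."""

    def __init__(self):
        self.chains: list[Chain] = []
        self.waters: list[Atom] = []
        self._chain_map: dict[str, Chain] = {}
        self.n_records = 0

    def add(self, atom: Atom, resname: str, chain_id: str,
            resnum: int, icode: str):
        # deterministic single-conformer model: keep altloc A or blank
        if atom.altloc not in ("", "A"):
            return
        self.n_records += 1
        if resname in WATER_RESNAMES:
            self.waters.append(atom)
            return
        chain = self._chain_map.get(chain_id)
        if chain is None:
            chain = Chain(chain_id)
            self.chains.append(chain)
            self._chain_map[chain_id] = chain
        if (chain.residues and chain.residues[-1].number == resnum
                and chain.residues[-1].insertion_code == icode
                and chain.residues[-1].name == resname):
            chain.residues[-1].atoms.append(atom)
        else:
            chain.residues.append(
                Residue(resname, resnum, [atom], icode))

    def build(self, cell, sg) -> StructureModel:
        return StructureModel(self.chains, cell, sg, self.waters)


def read_pdb(path) -> StructureModel:
    """Read a single-model PDB file.

    Water residues (HOH/WAT/TIP3) are collected separately; CRYST1 populates
    the unit cell and space group.  A missing CRYST1 yields a structure
    without a cell (logged as a warning, since symmetry expansion then
    cannot run).
    """
    path = Path(path)
    text = path.read_text()
    builder = _ModelBuilder()
    cell, sg = None, None
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec == "CRYST1":
            try:
                cell, sg = _parse_cryst1(line)
            except (ValueError, IndexError) as exc:
                raise PDBParseError(
                    f"malformed CRYST1 at line {lineno}: {exc}") from None
        elif rec in ("ATOM  ", "HETATM"):
            builder.add(*_parse_atom_line(line, lineno))
    if builder.n_records == 0:
        raise PDBParseError(f"{path}: no ATOM/HETATM records found")
    if cell is None:
        logger.warning("%s: no CRYST1 record; unit cell unavailable", path)
    return builder.build(cell, sg)


def read_ensemble(path) -> list:
    """Read a multi-model PDB as an ordered list of TrajectoryFrame.

    Each frame's unit cell is the nearest preceding CRYST1 (which may sit
    inside the MODEL block, as written for per-frame constant-pressure
    cells, or once in the header).  All frames must have identical atom
    counts.  A file without MODEL records yields a single frame.
    """
    path = Path(path)
    text = path.read_text()
    frames: list[TrajectoryFrame] = []
    current_cell, current_sg = None, None
    builder: Optional[_ModelBuilder] = None
    saw_model = False

    def finish(builder):
        if builder is None or builder.n_records == 0:
            return
        if current_cell is None:
            raise PDBParseError(
                f"{path}: model {len(frames)} has no preceding CRYST1")
        structure = builder.build(current_cell, current_sg)
        frames.append(TrajectoryFrame(len(frames), structure, current_cell))

    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec == "CRYST1":
            current_cell, current_sg = _parse_cryst1(line)
        elif rec.startswith("MODEL"):
            saw_model = True
            finish(builder)
            builder = _ModelBuilder()
        elif rec == "ENDMDL":
            finish(builder)
            builder = None
        elif rec in ("ATOM  ", "HETATM"):
            if builder is None:
                builder = _ModelBuilder()
            builder.add(*_parse_atom_line(line, lineno))
    finish(builder)

    if not frames:
        raise PDBParseError(f"{path}: no atom records found")
    counts = {f.structure.n_atoms() for f in frames}
    if len(counts) > 1:
        raise StructureError(
            f"{path}: frames differ in atom count ({sorted(counts)})")
    if not saw_model and len(frames) > 1:  # pragma: no cover - defensive
        raise StructureError(f"{path}: multiple frames without MODEL records")
    return frames


# --- writing ---------------------------------------------------------------


def _format_atom_name(name: str, element: str) -> str:
    """PDB atom-name column alignment (element right-justified in 13-14)."""
    if len(name) >= 4:
        return name[:4]
    if len(element) == 2:
        return f"{name:<4}"[:4]
    return f" {name:<3}"


def _atom_line(record: str, serial: int, atom: Atom, resname: str,
               chain_id: str, resnum: int, icode: str,
               segid: str = "") -> str:
    name = _format_atom_name(atom.name, atom.element)
    el = atom.element.upper().rjust(2)
    x, y, z = atom.coords
    return (f"{record:<6}{serial:>5} {name}{atom.altloc or ' ':1}"
            f"{resname:>3} {chain_id[:1]:1}{resnum:>4}{icode or ' ':1}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}"
            f"{atom.b_factor:6.2f}      {segid:<4}{el}")


def _cryst_records(cell: UnitCell, space_group: Optional[str]) -> list:
    sg = (space_group or "P 1")[:11]
    lines = [f"CRYST1{cell.a:9.3f}{cell.b:9.3f}{cell.c:9.3f}"
             f"{cell.alpha:7.2f}{cell.beta:7.2f}{cell.gamma:7.2f} {sg:<11}"
             f"{1:>4}"]
    for i, row in enumerate(np.eye(3)):
        lines.append(f"ORIGX{i + 1}    {row[0]:10.6f}{row[1]:10.6f}"
                     f"{row[2]:10.6f}     {0.0:10.5f}")
    frac = cell.fractionalization_matrix()
    for i, row in enumerate(frac):
        lines.append(f"SCALE{i + 1}    {row[0]:10.6f}{row[1]:10.6f}"
                     f"{row[2]:10.6f}     {0.0:10.5f}")
    return lines


def _serial_check(n: int):
    if n > 99999:
        raise StructureError(
            f"{n} atoms exceed the 5-digit PDB serial field")


def _structure_body(structure: StructureModel, start_serial: int = 1) -> list:
    lines = []
    serial = start_serial
    for chain in structure.chains:
        base = chain.id.split("_")[0][:1]
        op = chain.operator_index
        segid = "" if op is None else str(op)
        for res in chain.residues:
            for atom in res.atoms:
                _serial_check(serial)
                lines.append(_atom_line("ATOM", serial, atom, res.name,
                                        base, res.number,
                                        res.insertion_code, segid))
                serial += 1
        lines.append(f"TER   {serial:>5}")
        _serial_check(serial)
        serial += 1
    for i, w in enumerate(structure.waters):
        _serial_check(serial)
        lines.append(_atom_line("HETATM", serial, w, "HOH", "w",
                                (i % 9999) + 1, ""))
        serial += 1
    return lines


def write_pdb(structure: StructureModel, path) -> None:
    """Write a structure as fixed-column PDB.

    Emits CRYST1 plus identity ORIGXn and cell-consistent SCALEn whenever a
    unit cell is present.  Raises on serial overflow (>99999 atoms).
    """
    if structure.n_atoms() == 0:
        raise StructureError("refusing to write a structure with no atoms")
    lines: list[str] = []
    if structure.unit_cell is not None:
        lines.extend(_cryst_records(structure.unit_cell, structure.space_group))
    else:
        logger.warning("writing %s without CRYST1 (no unit cell)", path)
    lines.extend(_structure_body(structure))
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_ensemble(frames: Iterable[TrajectoryFrame], path,
                   space_group: Optional[str] = None) -> None:
    """Write frames as multi-model PDB with one CRYST1 per MODEL block."""
    frames = list(frames)
    if not frames:
        raise StructureError("no frames to write")
    lines: list[str] = []
    for k, frame in enumerate(frames):
        lines.append(f"MODEL     {k + 1:>4}")
        sg = space_group or frame.structure.space_group
        lines.extend(_cryst_records(frame.cell, sg))
        lines.extend(_structure_body(frame.structure))
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
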