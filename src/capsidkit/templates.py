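"""Ideal amino-acid geometry: side-chain topologies, rotamers, peptides.

Side chains are described as internal-coordinate trees (bond length, bond
angle, torsion) rooted on the backbone, so a residue can be (re)built on any
fixed backbone given its chi angles.  A coarse backbone-independent rotamer
library enumerates canonical gauche/trans chi combinations with prior
weights; richer libraries can be loaded from a simple text format.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .geometry import place_atom
from .structure_io import Atom, Chain, Residue, StructureModel

# --- backbone ideal geometry (angstrom / degrees) ---------------------------

BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5

# CB placement off the backbone: dihedral C-N-CA-CB fixes L-chirality
BOND_CA_CB = 1.530
ANGLE_N_CA_CB = 110.4
TORSION_C_N_CA_CB = -122.6

# --- side-chain topology -----------------------------------------------------
# entry: (atom, element, ref_a, ref_b, ref_c, bond, angle, torsion)
# torsion is a float (fixed) or ("chi", k, offset_degrees) with k 1-based.
# refs name previously placed atoms of the same residue.

_X = "chi"

SIDECHAIN_TOPOLOGY = {
    "ALA": [],
    "GLY": None,  # no CB at all
    "SER": [("OG", "O", "N", "CA", "CB", 1.417, 110.8, (_X, 1, 0))],
    "CYS": [("SG", "S", "N", "CA", "CB", 1.808, 114.4, (_X, 1, 0))],
    "THR": [("OG1", "O", "N", "CA", "CB", 1.433, 109.6, (_X, 1, 0)),
            ("CG2", "C", "N", "CA", "CB", 1.521, 110.5, (_X, 1, -120.0))],
    "VAL": [("CG1", "C", "N", "CA", "CB", 1.527, 110.5, (_X, 1, 0)),
            ("CG2", "C", "N", "CA", "CB", 1.527, 110.5, (_X, 1, 120.0))],
    "LEU": [("CG", "C", "N", "CA", "CB", 1.530, 116.3, (_X, 1, 0)),
            ("CD1", "C", "CA", "CB", "CG", 1.524, 110.7, (_X, 2, 0)),
            ("CD2", "C", "CA", "CB", "CG", 1.524, 110.7, (_X, 2, 120.0))],
    "ILE": [("CG1", "C", "N", "CA", "CB", 1.530, 110.4, (_X, 1, 0)),
            ("CG2", "C", "N", "CA", "CB", 1.521, 110.5, (_X, 1, -120.0)),
            ("CD1", "C", "CA", "CB", "CG1", 1.513, 113.8, (_X, 2, 0))],
    "MET": [("CG", "C", "N", "CA", "CB", 1.520, 114.1, (_X, 1, 0)),
            ("SD", "S", "CA", "CB", "CG", 1.807, 112.7, (_X, 2, 0)),
            ("CE", "C", "CB", "CG", "SD", 1.789, 100.9, (_X, 3, 0))],
    "PHE": [("CG", "C", "N", "CA", "CB", 1.500, 113.8, (_X, 1, 0)),
            ("CD1", "C", "CA", "CB", "CG", 1.390, 120.8, (_X, 2, 0)),
            ("CD2", "C", "CA", "CB", "CG", 1.390, 120.8, (_X, 2, 180.0)),
            ("CE1", "C", "CB", "CG", "CD1", 1.390, 120.8, 180.0),
            ("CE2", "C", "CB", "CG", "CD2", 1.390, 120.8, 180.0),
            ("CZ", "C", "CG", "CD1", "CE1", 1.390, 120.0, 0.0)],
    "TYR": [("CG", "C", "N", "CA", "CB", 1.500, 113.8, (_X, 1, 0)),
            ("CD1", "C", "CA", "CB", "CG", 1.390, 120.8, (_X, 2, 0)),
            ("CD2", "C", "CA", "CB", "CG", 1.390, 120.8, (_X, 2, 180.0)),
            ("CE1", "C", "CB", "CG", "CD1", 1.390, 120.8, 180.0),
            ("CE2", "C", "CB", "CG", "CD2", 1.390, 120.8, 180.0),
            ("CZ", "C", "CG", "CD1", "CE1", 1.390, 120.0, 0.0),
            ("OH", "O", "CD1", "CE1", "CZ", 1.380, 120.0, 180.0)],
    "TRP": [("CG", "C", "N", "CA", "CB", 1.500, 113.6, (_X, 1, 0)),
            ("CD1", "C", "CA", "CB", "CG", 1.365, 126.9, (_X, 2, 0)),
            ("CD2", "C", "CA", "CB", "CG", 1.433, 126.7, (_X, 2, 180.0)),
            ("NE1", "N", "CB", "CG", "CD1", 1.374, 110.2, 180.0),
            ("CE2", "C", "CB", "CG", "CD2", 1.409, 107.2, 180.0),
            ("CE3", "C", "CB", "CG", "CD2", 1.400, 133.9, 0.0),
            ("CZ2", "C", "CG", "CD2", "CE2", 1.390, 122.4, 180.0),
            ("CZ3", "C", "CG", "CD2", "CE3", 1.390, 118.7, 180.0),
            ("CH2", "C", "CE2", "CZ2", "CG", 1.370, 117.5, 0.0)],
    "ASP": [("CG", "C", "N", "CA", "CB", 1.520, 112.6, (_X, 1, 0)),
            ("OD1", "O", "CA", "CB", "CG", 1.250, 118.4, (_X, 2, 0)),
            ("OD2", "O", "CA", "CB", "CG", 1.250, 118.4, (_X, 2, 180.0))],
    "ASN": [("CG", "C", "N", "CA", "CB", 1.520, 112.6, (_X, 1, 0)),
            ("OD1", "O", "CA", "CB", "CG", 1.231, 120.8, (_X, 2, 0)),
            ("ND2", "N", "CA", "CB", "CG", 1.328, 116.4, (_X, 2, 180.0))],
    "GLU": [("CG", "C", "N", "CA", "CB", 1.520, 114.1, (_X, 1, 0)),
            ("CD", "C", "CA", "CB", "CG", 1.520, 112.6, (_X, 2, 0)),
            ("OE1", "O", "CB", "CG", "CD", 1.250, 118.4, (_X, 3, 0)),
            ("OE2", "O", "CB", "CG", "CD", 1.250, 118.4, (_X, 3, 180.0))],
    "GLN": [("CG", "C", "N", "CA", "CB", 1.520, 114.1, (_X, 1, 0)),
            ("CD", "C", "CA", "CB", "CG", 1.520, 112.6, (_X, 2, 0)),
            ("OE1", "O", "CB", "CG", "CD", 1.231, 120.8, (_X, 3, 0)),
            ("NE2", "N", "CB", "CG", "CD", 1.328, 116.4, (_X, 3, 180.0))],
    "LYS": [("CG", "C", "N", "CA", "CB", 1.520, 114.1, (_X, 1, 0)),
            ("CD", "C", "CA", "CB", "CG", 1.520, 111.3, (_X, 2, 0)),
            ("CE", "C", "CB", "CG", "CD", 1.520, 111.3, (_X, 3, 0)),
            ("NZ", "N", "CG", "CD", "CE", 1.489, 111.5, (_X, 4, 0))],
    "ARG": [("CG", "C", "N", "CA", "CB", 1.520, 114.1, (_X, 1, 0)),
            ("CD", "C", "CA", "CB", "CG", 1.520, 111.3, (_X, 2, 0)),
            ("NE", "N", "CB", "CG", "CD", 1.461, 112.0, (_X, 3, 0)),
            ("CZ", "C", "CG", "CD", "NE", 1.329, 124.2, (_X, 4, 0)),
            ("NH1", "N", "CD", "NE", "CZ", 1.326, 120.0, 0.0),
            ("NH2", "N", "CD", "NE", "CZ", 1.326, 120.0, 180.0)],
    "HIS": [("CG", "C", "N", "CA", "CB", 1.490, 113.8, (_X, 1, 0)),
            ("ND1", "N", "CA", "CB", "CG", 1.380, 122.7, (_X, 2, 0)),
            ("CD2", "C", "CA", "CB", "CG", 1.350, 131.0, (_X, 2, 180.0)),
            ("CE1", "C", "CB", "CG", "ND1", 1.320, 109.3, 180.0),
            ("NE2", "N", "CB", "CG", "CD2", 1.370, 107.2, 180.0)],
    "PRO": [("CG", "C", "N", "CA", "CB", 1.500, 104.5, -25.0),
            ("CD", "C", "CA", "CB", "CG", 1.500, 106.1, 35.0)],
}

#: number of freely rotatable chi angles per residue
N_CHI = {
    "ALA": 0, "GLY": 0, "PRO": 0,
    "SER": 1, "CYS": 1, "THR": 1, "VAL": 1,
    "LEU": 2, "ILE": 2, "PHE": 2, "TYR": 2, "TRP": 2, "HIS": 2,
    "ASP": 2, "ASN": 2,
    "MET": 3, "GLU": 3, "GLN": 3,
    "LYS": 4, "ARG": 4,
}

# canonical staggered chi values with coarse prior weights
_CHI_VALUES = (-60.0, 180.0, 60.0)
_CHI_WEIGHTS = (0.50, 0.35, 0.15)


@dataclass
class RotamerLibrary:
    """Per-residue chi-angle tuples with prior weights (summing to 1)."""
    rotamers: dict  # resname -> list of (chis: tuple, weight: float)

    def for_residue(self, resname: str):
        if resname not in self.rotamers:
            raise KeyError(f"no rotamers for residue {resname!r}")
        return self.rotamers[resname]

    @classmethod
    def default(cls) -> "RotamerLibrary":
        lib = {}
        for resname, nchi in N_CHI.items():
            if nchi == 0:
                lib[resname] = [((), 1.0)]
                continue
            entries = []
            for combo in itertools.product(range(3), repeat=nchi):
                chis = tuple(_CHI_VALUES[i] for i in combo)
                w = math.prod(_CHI_WEIGHTS[i] for i in combo)
                entries.append((chis, w))
            total = sum(w for _, w in entries)
            lib[resname] = [(c, w / total) for c, w in entries]
        return cls(lib)

    @classmethod
    def from_file(cls, path) -> "RotamerLibrary":
        """Load 'RES chi1 chi2 ... weight' lines ('#' comments allowed)."""
        lib: dict = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#")[0].strip()
            if not line:
                continue
            parts = line.split()
            resname = parts[0].upper()
            *chis, weight = (float(x) for x in parts[1:])
            lib.setdefault(resname, []).append((tuple(chis), weight))
        for resname, entries in lib.items():
            total = sum(w for _, w in entries)
            if total <= 0:
                raise ValueError(f"{resname}: rotamer weights must sum > 0")
            lib[resname] = [(c, w / total) for c, w in entries]
        return cls(lib)


# --- building ----------------------------------------------------------------


def build_sidechain(residue: Residue, chis: Sequence[float],
                    serial_start: int = 0) -> None:
    """Rebuild the side chain of `residue` in place on its fixed backbone.

    Backbone N/CA/C (and O) are untouched; all other atoms are replaced by
    ideal-geometry atoms at the given chi angles.  Glycine ends up with a
    bare backbone, alanine with CB only.
    """
    topo = SIDECHAIN_TOPOLOGY.get(residue.name)
    if topo is None and residue.name not in SIDECHAIN_TOPOLOGY:
        raise KeyError(f"no template for residue {residue.name!r}")
    backbone = {"N", "CA", "C", "O", "OXT"}
    kept = [a for a in residue.atoms if a.name in backbone]
    if len([a for a in kept if a.name in ("N", "CA", "C")]) < 3:
        raise ValueError(
            f"residue {residue.name}{residue.number}: backbone incomplete")
    residue.atoms = kept
    placed = {a.name: a.coords for a in kept}
    if topo is None:   # glycine
        return

    serial = serial_start or (max(a.serial for a in kept) + 1)
    # CB off the backbone frame (fixed, chi-independent)
    cb = place_atom(placed["C"], placed["N"], placed["CA"],
                    BOND_CA_CB, ANGLE_N_CA_CB, TORSION_C_N_CA_CB)
    residue.atoms.append(Atom(serial, "CB", "C", cb))
    placed["CB"] = cb
    serial += 1

    for (name, element, ra, rb, rc, bond, angle, torsion) in topo:
        if isinstance(torsion, tuple):
            _, k, offset = torsion
            if k > len(chis):
                raise ValueError(
                    f"{residue.name} needs chi{k} but only "
                    f"{len(chis)} supplied")
            tor = chis[k - 1] + offset
        else:
            tor = torsion
        xyz = place_atom(placed[ra], placed[rb], placed[rc],
                         bond, angle, tor)
        residue.atoms.append(Atom(serial, name, element, xyz))
        placed[name] = xyz
        serial += 1


def measured_chis(residue: Residue) -> tuple:
    """Chi angles measurable from the residue's current coordinates."""
    from .geometry import dihedral
    # walk the topology's chi-defining atoms (offset-0 torsion entries)
    topo = SIDECHAIN_TOPOLOGY.get(residue.name) or []
    chis = []
    for (name, _el, ra, rb, rc, _b, _ang, torsion) in topo:
        if isinstance(torsion, tuple) and torsion[2] == 0:
            atoms = [residue.atom(x) for x in (ra, rb, rc, name)]
            if any(a is None for a in atoms):
                break
            chis.append(dihedral(*(a.coords for a in atoms)))
    return tuple(chis)


def build_peptide(sequence: Sequence[str], chain_id: str = "A",
                  chis: Optional[dict] = None,
                  phi: float = -140.0, psi: float = 135.0,
                  start_number: int = 1) -> Chain:
    """Build an ideal extended peptide chain from 3-letter residue names.

    `chis` maps residue index (0-based) to a chi tuple; unspecified residues
    get all-trans side chains.  The chain starts at the origin in a
    canonical frame; callers rigid-place it afterwards.
    """
    omega = 180.0
    chain = Chain(chain_id)
    serial = 1
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([BOND_N_CA, 0.0, 0.0])
    ang = math.radians(ANGLE_N_CA_C)
    c = ca + BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])

    for i, resname in enumerate(sequence):
        resname = resname.upper()
        if resname not in SIDECHAIN_TOPOLOGY:
            raise KeyError(f"unknown residue {resname!r}")
        res = Residue(resname, start_number + i)
        res.atoms = [Atom(serial, "N", "N", n.copy()),
                     Atom(serial + 1, "CA", "C", ca.copy()),
                     Atom(serial + 2, "C", "C", c.copy())]
        serial += 3
        n_next = place_atom(n, ca, c, BOND_C_N, ANGLE_CA_C_N, psi)
        o = place_atom(n, ca, c, BOND_C_O, ANGLE_CA_C_O, psi + 180.0)
        res.atoms.append(Atom(serial, "O", "O", o))
        serial += 1
        res_chis = (chis or {}).get(i)
        if res_chis is None:
            res_chis = tuple([180.0] * N_CHI.get(resname, 0))
        build_sidechain(res, res_chis, serial_start=serial)
        serial = max((a.serial for a in res.atoms), default=serial) + 1
        chain.residues.append(res)

        ca_next = place_atom(ca, c, n_next, BOND_N_CA, ANGLE_C_N_CA, omega)
        c_next = place_atom(c, n_next, ca_next, BOND_CA_C, ANGLE_N_CA_C, phi)
        n, ca, c = n_next, ca_next, c_next
    return chain


def rigid_place_chain(chain: Chain, rotation: np.ndarray,
                      translation: np.ndarray) -> None:
    """Apply x -> R x + t to every atom of the chain, in place."""
    for atom in chain.atoms():
        atom.coords = rotation @ atom.coords + translation


def peptide_structure(chains: Sequence[Chain], **kwargs) -> StructureModel:
    return StructureModel(list(chains), **kwargs)
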