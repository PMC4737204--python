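"""Synthetic capsid systems and conformational ensembles.

`generate_toy_capsid` builds a desk-scale dodecahedral capsid crystal: one
C5-symmetric pentamer of short ideal-geometry peptides as the asymmetric
unit, with I23 cell metadata chosen so that symmetry expansion yields two
complete capsids of 12 pentamers per cubic cell (a synthetic stand-in for a
capsid crystal structure).  Each monomer is a 5-residue strand laid along
one edge of its pentagonal face; the residues facing the edge are the
interface sites, and the icosahedral 2-fold through the edge midpoint maps
them onto the neighbouring pentamer's copies so that every one of the 30
pentamer-pentamer interfaces carries the same salt bridge, hydrophobic
cluster and hydrogen-bond geometry.

`generate_ensemble` emulates the dominant fluctuation seen in
constant-pressure capsid simulations: a global breathing mode (the capsid
radius fluctuating a few percent around its mean, the unit cell co-scaling)
plus per-atom thermal noise with a configurable per-residue RMSF profile.

`generate_volume_series` draws unit-cell volumes whose fluctuations encode
a chosen isothermal compressibility via chi_T = <dV^2> / (kB T V).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .constants import (A3_TO_M3, INV_PA_TO_INV_GPA, KB_J_K,
                        DEFAULT_TEMPERATURE_K)
from .geometry import dodecahedron_face_normals, rotation_about_axis
from .structure_io import (Chain, StructureModel, TrajectoryFrame, UnitCell)
from .templates import N_CHI, build_peptide, rigid_place_chain

# default interface composition, one residue type per contact site
DEFAULT_COMPOSITION = {
    "salt_anion": "GLU",      # strand start, faces the edge
    "hbond": "HIS",           # inward-facing, packs against the neighbour
    "hydrophobic": "LEU",     # strand centre, faces the edge
    "filler": "ALA",          # inward-facing
    "salt_cation": "ARG",     # strand end, faces the edge
}

# placement constants (angstrom), calibrated once for the default
# composition so that the 2-fold image contacts land in detection range
STRAND_INSET = 6.5           # backbone CA line, inward from the edge
STRAND_HEIGHT = 0.0          # above the face plane

#: chi angles used for the interface anchor residues (side chains must
#: reach the edge without crossing it; everything else is all-trans).
#: Chosen so the 2-fold image pairs land at salt-bridge (~3.2 A) and
#: van der Waals (~4.4 A) distances with no steric overlap.
ANCHOR_CHIS: dict = {
    "ARG": (-60.0, 180.0, 180.0, 180.0),
    "GLU": (60.0, 180.0, 60.0),
}


class PackingError(ValueError):
    """Toy-capsid parameters that cannot be packed into the cell."""


@dataclass
class ToyCapsidParams:
    inradius: float = 34.0
    residues_per_monomer: int = 5
    interface_composition: dict = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITION))
    cell_side: float = 150.0
    seed: int = 0

    def __post_init__(self):
        if self.inradius <= 0:
            raise ValueError("inradius must be positive")
        if self.cell_side <= 4 * self.inradius:
            raise PackingError(
                f"cell side {self.cell_side} too small: two capsids of "
                f"inradius {self.inradius} need > {4 * self.inradius}")
        if self.residues_per_monomer % 4 != 1:
            raise ValueError("residues_per_monomer must be 5, 9, ... "
                             "(anchor sites need even strand positions)")


@dataclass
class EnsembleParams:
    n_frames: int = 50
    breathing_amplitude: float = 0.02    # fractional SD of capsid radius
    atomic_noise_sd: float = 0.15        # angstrom per coordinate
    rmsf_profile: Optional[Sequence[float]] = None  # per-residue scales
    cell_coupling: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        if self.breathing_amplitude < 0 or self.atomic_noise_sd < 0:
            raise ValueError("amplitudes must be >= 0")


# --- toy capsid ----------------------------------------------------------------


def _monomer_sequence(n: int, comp: dict) -> list:
    """Residue layout: anchors at even strand positions facing the edge."""
    seq = []
    center = (n - 1) // 2
    for i in range(n):
        if i == 0:
            seq.append(comp.get("salt_anion", "GLU"))
        elif i == n - 1:
            seq.append(comp.get("salt_cation", "ARG"))
        elif i == center:
            seq.append(comp.get("hydrophobic", "LEU"))
        elif i == 1:
            seq.append(comp.get("hbond", "HIS"))
        else:
            seq.append(comp.get("filler", "ALA"))
    return seq


def _face_frame(inradius: float):
    """Geometry of face 0 and its first edge.

    Returns (normal, edge_unit, inward_unit, edge_midpoint) for the face
    whose normal is closest to (0, 1, phi) in a dodecahedron of the given
    inradius, oriented for the I23 point group (2-folds on the axes).
    """
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    normals = dodecahedron_face_normals()
    target = np.array([0.0, 1.0, phi])
    target /= np.linalg.norm(target)
    n0 = normals[int(np.argmax(normals @ target))]
    # the 5 neighbouring faces subtend arccos(1/sqrt(5)); edge midpoints lie
    # midway between adjacent face centers (both at the inradius)
    cosang = normals @ n0
    neighbors = normals[(cosang > 0.3) & (cosang < 0.99)]
    nb = neighbors[0]
    center = inradius * n0
    m = inradius * 0.5 * (n0 + nb)          # edge midpoint direction
    # rescale: edge midpoints of a dodecahedron sit at r / cos(theta/2)
    # along the bisector of two adjacent normals -- equivalently the
    # midpoint of the two face centers projected onto the edge line; use
    # the exact construction via the in-plane component:
    inplane = m - (m @ n0) * n0
    edge_mid = center + inplane * (inradius / (m @ n0))
    d_in = center - edge_mid
    d_in /= np.linalg.norm(d_in)
    e = np.cross(n0, d_in)
    e /= np.linalg.norm(e)
    return n0, e, d_in, edge_mid


def build_toy_monomer(params: ToyCapsidParams) -> Chain:
    """Monomer 0 of pentamer 0, placed at the first edge of face 0."""
    n = params.residues_per_monomer
    seq = _monomer_sequence(n, params.interface_composition)
    # all-trans side chains extend the interface residues toward the edge;
    # anchors may override their chis so the tips land in contact range
    chis = {}
    for i in range(n):
        override = ANCHOR_CHIS.get(seq[i])
        chis[i] = (tuple(override) if override is not None
                   else tuple([180.0] * N_CHI.get(seq[i], 0)))
    chain = build_peptide(seq, chain_id="A", chis=chis)

    n0, e_hat, d_in, edge_mid = _face_frame(params.inradius)

    # canonical strand frame: axis from first to last CA, 'down' = the
    # direction the centre residue's side chain points (toward the edge)
    ca = [res.atom("CA").coords for res in chain.residues]
    axis = ca[-1] - ca[0]
    axis /= np.linalg.norm(axis)
    center_res = chain.residues[(n - 1) // 2]
    cb = center_res.atom("CB")
    down = (cb.coords - center_res.atom("CA").coords) if cb is not None \
        else np.cross(axis, [0.0, 0.0, 1.0])
    down = down - (down @ axis) * axis
    down /= np.linalg.norm(down)
    third = np.cross(axis, down)

    # target frame: strand along the edge, side chains pointing outward
    # from the face center toward the edge (-d_in), lying in the face plane
    t_axis = e_hat
    t_down = -d_in
    t_third = np.cross(t_axis, t_down)
    rot = (np.column_stack([t_axis, t_down, t_third])
           @ np.column_stack([axis, down, third]).T)

    # position: centre CA on the strand line at STRAND_INSET from the edge
    strand_center = (edge_mid + STRAND_INSET * d_in + STRAND_HEIGHT * n0)
    t = strand_center - rot @ ca[(n - 1) // 2]
    rigid_place_chain(chain, rot, t)
    return chain


def generate_toy_capsid(params: Optional[ToyCapsidParams] = None
                        ) -> StructureModel:
    """Asymmetric unit of the toy capsid crystal: one C5 pentamer.

    The pentamer sits on one face of a dodecahedron centred at the origin;
    expanding with the I23 operators in the attached cubic cell produces
    two capsids of 12 pentamers.  The pentamer is shifted along its 5-fold
    axis so that its heavy-atom mass-weighted centre of mass lies exactly
    at the construction inradius, making the COM-based capsid radius
    recover `params.inradius` exactly.  Deterministic given the parameters.
    """
    params = params or ToyCapsidParams()
    monomer = build_toy_monomer(params)
    n0, _e, _d, _m = _face_frame(params.inradius)

    chains = []
    for j, cid in enumerate("ABCDE"):
        rot = rotation_about_axis(n0, 2.0 * math.pi * j / 5.0)
        copy = monomer.copy()
        copy.id = cid
        rigid_place_chain(copy, rot, np.zeros(3))
        chains.append(copy)

    # recentre the COM onto the inradius along the 5-fold axis
    pent = StructureModel(chains)
    com = pent.center_of_mass()
    shift = (params.inradius - float(com @ n0)) * n0
    for c in chains:
        rigid_place_chain(c, np.eye(3), shift)

    cell = UnitCell(params.cell_side, params.cell_side, params.cell_side)
    return StructureModel(chains, cell, "I 2 3", [])


def reference_toy_capsid(params: Optional[ToyCapsidParams] = None
                         ) -> StructureModel:
    """One complete capsid built directly from the icosahedral orbit.

    Independent of the crystallographic expansion path: the 12 pentamer
    placements come from the tetrahedral rotation group acting on the
    asymmetric pentamer in Cartesian space.  Used as an oracle for
    `expand_asymmetric_unit`.
    """
    from .symmetry import space_group_operators
    params = params or ToyCapsidParams()
    asu = generate_toy_capsid(params)
    ops = space_group_operators("I23")[:12]     # the pure rotations
    chains = []
    for k, op in enumerate(ops):
        for chain in asu.chains:
            copy = chain.copy()
            copy.id = f"{chain.id}_{k}"
            rigid_place_chain(copy, op.R, np.zeros(3))
            chains.append(copy)
    return StructureModel(chains, asu.unit_cell, asu.space_group, [])


# --- ensembles -----------------------------------------------------------------


def _per_atom_scales(structure: StructureModel,
                     rmsf_profile: Optional[Sequence[float]]) -> np.ndarray:
    """Per-atom noise scale from a per-residue profile (1.0 if absent).

    The profile indexes residues by their position within each chain, so a
    pentamer of identical chains shares one per-monomer profile.
    """
    scales = []
    for chain in structure.chains:
        for i, res in enumerate(chain.residues):
            s = 1.0
            if rmsf_profile is not None:
                s = float(rmsf_profile[i % len(rmsf_profile)])
            scales.extend([s] * len(res.atoms))
    return np.array(scales)


def generate_ensemble(structure: StructureModel,
                      params: Optional[EnsembleParams] = None,
                      center: Optional[np.ndarray] = None) -> list:
    """Synthetic conformational ensemble around a reference structure.

    Frame k scales all coordinates radially about the capsid centre
    (default: the origin, where the crystal construction puts the capsid)
    by s_k ~ Normal(1, breathing_amplitude), then adds isotropic Gaussian
    displacement of SD atomic_noise_sd * rmsf_profile(residue).  With
    `cell_coupling` the unit cell scales by s_k as well, so fractional
    positions breathe with the crystal.  Reproducible under the seed.
    """
    params = params or EnsembleParams()
    if params.cell_coupling and structure.unit_cell is None:
        raise ValueError("cell_coupling requires a unit cell")
    center = np.zeros(3) if center is None else np.asarray(center, float)
    rng = np.random.default_rng(params.seed)

    atoms = list(structure.atoms()) + list(structure.waters)
    coords0 = np.array([a.coords for a in atoms])
    scales = _per_atom_scales(structure, params.rmsf_profile)
    if structure.waters:
        scales = np.concatenate([scales, np.ones(len(structure.waters))])

    frames = []
    for k in range(params.n_frames):
        s = rng.normal(1.0, params.breathing_amplitude) \
            if params.breathing_amplitude > 0 else 1.0
        coords = center + s * (coords0 - center)
        if params.atomic_noise_sd > 0:
            coords = coords + rng.normal(
                0.0, 1.0, coords0.shape) * (params.atomic_noise_sd
                                            * scales)[:, None]
        snap = structure.copy()
        snap_atoms = list(snap.atoms()) + list(snap.waters)
        for a, xyz in zip(snap_atoms, coords):
            a.coords = xyz
        cell = structure.unit_cell
        if params.cell_coupling:
            cell = structure.unit_cell.scaled(s)
        elif cell is None:
            cell = UnitCell(1.0, 1.0, 1.0)
        snap.unit_cell = cell
        frames.append(TrajectoryFrame(k, snap, cell))
    return frames


def generate_volume_series(v0: float, chi: float,
                           temperature: float = DEFAULT_TEMPERATURE_K,
                           n: int = 1000, seed: int = 0) -> np.ndarray:
    """Unit-cell volumes (A^3) encoding an isothermal compressibility.

    Draws i.i.d. Normal(v0, sigma^2) with sigma^2 = kB T v0 chi (chi in
    GPa^-1, volumes in A^3); inverting the fluctuation relation
    chi_T = <dV^2> / (kB T V) on the sample recovers chi.
    """
    if v0 <= 0 or chi < 0 or temperature <= 0 or n < 1:
        raise ValueError("v0, temperature must be positive; chi >= 0; n >= 1")
    chi_pa = chi / INV_PA_TO_INV_GPA
    sigma2_m6 = KB_J_K * temperature * (v0 * A3_TO_M3) * chi_pa
    sigma_a3 = math.sqrt(sigma2_m6) / A3_TO_M3
    rng = np.random.default_rng(seed)
    return v0 + sigma_a3 * rng.standard_normal(n)
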