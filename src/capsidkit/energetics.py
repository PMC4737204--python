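"""Empirical association free-energy model for protein assemblies.

The free energy of association of a complex from N components is

    dG_association = G(complex) - sum_i G(component_i) + (N - 1) * S_rb

with G a pure function of one structure's coordinates:

    G = sum_atoms sigma(class) * SASA(atom)
        + E_hb * n_hbonds + E_sb * n_saltbridges

The solvation term uses atomic solvation parameters: burying apolar (C/S)
area is rewarded, burying charged N/O area is penalised.  Hydrogen bonds
and salt bridges are geometric counts with fixed per-contact energies, and
S_rb is a constant rigid-body entropy penalty per association event.
Negative dG favours the assembled state; the difference between a mutant's
and the wild type's dG (ddG, positive = destabilising) is the prediction
the pipeline is built around.

Waters never contribute to G; they are only counted by `cavity_waters`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .constants import VDW_RADII
from .geometry import angle_deg, spiral_sphere_points
from .structure_io import StructureModel, StructureError

# atoms carrying a formal charge at neutral pH (side-chain termini);
# doubles as the salt-bridge participant table
CATION_ATOMS = {
    "ARG": ("NH1", "NH2", "NE"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),
}
ANION_ATOMS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}
# C-terminal carboxylate oxygen counts as an anion in any residue
ANION_EXTRA = ("OXT",)


class SasaError(ValueError):
    """Unknown element or invalid SASA parameters."""


@dataclass
class SolvationParams:
    """Tunable parameters of the empirical association model.

    Defaults are calibrated once for the synthetic capsid systems so that
    a wild-type toy capsid associates strongly (dG well below zero) and
    charged substitutions in a hydrophobic interface destabilise it.
    """
    probe_radius: float = 1.4                     # angstrom
    #: kcal/mol/A^2 by atom class
    atomic_solvation: dict = field(default_factory=lambda: {
        "apolar": 0.016,       # C, S: burial rewarded
        "polar": -0.006,       # neutral N, O
        "charged": -0.024,     # charged N/O (see CATION/ANION tables)
    })
    hbond_energy: float = -0.5                    # kcal/mol per bond
    saltbridge_energy: float = -1.5               # kcal/mol per bridge
    rigid_body_entropy: float = 10.0              # kcal/mol per event, >= 0
    temperature: float = 300.0                    # K
    n_sphere_points: int = 960
    hbond_cutoff: float = 3.5                     # angstrom, donor-acceptor
    hbond_min_angle: float = 120.0                # degrees
    saltbridge_cutoff: float = 4.0                # angstrom

    def __post_init__(self):
        if self.probe_radius <= 0:
            raise ValueError("probe radius must be positive")
        if self.rigid_body_entropy < 0:
            raise ValueError("rigid-body entropy term must be >= 0")
        if self.hbond_energy > 0 or self.saltbridge_energy > 0:
            raise ValueError("contact energies must be favourable (<= 0)")


@dataclass
class AssociationResult:
    dg_total: float
    dg_solvation: float
    dg_hbond: float
    dg_saltbridge: float
    dg_entropy: float
    n_components: int
    buried_area: float
    n_hbonds: int
    n_saltbridges: int


@dataclass
class ContactRecord:
    kind: str                  # 'hbond' | 'saltbridge'
    donor: tuple               # (chain_id, resname, resnum, atom_name)
    acceptor: tuple
    distance: float
    inter_assembly: bool = False


# --- SASA ---------------------------------------------------------------------


def _heavy_atom_table(structure: StructureModel):
    """Flat arrays of heavy protein atoms: coords, radii, classes, labels."""
    coords, radii, labels = [], [], []
    for chain in structure.chains:
        for res in chain.residues:
            for a in res.atoms:
                if a.is_hydrogen:
                    continue
                el = a.element.upper()
                if el not in VDW_RADII:
                    raise SasaError(
                        f"no van der Waals radius for element {el!r} "
                        f"({chain.id}/{res.name}{res.number}/{a.name})")
                coords.append(a.coords)
                radii.append(VDW_RADII[el])
                labels.append((chain.id, res.name, res.number, a.name, el))
    return (np.array(coords).reshape(-1, 3), np.array(radii), labels)


def _atom_class(resname: str, atom_name: str, element: str) -> str:
    if element in ("C", "S"):
        return "apolar"
    if element in ("N", "O"):
        if atom_name in CATION_ATOMS.get(resname, ()):
            return "charged"
        if atom_name in ANION_ATOMS.get(resname, ()):
            return "charged"
        if atom_name in ANION_EXTRA:
            return "charged"
        return "polar"
    return "polar"


def compute_sasa(structure: StructureModel,
                 params: Optional[SolvationParams] = None,
                 n_sphere_points: Optional[int] = None) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Shrake-Rupley), A^2.

    Heavy protein atoms only (hydrogens and waters ignored).  The sphere
    point set is a deterministic spiral lattice, so results are
    bit-reproducible for a given point count.
    """
    params = params or SolvationParams()
    n_pts = n_sphere_points or params.n_sphere_points
    if n_pts < 64:
        raise ValueError("need at least 64 sphere points")
    coords, radii, _ = _heavy_atom_table(structure)
    if len(coords) == 0:
        raise StructureError("no heavy atoms for SASA")
    return sasa_from_arrays(coords, radii, params.probe_radius, n_pts)


def _local_frame(center: np.ndarray, neigh_coords: np.ndarray,
                 order: np.ndarray) -> np.ndarray:
    """Rotation matrix of a neighbor-derived frame for one atom.

    The frame co-rotates with the structure (axes built from the vectors to
    the nearest neighbors, ties broken by rounded distance then input
    order), which makes the sphere-point quadrature — and hence SASA —
    invariant under rigid motion of the whole system and identical across
    congruent symmetry copies.
    """
    e1 = None
    e2 = None
    for j in order:
        v = neigh_coords[j] - center
        nv = np.linalg.norm(v)
        if nv < 1e-9:
            continue
        v = v / nv
        if e1 is None:
            e1 = v
        else:
            w = v - np.dot(v, e1) * e1
            nw = np.linalg.norm(w)
            if nw > 1e-2:
                e2 = w / nw
                break
    if e1 is None:
        return np.eye(3)
    if e2 is None:
        # single (or colinear) neighborhood: burial is nearly symmetric
        # about e1; use a deterministic perpendicular
        helper = np.array([1.0, 0.0, 0.0])
        if abs(e1[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        e2 = np.cross(e1, helper)
        e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    return np.column_stack([e1, e2, e3])


def sasa_from_arrays(coords: np.ndarray, radii: np.ndarray,
                     probe_radius: float, n_pts: int,
                     subset: Optional[np.ndarray] = None) -> np.ndarray:
    """Shrake-Rupley areas; `subset` restricts which atoms are evaluated
    (all atoms still occlude).  Returns areas for the evaluated atoms in
    subset order (all atoms when subset is None)."""
    unit = spiral_sphere_points(n_pts)
    ext = radii + probe_radius
    tree = cKDTree(coords)
    max_ext = ext.max()
    eval_idx = np.arange(len(coords)) if subset is None \
        else np.asarray(subset, dtype=int)
    # one batched neighbor query (per-atom search radius)
    neigh_lists = tree.query_ball_point(coords[eval_idx],
                                        ext[eval_idx] + max_ext)
    areas = np.empty(len(eval_idx))
    full_sphere = 4.0 * np.pi
    for row, i in enumerate(eval_idx):
        neigh = [j for j in neigh_lists[row] if j != i]
        if not neigh:
            areas[row] = full_sphere * ext[i] ** 2
            continue
        nc = coords[neigh]
        nr2 = ext[np.array(neigh)] ** 2
        rel = nc - coords[i]
        d = np.sqrt(np.einsum("ij,ij->i", rel, rel))
        order = np.lexsort((np.arange(len(neigh)), np.round(d, 6)))
        frame = _local_frame(coords[i], nc, order)
        pts = ext[i] * (unit @ frame.T)
        # |p - rel_j|^2 = |p|^2 + |rel_j|^2 - 2 p.rel_j
        cross = pts @ rel.T
        d2 = (ext[i] ** 2 + (d * d)[None, :]) - 2.0 * cross
        buried = (d2 < nr2[None, :]).any(axis=1)
        n_acc = int(len(buried) - buried.sum())
        areas[row] = full_sphere * ext[i] ** 2 * n_acc / n_pts
    return areas


# --- contacts ------------------------------------------------------------------


def _different_operator(ca: str, cb: str) -> bool:
    base = lambda c: c.split("_")[0]
    op = lambda c: c.rsplit("_", 1)[1] if "_" in c else ""
    return op(ca) != op(cb)


def _scope_ok(scope, chain_a: str, chain_b: str) -> bool:
    if scope is None:
        return True
    if scope == "interchain":
        return chain_a != chain_b
    if scope == "interassembly":
        return _different_operator(chain_a, chain_b)
    if callable(scope):
        return bool(scope(chain_a, chain_b))
    raise ValueError(f"bad scope {scope!r}")


def _contact_atoms(structure: StructureModel, selector: Callable):
    """(coords, info) for atoms passing `selector(res, atom)`."""
    coords, info = [], []
    for chain in structure.chains:
        for res in chain.residues:
            for a in res.atoms:
                if a.is_hydrogen:
                    continue
                if selector(res, a):
                    coords.append(a.coords)
                    info.append((chain.id, res, a))
    return np.array(coords).reshape(-1, 3), info


def _antecedent(res, atom):
    """Nearest covalently-plausible heavy atom in the same residue."""
    best, best_d = None, 1.8
    for other in res.atoms:
        if other is atom or other.is_hydrogen:
            continue
        d = float(np.linalg.norm(other.coords - atom.coords))
        if d < best_d:
            best, best_d = other, d
    return best


def detect_hbonds(structure: StructureModel, scope=None,
                  params: Optional[SolvationParams] = None) -> list:
    """Geometric hydrogen bonds: N donors to O acceptors.

    Donor-acceptor distance <= cutoff (default 3.5 A) and, when the donor
    has a covalent antecedent, antecedent-donor-acceptor angle >= 120 deg.
    Intra-residue pairs are excluded.  `scope` filters chain pairs: None,
    'interchain', 'interassembly' (different symmetry-operator tags), or a
    predicate on two chain ids.
    """
    params = params or SolvationParams()
    don_xyz, donors = _contact_atoms(
        structure, lambda r, a: a.element.upper() == "N")
    acc_xyz, acceptors = _contact_atoms(
        structure, lambda r, a: a.element.upper() == "O")
    records = []
    if len(donors) == 0 or len(acceptors) == 0:
        return records
    tree = cKDTree(acc_xyz)
    for i, (cid, res, atom) in enumerate(donors):
        for j in sorted(tree.query_ball_point(don_xyz[i],
                                              params.hbond_cutoff)):
            a_cid, a_res, a_atom = acceptors[j]
            if a_res is res:
                continue
            if not _scope_ok(scope, cid, a_cid):
                continue
            ante = _antecedent(res, atom)
            if ante is not None:
                ang = angle_deg(ante.coords, atom.coords, a_atom.coords)
                if ang < params.hbond_min_angle:
                    continue
            d = float(np.linalg.norm(a_atom.coords - atom.coords))
            records.append(ContactRecord(
                "hbond",
                (cid, res.name, res.number, atom.name),
                (a_cid, a_res.name, a_res.number, a_atom.name),
                d, _different_operator(cid, a_cid)))
    return records


def detect_salt_bridges(structure: StructureModel, scope=None,
                        params: Optional[SolvationParams] = None) -> list:
    """Geometric salt bridges between side-chain charge centers.

    (Arg NH1/NH2/NE, Lys NZ, His ND1/NE2) against (Asp OD1/OD2,
    Glu OE1/OE2, C-terminal OXT), any-atom distance <= cutoff (default 4 A).
    """
    params = params or SolvationParams()

    def is_cation(r, a):
        return a.name in CATION_ATOMS.get(r.name, ())

    def is_anion(r, a):
        return a.name in ANION_ATOMS.get(r.name, ()) or a.name in ANION_EXTRA

    cat_xyz, cations = _contact_atoms(structure, is_cation)
    an_xyz, anions = _contact_atoms(structure, is_anion)
    records = []
    if len(cations) == 0 or len(anions) == 0:
        return records
    tree = cKDTree(an_xyz)
    for i, (cid, res, atom) in enumerate(cations):
        for j in sorted(tree.query_ball_point(cat_xyz[i],
                                              params.saltbridge_cutoff)):
            a_cid, a_res, a_atom = anions[j]
            if a_res is res:
                continue
            if not _scope_ok(scope, cid, a_cid):
                continue
            d = float(np.linalg.norm(a_atom.coords - atom.coords))
            records.append(ContactRecord(
                "saltbridge",
                (cid, res.name, res.number, atom.name),
                (a_cid, a_res.name, a_res.number, a_atom.name),
                d, _different_operator(cid, a_cid)))
    return records


# --- free energies --------------------------------------------------------------


def _solvation_energy(structure: StructureModel,
                      params: SolvationParams) -> tuple:
    """(sigma-weighted SASA sum, total SASA) over heavy protein atoms."""
    coords, radii, labels = _heavy_atom_table(structure)
    if len(coords) == 0:
        return 0.0, 0.0
    areas = sasa_from_arrays(coords, radii, params.probe_radius,
                             params.n_sphere_points)
    sigma = np.array([params.atomic_solvation[_atom_class(rn, an, el)]
                      for (_c, rn, _num, an, el) in labels])
    return float(sigma @ areas), float(areas.sum())


def structure_energy(structure: StructureModel,
                     params: Optional[SolvationParams] = None) -> float:
    """G of one state (kcal/mol): solvation + internal contact terms."""
    params = params or SolvationParams()
    if all(len(c.residues) == 0 for c in structure.chains):
        return 0.0
    g_solv, _ = _solvation_energy(structure, params)
    n_hb = len(detect_hbonds(structure, None, params))
    n_sb = len(detect_salt_bridges(structure, None, params))
    return (g_solv + params.hbond_energy * n_hb
            + params.saltbridge_energy * n_sb)


def _atom_multiset(structure: StructureModel):
    from collections import Counter
    return Counter((c.id.split("_")[0], r.number, r.name, a.name)
                   for c in structure.chains
                   for r in c.residues for a in r.atoms)


def association_free_energy(complex_structure: StructureModel,
                            components: Sequence[StructureModel],
                            params: Optional[SolvationParams] = None,
                            check_partition: bool = True
                            ) -> AssociationResult:
    """dG of forming `complex_structure` from `components` (kcal/mol).

    The components must partition the complex's protein atoms.  Negative
    total = association favoured.  The entropy term charges
    rigid_body_entropy once per association event, i.e. (N-1) times.
    """
    params = params or SolvationParams()
    n = len(components)
    if n == 0:
        raise StructureError("need at least one component")
    if check_partition:
        whole = _atom_multiset(complex_structure)
        parts = _atom_multiset(components[0])
        for comp in components[1:]:
            parts.update(_atom_multiset(comp))
        if whole != parts:
            raise StructureError(
                "components do not partition the complex "
                f"({sum(whole.values())} vs {sum(parts.values())} atoms)")

    g_solv_cx, sasa_cx = _solvation_energy(complex_structure, params)
    hb_cx = len(detect_hbonds(complex_structure, None, params))
    sb_cx = len(detect_salt_bridges(complex_structure, None, params))

    g_solv_parts, sasa_parts, hb_parts, sb_parts = 0.0, 0.0, 0, 0
    for comp in components:
        gs, sa = _solvation_energy(comp, params)
        g_solv_parts += gs
        sasa_parts += sa
        hb_parts += len(detect_hbonds(comp, None, params))
        sb_parts += len(detect_salt_bridges(comp, None, params))

    dg_solv = g_solv_cx - g_solv_parts
    n_hb = hb_cx - hb_parts
    n_sb = sb_cx - sb_parts
    dg_hb = params.hbond_energy * n_hb
    dg_sb = params.saltbridge_energy * n_sb
    dg_ent = (n - 1) * params.rigid_body_entropy
    return AssociationResult(
        dg_total=dg_solv + dg_hb + dg_sb + dg_ent,
        dg_solvation=dg_solv, dg_hbond=dg_hb, dg_saltbridge=dg_sb,
        dg_entropy=dg_ent, n_components=n,
        buried_area=max(0.0, sasa_parts - sasa_cx),
        n_hbonds=n_hb, n_saltbridges=n_sb)


def symmetric_structure_energy(structure: StructureModel,
                               params: SolvationParams,
                               n_copies: int,
                               rep_tag: str = "0") -> float:
    """G of an assembly of `n_copies` symmetry-equivalent units.

    Exploits exact point-group symmetry: every copy (chains tagged
    'id_<op>') contributes identically, so G = n_copies x the contribution
    of the copy tagged `rep_tag` evaluated in the full-assembly context.
    Exact because the SASA quadrature is rotation-covariant (per-atom local
    frames) and contact detection is purely metric.
    """
    coords, radii, labels = _heavy_atom_table(structure)
    tags = np.array([lab[0].rsplit("_", 1)[1] if "_" in lab[0] else ""
                     for lab in labels])
    subset = np.where(tags == rep_tag)[0]
    if len(subset) == 0:
        raise StructureError(f"no chains tagged _{rep_tag}")
    areas = sasa_from_arrays(coords, radii, params.probe_radius,
                             params.n_sphere_points, subset)
    sigma = np.array([params.atomic_solvation[_atom_class(lab[1], lab[3],
                                                          lab[4])]
                      for lab in (labels[i] for i in subset)])
    g_solv = n_copies * float(sigma @ areas)

    def rep_scope(donor_chain: str, _acceptor_chain: str) -> bool:
        return ("_" in donor_chain
                and donor_chain.rsplit("_", 1)[1] == rep_tag)

    n_hb = n_copies * len(detect_hbonds(structure, rep_scope, params))
    n_sb = n_copies * len(detect_salt_bridges(structure, rep_scope, params))
    return (g_solv + params.hbond_energy * n_hb
            + params.saltbridge_energy * n_sb)


def delta_delta_g(dg_mutant: float, dg_wildtype: float) -> float:
    """ddG = dG(mutant) - dG(wild type); positive = destabilising."""
    return dg_mutant - dg_wildtype


def cavity_waters(structure: StructureModel, site_residues,
                  capture_radius: float = 5.0) -> int:
    """Water oxygens within `capture_radius` of a site's side-chain center.

    `site_residues` is a list of (chain_id, residue_number) pairs; the site
    center is the geometric mean of their side-chain heavy atoms.
    """
    centers = []
    for chain_id, resnum in site_residues:
        chain = structure.chain(chain_id)
        res = chain.residue(resnum) if chain else None
        if res is None:
            raise StructureError(f"residue {chain_id}/{resnum} not found")
        atoms = res.sidechain_heavy_atoms() or res.heavy_atoms()
        centers.extend(a.coords for a in atoms)
    if not centers:
        raise StructureError("empty site selection")
    center = np.mean(np.array(centers), axis=0)
    count = 0
    for w in structure.waters:
        if w.element.upper() == "O" and \
                np.linalg.norm(w.coords - center) <= capture_radius:
            count += 1
    return count
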