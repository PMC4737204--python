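"""Crystallographic symmetry expansion and capsid assembly detection.

The body-centered cubic space group I23 has 24 proper operators: the 12
rotations of point group 23 (identity, three 2-folds along the cell axes,
eight 3-folds along the body diagonals), each combined with the centering
translations (0,0,0) and (1/2,1/2,1/2).  Applying them to an asymmetric
unit containing one pentamer regenerates the full unit cell: two
dodecahedral capsids of 12 pentamers each.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .constants import NEIGHBOR_DISTANCE_OVER_INRADIUS
from .structure_io import Chain, StructureModel, StructureError, UnitCell


class SpaceGroupError(ValueError):
    """Unknown or unsupported space-group symbol."""


# --- symmetry operators -----------------------------------------------------


@dataclass(frozen=True)
class SymOp:
    """Rotation + translation in the fractional-coordinate basis."""
    rotation: tuple          # 3x3 nested tuple
    translation: tuple       # length-3 tuple, components in [0, 1)

    @property
    def R(self) -> np.ndarray:
        return np.array(self.rotation, dtype=float)

    @property
    def t(self) -> np.ndarray:
        return np.array(self.translation, dtype=float)

    def compose(self, other: "SymOp") -> "SymOp":
        """self after other: x -> R_self (R_other x + t_other) + t_self."""
        r = self.R @ other.R
        t = (self.R @ other.t + self.t) % 1.0
        return SymOp(_mat_key(r), tuple(np.round(t, 9) % 1.0))

    def is_identity(self) -> bool:
        return (np.allclose(self.R, np.eye(3))
                and np.allclose(self.t, 0.0))


def _mat_key(m: np.ndarray) -> tuple:
    return tuple(tuple(int(round(x)) for x in row) for row in m)


def parse_symop(xyz: str) -> SymOp:
    """Parse an operator string like '-x,y+1/2,-z' into a SymOp."""
    rows = xyz.lower().replace(" ", "").split(",")
    if len(rows) != 3:
        raise SpaceGroupError(f"bad operator string: {xyz!r}")
    rot = np.zeros((3, 3))
    trans = np.zeros(3)
    axes = {"x": 0, "y": 1, "z": 2}
    for i, expr in enumerate(rows):
        # tokenize into signed terms
        expr = expr.replace("-", "+-")
        for term in filter(None, expr.split("+")):
            sign = -1.0 if term.startswith("-") else 1.0
            term = term.lstrip("-")
            if term in axes:
                rot[i, axes[term]] = sign
            elif "/" in term:
                num, den = term.split("/")
                trans[i] += sign * float(num) / float(den)
            elif term:
                trans[i] += sign * float(term)
    return SymOp(_mat_key(rot), tuple(np.round(trans % 1.0, 9)))


# the 12 proper rotations of point group 23 as xyz strings
_POINT_GROUP_23 = [
    "x,y,z", "-x,-y,z", "-x,y,-z", "x,-y,-z",
    "z,x,y", "z,-x,-y", "-z,-x,y", "-z,x,-y",
    "y,z,x", "-y,z,-x", "y,-z,-x", "-y,-z,x",
]


def space_group_operators(name, extra_ops: Optional[Sequence[str]] = None):
    """Symmetry operators for a space group (I23 built in).

    `name` may be 'I23' / 'I 2 3', or a list of xyz operator strings may be
    passed directly (either as `name` or via `extra_ops`).  For I23 the
    result is exactly 24 operators, identity first: the 12 rotations of
    point group 23 combined with the (0,0,0) and (1/2,1/2,1/2) centering
    translations.
    """
    if extra_ops is not None:
        return [parse_symop(s) for s in extra_ops]
    if isinstance(name, (list, tuple)):
        return [parse_symop(s) for s in name]
    symbol = str(name).replace(" ", "").upper()
    if symbol == "I23":
        ops = [parse_symop(s) for s in _POINT_GROUP_23]
        centering = SymOp(_mat_key(np.eye(3)), (0.5, 0.5, 0.5))
        return ops + [centering.compose(op) for op in ops]
    if symbol == "P1":
        return [parse_symop("x,y,z")]
    raise SpaceGroupError(
        f"unsupported space group {name!r}; pass explicit operator strings")


# --- applying operators ------------------------------------------------------


def apply_symop(structure: StructureModel, op: SymOp, cell: UnitCell,
                tag: Optional[int] = None,
                wrap: bool = False) -> StructureModel:
    """Return a copy of `structure` transformed by `op` in cell `cell`.

    Coordinates go orthogonal -> fractional -> (rotate, translate) ->
    orthogonal.  When `tag` is given, chain ids are suffixed '_<tag>'.
    With `wrap`, the copy is shifted by whole cells so the center of mass
    of each chain lands in [0,1)^3 fractional.
    """
    if cell is None:
        raise StructureError("apply_symop needs a unit cell")
    ortho = cell.orthogonalization_matrix()
    frac = cell.fractionalization_matrix()
    rot = op.R
    trans = op.t

    def transform(points: np.ndarray) -> np.ndarray:
        f = points @ frac.T
        f = f @ rot.T + trans
        return f @ ortho.T

    out = structure.copy()
    for chain in out.chains:
        coords = np.array([a.coords for a in chain.atoms()])
        new = transform(coords)
        if wrap:
            com_frac = frac @ new.mean(axis=0)
            shift = ortho @ (-np.floor(com_frac))
            new = new + shift
        for a, xyz in zip(chain.atoms(), new):
            a.coords = xyz
        if tag is not None:
            chain.id = f"{chain.id}_{tag}"
    if out.waters:
        coords = np.array([w.coords for w in out.waters])
        new = transform(coords)
        for w, xyz in zip(out.waters, new):
            w.coords = xyz
    return out


def expand_asymmetric_unit(structure: StructureModel,
                           operators: Optional[Sequence[SymOp]] = None
                           ) -> StructureModel:
    """Generate the full unit-cell contents from the asymmetric unit.

    One copy of every chain per operator, chain ids suffixed with the
    operator index, each copy wrapped so its chains' centers of mass lie in
    [0,1)^3 fractional.
    """
    cell = structure.unit_cell
    if cell is None:
        raise StructureError("expansion requires a unit cell")
    if operators is None:
        if structure.space_group is None:
            raise StructureError(
                "expansion requires a space group or explicit operators")
        operators = space_group_operators(structure.space_group)

    chains: list[Chain] = []
    waters = []
    for k, op in enumerate(operators):
        copy = apply_symop(structure, op, cell, tag=k, wrap=True)
        chains.extend(copy.chains)
        waters.extend(copy.waters)
    return StructureModel(chains, cell, structure.space_group, waters)


# --- assemblies ---------------------------------------------------------------


@dataclass
class Assembly:
    level: str                       # 'monomer' | 'pentamer' | 'capsid'
    members: list                    # chain ids (pentamer) / Assembly (capsid)
    com: np.ndarray = field(default_factory=lambda: np.zeros(3))

    @property
    def chain_ids(self) -> list:
        if self.level == "capsid":
            out = []
            for sub in self.members:
                out.extend(sub.chain_ids)
            return out
        return list(self.members)


@dataclass
class CapsidGeometry:
    inradius_r: float
    neighbor_distance_d_mean: float
    neighbor_distance_d_sd: float
    n_neighbor_pairs: int


def _min_image_diff(diff: np.ndarray, cell: Optional[UnitCell]) -> np.ndarray:
    if cell is None:
        return diff
    frac = cell.fractionalization_matrix()
    ortho = cell.orthogonalization_matrix()
    f = diff @ frac.T
    f -= np.round(f)
    return f @ ortho.T


def _chains_in_contact(coords_a, coords_b, cutoff, cell) -> bool:
    """Any heavy-atom pair within cutoff, minimum-image when cell given.

    The minimum image is resolved once per chain pair from the difference of
    the chain centroids — exact whenever chain extents are small relative to
    half the cell, which holds for protein chains in a capsid crystal.
    """
    if len(coords_a) == 0 or len(coords_b) == 0:
        return False
    if cell is not None:
        delta = coords_b.mean(axis=0) - coords_a.mean(axis=0)
        shift = _min_image_diff(delta[None, :], cell)[0] - delta
        coords_b = coords_b + shift
    ta = cKDTree(coords_a)
    counts = ta.query_ball_point(coords_b, cutoff, return_length=True)
    return bool(np.any(counts))


def _mass_weighted_com(structure: StructureModel, chain_ids,
                       cell: Optional[UnitCell] = None) -> np.ndarray:
    """Mass-weighted COM over protein heavy atoms of the given chains.

    Chains are wrapped into the cell individually during expansion, so with
    a cell present each chain COM is first unwrapped to the image nearest
    the first chain before averaging.
    """
    chain_coms, chain_masses = [], []
    for cid in chain_ids:
        chain = structure.chain(cid)
        coords, masses = [], []
        for a in chain.atoms():
            if not a.is_hydrogen:
                coords.append(a.coords)
                masses.append(a.mass)
        coords = np.array(coords)
        masses = np.array(masses)
        chain_coms.append(coords.T @ masses / masses.sum())
        chain_masses.append(masses.sum())
    coms = np.array(chain_coms)
    w = np.array(chain_masses)
    if cell is not None and len(coms) > 1:
        coms = coms[0] + _min_image_diff(coms - coms[0], cell)
    return coms.T @ w / w.sum()


def cluster_assemblies(structure: StructureModel, contact_cutoff: float = 4.5,
                       use_pbc: bool = True) -> list:
    """Group chains into pentamers and pentamers into capsids.

    Pentamer level: chains carrying a symmetry-operator tag (expanded
    copies named 'id_opindex') are grouped by tag — the asymmetric unit is
    one pentamer by construction, so each operator copy is one pentamer.
    Untagged chains fall back to connected components of the heavy-atom
    contact graph at `contact_cutoff`.

    Capsid level: connected components of the pentamer contact graph (any
    heavy-atom pair across two pentamers within the cutoff, minimum-image
    convention when `use_pbc` and a cell is present).

    Returns pentamer assemblies followed by capsid assemblies.
    """
    if contact_cutoff <= 0:
        raise ValueError("contact cutoff must be positive")
    cell = structure.unit_cell if use_pbc else None

    # --- pentamer level
    groups: dict = {}
    untagged = []
    for chain in sorted(structure.chains, key=lambda c: c.id):
        op = chain.operator_index
        if op is None:
            untagged.append(chain)
        else:
            groups.setdefault(op, []).append(chain.id)
    pentamer_groups = [groups[k] for k in sorted(groups)]

    if untagged:
        coords = {c.id: c.heavy_coords() for c in untagged}
        ids = [c.id for c in untagged]
        parent = {i: i for i in ids}

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for a, b in itertools.combinations(ids, 2):
            if _chains_in_contact(coords[a], coords[b], contact_cutoff, cell):
                parent[find(a)] = find(b)
        comp: dict = {}
        for i in ids:
            comp.setdefault(find(i), []).append(i)
        pentamer_groups.extend(comp[k] for k in sorted(comp))

    pentamers = [Assembly("pentamer", sorted(g),
                          _mass_weighted_com(structure, g, cell))
                 for g in pentamer_groups]

    # --- capsid level: pentamer pairs touch if any chain pair touches
    chain_coords = {c.id: c.heavy_coords() for c in structure.chains}
    chain_extent = max((np.ptp(v, axis=0).max() for v in
                        chain_coords.values() if len(v)), default=0.0)
    n = len(pentamers)
    parent2 = list(range(n))

    def find2(i):
        while parent2[i] != i:
            parent2[i] = parent2[parent2[i]]
            i = parent2[i]
        return i

    def pentamers_touch(pa: Assembly, pb: Assembly) -> bool:
        for ca in pa.members:
            for cb in pb.members:
                a, b = chain_coords[ca], chain_coords[cb]
                if len(a) == 0 or len(b) == 0:
                    continue
                d = _min_image_diff(
                    (b.mean(axis=0) - a.mean(axis=0))[None, :], cell)[0]
                if np.linalg.norm(d) > chain_extent + contact_cutoff:
                    continue
                if _chains_in_contact(a, b, contact_cutoff, cell):
                    return True
        return False

    for i, j in itertools.combinations(range(n), 2):
        if pentamers_touch(pentamers[i], pentamers[j]):
            parent2[find2(i)] = find2(j)
    comp2: dict = {}
    for i in range(n):
        comp2.setdefault(find2(i), []).append(i)
    capsids = []
    for key in sorted(comp2):
        members = [pentamers[i] for i in comp2[key]]
        coms = np.array([m.com for m in members])
        if cell is not None and len(members) > 1:
            # unwrap pentamer centers around the first member before averaging
            ref = coms[0]
            coms = ref + _min_image_diff(coms - ref, cell)
        capsids.append(Assembly("capsid", members, coms.mean(axis=0)))
    return pentamers + capsids


def capsid_pentamer_coms(structure: StructureModel, capsid: Assembly,
                         unwrap: bool = True) -> np.ndarray:
    """Pentamer centers of one capsid, unwrapped to a common image."""
    coms = np.array([m.com for m in capsid.members])
    cell = structure.unit_cell
    if unwrap and cell is not None and len(coms) > 1:
        ref = coms[0]
        coms = ref + _min_image_diff(coms - ref, cell)
    return coms


def capsid_inradius(pentamer_coms: np.ndarray) -> CapsidGeometry:
    """Capsid inradius from neighboring pentamer center-of-mass distances.

    Each pentamer's neighbors are its 5 nearest other centers (robust to
    breathing distortion); deduplicated pairs give 30 for a complete
    capsid.  With adjacent dodecahedron face normals subtending
    arccos(1/sqrt(5)), centers at inradius r give neighbor distance
    d = 2 r sin(arccos(1/sqrt(5)) / 2), inverted here.
    """
    coms = np.asarray(pentamer_coms, dtype=float)
    if len(coms) < 2:
        raise StructureError("need at least 2 pentamer centers")
    n = len(coms)
    dists = np.linalg.norm(coms[:, None, :] - coms[None, :, :], axis=-1)
    np.fill_diagonal(dists, np.inf)
    k = min(5, n - 1)
    pairs = set()
    for i in range(n):
        for j in np.argsort(dists[i])[:k]:
            pairs.add((min(i, int(j)), max(i, int(j))))
    pair_d = np.array(sorted(dists[i, j] for i, j in pairs))
    d_mean = float(pair_d.mean())
    d_sd = float(pair_d.std(ddof=0))
    r = d_mean / NEIGHBOR_DISTANCE_OVER_INRADIUS
    return CapsidGeometry(r, d_mean, d_sd, len(pairs))


def cell_volume(cell: UnitCell) -> float:
    """Unit-cell volume in cubic angstroms (triclinic formula)."""
    return cell.volume()


def assembly_inventory(structure: StructureModel, assemblies) -> str:
    """Tab-separated inventory of assemblies (id, level, members, COM, r)."""
    lines = ["#assembly_id\tlevel\tn_members\tmember_chains\tcom_x\tcom_y"
             "\tcom_z\tinradius"]
    for k, a in enumerate(assemblies):
        radius = ""
        if a.level == "capsid" and len(a.members) >= 2:
            coms = capsid_pentamer_coms(structure, a)
            radius = f"{capsid_inradius(coms).inradius_r:.3f}"
        members = ",".join(a.chain_ids if a.level != "capsid"
                           else [f"p{i}" for i in range(len(a.members))])
        lines.append(f"{k}\t{a.level}\t{len(a.members)}\t{members}"
                     f"\t{a.com[0]:.3f}\t{a.com[1]:.3f}\t{a.com[2]:.3f}"
                     f"\t{radius}")
    return "\n".join(lines) + "\n"
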