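"""In-place point mutagenesis with rotamer repacking.

Mutant side chains are rebuilt from ideal internal geometry on the fixed
backbone; the rotamer is chosen to minimise a soft-sphere clash score plus
a -log(prior weight) term, and neighbouring side chains within the repack
radius are then re-optimised greedily (in order of decreasing clash) until
no single-residue change improves the total, with a sweep cap.  Everything
is deterministic: same structure + library -> same output.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .constants import AA_1TO3, AA_3TO1, VDW_RADII
from .structure_io import Residue, StructureModel
from .templates import N_CHI, RotamerLibrary, build_sidechain

logger = logging.getLogger(__name__)

#: soft-sphere scale: overlap counts below 0.8 * (r_i + r_j)
CLASH_SCALE = 0.8
#: weight of the rotamer prior relative to the clash term (kcal-ish units)
PRIOR_WEIGHT = 0.1
#: squared-overlap total below which a rotamer counts as clash-free
#: (allows one sub-0.25 A soft contact rather than warning on every
#: close-packed interface)
CLASH_FREE_TOL = 0.05


class MutationError(ValueError):
    """Malformed mutation spec or wild-type mismatch."""


@dataclass
class Mutation:
    wt_residue: str        # 1-letter
    position: int          # author numbering
    new_residue: str       # 1-letter
    all_chains: bool = True

    @property
    def wt_resname(self) -> str:
        return AA_1TO3[self.wt_residue]

    @property
    def new_resname(self) -> str:
        return AA_1TO3[self.new_residue]

    def __str__(self) -> str:
        return f"{self.wt_residue}{self.position}{self.new_residue}"


_SPEC_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


def parse_mutation_spec(spec: str) -> Mutation:
    """Parse 'R40E'-style mutation strings (wild type, position, new)."""
    m = _SPEC_RE.match(spec.strip())
    if not m:
        raise MutationError(f"malformed mutation spec {spec!r} "
                            "(expected e.g. 'R40E')")
    wt, pos, new = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
    for code in (wt, new):
        if code not in AA_1TO3:
            raise MutationError(
                f"{spec!r}: {code!r} is not a standard amino acid")
    return Mutation(wt, pos, new)


def parse_mutation_list(specs: str) -> list:
    """Parse a comma-separated list of mutation specs ('R40E,H41E')."""
    return [parse_mutation_spec(s) for s in specs.split(",") if s.strip()]


# --- repacking machinery -----------------------------------------------------


def _residue_key(chain_id: str, resnum: int) -> tuple:
    return (chain_id, resnum)


class _Repacker:
    """Holds the coordinate state during mutation + repacking."""

    def __init__(self, structure: StructureModel, library: RotamerLibrary,
                 repack_radius: float):
        self.structure = structure
        self.library = library
        self.radius = repack_radius
        self.warnings: list[str] = []

    # -- clash scoring

    def _context(self, chain_id: str, resnum: int):
        """Coordinates + radii of all heavy atoms except the residue's own."""
        coords, radii = [], []
        for chain in self.structure.chains:
            for res in chain.residues:
                if chain.id == chain_id and res.number == resnum:
                    continue
                for a in res.atoms:
                    if a.is_hydrogen:
                        continue
                    coords.append(a.coords)
                    radii.append(VDW_RADII.get(a.element.upper(), 1.7))
        return np.array(coords).reshape(-1, 3), np.array(radii)

    @staticmethod
    def _clash(sidechain_atoms, ctx_coords, ctx_radii) -> float:
        """Sum of squared soft-sphere overlaps of side-chain heavy atoms."""
        if len(ctx_coords) == 0:
            return 0.0
        score = 0.0
        for a in sidechain_atoms:
            if a.is_hydrogen:
                continue
            r_a = VDW_RADII.get(a.element.upper(), 1.7)
            d = np.linalg.norm(ctx_coords - a.coords, axis=1)
            thresh = CLASH_SCALE * (r_a + ctx_radii)
            over = np.maximum(0.0, thresh - d)
            score += float((over ** 2).sum())
        return score

    def residue_clash(self, chain_id: str, resnum: int) -> float:
        chain = self.structure.chain(chain_id)
        res = chain.residue(resnum)
        ctx_coords, ctx_radii = self._context(chain_id, resnum)
        side = [a for a in res.atoms
                if a.name not in ("N", "CA", "C", "O", "OXT")]
        return self._clash(side, ctx_coords, ctx_radii)

    # -- rotamer optimisation

    def best_rotamer(self, chain_id: str, resnum: int) -> tuple:
        """(best_chis, best_score, clash_free) by exhaustive enumeration."""
        chain = self.structure.chain(chain_id)
        res = chain.residue(resnum)
        rotamers = self.library.for_residue(res.name)
        ctx_coords, ctx_radii = self._context(chain_id, resnum)
        best = None   # (score, chis, clash)
        for chis, weight in rotamers:
            build_sidechain(res, chis)
            side = [a for a in res.atoms
                    if a.name not in ("N", "CA", "C", "O", "OXT")]
            clash = self._clash(side, ctx_coords, ctx_radii)
            score = clash - PRIOR_WEIGHT * math.log(max(weight, 1e-12))
            if best is None or score < best[0] - 1e-12:
                best = (score, chis, clash)
        return best[1], best[0], best[2] <= CLASH_FREE_TOL

    def optimise_residue(self, chain_id: str, resnum: int) -> float:
        chis, score, clash_free = self.best_rotamer(chain_id, resnum)
        chain = self.structure.chain(chain_id)
        res = chain.residue(resnum)
        build_sidechain(res, chis)
        if not clash_free:
            msg = (f"{chain_id}/{res.name}{resnum}: no clash-free rotamer; "
                   "keeping best-effort conformation")
            if msg not in self.warnings:
                self.warnings.append(msg)
                logger.warning(msg)
        return score

    def neighbors_with_sidechains(self, chain_id: str, resnum: int) -> list:
        """Residues whose side chains fall within the repack radius."""
        chain = self.structure.chain(chain_id)
        res = chain.residue(resnum)
        center_atoms = [a.coords for a in res.atoms
                        if a.name not in ("N", "CA", "C", "O", "OXT")]
        if not center_atoms:
            center_atoms = [a.coords for a in res.atoms]
        center = np.array(center_atoms)
        tree = cKDTree(center)
        out = []
        for ch in self.structure.chains:
            for r in ch.residues:
                if ch.id == chain_id and r.number == resnum:
                    continue
                if N_CHI.get(r.name, 0) == 0:
                    continue
                side = [a.coords for a in r.sidechain_heavy_atoms()]
                if not side:
                    continue
                if np.any(tree.query_ball_point(np.array(side), self.radius,
                                                return_length=True)):
                    out.append((ch.id, r.number))
        return out


def build_mutant(structure: StructureModel, mutations: Sequence[Mutation],
                 library: Optional[RotamerLibrary] = None,
                 repack_radius: float = 6.0,
                 max_sweeps: int = 10) -> StructureModel:
    """Apply point mutations, choosing rotamers and repacking neighbours.

    Mutations apply to every chain by default (homopentamer convention).
    The wild-type residue is validated at each position first; the backbone
    is never moved.  Identity mutations (e.g. R40R) leave coordinates
    untouched.
    """
    library = library or RotamerLibrary.default()
    out = structure.copy()

    # validate everything before touching coordinates
    targets = []
    for mut in mutations:
        chains = out.chains if mut.all_chains else out.chains[:1]
        for chain in chains:
            res = chain.residue(mut.position)
            if res is None:
                raise MutationError(
                    f"chain {chain.id} has no residue {mut.position}")
            found = AA_3TO1.get(res.name, "?")
            if found != mut.wt_residue:
                raise MutationError(
                    f"wild-type mismatch at {chain.id}/{mut.position}: "
                    f"expected {mut.wt_residue}, found {found} ({res.name})")
            if mut.new_residue != mut.wt_residue:
                targets.append((chain.id, mut.position, mut.new_resname))

    if not targets:
        return out

    repacker = _Repacker(out, library, repack_radius)

    for chain_id, resnum, new_resname in targets:
        chain = out.chain(chain_id)
        res = chain.residue(resnum)
        res.name = new_resname
        # strip to backbone; build_sidechain rebuilds CB and beyond
        repacker.optimise_residue(chain_id, resnum)

    # iterative neighbour repacking, greediest first
    neighbor_set: dict = {}
    for chain_id, resnum, _ in targets:
        for key in repacker.neighbors_with_sidechains(chain_id, resnum):
            neighbor_set[key] = True
    neighbors = sorted(neighbor_set)

    for _sweep in range(max_sweeps):
        improved = False
        clashes = sorted(((repacker.residue_clash(c, r), c, r)
                          for c, r in neighbors), reverse=True)
        for clash, chain_id, resnum in clashes:
            if clash <= 0.0:
                continue
            before = repacker.residue_clash(chain_id, resnum)
            repacker.optimise_residue(chain_id, resnum)
            after = repacker.residue_clash(chain_id, resnum)
            if after < before - 1e-9:
                improved = True
        if not improved:
            break

    out.mutation_warnings = list(repacker.warnings)  # type: ignore[attr-defined]
    return out
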