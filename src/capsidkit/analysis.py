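"""Per-trajectory observables and ensemble statistics.

RMSD/RMSF of conformational ensembles, equilibration detection on RMSD
series, capsid radius time series, isothermal compressibility from
unit-cell volume fluctuations, and the per-variant dG statistics that feed
the capsid/pentamer classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .constants import A3_TO_M3, INV_PA_TO_INV_GPA, KB_J_K
from .structure_io import StructureModel, StructureError, TrajectoryFrame


class AnalysisError(ValueError):
    pass


@dataclass
class SeriesStats:
    mean: float
    sd: float
    min: float
    max: float
    bin_edges: np.ndarray
    counts: np.ndarray
    modal_bin_center: float


@dataclass
class CompressibilityResult:
    chi_T: float          # GPa^-1
    mean_volume: float    # A^3
    temperature: float    # K
    n_frames: int


@dataclass
class VariantReport:
    name: str
    mutations: str
    dg_stats: SeriesStats
    ddg_vs_wt: float
    predicted_state: str                  # 'capsid' | 'pentamer'
    experimental_state: Optional[str] = None
    dg_monomer_stats: Optional[SeriesStats] = None
    n_frames: int = 0
    warning: str = ""

    @property
    def disagrees(self) -> bool:
        return (self.experimental_state is not None
                and self.experimental_state != self.predicted_state)


# --- structural observables -----------------------------------------------


def _select_coords(structure: StructureModel, selection) -> np.ndarray:
    """Coordinates of atoms passing the selection.

    `selection` is an atom-name string ('CA'), a set of names, a predicate
    on (chain, residue, atom), or None for all heavy atoms.
    """
    coords = []
    for chain in structure.chains:
        for res in chain.residues:
            for a in res.atoms:
                if a.is_hydrogen:
                    continue
                if selection is None:
                    keep = True
                elif isinstance(selection, str):
                    keep = a.name == selection
                elif isinstance(selection, (set, frozenset)):
                    keep = a.name in selection
                elif callable(selection):
                    keep = selection(chain, res, a)
                else:
                    raise AnalysisError(f"bad selection {selection!r}")
                if keep:
                    coords.append(a.coords)
    return np.array(coords).reshape(-1, 3)


def superpose_rmsd(reference: StructureModel, mobile: StructureModel,
                   selection="CA") -> float:
    """RMSD after optimal (Kabsch) rigid superposition of the selection."""
    from .geometry import kabsch
    ref = _select_coords(reference, selection)
    mob = _select_coords(mobile, selection)
    if ref.shape != mob.shape:
        raise AnalysisError(
            f"selection size mismatch: {len(ref)} vs {len(mob)} atoms")
    if len(ref) == 0:
        raise AnalysisError("empty selection")
    _, _, rmsd = kabsch(ref, mob)
    return rmsd


def superpose_frames(frames: Sequence[TrajectoryFrame],
                     selection="CA") -> list:
    """Frames rigidly superposed onto frame 0 over the selection."""
    from .geometry import kabsch
    ref = _select_coords(frames[0].structure, selection)
    out = []
    for f in frames:
        mob = _select_coords(f.structure, selection)
        rot, t, _ = kabsch(ref, mob)
        snap = f.structure.copy()
        for a in list(snap.atoms()) + list(snap.waters):
            a.coords = rot @ a.coords + t
        out.append(TrajectoryFrame(f.index, snap, f.cell))
    return out


def rmsf(frames: Sequence[TrajectoryFrame], selection=None) -> np.ndarray:
    """Per-residue RMSF (angstrom) about the time-average structure.

    Frames must already be superposed onto frame 0.  Per-atom root mean
    squared deviations from the mean position are averaged within each
    residue; residues follow the first frame's chain order.
    """
    if len(frames) < 2:
        raise AnalysisError("RMSF needs at least 2 frames")

    def atom_rows(structure):
        rows, owner = [], []
        ridx = 0
        for chain in structure.chains:
            for res in chain.residues:
                for a in res.atoms:
                    if a.is_hydrogen:
                        continue
                    if selection is None or a.name == selection or (
                            callable(selection)
                            and selection(chain, res, a)):
                        rows.append(a.coords)
                        owner.append(ridx)
                ridx += 1
        return np.array(rows), np.array(owner)

    coords = []
    owner = None
    for f in frames:
        rows, own = atom_rows(f.structure)
        coords.append(rows)
        owner = own
    coords = np.array(coords)                       # (T, A, 3)
    mean = coords.mean(axis=0)
    msd = ((coords - mean) ** 2).sum(axis=2).mean(axis=0)
    atom_rmsf = np.sqrt(msd)
    n_res = owner.max() + 1
    out = np.zeros(n_res)
    for r in range(n_res):
        sel = owner == r
        out[r] = atom_rmsf[sel].mean() if sel.any() else 0.0
    return out


def detect_equilibration(rmsd_series: Sequence[float],
                         slope_tol: float = 1e-3,
                         window_frac: float = 0.25) -> int:
    """First index whose trailing series is flat (production start).

    Returns the smallest i such that the least-squares slope of
    series[i:] has magnitude <= slope_tol (angstrom per frame), requiring
    at least `window_frac` of the series to remain.  0 means the whole
    series qualifies; a series that never flattens raises.
    """
    y = np.asarray(rmsd_series, dtype=float)
    n = len(y)
    if n < 20:
        raise AnalysisError("equilibration detection needs >= 20 points")
    window = max(5, int(round(window_frac * n)))
    for i in range(0, n - window + 1):
        tail = y[i:]
        x = np.arange(len(tail), dtype=float)
        slope = np.polyfit(x, tail, 1)[0]
        if abs(slope) <= slope_tol:
            return i
    raise AnalysisError("no plateau found in RMSD series")


def radius_series(frames: Sequence[TrajectoryFrame],
                  expand: bool = True) -> np.ndarray:
    """Capsid inradius per frame (angstrom).

    Frames holding an asymmetric unit are expanded with their own cell and
    space group; capsid membership (the set of symmetry-operator tags of
    one capsid) is fixed from frame 0.
    """
    from .symmetry import (capsid_inradius, capsid_pentamer_coms,
                           cluster_assemblies, expand_asymmetric_unit)
    if not frames:
        raise AnalysisError("no frames")

    membership: Optional[list] = None
    radii = []
    for f in frames:
        s = f.structure
        if expand and all(c.operator_index is None for c in s.chains):
            s = StructureModel(s.chains, f.cell, s.space_group, s.waters)
            s = expand_asymmetric_unit(s)
        assemblies = cluster_assemblies(s)
        capsids = [a for a in assemblies if a.level == "capsid"]
        if not capsids:
            raise AnalysisError(f"frame {f.index}: no capsid found")
        def tags(a):
            return sorted({c.split("_")[1] for c in a.chain_ids
                           if "_" in c})

        if membership is None:
            cap = max(capsids, key=lambda a: len(a.members))
            if len(cap.members) < 2:
                raise StructureError(
                    f"frame {f.index}: capsid has fewer than 2 pentamers")
            membership = tags(cap)
        else:
            if membership:
                cap = next((a for a in capsids
                            if tags(a) == membership), None)
            else:
                cap = max(capsids, key=lambda a: len(a.members))
            if cap is None:
                raise AnalysisError(
                    f"frame {f.index}: frame-0 capsid not found")
        coms = capsid_pentamer_coms(s, cap)
        radii.append(capsid_inradius(coms).inradius_r)
    return np.array(radii)


def compressibility(volumes: Sequence[float],
                    temperature: float) -> CompressibilityResult:
    """Isothermal compressibility from volume fluctuations.

    chi_T = <dV^2> / (kB T <V>), volumes in A^3, result in GPa^-1.
    """
    v = np.asarray(volumes, dtype=float)
    if len(v) < 2:
        raise AnalysisError("need at least 2 volumes")
    if np.any(v <= 0) or temperature <= 0:
        raise AnalysisError("volumes and temperature must be positive")
    var_m6 = v.var(ddof=1) * A3_TO_M3 ** 2
    chi_pa = var_m6 / (KB_J_K * temperature * v.mean() * A3_TO_M3)
    return CompressibilityResult(chi_T=chi_pa * INV_PA_TO_INV_GPA,
                                 mean_volume=float(v.mean()),
                                 temperature=temperature, n_frames=len(v))


# --- dG statistics and classification ------------------------------------------


def ensemble_dg_stats(dg_series: Sequence[float],
                      n_bins: int = 30) -> SeriesStats:
    """Mean/SD/extrema/histogram of a per-frame dG series.

    Equal-width bins span [min, max]; the modal bin center is the center of
    the highest-count bin, leftmost on ties.
    """
    y = np.asarray(dg_series, dtype=float)
    if len(y) == 0:
        raise AnalysisError("empty series")
    lo, hi = float(y.min()), float(y.max())
    if hi == lo:
        hi = lo + 1e-9
    counts, edges = np.histogram(y, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    modal = float(centers[int(np.argmax(counts))])
    return SeriesStats(mean=float(y.mean()),
                       sd=float(y.std(ddof=0)) if len(y) > 1 else 0.0,
                       min=lo, max=float(y.max()),
                       bin_edges=edges, counts=counts,
                       modal_bin_center=modal)


def classify_variant(ddg_vs_wt: float, threshold: float = 100.0) -> str:
    """'capsid' if the destabilisation stays within the threshold.

    ddG <= threshold (inclusive) predicts the capsid state; larger
    destabilisation predicts dissociation into pentamers.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return "capsid" if ddg_vs_wt <= threshold else "pentamer"
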