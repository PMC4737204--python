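#!/usr/bin/env python
"""Wild-type capsid dynamics: breathing, RMSD/RMSF, volume fluctuations.

Generates a breathing ensemble of the wild-type pentamer (2% radial
amplitude, per-atom thermal noise), then measures the observables a
constant-pressure capsid simulation provides: the capsid-radius time
series, Calpha RMSD against the first frame, per-residue RMSF, and the
isothermal compressibility encoded in unit-cell volume fluctuations.

Writes: results/wt_radius_series.tsv, results/wt_rmsf.tsv,
        results/wt_compressibility.tsv
"""

from pathlib import Path

import numpy as np

from capsidkit.analysis import (compressibility, radius_series, rmsf,
                                superpose_frames, superpose_rmsd)
from capsidkit.ensemble_synth import (EnsembleParams, generate_ensemble,
                                      generate_toy_capsid,
                                      generate_volume_series)

OUT = Path("results")
OUT.mkdir(exist_ok=True)
SEED = 2026

asu = generate_toy_capsid()
frames = generate_ensemble(asu, EnsembleParams(
    n_frames=150, breathing_amplitude=0.02, atomic_noise_sd=0.15,
    seed=SEED))

radii = radius_series(frames)
rmsds = [superpose_rmsd(frames[0].structure, f.structure, "CA")
         for f in frames]
rows = ["#frame\tradius_A\tcell_a_A\trmsd_ca_A"]
rows += [f"{f.index}\t{r:.4f}\t{f.cell.a:.4f}\t{d:.4f}"
         for f, r, d in zip(frames, radii, rmsds)]
(OUT / "wt_radius_series.tsv").write_text("\n".join(rows) + "\n")
cv = radii.std(ddof=1) / radii.mean()
print(f"capsid radius {radii.mean():.2f} A, CV {cv:.4f} "
      f"(breathing amplitude injected: 0.02); "
      f"max Calpha RMSD {max(rmsds):.2f} A")

per_res = rmsf(superpose_frames(frames))
rows = ["#chain\tresidue\trmsf_A"]
i = 0
for chain in asu.chains:
    for res in chain.residues:
        rows.append(f"{chain.id}\t{res.number}\t{per_res[i]:.4f}")
        i += 1
(OUT / "wt_rmsf.tsv").write_text("\n".join(rows) + "\n")
print(f"per-residue RMSF range {per_res.min():.3f}-{per_res.max():.3f} A "
      "(uniform by construction: no per-residue profile injected)")

# compressibility from volume fluctuations at the reported capsid value
chi_inject = 0.3     # GPa^-1
vols = generate_volume_series(180.56 ** 3, chi_inject, 300.0, 10_000,
                              seed=SEED)
res = compressibility(vols, 300.0)
(OUT / "wt_compressibility.tsv").write_text(
    "#chi_injected_gpa\tchi_estimated_gpa\tmean_volume_A3\tn\n"
    f"{chi_inject}\t{res.chi_T:.5f}\t{res.mean_volume:.1f}\t{res.n_frames}\n")
print(f"compressibility: injected {chi_inject} GPa^-1, "
      f"recovered {res.chi_T:.4f} GPa^-1 from {res.n_frames} volumes")
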