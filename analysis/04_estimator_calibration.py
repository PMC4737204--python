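#!/usr/bin/env python
"""Calibration of the fluctuation estimators on synthetic ground truth.

Round-trips the compressibility estimator over a grid of injected values
and replicate seeds, and the RMSF estimator against an injected
per-residue mobility profile.

Writes: results/compressibility_calibration.tsv, results/rmsf_recovery.tsv
"""

from pathlib import Path

import numpy as np
from scipy.stats import spearmanr

from capsidkit.analysis import compressibility, rmsf, superpose_frames
from capsidkit.ensemble_synth import (EnsembleParams, generate_ensemble,
                                      generate_toy_capsid,
                                      generate_volume_series)

OUT = Path("results")
OUT.mkdir(exist_ok=True)
SEED = 2026
N, T, V0 = 10_000, 300.0, 180.56 ** 3

rows = ["#chi_injected_gpa\tchi_mean_gpa\tchi_sd_gpa\tn_seeds\tn_frames"]
for chi in (0.1, 0.3, 1.0):
    est = [compressibility(
        generate_volume_series(V0, chi, T, N, seed=SEED + 13 * k), T).chi_T
        for k in range(20)]
    rows.append(f"{chi}\t{np.mean(est):.5f}\t{np.std(est, ddof=1):.5f}"
                f"\t20\t{N}")
    print(f"chi {chi} GPa^-1 -> {np.mean(est):.4f} +- "
          f"{np.std(est, ddof=1):.4f} over 20 seeds")
(OUT / "compressibility_calibration.tsv").write_text("\n".join(rows) + "\n")

profile = [0.5, 1.0, 2.0, 1.5, 3.0]
asu = generate_toy_capsid()
frames = generate_ensemble(asu, EnsembleParams(
    n_frames=1000, breathing_amplitude=0.0, atomic_noise_sd=0.15,
    rmsf_profile=profile, seed=SEED))
values = rmsf(superpose_frames(frames))
injected = np.tile(profile, 5)
rho = spearmanr(injected, values).statistic
rows = ["#chain_pos\tinjected_scale\tmeasured_rmsf_A"]
rows += [f"{i % 5 + 1}\t{injected[i]}\t{values[i]:.4f}"
         for i in range(len(values))]
(OUT / "rmsf_recovery.tsv").write_text("\n".join(rows) + "\n")
print(f"RMSF profile recovery: rank correlation {rho:.4f} "
      f"over {len(values)} residues (1000 frames)")
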