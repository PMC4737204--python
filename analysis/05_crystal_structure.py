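#!/usr/bin/env python
"""Crystal-structure geometry for a user-supplied capsid asymmetric unit.

Runs the same expansion/clustering/geometry pipeline as the synthetic
system on a real PDB entry — intended for the lumazine-synthase pentamer
asymmetric unit (PDB 1NQU, space group I23, cubic cell 180.56 A), which is
not redistributed here.  Download it first, e.g.:

    curl -o data/1NQU.pdb https://files.rcsb.org/download/1NQU.pdb

Writes: results/crystal_geometry.tsv (when the input is available)
"""

import sys
from pathlib import Path

from capsidkit.structure_io import read_pdb
from capsidkit.symmetry import (capsid_inradius, capsid_pentamer_coms,
                                cluster_assemblies, expand_asymmetric_unit)

OUT = Path("results")
OUT.mkdir(exist_ok=True)

path = Path(sys.argv[1]) if len(sys.argv) > 1 else Path("data/1NQU.pdb")
if not path.exists():
    print(f"{path} not found - supply a capsid asymmetric unit PDB "
          "(see the docstring); nothing to do")
    sys.exit(0)

s = read_pdb(path)
print(f"{path.name}: {len(s.chains)} chains, "
      f"{s.n_atoms(include_waters=False)} protein atoms, "
      f"cell {s.unit_cell.a:.2f} A, space group {s.space_group}")

full = expand_asymmetric_unit(s)
assemblies = cluster_assemblies(full)
pentamers = [a for a in assemblies if a.level == "pentamer"]
capsids = [a for a in assemblies if a.level == "capsid"]
print(f"expansion: {len(full.chains)} chains -> {len(pentamers)} pentamers "
      f"-> {len(capsids)} capsids of {[len(c.members) for c in capsids]}")

rows = ["#capsid\tn_pentamers\tinradius_A\td_mean_A\td_sd_A\tmass_mda"]
mass_mda = 12 * s.protein_mass() / 1e6      # 12 pentamers = 60 monomers
for k, cap in enumerate(capsids):
    geo = capsid_inradius(capsid_pentamer_coms(full, cap))
    rows.append(f"{k}\t{len(cap.members)}\t{geo.inradius_r:.3f}\t"
                f"{geo.neighbor_distance_d_mean:.3f}\t"
                f"{geo.neighbor_distance_d_sd:.3f}\t{mass_mda:.3f}")
    print(f"capsid {k}: inradius {geo.inradius_r:.2f} A "
          f"({geo.n_neighbor_pairs} neighbour pairs), "
          f"60-mer mass {mass_mda:.2f} MDa")
(OUT / "crystal_geometry.tsv").write_text("\n".join(rows) + "\n")
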