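# Methods

## The procedure

The pipeline treats capsid stability as an ensemble property. For each
variant it (1) builds the mutant pentamer on the fixed backbone, (2)
generates a conformational ensemble of the asymmetric unit, (3) regenerates
one complete capsid per frame by applying the 12 point-group rotations of
I23 (the crystal's body-centering translation only adds the second, identical
capsid and is skipped when scoring), (4) scores the association free energy
at two partition levels — capsid → 12 pentamers and pentamer → 5 monomers —
(5) drops pre-plateau frames found by the RMSD equilibration detector, and
(6) summarises mean ± SD, ΔΔG against wild type, and the predicted
oligomeric state. Averaging over the ensemble, not scoring a single
structure, is the point: per-frame ΔG varies far more than the underlying
conformations do, and only the ensemble mean orders variants reliably.

## The energy model

G(structure) = Σ σ(class)·SASA + E_hb·n_hbonds + E_sb·n_saltbridges, and
ΔG_assoc = G(complex) − Σ G(components) + (N−1)·S_rb. Defaults:

| parameter | value | meaning |
|---|---|---|
| σ(C,S) | +0.016 kcal·mol⁻¹·Å⁻² | burying apolar area is rewarded |
| σ(neutral N,O) | −0.006 | mild penalty for burying polar area |
| σ(charged N,O) | −0.024 | strong penalty for burying charge |
| E_hb | −0.5 kcal·mol⁻¹ | per N-donor→O-acceptor bond (≤3.5 Å, ≥120°) |
| E_sb | −1.5 kcal·mol⁻¹ | per cation–anion contact (≤4.0 Å) |
| S_rb | +10 kcal·mol⁻¹ | rigid-body entropy per association event |
| probe | 1.4 Å; 960 sphere points | SASA quadrature |

Charged atoms are the side-chain termini of Arg/Lys/His and Asp/Glu plus
OXT; waters never enter G (they are only counted by the cavity-water
analysis). Sign convention: negative ΔG favours association (the
crystallographic "free energy of dissociation" convention is its negation).
The estimator is deliberately replaceable — it stands where published
pipelines call external black-box scorers — so all parameters live in
`SolvationParams`.

Two numerical choices matter. First, SASA uses a deterministic golden-angle
spiral point set, so results are bit-reproducible. Second, each atom's
point set is oriented in a local frame built from its nearest neighbours
(ties broken by rounded distance, then input order). This makes SASA
rotation-covariant: G is invariant under rigid motion of the whole system,
congruent symmetry copies score identically (the 30 toy interfaces agree to
~1e-15 relative), G of a symmetric assembly can be computed as 12× one
pentamer's contribution evaluated in context (the fast path the pipeline
uses), and a zero-contact partition gives ΔG = (N−1)·S_rb exactly. Atoms
whose neighbourhood is empty or colinear fall back to a lab-frame
perpendicular; in practice this only occurs in constructed two-atom tests.

The additive form makes the partition identity exact by construction:
ΔG(capsid→60 monomers) = ΔG(capsid→12 pentamers) + Σ ΔG(pentamer→5
monomers), including the entropy bookkeeping (59 = 11 + 12·4 events). The
identity is asserted to float tolerance in the tests; it also fixes the
convention that the entropy term applies identically at every partition
level.

## Mutant construction

Side chains are rebuilt from ideal internal geometry (bond lengths/angles
matching standard tables; CB placed by the C-N-CA-CB improper of −122.6°,
validated against reference residue geometry) on the untouched backbone. A
coarse backbone-independent rotamer library enumerates gauche⁻/trans/gauche⁺
per χ with prior weights 0.50/0.35/0.15; the chosen rotamer minimises a
soft-sphere clash score Σ max(0, 0.8(rᵢ+rⱼ) − d)² plus −0.1·log(prior).
Neighbouring side chains within 6 Å are then re-optimised greedily, worst
clash first, until no single-residue move improves (≤10 sweeps). Everything
is deterministic; a residue with no clash-free rotamer keeps the best-effort
conformation and raises a warning that propagates into the variant report.
Mutations apply to all five chains by default (homopentamer convention) and
identity mutations are exact no-ops. Backbone relaxation and fold-stability
scoring are out of scope.

## The synthetic study system

The generator emulates the structural situation the method needs, not the
chemistry of any real protein:

- **Architecture.** One 5-residue ideal-geometry peptide per monomer, laid
  along one edge of a dodecahedron face (inradius 34 Å by default, the
  smallest size at which neighbouring strand termini do not collide); C5
  copies fill the face; the I23 cell (150 Å, > 4× inradius so the two
  capsids never touch) regenerates 2 capsids × 12 pentamers. The pentamer is
  shifted along its 5-fold axis so its mass-weighted COM sits exactly at the
  inradius, making the COM-based radius estimator exact on the unperturbed
  system.
- **Interfaces.** Residues at even strand positions face the edge; the
  icosahedral 2-fold through the edge midpoint maps them onto the
  neighbouring pentamer. Defaults: Glu1/Arg5 form the ion pair (~3.2 Å,
  anchor χ chosen once so the tips meet without steric overlap — the pair
  also registers as a hydrogen bond, as real salt bridges do), Leu3 the
  hydrophobic cluster (~4.4 Å CD–CD), His2 the polar site packing inward.
  All 30 interfaces are congruent by construction.
- **Dynamics.** A single global breathing mode (radius ~ Normal(1, 2%)
  scaling about the capsid centre, cell co-scaling so fractional coordinates
  breathe with the crystal — the symmetry constraint forbids asymmetric
  modes) plus isotropic per-atom noise of SD 0.15 Å scaled by an optional
  per-residue RMSF profile. 2% and the noise scale are the fluctuation
  magnitudes reported for capsid crystal simulations.
- **Volumes.** `generate_volume_series` draws Normal(V₀, k_B T V₀ χ_T)
  volumes; 0.3 GPa⁻¹ — the reported capsid value, close to the intrinsic
  compressibility of globular proteins — is the default injected truth.

What the toy does *not* model: electrostatics (no like-charge repulsion),
solvent, backbone flexibility, and realistic interface areas (~250 Å²
buried per interface against ~10× that in a real capsid). Consequences
worth knowing: the ionic network carries a larger share of the binding
energy than in the real system, so the salt-bridge-only variant W2 is
over-penalised (the panel's one disagreement, where the published analysis
failed on W7 instead); and a *lone* charged substitution in the hydrophobic
cluster can be absorbed by a bifurcated salt bridge to the intact arginine —
which is why the directional tests use the panel's own design, where
hydrophobic-cluster substitutions always co-occur with ionic/H-bond ones
(the experimental panel contains no lone hydrophobic mutant either).
Passing tests demonstrate that the machinery — symmetry expansion, SASA,
contact counting, ensemble statistics, classification — is correct and
self-consistent, not that the toy energetics transfer quantitatively to
real capsids.

## Variant panel and classification

The packaged panel maps the experimentally characterised variants onto the
toy sites by role (ionic → Glu1/Arg5, H-bond → His2, hydrophobic → Leu3;
the two real hydrophobic positions share the single toy site, so W6
collapses onto W5's specs). The classification threshold defaults to
100 kcal/mol for paper-scale inputs — between the ~80 kcal/mol landmark of
capsid-forming and the ~120 kcal/mol of non-forming variants — and is
always reported with the results, since no published value exists. On the
toy system the pipeline's "auto" rule is used instead: a variant is
predicted pentameric when its mean ΔG_assoc turns unfavourable, i.e.
threshold = |mean wild-type ΔG|. This rule was fixed before any mutant was
scored. Predictions contradicting a supplied experimental state are
flagged, never corrected.

## Analysis conventions

- RMSD: Kabsch superposition with the proper-rotation constraint; RMSF:
  per-atom deviation about the time-average after superposing all frames
  onto frame 0 over Cα, averaged within residues.
- Equilibration: production starts at the first index whose trailing
  least-squares slope is ≤ 1e-3 Å/frame, requiring ≥25% of the series to
  remain; the magnitude is used so decaying series do not qualify. On short
  stationary noisy series no index may qualify; the pipeline then keeps all
  frames and logs it.
- Capsid radius: each pentamer's 5 nearest neighbours define the pairs
  (30 in a complete capsid, deduplicated; robust to breathing distortion —
  the mean over all pairs is used); r = d̄ / (2·sin(½·arccos(1/√5))).
  Capsid membership is fixed from frame 0 by operator tag.
- Compressibility: χ_T = Var(V)/(k_B T V̄) with the absolute k_B
  (1.380649e-23 J/K); volumes in Å³, result in GPa⁻¹. Note that applying
  the estimator to cells that co-scale with the synthetic breathing mode
  measures the imposed 2% radial fluctuation (a huge apparent χ), not a
  thermodynamic compressibility; χ studies use `generate_volume_series`,
  whose fluctuations encode the target value by construction. Histogram bins: 30
  equal-width bins over [min, max], modal bin leftmost on ties.
- k_B (molar) = 1.98720425864e-3 kcal·mol⁻¹·K⁻¹; all unit conversions live
  in one constants module.

## Problem sizes

Defaults are chosen so the whole analysis runs on one CPU in minutes: 40
frames per variant for the panel (toy capsid ≈ 2,600 heavy atoms; scoring
exploits the exact 12-fold symmetry), 10⁴ volumes × 20 seeds for the
compressibility round trip, 10³–2·10³ frames for RMSF recovery, 120 frames
for the breathing CV. Estimator tolerances in the tests are 3 standard
errors of the corresponding sample statistic.

## Known limitations

Single-conformer altloc handling (keep 'A'), no hybrid-36 serials (>99999
atoms is an error), I23/P1 built in (other groups need explicit operator
strings), no mmCIF or binary trajectories, rigid-backbone mutagenesis, and
an energy model without electrostatics or conformational entropy. The
equilibration detector assumes a monotone-then-flat RMSD shape; the
classification threshold is a reported convention, not a fitted quantity.
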