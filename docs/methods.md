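# Methods

## Model and assumptions

The package treats a protein (or any residue selection) as a cloud of
single-point residues and asks whether the observed spatial arrangement of
hydrophobicity matches the idealized micelle: a centric hydrophobic core with
polarity increasing outward. Three per-residue probability vectors are
compared — the Gaussian target T, the interaction-derived observation O and
the uniform reference R — through Kullback–Leibler divergences in bits, and
summarized by RD = D(O‖T)/(D(O‖T)+D(O‖R)) with the conventional 0.5
threshold, plus the FOD-M environment parameter K.

Assumptions worth keeping in mind:

- **One point per residue.** The effective atom is the side-chain heavy-atom
  centroid (Cα for glycine or unresolved side chains). Sub-residue detail,
  solvent accessibility and atom-level contact areas are outside the model.
- **The Gaussian tracks geometric extent, not mass.** The unit is rotated to
  the principal axes of its effective-atom cloud (covariance eigenvectors,
  spread ordered x ≥ y ≥ z) and centered on the bounding-box midpoint *in
  that frame*; centering in the canonical frame rather than the input frame
  is what makes T exactly invariant to rigid-body motion of the input file.
  Eigenvector signs are fixed deterministically (largest-magnitude component
  positive, determinant +1); sign flips cannot affect T because the Gaussian
  is even along each axis.
- **First model, single conformer.** Multi-model (NMR) files contribute only
  model 1; alternate locations resolve to the highest-occupancy conformer
  (ties: first encountered). Waters, ligands and nucleic acids are excluded
  from the field and logged.

## Parameters

| parameter | default | meaning |
|---|---|---|
| interaction cutoff c | 9.0 Å | range of the pairwise hydrophobic interaction; also the interface contact criterion |
| contact form | sigmoid polynomial | `1 − ½(7x²−9x⁴+5x⁶−x⁸)`, x = r/c; a linear ramp is available for sensitivity checks |
| σ per axis | `max(extent/2 + pad, 1 Å)/3` | puts the molecular surface near 3σ; `pad` (default 0) and the 1 Å floor are exposed because the convention varies across the literature |
| hydrophobicity scale | Kyte–Doolittle, min-max → [0,1] | shipped as TSV; any two-column TSV can be substituted. Absolute RD values shift a few hundredths between common scales; the RD < 0.5 classification is much more stable |
| K grid | step 0.01, max 10 | dense deterministic grid; ties resolve to the smallest K, so a uniform T yields K = 0. RD is reported raw and at 3 decimals, K raw and at 0.1 |
| profile floor | 1e-12 | entries are floored and renormalized before any divergence, guarding against Gaussian-tail underflow for residues far from the center |

M(K) is the normalized blend `T + K(Tmax − T)`: K = 0 reproduces T exactly
and large K approaches the normalized inverted field. The blend is isolated
in `fod_stats.m_profile` so an alternative parameterization can be swapped
in without touching callers.

## Assessment modes

- *individual*: Gaussian and interactions span the unit alone (whole
  complex, single chain, or a domain extracted as its own unit).
- *in context*: Gaussian and interactions span the whole complex; T and O
  are then restricted to the selection and renormalized, so the statistic
  measures the selection's share in the complex-wide core. A selection equal
  to the whole complex reproduces the individual status exactly.
- *interface*: effective-atom distance ≤ cutoff to any residue of another
  chain, scored in context.
- *SS fragments*: one closed residue range per intra-chain disulfide bond.
- *cross-form*: the bound form's interface residues scored on the unbound
  form's profile, through an identity-or-explicit residue correspondence.

## Synthetic data

The generator emulates exactly the statistical structure the analysis
assumes: effective atoms drawn from an anisotropic 3D Gaussian (default σ =
18 × 14 × 10 Å, the proportions of a small globular protein) with a 3.5 Å
minimum spacing enforced by rejection, and intrinsic hydrophobicity
rank-mapped to decrease with sigma-scaled distance from the center
(`ideal_micelle`), increase (`inverted_micelle`), stay constant
(`uniform_h`) or vary randomly (`mixed`). Residue types are chosen as the
nearest-H amino acid under the active scale and coordinates are quantized to
the PDB 0.001 Å field precision, so fixtures survive a write/parse round
trip bit-exactly. Two-chain complexes place independent clouds at a
controllable centroid gap, so interface existence is a function of gap vs
cutoff.

What the generator does **not** emulate: backbone connectivity and secondary
structure, realistic side-chain packing, sequence statistics, crystal
contacts, or partially occupied/disordered regions. Passing tests on
synthetic micelles therefore validate the *mathematics and plumbing* of the
pipeline — profile construction, statistics, selections, I/O — not the
biological claim that real proteins of a given class have low RD; for that,
the published-value test run on deposited PDB entries is the relevant check.
At 300 residues per chain, ideal and inverted micelles separate at the
RD = 0.5 threshold in 100/100 seeds (calibrated once with the defaults
above and asserted since).

## Numerical choices and degenerate inputs

- Divergences use base-2 logarithms; RD itself is base-invariant.
- K search is an exhaustive grid rather than a derivative method: D(O‖M(K))
  can be nearly flat around its minimum, and the grid is deterministic.
- Zero observed mass (no residue pair within the cutoff, or all-zero H)
  raises a degenerate-profile error naming the cause; selections of fewer
  than two residues raise; single-chain structures report "interface:
  single-chain structure" in the skip log rather than failing the report.
- A single point orients with the identity rotation; exactly degenerate
  covariance eigenvalues fall back to a stable, documented ordering.
- PDB output refuses coordinates outside the fixed-column field width.

## Known limitations

- The FOD literature does not fix one intrinsic-hydrophobicity scale, σ
  padding convention or M(K) parameterization; this package makes each
  explicit and configurable, but absolute RD/K values from other
  implementations may differ by a few hundredths even when classifications
  agree.
- Domain boundaries are user input (YAML ranges); there is no automatic
  domain decomposition, catalytic-site prediction, structure repair,
  hydrogen placement or biological-assembly expansion.
- Problem sizes in the test suite and acceptance script (chains of 150–300
  residues, 100-seed studies, 200-bin profile pairs) were chosen as the
  smallest sizes at which the separation and recovery statistics are stable.
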