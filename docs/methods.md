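# Methods

## The model

A flexible protein in solution populates an ensemble of conformations;
SAXS measures the ensemble-averaged intensity. Given a starting structure
with rigid domains joined by flexible segments, the observable of a
candidate ensemble `{(wᵢ, structureᵢ)}` is the weighted sum of the
per-conformer profiles, because scattering is linear in the (incoherent)
mixture of species. The pipeline therefore factors into three
independent pieces: conformer generation, per-conformer forward
calculation, and non-negative linear inversion.

### Conformer generation (torsion Monte Carlo)

Each trial perturbs one backbone dihedral (φ or ψ) of one residue drawn
uniformly from the flexible regions, by an angle uniform in
[−`max_angle`, +`max_angle`] (default 30°). The rotation acts rigidly on
everything C-terminal of the pivot bond in the N→C sense: for φ (N–Cα
axis) the sidechain, carbonyl group and all later residues; for ψ (Cα–C
axis) the carbonyl oxygen and all later residues. Keeping the sidechain
with the rotating branch of φ is required to preserve the fixed bond
angles around Cα — torsion moves change only dihedrals, never bond
lengths or 1–3 distances, and the test suite enforces this to 1e-8 Å
pool-wide.

A trial is accepted iff the new structure is free of steric clashes:
no pair of basis atoms (heavy atoms by default; backbone-only and
all-atom bases available, the latter requiring hydrogens) separated by
three or more bonds lies closer than 0.8× the sum of their van der Waals
radii (Bondi radii; strict `<`). Bond topology is inferred once from
covalent distances on the starting structure. There is no force field:
in this pipeline the selection pressure comes from the SAXS fit, not from
sampler energetics, so the configured temperature (300 K default) is
inert unless a user-supplied torsion-energy callback switches on
Metropolis acceptance. After 20 consecutive rejections (configurable)
the working coordinates reset to the last accepted frame, which keeps
the chain from wedging itself into a clashed corner of torsion space.

Accepted frames are superposed on the starting structure by Kabsch
least-squares over the Cα atoms of a user-chosen rigid alignment range
(validated to intersect no flexible region) and numbered consecutively
by their position in the accepted pool — the numbering every downstream
report uses. The trial index that produced each frame is kept alongside.
Identical seeds give bit-identical pools.

One torsion is perturbed per trial (the alternative — perturbing every
flexible torsion each trial — lowers acceptance sharply at equal step
size); this is a design choice, not a physical necessity.

### Forward calculation

**P(r).** Every unordered atom pair adds the product of its electron
counts to the left-closed bin `[kΔr, (k+1)Δr)` containing its distance
(Δr = 1 Å default, self-terms excluded); the histogram is rescaled so
`Σ p·Δr` equals the molecular mass in Da. Moments are evaluated at bin
centers; the second-moment relation `Rg² = Σ p rᶜ² / (2 Σ p)` then
agrees with the coordinate-space Rg to ~0.5 Å at 1 Å binning.

**I(q).** The Debye equation with either constant form factors
`fᵢ = Zᵢ` ("point", the default) or 4-Gaussian Cromer–Mann form factors,
`sin(x)/x → 1` as `x → 0`. This is a vacuum calculation: no excluded
volume and no hydration shell. Those belong to dedicated external
calculators, which can be registered behind the same
`fn(structure, q_grid) → curve` contract and flow through identical
interpolation/scaling steps; the internal calculator's job is to be
exact for what it models (verified against an O(N²) double loop at
1e-10 relative), not to be complete.

**Scaling.** Calculated curves are linearly interpolated onto the
experimental q-grid (extrapolation refused) and scaled by
`c = Σ(IₑIᶜ/σ²)/Σ(Iᶜ²/σ²)` (σ ≡ 1 without SDs), reporting
`nχ² = Σ((Iₑ − cIᶜ)/σ)²/(N−1)` (one fitted parameter) and the RMSD.
Units convert on input: q in nm⁻¹ divides by 10, r in nm multiplies by
10 with P(r) frequencies rescaled so the area is conserved.

### Pool reduction and ensemble selection

Stride/offset reduction keeps 1-based positions `offset+1, offset+1+s, …`
of the accepted pool — `floor((n − offset − 1)/s) + 1` frames. Whether
the reduced pool still represents the full pool's size distribution is
reported as the total-variation distance between unit-mass Rg histograms
(shared 1 Å bins); the metric is advisory, matching an interactive
workflow where the user judges the histogram overlay.

NNLS (`scipy.optimize.nnls`, the Lawson–Hanson active-set algorithm,
exact at its KKT conditions) fits the experimental curve as a
non-negative combination of per-model profiles. Rows are weighted by
1/SD when SD weighting is requested and SDs exist (silent fallback with
a warning otherwise); for P(r) the fit runs unweighted and, when the
experimental curve carries SDs, also SD-weighted, reported side by side.
Columns enter unscaled so the weights absorb the overall scale and stay
identifiable as fractional contributions. The ensemble nχ² uses an
N−m denominator (m positive weights). Weights at the solver's numerical
floor (≤1e-9 of the largest weight) are zeroed before reporting: the
active-set method can park ~1e-14 weights on near-collinear columns,
and these are numerical zeros, not contributions. Ties between duplicate
columns resolve by the solver's insertion order (ascending model
number) — deterministic.

After preselection, up to `k ≤ floor(stride/2)` frames flanking each
preselected model (in accepted-pool ordering — the frames the stride
skipped) are added, and the final NNLS runs on the augmented set. The
cap on k guarantees augmentation stays a local refinement of the stride
grid. The final report lists each model's number, percent and Rg, the
ensemble `√(Σ (pᵢ/100) Rg,ᵢ²)`, and three reference Rg values: starting
structure (coordinates), weighted ensemble, and experimental P(r)
(second moment).

## Flexible-region detection

A residue is flexible when its confidence is strictly below the
threshold (default 60; "below" read literally, so a residue exactly at
the threshold is rigid); maximal runs of ≥5 such residues become
regions, including runs touching the termini (disordered tails).
Per-residue confidence is the B-factor of the residue's first atom —
AlphaFold writes identical values across a residue, and the first-atom
convention makes mixed-value residues deterministic. Manual ranges pass
through the same validation as detected ones.

## The synthetic data

The toy chain is a poly-alanine backbone (N, Cα, C, O, Cβ) built by NeRF
from ideal internal coordinates (N–Cα 1.458 Å, Cα–C 1.525 Å, C–N
1.329 Å, C=O 1.229 Å, Cα–Cβ 1.521 Å; ω = 180°, φ = −139°, ψ = 135°, an
extended β-like conformation; Cβ placed with L-handedness). Two
20-residue "domains" at confidence 90 flank a 10-residue "linker" at
confidence 40 — the two-domain-plus-linker topology the pipeline
targets, with counts and confidences chosen so the linker is
unambiguous at the default threshold and the chain is comfortably
clash-free under the default basis. Synthetic experiments mix the exact
Debye I(q) and P(r) of chosen pool conformers with known weights, apply
multiplicative Gaussian noise `(1 + ε)`, ε ~ N(0, nf²), and carry an SD
column equal to the applied noise scale so SD weighting is exercised
honestly (noiseless curves carry no SD column, since a zero SD is not a
valid weight).

What the toy does **not** emulate: sidechain packing beyond Cβ,
realistic Ramachandran statistics, hydration-shell and excluded-volume
contrast, interparticle effects, and the q-dependent error structure of
real detectors. Tests passing on it demonstrate the correctness of the
geometry, scattering and selection machinery — not that a real
AlphaFold model with real SASBDB data would yield any particular
ensemble.

## Numerical choices and degenerate inputs

- P(r) bins are left-closed/right-open, curves reported at left edges,
  moments at bin centers; pair histograms are chunked (4M pairs) to
  bound memory.
- Superposition requires ≥3 Cα atoms and forbids reflections
  (determinant-corrected SVD).
- Undefined torsions (φ of residue 1, ψ of the last residue) are
  errors in `apply_torsion`; the sampler counts a draw that lands on
  one as a rejected trial, keeping the trial count exact.
- `trial_attempts = 0` is a valid empty run; an empty pool cannot be
  written as a multi-model PDB; a single atom has no P(r); zero-area
  P(r) has no Rg; all-zero calculated curves cannot be scaled.
- Seeds: every stochastic component (MC, synthetic noise) takes an
  explicit integer seed; the pipeline threads one project seed through
  all stages, so reruns are byte-identical.

## Problem sizes

The shipped tests and the acceptance script run the study at desk
scale: a 50-residue toy chain, pools of 400–2000 trials, stride 5–10,
reduced pools of ~50–190 models on 120–256-point q-grids. These sizes
were chosen so the full synthetic study demonstrates every stage —
including adjacent-frame augmentation, which needs a stride worth
skipping — while each pipeline property remains checkable in seconds to
minutes.

## Known limitations

- Vacuum Debye I(q): absolute comparisons with hydrated-particle
  calculators (CRYSOL/Pepsi-SAXS/WAXSiS-class) require registering such
  a calculator; the internal one is exact only for its vacuum model.
- Single chain, no ligands/prosthetic groups, no glycosylation.
- Hard-sphere acceptance means torsion sampling is uniform within the
  clash-free region, not Boltzmann-weighted; the ensemble's realism
  rests on the SAXS selection, as designed.
- P(r) model curves longer than the experimental grid are truncated at
  the grid's end for the NNLS fit; with experimental grids extending to
  the true Dmax this loses nothing, but a too-short experimental grid
  silently discards long-distance information.
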