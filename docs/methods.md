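# Methods

## Coordinate frame and correspondence

All DNA positions live in a dyad-centred per-strand frame: numbering
increases 5′→3′ on each strand, the dyad nucleotide is 0, and paired
nucleotides satisfy partner(*i*) = −*i*. This is the only convention under
which a damage site at −c on the bottom strand has its base-pair window on
the top strand at +c, and it reproduces the printed 152-nt Widom 601
bottom strands exactly: 1-based string index *i* maps to position *i* − 78,
placing the four single-inosine variants at −30, −50, −53 and −55 with zero
residual in an affine least-squares fit. Author residue numbers are never
assumed to equal frame positions; the frame is always built explicitly from
a dyad specification (deposited nucleosome models variously use 1-based or
±73 author numbering).

Residue correspondence between two models supports three modes: author
numbering (default for histones of identically-numbered depositions),
global sequence alignment (biopython PairwiseAligner, match +1 / mismatch
−1 / gap −2; robust to renumbering), and frame position (for DNA). Shared
atoms are intersected per residue pair; the default anchor filter is Cα.

## Superposition

Rigid superposition is the closed-form Kabsch solution (SVD of the weighted
cross-covariance, smallest singular direction sign-flipped when the
unconstrained optimum is a reflection — biomolecular chirality must be
preserved). The similarity variant (Umeyama) adds a jointly-optimal
isotropic scale; with scale constrained to 1 it reproduces Kabsch exactly.
A scale away from 1 between two nucleosome models refined against different
maps indicates voxel-size miscalibration of order the scale factor, so the
pipeline reports the anchor scale before every comparison.

The anchor is histone H3 with both copies pooled by default: pooling is
symmetric under the particle's pseudo-two-fold and deterministic, whereas
picking "the" H3 copy nearest a damage site injects an arbitrary choice.
A flag (`pool_copies=False`) restricts to one copy for sensitivity checks.
Optional iterative pruning (drop atom pairs with residual > 2 Å, refit, ≤10
iterations) is off for headline numbers and available for sensitivity
analysis, because published comparisons do not always state whether their
matching tool pruned; the pipeline records pairs used/dropped either way.

## Distortion profiles

Per-nucleotide RMSD is computed over the intersection of the 11 heavy
backbone atoms present at that position in both models — abasic sites
contribute their full backbone, which is all the profile uses — after the
single global anchor superposition, with no window-local refit. Positions
missing in either model are omitted, never zero-filled; entries with < 4
shared atoms are flagged low-confidence. A windowed value is the pooled
RMSD over all backbone atoms of positions [c − h, c + h] (default h = 5),
so pooled² is identically the atom-count-weighted mean of per-residue
rmsd² — a checked algebraic identity. A `mean_of_residues` mode (plain
average of per-residue RMSDs) is also provided because published windowed
figures do not always state which convention was used; both are reported
by the pipeline. Extrema: global maximum with ties broken toward the most
5′ position, plus local maxima above a configurable fraction (0.5) of the
global maximum as secondary peaks.

Minor-groove width near a position is the minimum cross-strand P–P
distance, searched over phosphates of the query position ± 2 against
partner-side offsets within 4 bp (bracketing the ~3-bp minor-groove stagger
without assuming helical parameters), minus 5.8 Å for two phosphate-group
radii; negative values clamp to zero with a flag.

## Interface geometry

SASA is Shrake–Rupley sampling with a Fibonacci-lattice point set (default
960 points, probe 1.4 Å) and an element-keyed united-atom radius table
(C 1.70, N 1.55, O 1.52, P 1.80 Å, …). The lattice is deterministic, so
every area — and therefore every buried-area difference — is
bit-reproducible across runs. On analytic references the sampling is
accurate to ≤0.5 % for an isolated sphere and ≤1 % against the two-sphere
spherical-cap closed form. Buried interface area between two disjoint role
groups (defaults: the two DNA strands versus the eight histone chains;
ligands excluded) is derived from three SASA evaluations with identical
parameters and reported under both conventions,
`sum = sasa_A + sasa_B − sasa_AB` and `avg = sum/2`. Both are always
computed because published "buried area" numbers split between the two; the
pipeline default is `sum`, switchable per run. Absolute areas depend on the
radius table and probe, which differ between tools — comparisons of
differences and ratios are far more transferable than raw values.

## Register-shift detection

After superposition, each test nucleotide's offset is the argmin over
reference positions within ±3 of the distance between C1′ anchors (backbone
centroid when C1′ is absent — abasic sites keep C1′, so this fallback is
rare), minus its own position. Ties break toward offset 0, then toward the
negative offset: prefer "no shift". Runs of constant offset are segmented;
nonzero runs of length ≥ 3 are reported as shifts, shorter excursions are
noise unless they contain a declared damage site. If fewer than 60 % of
tracked positions sit at offset zero, the global register itself may
differ and the track carries a warning. The anchor atom is configurable
because a published register assignment may have been made on phosphates
or whole-nucleotide fits rather than C1′.

The flipped-nucleotide score measures base-extrusion geometry: the distance
of a nucleotide's C1′ from the midpoint of the C1′ atoms of its
cross-strand neighborhood partners (positions −(i−1), −(i+1)), normalized
by the strand's interior median, so ideal duplex geometry scores ≈1 and
extruded nucleotides score ≫1.

## Synthetic nucleosome generator

The generator emulates the geometry every analysis needs and nothing more:
147 pseudo-nucleotides per strand wound 1.65 superhelical turns at 41.8 Å
radius and 23.9 Å pitch, 34.5°/bp duplex twist, backbone radius 9 Å, the
two backbones 164° apart in azimuth (giving B-DNA-like asymmetric grooves,
minor-groove widths 4.4–7.1 Å on the ideal particle), 11 named backbone
pseudo-atoms per nucleotide at fixed local offsets (5′ termini lack
P/OP1/OP2), and a 32 Å pseudo-atom ball core partitioned into eight chains
whose residue counts (135/102/128/122 ×2) fall in the histone-class length
ranges used by automatic role assignment. Everything is deterministic;
noise perturbations consume an explicit seed.

Injectable deformations mirror the three modes seen when repair factors
engage damaged nucleosomes: a Gaussian-profiled rigid outward **bump**
(per-nucleotide displacement d(i) = A·exp(−(i−c)²/2w²), so the profile peak
recovers A exactly); a **register** slide moving nucleotides from a start
position to a strand end onto the path positions of their offset-removed
neighbors (author numbering preserved; nucleotides slid past the wrapped
range are deleted, as they would be disordered in a real map — so a slide
away from the dyad shortens the tracked run by |k|); terminal **unwrap**
(rigid rotation off the core about the radial axis at the boundary, or
deletion emulating unmodeled density); and seeded Gaussian **noise**. The
per-nucleotide displacement of a +1 slide equals the distance between
consecutive ideal nucleotides (~5.5 Å on the default geometry — helical
twist at the backbone radius dominates the ~3.0 Å path arc), and tests
assert the value computed from the generator's own parametric path.

What the generator does **not** emulate: sequence-dependent mechanics,
all-atom histones and their side-chain contacts, base atoms, realistic
B-factors/occupancies, or experimental noise structure. Passing the
ground-truth recovery tests therefore demonstrates the correctness of the
geometry pipeline (frames, superposition, profiles, register logic, SASA
bookkeeping), not the biological accuracy of any particular deposited
model; absolute synthetic buried areas are far smaller than experimental
nucleosome interfaces because the pseudo-core is a coarse lattice.

## Numerical choices and problem sizes

Deterministic throughout: fixed Fibonacci SASA points, explicit seeds for
all noise, 5′-most tie-breaks in extrema, toward-zero tie-breaks in
register matching, highest-occupancy-then-first altloc resolution. The
verification script exercises 50 random ≤10-point clouds against a
1200-sample rotation-search + Nelder–Mead oracle for Kabsch, 300
scale-recovery fits on 40-point clouds of 15 Å spread under 0.05 Å noise
(clouds sized so estimator sampling noise sits well below the 0.002
recovery bound), the full 10-fixture suite for self-comparison nullity,
12 bump and 4 register recovery cases, and 26 windows for the pooled
identity. Hydrogens and waters are excluded everywhere; analyses are
heavy-atom based.

## Known limitations

- Automatic role assignment is built for well-behaved or idealized models;
  deposited structures should supply explicit chain-role maps (chain naming
  conventions vary by deposition and are not guessed).
- The register tracker detects translational shifts only; rotational-
  setting (helical phase) changes and screw decompositions are out of
  scope, as are base-pair step parameters and elastic-energy models.
- Buried-area absolute values are convention- and radius-table-dependent;
  use one configuration consistently within a study.
- PDB output is limited to what the fixed-column format can carry
  (single-character chain IDs from the generator, 3-decimal coordinates).
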