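# Methods

This note records the scientific conventions `hexchan` implements, the
choices made where a convention was genuinely open, and what the synthetic
validation does and does not demonstrate.

## Trajectory model and PDB dialect

A trajectory is an ordered sequence of frames sharing one atom table; frames
come from MODEL/ENDMDL blocks of a fixed-column (v3.3) PDB file, with ATOM
and HETATM both accepted. A file without MODEL records is a one-frame
trajectory. Every model must contain the same atoms in the same order; a
mismatch is a hard error, because per-frame metric series are only defined
over a stable atom ordering. Coordinate fields are float-validated with line
numbers before parsing, since permissive readers otherwise truncate malformed
numbers silently.

Conventions:

- Waters are recognised by residue name HOH, TIP3 (also its 3-column
  truncation TIP), SOL or WAT, case-insensitive, and counted through their
  oxygen atom — one oxygen per molecule, so heavy-atom-only files are
  first-class inputs. Hydrogens, when present, are carried but unused: every
  metric here is defined on heavy atoms.
- Alternate locations other than blank/'A' are dropped with a warning.
- Masses come from the element column, or are inferred from the atom name
  when that column is blank; standard atomic masses are used.
- Residue numbering is taken as-is (PDB numbering is authoritative).
- Frames are assumed whole-molecule imaged. No periodic-boundary re-wrapping
  is applied; inputs with molecules split across a box boundary are the
  caller's responsibility. This is a documented precondition, not a detected
  error.
- The frame interval `dt_ps` is metadata supplied by the caller (default
  1 ps); the PDB format does not carry it. A frame-range option allows
  excluding initial frames; the default analyses all frames.

## Geometry

**Superposition.** Optimal proper rotation + translation via quaternion-based
alignment (scipy); the determinant is never −1, so a mirror image cannot
reach RMSD 0. The residual is recomputed from the superposed coordinates
because the eigenvalue route loses precision near zero and exact copies must
read as ≈ 0 (< 1e-9 Å). RMSD series superpose each frame onto a chosen
reference frame using the same selection being measured — by default the
protomer Cα set, uniform weights, no mass weighting (conventional for
Cα-based profiles). RMSF uses a two-pass alignment: align to frame 0, form
the mean structure, re-align to the mean, then
RMSF_i = sqrt(mean_k |r_i(k) − ⟨r_i⟩|²). For isotropic per-coordinate jitter
of s.d. σ the expectation is σ√3, deflated slightly (by ≈ sqrt(1 − 6/(3N))
for N fitted atoms) because superposition absorbs six rigid-body degrees of
freedom; the validation tolerances account for this.

**Helix axes.** The "best straight line" through a segment's Cα atoms is the
total least-squares line: the first principal component of the centered
coordinates. It is rotation-equivariant and unique up to sign; the sign is
fixed by residue order (the direction points from the first toward the last
residue, N→C). Inter-axis angles therefore live in [0°, 180°]: TM2/TM4,
antiparallel to TM1 in connexin topology, read near 180° rather than being
folded to 0°. Angles are computed with the atan2 form, which is accurate near
0° and 180° where arccos loses digits. Note that the TLS axis of a *finite*
ideal helix deviates from the nominal helix axis by a length-dependent
offset (≈ 1.4° at 22 residues, < 1° at 28); inclination values are
*differences* of axes fitted with the same convention, so this offset cancels
in the synthetic recovery checks.

## Channel metrics

**Salt bridges.** The distance between two residues is measured between the
mass-weighted centers of their terminal side-chain moieties: Arg guanidinium
{CZ, NH1, NH2, NE}, Glu carboxylate {CD, OE1, OE2}, Gln amide {CD, OE1, NE2}.
Lys {NZ} and Asp {CG, OD1, OD2} are included as well so that lysine bridges
(e.g. K158–E223) are measurable; all sets are configurable. A missing moiety
atom or an unmapped residue type is a hard, named error. The interacting
criterion is d ≤ 4.0 Å. The occupancy of a pair is the fraction of frames
meeting the criterion; since published analyses report a protomer as
"forming" a bridge without an explicit occupancy rule, the default
classification is occupancy ≥ 0.5 of analysed frames, configurable via
`occupancy_threshold`. Bridged-protomer counts apply the same rule within
each of the six chains; with replicas, occupancies are averaged across
replicas before thresholding.

**TM distances and inclinations.** TM1–TM3 is the Cα–Cα distance between
representative residues 25 and 159, TM2–TM4 between 85 and 220. Inclination
of TM2/TM3/TM4 is the angle between that helix's fitted axis and TM1's, per
protomer per frame. TM segment boundaries are structure-specific and must be
supplied in the channel configuration — there is deliberately no hard-coded
default; the synthetic generator writes the matching configuration next to
its output. Distances and angles are computed per frame and pooled (frames ×
replicas) for summaries and tests, mirroring analyses that pool "all frames
from all replicas".

**Pocket hydration.** The pocket centroid of a protomer is the center of mass
of the Cα atoms of its 30 pocket-lining residues (N9, E12, E13, E16, S18,
R23, L26, T27, F30, R33, I34, Q81, V85, S86, P88, S89, Y92, V93, L148, Y151,
H154, I155, K158, T159, E162, S216, L219, N220, E223, L227). A water counts
if its oxygen lies within ≤ 6.0 Å of the centroid; the boundary is inclusive.
The centroid is recomputed every frame because it is bound to a moving atom
set; a fixed-centroid (frame 0) mode exists as an option. Missing pocket
residues are logged and the centroid uses those present; representative
residues, by contrast, hard-fail when absent, since those metrics are defined
by exact positions. With several replicas, the per-frame mean ± s.d. across
replicas uses the sample (n−1) estimator, and the pooled distribution
concatenates all frames from all replicas and protomers.

## Statistics

Box-plot summaries use linear interpolation between order statistics
("type 7") for quartiles — recorded in run metadata, since box-plot numbers
depend on the convention — with Tukey 1.5·IQR whiskers and outliers.

Group comparisons use the Kruskal–Wallis rank test: mid-ranks, the standard
tie correction, H = 12/(N(N+1)) · Σ R²ⱼ/nⱼ − 3(N+1), and a χ² p-value with
df = k − 1. The χ² approximation is used at all n because the intended
per-protomer samples are large (frames × replicas); an exact label-permutation
mode exists for small-sample checks, and calibration tests use 60 observations
per group, where the approximation's small-sample conservatism is negligible.
All-identical data returns H = 0, p = 1 rather than an error. Two-group
(mutant vs wild-type protomer) comparisons also use Kruskal–Wallis, which at
k = 2 is equivalent to a two-sided rank-sum test. No multiple-testing
correction is applied by default (flags are plain p < α per protomer,
mirroring per-protomer asterisk panels); a Bonferroni option is exposed.

## Synthetic generator

`build_hexamer` constructs what the analysis assumes and nothing more: six
protomers placed with 6-fold symmetry on a ring (radius 25 Å), each with four
ideal α-helices (22 residues; rise 1.5 Å/residue, 100°/residue, radius
2.3 Å) at segments TM1 14–35, TM2 75–96, TM3 144–165, TM4 210–231, plus a
9-residue N-terminal helix (residues 5–13) so that every default pocket
residue has a Cα. Residues at pocket-lining positions carry their connexin
identities (R33, E162, K158, E223, …); all others are alanine. Only Cα atoms,
planted moiety atoms and water oxygens are emitted — every in-scope metric
touches nothing else, and physical realism (sterics, membrane, force field)
is an explicit non-goal.

Exactness guarantees, used by the recovery tests:

- Representative Cα atoms are placed exactly at the planted TM1–TM3 and
  TM2–TM4 separations, at equal height, so the planted distance is the
  as-built distance.
- Every TM helix is a rigid copy (TM2/TM4: point-inverted copy, giving exact
  180° orientation reversal) of one canonical template whose fitted axis has
  been aligned with +z. Planted tilts are applied about the x-axis through
  the representative residue, which commutes exactly with the axis fit, so
  planted inclinations (t for TM3, 180° − t for TM2/TM4) are recovered to
  machine precision at zero jitter.
- Planted bridges place the two moiety clusters along the line between the
  residues' Cα atoms at exactly the target center-of-mass distance on the
  first ⌈dwell · n_frames⌉ frames and at a far distance (default 6.5 Å)
  otherwise — deterministic scheduling, so occupancy targets are exact
  counting fractions. Per-frame jitter applied to a moiety cluster has its
  mass-weighted mean removed, so occupancies stay exact at any jitter level
  (a single-atom moiety such as Lys NZ consequently receives no jitter).
- Waters are rejection-sampled: each protomer receives its configured pocket
  count inside a 4.5 Å ball around its pocket centroid (excluded from other
  protomers' neighbourhoods), and bulk waters land at least 7.5 Å from every
  centroid. Pre-jitter counts are therefore exact integers, with a 1.5 Å
  margin against jitter-induced boundary crossings.

Defaults emulate a stable wild-type-like system at desk scale: 100 frames at
1 ps (standing in for the 100,000-frame production runs the bookkeeping
calculator describes), jitter σ = 0.3 Å per coordinate (RMSF ≈ 0.52 Å, a
typical stable-TM fluctuation), 25 pocket waters and 150 bulk waters per
system, bridge 33–162 stable in all six protomers and 158–223 formed in four
of six. The seed fixes the output bit-for-bit.

**What passing tests show — and don't.** Recovery of planted geometry under
Gaussian jitter validates the estimators and their implementation, not their
behaviour on real MD data: real trajectories have correlated, anisotropic
fluctuations, conformational drift, periodic-boundary artefacts and imperfect
helices. The generator also plants fluctuations about a single structure, so
occupancies are step functions rather than the gradual dwell patterns of real
salt bridges. Oracle-equivalence tests (brute-force distance scans,
independent rank-sum formula, rotation-grid superposition scans) validate the
fast implementations unconditionally.

## Pipeline

`run_analysis` evaluates the enabled metrics for every condition and replica,
writes tidy TSV tables (floats at 4 decimals for stable diffs; full precision
in JSON summaries), a per-protomer significance table against the declared
reference condition, and `run_metadata.json` recording version, frame range
and the conventions above. Output ordering is fixed, so identical inputs and
configuration reproduce byte-identical TSVs. Any metric error aborts the run
with a message naming the metric and condition.

## Known limitations

- No binary trajectory formats (XTC/DCD/TRR) or topology files; multi-model
  PDB only, which limits practical trajectory sizes.
- No periodic-boundary handling (see above).
- The occupancy ≥ 0.5 bridge classification is a convention; published
  bridged-protomer counts may have used a different implicit rule.
- Pocket hydration is a volume proxy; no pore-radius profiling, cavity
  meshing or electrostatics.
- The χ² Kruskal–Wallis p-value is approximate for very small groups; use the
  permutation mode there.
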