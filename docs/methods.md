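# Methods

## Scope and model

`mvcpair` implements surface-based pair-matching of bilateral skeletal
elements. The underlying model is geometric, not statistical: two bones of
one individual are assumed to be mirror images of each other up to a small
bilateral-asymmetry deformation and scan noise, while bones of different
individuals differ in overall size and shape by a much larger margin. All
comparisons are rigid — no scaling, no affine or non-rigid warping —
because size itself is part of the matching signal. Units are millimetres
throughout and are taken verbatim from the input files.

## Registration

Registration is two-stage ICP (iterative closest point), with the stages
configured the way the automated comparison protocol for this task fixes
them: a coarse multi-start stage followed by a high-precision refinement.

**Rough stage.** Point-to-point ICP on a fixed, seeded random sample of
1 % of the source vertices (at least 4), with approximate nearest
neighbours, at most 100 iterations per start. "Approximate" is realised as
a (1+ε) KD-tree query with ε = 0.1: the named menu behaviour of the
original software is not documented, and exactness is irrelevant before
the fine stage. Twenty starting orientations are used: principal-axis
alignment of source onto target, the same under the four proper axis
flips (covering the 180° ambiguities of elongated bones), and
quasi-uniform random rotations to fill the budget. Finished candidates
are ranked by exact-NN RMS on a denser evaluation subset of up to 1000
vertices rather than on the 1 % sample itself — twenty finishes measured
on ~20 points cannot be ranked reliably — and the best transform wins.
Within each run the best-so-far transform is tracked, which protects
against the slack-sized non-monotone steps the approximate query can
introduce. An optional mode redraws the sample every iteration
(`resample_each_iteration`); the default keeps it fixed per run. Both are
deterministic given the seed.

**Fine stage.** Point-to-plane ICP on 100 % of the source vertices with
exact nearest neighbours. A correspondence is rejected when the source
and target vertex normals subtend more than `normal_angle_max` (default
45°; the original software's threshold is undocumented), which prevents
front-to-back surface mismatches. With `overlap_fraction < 1` only the
best fraction of accepted residuals is kept each iteration; the default
1.0 (estimated overlap 100 %) keeps everything — the trimming option
exists for future work on fragmentary elements. Each iteration solves the
standard small-angle linearisation of the point-to-plane objective as a
6×6 normal system and projects the linearised rotation back onto SO(3) by
SVD.

**Termination and degeneracies.** Both stages stop early when the RMS
residual changes by less than `convergence_tol` (10⁻⁷ mm; the protocol
itself fixes only the 100-iteration caps), and the fine stage also stops
when the transform increment becomes negligible (a fixed point: the
correspondence set can no longer change). Rigid estimators raise a
degenerate-geometry error naming the unconstrained motion when the system
is rank deficient (collinear points; all normals parallel; a sphere's
rotations, which are invisible to point-to-plane). Inside the stage
drivers these conditions are handled rather than propagated: a degenerate
step inside one rough start abandons that start only, and a rank-deficient
fine step ends refinement with the current — still valid — alignment.
This matters in practice because on badly mismatched bones the normal
gate can whittle correspondences down to a near-cylindrical shaft patch
whose axial translation is unconstrained. A fine stage that rejects
*every* correspondence is a genuine alignment failure and is reported as
a failed matrix cell, never as a silently large value.

## The mesh-to-mesh value

The value of a registered pair is the symmetric RMS nearest-neighbour
distance over all vertices of both meshes under the final transform, with
no normal rejection at evaluation time. The evaluation deliberately
ignores the optimiser's sampling settings: the value characterises the
surfaces, not the optimisation path. Symmetry is guaranteed exactly by
canonicalising the registration direction (the lexicographically smaller
id moves), so `value(A,B) == value(B,A)` bit-for-bit. Alternative metrics
(mean absolute, Hausdorff, one-directional RMS) are available through
`value_metric`; the symmetric RMS default is symmetric, zero iff the
surfaces coincide, and in mm, which the mutual-agreement rule needs.

Correspondences are vertex-to-vertex throughout, not point-to-surface:
with full sampling on meshes of this density the difference is below the
method's discrimination scale, and no point-to-surface backend is
available in the dependency set. The known consequence is a positive
discretisation bias of the value — a true pair with 0.3 mm planted
asymmetry measures ≈ 0.3–0.5 mm because tangential registration slack
(invisible to the point-to-plane objective) shows up in vertex-NN
distances. The bias is shared across all cells of a matrix and does not
perturb the ordering the matching rule consumes; tests that need the true
surface distance use an exact point-to-triangle oracle instead.

Per-cell seeds in `compare_all` are derived from the global seed and the
two specimen ids (CRC32, kept below 2³¹), so the matrix is identical
whether cells are computed serially, in any order, or in parallel.

## Matching and evaluation

A pair is declared iff each bone is the other's single lowest-value
candidate (*mutual best*). The looser reading — agreement anywhere within
the top-3 lists — is available as `agreement="topk"` but is not the
default: when left A's best is right B but B's best is left C, no A–B
pair should be declared, and mutual-best encodes exactly that. Exact
value ties are declared for neither candidate (conservative; ties have
measure zero on real data). Failed cells are absent candidates. The
top-3 lists of every bone are kept in the report for audit.

Mutual best is deliberately value-free: it never asks whether the winning
value is plausibly small. The known failure mode is that the leftover
unpaired bones of a left-only and a right-only individual can be mutual
nearest neighbours and be declared a (large-valued) false pair. On the
default synthetic populations this happens in roughly one population in
ten — measured at 10.3 % over 300 populations — and is visible in the
report because the false pair's value (≈ 2 mm) sits far above the
true-pair range (≈ 0.3–1.1 mm). The threshold analysis quantifies the
same information (mean + 2·SD of true-pair values, sample SD with the
n−1 denominator, plus counts of true and non-pair values under the
cutoff) but is kept diagnostic: as a declaration rule a single cutoff
fails in the opposite direction whenever the distributions overlap.

Scoring is per bone, the only unit that is consistent with counting a
perfect 21-pair/3-singleton assemblage as 42 true positives. A truly
paired bone placed in a wrong pair counts as a false positive (it asserts
a match that does not exist); its abandoned partner, if left single,
counts as a false negative. A swap between two true pairs therefore
counts 4 FP, not 2 FP + 2 FN. Sensitivity and specificity are displayed
rounded to whole percent; JSON output keeps full precision. A zero
denominator is reported as `n/a`, distinguishing "nothing to detect" from
failure.

## Synthetic populations

The generator replaces unavailable scan collections with a procedural
shape family: a tubular shaft (length ~300 mm, radius ~10 mm, gentle
bow) with two enlarged elliptical ends and a low-order radial modulation
field that individualises each bone. What matters for pair-matching is
not anatomical realism but the ratio of between-individual variation to
within-pair asymmetry, and both are explicit: `individual_variation`
scales the parameter spread (at the default 1.0, different individuals
differ by several mm of surface distance), `asymmetry_mm` sets the RMS
amplitude of a smooth displacement field applied along the left bone's
normals (default 0.3 mm), and `surface_noise_mm` adds per-vertex jitter
(default 0.05 mm). Every mesh is re-posed by a random rigid motion so
nothing downstream can exploit initial placement. Singletons are extra
individuals contributing one side only; the default composition is one
left-only and two right-only individuals, matching a typical assemblage.
With these defaults true-pair values land at 0.31–1.11 mm — inside the
0.4–1.2 mm band reported for real paired humeri, a plausibility anchor
rather than an equivalence claim.

Two deliberate realism choices: meshes are closed (watertight, outward
winding, Euler characteristic 2), and the triangulation is irregular —
ring heights and angular positions are jittered (seeded per bone).
Scanned surfaces never come on a regular lattice, and a regular lattice
is not merely cosmetic: it creates artificial "lattice-locking" local
minima for vertex-correspondence ICP that produced value scatter of
0.36–0.92 mm across restarts on a single pair; with irregular
triangulations the value is stable to < 10⁻⁴ mm.

What the generator does *not* emulate: real anatomy (muscle attachment
sites, torsion), fragmentation and taphonomic damage, scanner-specific
artefacts (holes, hole-filling), or spatially correlated scan noise.
Passing tests therefore demonstrate the pipeline's behaviour under
controlled separation of shape scales, not its accuracy on real bone
scans.

## Numerical choices

- STL input is welded at 10⁻⁸ × the bounding-box diagonal (STL stores
  per-facet vertices; welding is idempotent). OBJ/PLY vertices are taken
  as stored; stored normals are ignored and recomputed.
- Vertex normals are area-weighted averages of incident face normals
  (raw cross products, whose magnitude is twice the face area, summed per
  vertex). Isolated vertices get a zero normal, are flagged, and are
  excluded from normal-compatibility tests.
- Rotations are validated to orthonormality and det +1 within 10⁻⁸ and
  renormalised by polar decomposition on construction, so long
  composition chains cannot drift.
- Degenerate faces (repeated indices or area below 10⁻¹² mm²) are dropped
  on read.
- Deviation maps sign the nearest-vertex distance by the reference
  normal (positive = comparison outside reference) and label vertices
  within / larger / smaller against a band half-width (default 0.645 mm,
  a convenient scale for humeri).

## Problem sizes

The test suite and the acceptance script run at the "standard" mesh
resolution of ≈ 2000 vertices per bone, with populations of 10 pairs + 3
singletons (11 lefts × 12 rights = 132 registrations per population); one
population takes ≈ 25 s on one CPU. The planted-truth recovery test runs
20 such populations; the acceptance script runs 10 and a few
arithmetic-level checks.

## Known limitations

- The original software's value formula is proprietary and explicitly not
  a simple average of inter-surface distances; the symmetric RMS here is
  a principled stand-in, so absolute values are comparable within this
  package only, not across packages.
- Mutual-best matching declares cross-side leftover singletons as a pair
  in ~10 % of default-sized synthetic assemblages (see above); analysts
  should check declared-pair values against the true-pair value range in
  the report.
- Vertex-correspondence evaluation inflates values by up to ~0.2 mm at
  2k-vertex resolution; resolutions should be kept comparable across a
  study.
- Pose invariance of the value is exact for well-separated optima (copies
  of a shape re-posed arbitrarily agree to < 10⁻⁶ mm) but only ~1 %-level
  for pairs with substantial asymmetry, where point-to-plane ICP has a
  cluster of near-equivalent fixed points.
- No non-manifold repair, texture handling, or CT/DICOM segmentation;
  inputs are assumed to be clean triangle surfaces in mm.
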