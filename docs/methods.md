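# Methods

## Problem and model

Segmentation networks for short-axis cardiac MRI label each slice with four
classes: background (0), compacted external layer EL (1), internal cavity
IC (2) and trabecular zone TZ (3). The diagnostic statistic is the
trabecular volume percentage

    VT% = V_TZ / (V_TZ + V_EL) * 100,

with an LVNC call when VT% strictly exceeds 27.4. The cavity volume is
reported but never enters the denominator. VT% is a pure ratio, so it is
invariant to voxel geometry; absolute volumes use
`pixel_spacing_x * pixel_spacing_y * (slice_thickness + slice_gap)` per
labelled pixel (default geometry 1.5 × 1.5 × (8 + 2) mm). Whether per-slice
geometry weighting or raw counts are used is immaterial under uniform
geometry, which is the only case the package supports; the ratio cancels
either way.

Network hallucinations — extra ventricle-like regions, typically the right
ventricle — add spurious EL/TZ pixels and bias VT%. The clean-up treats
each slice's foreground as candidate clusters and keeps, across the stack,
the single track most consistent with one ventricle.

## Cluster generation (per slice)

1. **Top-3 components.** Connected components of the non-background mask
   under 8-connectivity (diagonal contact counts; the permissive standard
   for blob-like anatomy — 4-connectivity is available via `ClusterConfig`).
   Components are ordered by size, ties broken toward the smaller
   (row, col) centroid in lexicographic order; only the three largest are
   kept.
2. **IC+TZ splitting.** If a component's IC∪TZ pixels form more than one
   connected component, the cluster is split: each core seeds a sub-cluster
   and every EL pixel joins the sub-cluster containing its nearest pixel.
   Nearest-pixel (not centroid) distance is used because EL forms a ring
   around the cores and centroid distance mis-assigns ring pixels.
   Distances are exact integer squared Euclidean values; ties go to the
   larger sub-cluster.
3. **Mini-cluster merging.** Fragments smaller than 5% of the largest
   cluster are absorbed, smallest first and re-evaluated after each merge,
   into the cluster nearest by minimum pairwise pixel distance. The merge
   applies **within each fragmented component only**: fragments are
   artefacts of step 2, whereas separate components are genuine rival
   candidates that the selection stage must be allowed to reject. (Merging
   across components would absorb any small far hallucination straight into
   the ventricle — e.g. a 250-px right-ventricle mimic against a 5600-px
   ventricle — and defeat the entire clean-up.) Merged pixels keep their
   class labels; the alternative reading, relabelling absorbed mini-cluster
   pixels, is noted but not implemented. A merged cluster is a set union
   and is not guaranteed connected; connectivity is an invariant of steps 1
   and 2 only.

Pixels and labels are conserved through steps 2–3; only components beyond
the third largest are discarded. Splitting may raise the cluster count
above three.

## Cluster selection (across slices)

Let the candidates of slice *i* be C_i. Overlap between clusters a, b
(possibly from different slices, compared on 2D coordinates) is

    overlap(a, b) = 100 * |a ∩ b| / min(|a|, |b|),

symmetric and robust to the apex/base size taper (the natural alternative,
|a ∪ b| in the denominator, would flag the taper itself as inconsistency).

The selection iterates:

1. choose one cluster per non-skipped, non-empty slice minimising the sum
   of Euclidean distances between consecutive centroids — exact dynamic
   programming over per-slice candidates, skipped slices removed from the
   chain so their neighbours become adjacent; ties prefer larger total
   cluster size, then lexicographically smallest candidate indices;
2. if every adjacent pair overlaps ≥ 20%, go to 6;
3. otherwise count for each chosen cluster how many *other chosen*
   clusters overlap it > 20% ("valid overlaps"); the census is over chosen
   clusters only, not all candidates, since this step refines the sequence
   of step 1 (the broader reading is isolated in one helper and could be
   swapped);
4. add the earliest non-fixed slice with the fewest valid overlaps to the
   skip list; back to 1;
5. (step 6) on first arrival: mark surviving slices *fixed* (their DP
   choice is pinned and they can no longer be skipped), clear the skip
   list, rerun — previously skipped slices get a second chance against the
   trusted track; on second arrival, or when nothing remains skippable,
   stop;
6. output the chosen cluster per slice; skipped slices become blank
   (background) — the ventricle is declared "not found" there.

Each iteration either skips one slice or is one of at most two step-6
arrivals, so the loop terminates within 2 × n_slices + 2 iterations. The DP
is checked against exhaustive enumeration (same tie-break key) in the test
suite and the acceptance script.

## Evaluation

Per-class Dice 2|P∩T| / (|P|+|T|) is pooled over a patient's slices for the
patient report and also emitted per slice (for end-slice and area
analyses); whether population averages should be per-image or per-patient
is left to the caller, who can aggregate either table. Both-empty classes
score 1.0 — required so that correctly blank (skipped) slices count as
agreement. Diagnostic metrics from patient-level confusion counts use the
standard definitions; a zero-denominator metric is reported as absent
(None), never as 0. Report rounding is half-up at 3 decimals.

## Synthetic phantoms

No public dataset exists, so phantoms provide ground truth: an EL annulus
around a trabecular crown of radial TZ spokes around an IC pool, with the
radius tapering linearly toward the end slices (real stacks lose
trabeculation near apex and base). The crown is drawn as spokes so TZ is
contiguous with EL yet separable from IC, which exercises the splitting
branch. Defaults: 200 px frame (the segmentation core's working
resolution), 10 slices (typical short-axis coverage at 10 mm pitch),
48 px outer radius (≈72 mm ventricle diameter at 1.5 mm pixels, matching
the enlarged hypertrophic hearts that dominate the clinical population),
12 px wall, crown fraction 0.45, taper 0.35, 12 spokes at 0.5 angular
fill. Distractor kinds: `rv_mimic` (EL ring + IC core, the classic
mislabel), `el_fragment` (stray wall blob), `mini_cluster` (TZ speck);
their pixels are recorded as hallucination masks and must not touch the
true ventricle. `degrade_phantom` flips a fraction (≤0.2) of
class-boundary pixels to a neighbouring class, emulating ragged network
borders. Generation is a pure function of (config, seed).

Phantoms are schematic concentric shapes, not anatomy: passing tests show
the algorithms implement their contracts (splitting, merging, skipping,
DP optimality, conservation), not that any network segments real MRI well.
Clinical Dice levels and their improvements are not reproducible without
the private hospital data and trained weights; the published patient-level
confusion fractions are, and the package reproduces the derived metric
table exactly at 3 decimals.

## Network contracts

Only the arithmetic facts of the architectures are encoded: the
full-resolution wrapper maps (H, W) → (H/4, W/4) → (H, W) for sides
divisible by 4 (800 → 200 → 800 in the reference setting; batch
normalization in the wrapper blocks, as specified there, although the
nested variants use instance normalization internally); the
deep-supervision loss is the fixed combination (0.25, 0.25, 0.5, 0.75, 1.0)
of the four side outputs and the fused output; transfer learning freezes
every encoder-path parameter group (the X[i,0] backbone column in the
nested variant) and only decoder groups remain trainable. No layers are
instantiated and no training behaviour is claimed; the refinement stage's
schedule is out of scope.

## Numerical choices and edge cases

- All pixel-set distance computations use exact integer squared distances
  (KD-tree distances squared and rounded back to integers), so tie-breaks
  are deterministic and platform-independent.
- DP path costs accumulate float centroid distances left-to-right in the
  same order as the enumeration oracle, making equality exact in tests.
- An all-background slice has no candidates and is treated as skipped; an
  all-background stack yields an all-blank result and VT% = 0 (zero
  denominator guarded).
- NIfTI carries geometry as pixdim (sx, sy, thickness+gap) plus a
  `descrip` field `sx=..;sy=..;thk=..;gap=..`, because the format has no
  standard slot for slice gap; PNG directories use a JSON sidecar. Slice
  order is 0-based, NIfTI slice axis is the third array axis, and
  apex-first vs base-first is accepted as given (all algorithms are
  direction-symmetric).
- The strict boundary of the LVNC rule means VT% = 27.4 is negative.
- `normalized_slice` = (s − min)/(max − min) over a patient's slice
  numbers; a single-slice patient is rejected (zero denominator).

## Problem sizes in checks

The acceptance script uses 200 random selection instances (≤6 slices, ≤3
candidates) for the DP-vs-enumeration check and 100 default-size phantoms
(200 px, 10 slices, one jittered RV mimic) for the removal/recovery study;
the mean Dice gain on affected images is measured on 5%-degraded copies of
the same phantoms. These sizes were chosen as the smallest that exercise
every branch with comfortable statistical margin.

## Known limitations

- Phantom anatomy is schematic; no intensity images, no network inference.
- Selection assumes one ventricle per stack and no temporal (cardiac-phase)
  linking.
- Only uniform voxel geometry per stack is modelled.
- The "evidence the skip list" step of the published selection procedure is
  read as "empty the skip list" (a likely typo); the two-pass bound
  implemented here is the most conservative terminating reading of the
  loop-exit wording.
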