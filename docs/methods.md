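# Methods

This note documents the models, parameter choices and numerical details
behind `nucleotrace`, and what the synthetic-scene tests do and do not
demonstrate about real microscope data.

## Imaging model and the synthetic generator

The generator emulates wide-field two-channel (Hoechst / PI) time-lapse
acquisition of adherent neurons at desk scale: 25 frames standing for
24 h at 1 h intervals, 256×256-px fields (the reference instrument's
1024×1024 geometry is available via `frame_shape`), ~100 nuclei per
field.

**Nuclei.** A nucleus of nominal radius `r` is an isotropic Gaussian blob
with σ = r/2 truncated at 2.5σ, so its rendered support is the disk of
radius 1.25 r; that disk is also the ground-truth mask. Blob profiles are
brightest in the centre and dim toward the edges, matching the appearance
of stained condensed nuclei. Default radii are drawn U(5.5, 7.5) px so
segmented equivalent diameters (~2.5 r ≈ 14–19 px) fill the 9–20 px
Hoechst size gate, with room for condensed nuclei to stay above the lower
bound.

**States.** Each cell carries a per-frame schedule over
viable < apoptotic < necrotic that never decreases (death is
irreversible; apoptotic → necrotic models secondary necrosis). Defaults:
35% of cells become apoptotic, 25% primary necrotic, 15% of the apoptotic
rupture later; onset times are uniform over the interior frames.
Apoptotic nuclei render at 0.75× radius (≈ half the area) and 2× Hoechst
amplitude — chromatin condensation concentrates the dye. Necrotic nuclei
keep viable Hoechst appearance and gain a PI blob of comparable
amplitude. After secondary necrosis a nucleus is rendered like a primary
necrotic one (swollen, PI-positive); its condensed history survives only
in the state schedule.

**Motion.** Adherent neurons wobble rather than diffuse: trajectories are
mean-reverting (AR(1), pull 0.8) jitter around a fixed anchor with
per-frame step length hard-capped at `max_step` (default 2 px). A free
random walk over 25 frames would let initially separated nuclei collide
and would confound the clump-placement statistics.

**Placement and clumps.** Free cells sit on a jittered grid (keeping
nearest neighbours beyond one diameter); `clump_fraction` controls pairs
placed at 0.80–0.95 of one diameter, so `round(f·n/2)` satellite/anchor
pairs yield `f·n ± 1` cells whose nearest neighbour is closer than their
own diameter. An explicit capacity error is raised when the requested
density cannot be placed.

**Artifacts.** A planar background field (offset 200, amplitude 300 in
Hoechst by default — roughly 10% of blob peak), Gaussian read noise
(sd 20), per-cell per-frame multiplicative lognormal jitter of amplitude
(sd 0.12) and apparent radius (sd 0.04) emulating focus drift and
staining fluctuation, and transient dropouts (15% of cells invisible for
1–3 consecutive frames) exercising gap closing. Output is clipped to the
unsigned 16-bit camera range. All randomness derives from one seed; a
scene re-renders bit-for-bit.

**What the generator does not model:** optical PSF and defocus blur,
photobleaching kinetics, neurites and cytoplasmic background, cell
migration in/out of the field, plate-wide illumination drift over time,
and coordinated (wave-like) death. Passing tests therefore demonstrate
the correctness and internal consistency of the algorithms under the
stated statistical structure, not performance on any particular
instrument's data.

## Illumination correction

Additive model: observed = signal + smooth background. The background is
probed by per-block minima (8×8-px blocks; edge blocks smaller than 8×8
use their own minima, avoiding padding bias), smoothed by a 3×3 median
over the *block grid* (robust to a single saturated debris block — an
isolated outlier block cannot change the median of any neighbourhood it
does not dominate), bilinearly upsampled, and subtracted with clipping at
zero (negative intensities are meaningless and break thresholding). One
field is estimated per image; no cross-frame model is assumed. The block
size must satisfy 2 ≤ B ≤ min(H, W) and the block grid must be at least
as large as the median footprint.

## Segmentation

**Thresholding.** Otsu's criterion is evaluated on log1p intensities in
64-px windows, thresholds interpolated bilinearly between windows, with a
global floor of median + 4·(1.4826·MAD) of the frame. The log transform
matters: on a linear scale a window holding both bright and dim nuclei
puts the threshold inside the dim nuclei and clips them below the size
gate. The floor tracks the noise band, so windows containing only
background contribute no spurious foreground; constant images yield empty
masks by definition.

**Declumping.** Watershed on the distance transform of the binary mask
("shape-based"; intensity deliberately plays no role because intensity is
the phenotype signal). Seeds are local maxima of the *unsmoothed*
distance transform — on a clean binary mask these are stable — merged
greedily (deepest first) whenever two maxima lie within
`maxima_min_distance_px` *Euclidean* distance (default
min_diameter − 2 px: merging at the full minimum diameter under-segments
legitimate tight pairs). The watershed surface itself is the distance
transform mean-filtered with a 5-px kernel so dividing lines are smooth.
Any connected component left without a seed keeps its distance maximum,
so the watershed never loses (or creates) foreground. For two equal
overlapping discs the cut is the perpendicular bisector by symmetry.

**Size gate.** "9–20 px" (Hoechst) and "7–20 px" (PI) are interpreted as
equivalent-circle diameter — a 7-px² area object would be ~3 px across,
below reliable detection — with `interpret_as="area"` available. Kept
objects are relabelled consecutively; discarded ones returned separately
for audit.

**Features.** Per kept Hoechst label: unweighted centroid, area,
Hoechst mean/min/max/SD, and mean PI over the same support. The channels
are assumed pixel-registered. PI-channel segmentation exists as an
independent path with its own defaults, but classification consumes PI
intensity under Hoechst-derived labels: the class decision needs PI per
nucleus, not per PI object.

## Tracking

Frame-pair linking minimises total squared centroid displacement subject
to a hard gate (default 10 px), formulated as the standard augmented
(n+m)×(n+m) assignment matrix with birth/death alternatives priced at the
squared gate; `scipy.optimize.linear_sum_assignment` solves it exactly,
so per-pair linking cost equals the exhaustive-search optimum (verified
against brute force in the tests). Intensity/area terms are excluded from
the cost on purpose — they carry the phenotype.

Gap closing joins a fragment ending at frame t to one starting at
t+g+1 for 1 ≤ g ≤ 3, within a search radius growing linearly with the
gap (gate·(g+1), a diffusive bound); candidate joins are applied in order
of increasing distance with deterministic tie-breaks. Fragments that
cannot be joined remain separate, and chains with fewer than 3 detections
are discarded — the reading adopted for the ambiguous rule that tracks
with longer gaps are dropped. Merge and split events are recorded between
adjacent frames only (a track ending next to a continuing track = merge;
a track starting next to one = split); measurements are never averaged
across merged identities. Finally, tracks are padded to the full movie
with EXTENDED records carrying no measurements.

## Classification

A depth-≤4 binary decision tree (minimum leaf 3; both hyperparameters
exposed) on the five Hoechst features separates class 1 (large uniform:
viable or necrotic) from class 2 (condensed bright: apoptotic). Training
requires ≥5 rows per class and both classes present; contradictory
duplicate rows resolve by majority leaf. The fitted tree is exported as
flat arrays (children/feature/threshold/leaf class) so models are plain
JSON and prediction is independent of the fitting library. The
scikit-learn fitter is deterministic for a fixed training set
(`random_state=0`); exact impurity tie-breaking follows its
implementation rather than a bespoke feature-order rule.

The PI threshold comes from calibration images: Otsu's criterion
partitions the per-nucleus mean PI values; if the two groups are well
separated (≥3 nuclei each, means ≥ 2×(sd₁+sd₂) apart) the threshold is
the midpoint of the group means — with widely separated populations the
Otsu objective is nearly flat between them and its discrete argmax can
land on a cluster tail, so the midpoint is the stable representative —
otherwise the controls are taken as all-negative and the threshold is
mean + 5·SD. The method used is recorded alongside the threshold.

Class 2 ⇒ apoptotic regardless of PI (a condensed PI-positive nucleus
stays "apoptotic"; the PI split applies only within class 1 — a known,
biologically lossy simplification for late secondary necrosis).
Class 1 ⇒ viable below the PI threshold, necrotic above it. Records
without measurements (gap/extended) classify as UNKNOWN.

## Feasibility validation

Allowed transitions: stay in any state, viable → apoptotic,
viable → necrotic, apoptotic → necrotic; nothing leaves necrosis and
apoptosis never reverts. With states ordered viable < apoptotic <
necrotic, feasible sequences are exactly the non-decreasing ones. The
transition matrix is a parameter, so other graphs can be swapped in.

The validator returns the feasible sequence minimising the number of
disagreements with known raw labels (UNKNOWN frames cost nothing and
inherit the chosen path's state), computed by dynamic programming over
3 states — O(9·T). Among minimum-discrepancy sequences the
reconstruction, walking forward over cost-to-go values, prefers the state
matching the raw label and then the earliest state in the death ordering,
i.e. transitions happen as late as the evidence allows. Tests verify the
DP against exhaustive enumeration of all monotone sequences (lengths ≤ 8)
under the same tie-break, and that no single-frame edit of the output can
stay feasible and reduce the disagreement count. A greedy
forward/backward two-pass corrector (keep the lower-discrepancy pass,
forward on ties) is retained as an optional mode (`validation =
"two_pass"`); it is never better than the exact DP and exists for
comparison with the heuristic it reproduces.

## Reporting

Per well, the denominator is the number of tracks — constant across
frames because extension makes every track full-length — so per-frame
fractions of viable/apoptotic/necrotic sum to 1 exactly. Condition
summaries are medians and quartiles across wells plus an endpoint table;
significance testing is deliberately not reimplemented (the tidy CSVs
feed any stats tool). Plot helpers render the median ± IQR time-course,
endpoint boxplots and condition heatmaps.

## Problem sizes and determinism

The test suite and the acceptance script run at desk scale: 100 cells,
25 frames, 256×256 px per scene, a handful of seeded scenes per metric —
sizes chosen so the whole suite completes in well under a minute while
every statistic is estimated from thousands of object-frames. The full
pipeline is deterministic end to end for a fixed scene seed: reruns
produce byte-identical state tables, which the tests assert.

## Known limitations

- The apoptotic/viable contrast (0.75× radius, 2× intensity) is a
  stylised stand-in for a continuum of condensation morphologies; the
  classifier's measured accuracy on these scenes is an upper bound for
  real data.
- Merge/split lineage covers adjacent frames only; long co-moving clumps
  resolve through gap closing rather than explicit lineage.
- Cells never enter or leave the field; track extension therefore never
  has to distinguish death from emigration.
- Channels are assumed pixel-registered; no registration is performed.
- One illumination field per image; slow plate-wide drifts shared across
  frames are re-estimated each frame rather than modelled jointly.
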