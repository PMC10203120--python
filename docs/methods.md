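# Methods

## Problem setting

High-resolution 3D stacks (serial-section EM, confocal/widefield z-stacks)
are commonly segmented in two stages: a semantic stage that classifies voxels
as cell vs non-cell, and an instance stage that separates touching cells and
gives each one an ID. `seglink` implements the instance stage plus the
computer-assisted proofreading that realistic data always needs. The central
design premise is anisotropy: with a z step several times the in-plane pixel
size (e.g. 40 nm steps over 8 nm pixels), boundary evidence is far more
reliable within a slice than across slices, so the automatic stage works
slice-by-slice and identity along z is established by overlap, not by a 3D
watershed.

## Per-slice segmentation

For each binary slice: Euclidean distance transform of the foreground,
Gaussian blur of the distance map, h-maxima transform to find seeds, then a
marker-controlled watershed on the negated blurred map, masked to the
foreground. Every foreground pixel ends up in exactly one basin, so the
output partitions the predicted cell area.

Tunables (`Seg2DParams`):

- `gaussian_sigma` (px, default 2.0) — smooths the distance map so boundary
  roughness does not spawn spurious maxima.
- `h_maxima` (distance-map units, default 2.0) — minima shallower than `h`
  are not seeds; larger values mean fewer seeds per component. Both defaults
  were chosen once to give one seed per convex cell in the 10–50 px diameter
  range and are exposed in config; they are not sacred numbers.
- `connectivity_2d` (4 or 8, default 4) — 4 so that 1-px user-drawn
  boundaries disconnect regions, which the division operations rely on.
- `mask_threshold` (default 0.8) — with an ROI mask, a cell is deleted iff
  its in-ROI area proportion is *strictly* below the threshold (a cell at
  exactly the threshold is kept).

Degenerate inputs: a foreground component whose blurred distance map has no
h-maximum (small or flat) receives a single seed at its distance-map argmax,
first pixel in row-major order on ties. Seeds are renumbered 1..n in
row-major order of first occurrence, so identical inputs give bit-identical
labels.

The volumetric baseline (`watershed3d_baseline`) applies the same recipe in
3D (26-connectivity by default). It exists for comparison, not production
use; it is deliberately the distance-transform-watershed a practitioner would
get from standard tooling.

## Cross-slice linking

For cells X (slice i) and Y (slice i−1), the overlap coefficient is
`|X∩Y| / min(|X|, |Y|)`; pairs with coefficient strictly greater than
`overlap_threshold` (default 0.5; ties are not linked) form edges of a
bipartite graph between previous-slice final IDs and current-slice watershed
labels. Connected components of that graph define identity: every member
adopts the component's smallest previous ID, and previous IDs joined through
a shared current label are merged across all earlier slices. One rule
therefore covers ID propagation, automatic forward merge propagation (a
manual merge in slice i guides fragments in slice i+1 into one ID), and
backward merge propagation. Labels with no qualifying partner get fresh IDs
in ascending watershed-label order. Linking always uses the *resolved*
previous slice, so manual corrections immediately improve subsequent slices.
No slice-to-slice registration is attempted; displacement is treated as a
source of mistakes to correct manually.

## Storage layouts and editing

**Slice-wise store** (`LinkedStackState`): per slice, the immutable 2D
watershed label image plus a label list (groups mapping final ID → set of
watershed labels, and a tombstone set of deleted IDs). Merge/delete/link
rewrite only the lists; display/export resolves final IDs through a lookup
table. Rendering is windowed (default ±100 slices around the working slice)
because resolution is the expensive step. Division is the one operation that
must rewrite a slice's label image (it changes pixel geometry); it is
restricted to the current working slice in this store. Undo history holds 10
steps by default; every operation snapshots the label lists (plus the
affected base grid for division), and autosave after each slice/operation
writes a single zip archive (per-slice grids + JSON metadata). Resuming a
project restores the labels exactly but clears undo/redo.

**Dense store** (`LabelVolume`): a plain 3D integer array plus per-cell tight
bounding boxes and voxel counts, rebuilt incrementally after every operation.
The bbox cache serves two purposes: localization (`locate_cell` jumps to
`floor((z0+z1)/2)` and only ever scans inside the box) and memory-bounded
undo — each operation records voxel diffs only for the union of affected
bounding boxes (5 steps by default). Division and division+relink work at any
slice here; 3D division splits a cell into its 26-connected components
(permissive connectivity, so anisotropy alone does not cause spurious
splits). Insertion paints a new ID into background voxels only. Sorting by
volume relabels descending with ties broken by ascending old ID;
`remove_small` uses strict `<`.

Division semantics (both stores): connected components of the user-edited
mask become cells; the largest-area component keeps the original ID (a
deterministic stability choice — the rule itself is not externally dictated),
erased pixels stay background so the drawn boundary is visible, and fresh IDs
are issued in order of decreasing area then first pixel. Division+relink then
matches pieces to previous-slice cells by maximal overlap coefficient above
the threshold, at most one piece per previous ID (highest coefficient wins;
losers get fresh IDs so the division is not silently undone).

## Synthetic phantoms

`generate_phantom` emulates the regime the method targets, not microscopy
physics. Ground truth grows touching convex-ish cells from randomly placed
nuclei as a radius-weighted nearest-seed partition (a capped
multiplicatively-weighted Voronoi tessellation) in anisotropy-scaled
coordinates (`z_anisotropy` default 5, mirroring 40 nm z steps over 8 nm
pixels). Predictions are the foreground minus a 2-px inter-cell interface
computed with full 3D face adjacency — the membrane between z-stacked cells
is non-cell signal in the slices where they touch, which is exactly what
keeps their cross-sections disjoint for the linker. Failure modes are then
injected: each interface pixel flips back to foreground with
`boundary_dropout_rate`, and optional per-slice rigid shifts (applied to both
ground truth and predictions, since displacement is a property of the imaged
stack) emulate section misalignment.

What the phantoms do **not** model: intensity texture, membrane thickness
variation, imaging noise in the semantic stage, non-convex cell shapes
(processes, branching neurites), and staining artifacts. Passing the phantom
checks therefore shows the pipeline logic is correct under the stated failure
modes, not that any particular real dataset will segment at a given accuracy.

## Scoring

`score_segmentation` is detection-style: a ground-truth cell is
*undersegmented* when its best-matching predicted cell (max voxel overlap) is
also the best match of another true cell (or nothing covers it), and
*oversegmented* when more than one predicted cell claims at least 10%
(configurable) of its voxels. Both are reported as fractions of true cells.
The scores are invariant to relabeling of the prediction. These definitions
are this package's own; comparisons elsewhere that count mistakes differently
will produce different absolute percentages, so the benchmark here asserts
only the *direction* of the 2D+link vs 3D-watershed comparison, replicate by
replicate.

## Problem sizes and numerical choices

The shipped checks use a 64×256×256 clean phantom with ~50 cells (in-plane
radii 24–40 px) for the exactness check, and five 32×128×128 phantoms with 25
cells and 30% boundary dropout for the baseline comparison — sizes chosen so
a full verification run completes in well under a minute on one core while
still containing hundreds of cell-slice link decisions. Random-op properties
run 200 operation sequences against brute-force oracles (dense relabeling,
exhaustive bbox scans). All randomness flows from explicit seeds; identical
seeds give bit-identical volumes, labels and scores. Ties are broken
deterministically everywhere (row-major first pixel for seeds and pieces,
smallest ID for merges, ascending old ID for volume sorting).

## Known limitations

- Volumes must fit in memory; there is no out-of-core path.
- Linking is purely geometric overlap; no registration, shape priors, or
  probabilistic association. Strong per-slice displacement degrades linking
  and is left for manual correction.
- The multiplicatively-weighted Voronoi growth can in principle produce
  slightly non-convex cells when radii differ strongly; radii ratios ≤ ~2
  keep cross-sections convex-ish in practice.
- The backward merge rule (one current label confidently overlapping two
  previous IDs merges them) is a deliberate single-semantics choice; a
  max-overlap-only alternative would keep them separate. The threshold makes
  this rare on clean data, and division+relink exists to fix it when wrong.
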