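# seglink

Semi-automatic 3D cell segmentation from binary cell/non-cell predictions,
built for serial-section microscopy (e.g. EM connectomics) where the z step is
much coarser than the in-plane pixel size. Instead of a volumetric watershed —
which infers in-plane boundaries from poorly resolved neighboring slices —
`seglink` segments each slice independently with a seeded 2D watershed and
then links cells across slices, and it ships the full set of scriptable
proofreading operations (merge, delete, 2D/3D division, division+relink,
insert, sort, remove-small) with bounded undo/redo over two storage layouts
tuned for cheap editing.

## Method

**Per-slice instance segmentation.** Each binary prediction slice is turned
into cells by: Euclidean distance transform of the foreground → Gaussian blur
(σ = 2 px) → h-maxima seed detection (h = 2, suppressing shallow maxima so a
convex cell gets one seed) → marker-controlled watershed restricted to the
foreground. An optional ROI mask deletes cells whose in-ROI area proportion is
strictly below a threshold (default 0.8).

**Cross-slice linking.** A cell X in slice *i* and a cell Y in slice *i−1*
are linked when their overlap coefficient

    overlap(X, Y) = area(X ∩ Y) / min[area(X), area(Y)]

strictly exceeds a threshold (default 0.5). Links are resolved component-wise
on the bipartite overlap graph: all members of a component share one ID (the
smallest previous ID). This single rule also propagates manual merges — merge
two over-segmented IDs in slice *i* and the matching fragments in slice *i+1*
are merged automatically at link time.

**Two stores for proofreading.** The slice-wise store keeps, per slice, the
immutable watershed label image plus a small label list mapping watershed
labels to final cell IDs, so merge/delete/link rewrite only the lists (undo
capacity 10). The dense 3D store keeps a plain label volume with cached tight
bounding boxes and voxel counts per cell, making localization proportional to
cell size rather than image size and bounding the sub-region diffs recorded
for undo (capacity 5).

## Worked example

```python
import numpy as np
from seglink import (PhantomSpec, generate_phantom, run_seg2d_link,
                     resolve_volume, score_segmentation, watershed3d_baseline)

spec = PhantomSpec(shape=(32, 128, 128), n_cells=25,
                   boundary_dropout_rate=0.3, seed=1)
gt, pred = generate_phantom(spec)          # anisotropic phantom, 30% missing
state = run_seg2d_link(predictions=pred)   # slice-wise watershed + linking
print(score_segmentation(resolve_volume(state), gt))
print(score_segmentation(watershed3d_baseline(pred), gt))
```

prints

```
{'undersegmented_fraction': 0.28, 'oversegmented_fraction': 0.0}
{'undersegmented_fraction': 0.92, 'oversegmented_fraction': 0.0}
```

i.e. with 30% of boundary pixels missing, slice-wise watershed + linking
leaves 28% of the true cells under-segmented while the volumetric watershed
baseline (same distance-transform recipe applied in 3D) merges 92% of them —
the anisotropy makes 3D boundary inference much more fragile than in-plane
segmentation plus linking.

The same workflow is available from a shell:

```bash
seglink synth proj --shape 32,128,128 --n-cells 25 --seed 1
seglink run proj                 # resumable; autosaves after every slice
seglink import proj              # resolve Module-1 state into a 3D volume
seglink locate proj 5            # jump to a cell's central slice
seglink export proj out_tiffs    # one 16-bit TIFF per slice
```

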