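"""3D correction over a dense label volume with cached bounding boxes.

The Module-2 store keeps the segmentation as a plain 3D integer array plus two
caches: a tight bounding box and a voxel count per cell.  The bbox cache makes
cell localization depend on cell size rather than image size, and bounds the
sub-region voxel diffs recorded for undo/redo (default capacity 5 steps).
Corrections (merge, delete, 2D division, division+relink, 3D division, insert,
remove-small, sort-by-volume) update the caches incrementally; a property of
the design is that the incrementally maintained caches always equal a
from-scratch rebuild.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .crosslink import LinkParams
from .label_model import CellNotFoundError
from .segment2d import _conn_structure

__all__ = [
    "LabelVolume", "build_volume", "locate_cell", "sort_by_volume",
    "remove_small", "divide_3d", "insert_cell", "merge_cells_3d",
    "delete_cells_3d", "divide_cell_3d", "divide_relink_3d",
    "undo_3d", "redo_3d",
]

Bbox = tuple[int, int, int, int, int, int]  # (z0, z1, y0, y1, x0, x1) inclusive


@dataclass
class VolumeDelta:
    """Sub-region voxel diffs plus cache snapshots for one volume operation."""

    op_kind: str
    regions: list[tuple[Bbox, np.ndarray, np.ndarray]]  # (bbox, before, after)
    caches_before: tuple[dict, dict, int]
    caches_after: tuple[dict, dict, int]

    def _paint(self, vol: "LabelVolume", which: int) -> None:
        for bbox, before, after in self.regions:
            sub = before if which == 0 else after
            vol.labels[_bbox_slices(bbox)] = sub

    def apply_backward(self, vol: "LabelVolume") -> None:
        self._paint(vol, 0)
        vol.bboxes, vol.volumes, vol.next_id = _copy_caches(self.caches_before)

    def apply_forward(self, vol: "LabelVolume") -> None:
        self._paint(vol, 1)
        vol.bboxes, vol.volumes, vol.next_id = _copy_caches(self.caches_after)


def _copy_caches(caches):
    bboxes, volumes, next_id = caches
    return dict(bboxes), dict(volumes), next_id


def _bbox_slices(bbox: Bbox) -> tuple[slice, slice, slice]:
    z0, z1, y0, y1, x0, x1 = bbox
    return (slice(z0, z1 + 1), slice(y0, y1 + 1), slice(x0, x1 + 1))


def _bbox_union(a: Bbox, b: Bbox) -> Bbox:
    return (min(a[0], b[0]), max(a[1], b[1]), min(a[2], b[2]),
            max(a[3], b[3]), min(a[4], b[4]), max(a[5], b[5]))


@dataclass
class LabelVolume:
    """Dense 3D label grid + bbox/volume caches + bounded undo history."""

    labels: np.ndarray
    bboxes: dict[int, Bbox] = field(default_factory=dict)
    volumes: dict[int, int] = field(default_factory=dict)
    next_id: int = 1
    history_capacity: int = 5
    history: list[VolumeDelta] = field(default_factory=list)
    redo_stack: list[VolumeDelta] = field(default_factory=list)

    def ids(self) -> list[int]:
        return sorted(self.bboxes)

    def _require(self, cell_id: int) -> Bbox:
        try:
            return self.bboxes[int(cell_id)]
        except KeyError:
            raise CellNotFoundError(f"no cell with ID {cell_id}") from None

    # -- delta plumbing ----------------------------------------------------

    def _begin(self, bboxes_of_interest: list[Bbox]):
        """Snapshot the union sub-regions that the operation may touch."""
        merged: list[Bbox] = []
        for bbox in sorted(bboxes_of_interest):
            for i, m in enumerate(merged):
                if _bboxes_intersect(m, bbox):
                    merged[i] = _bbox_union(m, bbox)
                    break
            else:
                merged.append(bbox)
        before = [(b, self.labels[_bbox_slices(b)].copy()) for b in merged]
        caches = (dict(self.bboxes), dict(self.volumes), self.next_id)
        return before, caches

    def _commit(self, op_kind: str, before, caches_before) -> VolumeDelta:
        regions = [
            (bbox, old, self.labels[_bbox_slices(bbox)].copy())
            for bbox, old in before
        ]
        delta = VolumeDelta(
            op_kind, regions, caches_before,
            (dict(self.bboxes), dict(self.volumes), self.next_id),
        )
        self.history.append(delta)
        if len(self.history) > self.history_capacity:
            del self.history[: len(self.history) - self.history_capacity]
        self.redo_stack.clear()
        return delta

    def _rescan_region(self, bbox: Bbox, candidate_ids) -> None:
        """Recompute bbox/volume of the given IDs from the region + old bounds."""
        for cid in candidate_ids:
            cid = int(cid)
            scan = bbox
            if cid in self.bboxes:
                scan = _bbox_union(scan, self.bboxes[cid])
            sub = self.labels[_bbox_slices(scan)]
            hit = sub == cid
            n = int(hit.sum())
            if n == 0:
                self.bboxes.pop(cid, None)
                self.volumes.pop(cid, None)
                continue
            zz, yy, xx = np.nonzero(hit)
            self.bboxes[cid] = (
                scan[0] + int(zz.min()), scan[0] + int(zz.max()),
                scan[2] + int(yy.min()), scan[2] + int(yy.max()),
                scan[4] + int(xx.min()), scan[4] + int(xx.max()),
            )
            self.volumes[cid] = n


def _bboxes_intersect(a: Bbox, b: Bbox) -> bool:
    return (a[0] <= b[1] and b[0] <= a[1] and a[2] <= b[3]
            and b[2] <= a[3] and a[4] <= b[5] and b[4] <= a[5])


def _scan_caches(labels: np.ndarray) -> tuple[dict[int, Bbox], dict[int, int]]:
    """One-pass bbox + volume computation for every nonzero ID."""
    max_id = int(labels.max(initial=0))
    bboxes: dict[int, Bbox] = {}
    volumes: dict[int, int] = {}
    if max_id == 0:
        return bboxes, volumes
    objects = ndi.find_objects(labels, max_label=max_id)
    counts = np.bincount(labels.ravel(), minlength=max_id + 1)
    for cid, slc in enumerate(objects, start=1):
        if slc is None:
            continue
        # find_objects bounds may be loose for an ID when another ID fills the
        # corners, but never for the ID itself: they are exactly tight.
        bboxes[cid] = (slc[0].start, slc[0].stop - 1, slc[1].start,
                       slc[1].stop - 1, slc[2].start, slc[2].stop - 1)
        volumes[cid] = int(counts[cid])
    return bboxes, volumes


def build_volume(labels_3d: np.ndarray, history_capacity: int = 5) -> LabelVolume:
    """Wrap a dense 3D label grid, building the bbox and volume caches."""
    labels = np.asarray(labels_3d)
    if labels.ndim != 3:
        raise ValueError("expected a 3D label grid")
    if not np.issubdtype(labels.dtype, np.integer):
        raise ValueError("labels must be integers")
    if labels.size and labels.min() < 0:
        raise ValueError("labels must be non-negative")
    labels = labels.copy()
    bboxes, volumes = _scan_caches(labels)
    next_id = max(bboxes, default=0) + 1
    return LabelVolume(labels, bboxes, volumes, next_id,
                       history_capacity=history_capacity)


def locate_cell(vol: LabelVolume, cell_id: int, use_cache: bool = True):
    """Return (middle_z, bbox) of a cell; middle_z = floor bbox z-midpoint.

    ``use_cache=False`` performs the exhaustive full-volume scan instead, for
    verification and timing comparisons.
    """
    cell_id = int(cell_id)
    if use_cache:
        bbox = vol._require(cell_id)
    else:
        hit = vol.labels == cell_id
        if not hit.any():
            raise CellNotFoundError(f"no cell with ID {cell_id}")
        zz, yy, xx = np.nonzero(hit)
        bbox = (int(zz.min()), int(zz.max()), int(yy.min()),
                int(yy.max()), int(xx.min()), int(xx.max()))
    middle_z = (bbox[0] + bbox[1]) // 2
    return middle_z, bbox


def sort_by_volume(vol: LabelVolume) -> LabelVolume:
    """Relabel so ID 1 is the largest cell; ties broken by ascending old ID."""
    if not vol.volumes:
        raise ValueError("volume contains no cells")
    full = (0, vol.labels.shape[0] - 1, 0, vol.labels.shape[1] - 1,
            0, vol.labels.shape[2] - 1)
    before, caches = vol._begin([full])
    order = sorted(vol.volumes, key=lambda cid: (-vol.volumes[cid], cid))
    mapping = {old: new for new, old in enumerate(order, start=1)}
    lut = np.zeros(max(vol.bboxes) + 1, dtype=vol.labels.dtype)
    for old, new in mapping.items():
        lut[old] = new
    vol.labels[...] = lut[vol.labels]
    vol.bboxes = {mapping[o]: b for o, b in vol.bboxes.items()}
    vol.volumes = {mapping[o]: v for o, v in vol.volumes.items()}
    vol.next_id = len(order) + 1
    vol._commit("sort", before, caches)
    return vol


def remove_small(vol: LabelVolume, min_voxels: int):
    """Remove every cell strictly smaller than ``min_voxels``; returns IDs."""
    if min_voxels < 0:
        raise ValueError("min_voxels must be >= 0")
    removed = sorted(c for c, v in vol.volumes.items() if v < min_voxels)
    before, caches = vol._begin([vol.bboxes[c] for c in removed])
    for cid in removed:
        region = _bbox_slices(vol.bboxes[cid])
        sub = vol.labels[region]
        sub[sub == cid] = 0
        del vol.bboxes[cid]
        del vol.volumes[cid]
    vol._commit("remove_small", before, caches)
    return vol, removed


def divide_3d(vol: LabelVolume, cell_id: int, connectivity_3d: int = 26):
    """Split a cell into its 3D connected components (26-connectivity default).

    The largest component keeps ``cell_id``; the others get fresh IDs in
    deterministic order (size descending, then first-voxel order).  Useful for
    cells incorrectly linked along the z-axis.  Returns (vol, new_ids).
    """
    cell_id = int(cell_id)
    bbox = vol._require(cell_id)
    before, caches = vol._begin([bbox])
    region = _bbox_slices(bbox)
    sub = vol.labels[region]
    mask = sub == cell_id
    structure = _conn_structure(3, connectivity_3d)
    comps, n_comp = ndi.label(mask, structure=structure)
    new_ids: list[int] = []
    if n_comp > 1:
        areas = np.bincount(comps.ravel())[1:]
        first_vox = [int(np.flatnonzero(comps.ravel() == i + 1)[0])
                     for i in range(n_comp)]
        order = sorted(range(n_comp), key=lambda i: (-areas[i], first_vox[i]))
        for rank, i in enumerate(order):
            if rank == 0:
                continue
            nid = vol.next_id
            vol.next_id += 1
            sub[comps == i + 1] = nid
            new_ids.append(nid)
        vol._rescan_region(bbox, [cell_id] + new_ids)
    vol._commit("divide3d", before, caches)
    return vol, new_ids


def insert_cell(vol: LabelVolume, painted: np.ndarray):
    """Insert a manually painted new cell into background voxels.

    All painted voxels must currently be background; the new cell receives the
    next automatically assigned ID.  Returns (vol, new_id).
    """
    painted = np.asarray(painted, dtype=bool)
    if painted.shape != vol.labels.shape:
        raise ValueError("painted grid shape must match the volume")
    if not painted.any():
        raise ValueError("painted region is empty")
    if (vol.labels[painted] != 0).any():
        raise ValueError("painted region overlaps existing cells; "
                         "insert targets undetected (background) regions")
    zz, yy, xx = np.nonzero(painted)
    bbox: Bbox = (int(zz.min()), int(zz.max()), int(yy.min()),
                  int(yy.max()), int(xx.min()), int(xx.max()))
    before, caches = vol._begin([bbox])
    new_id = vol.next_id
    vol.next_id += 1
    vol.labels[painted] = new_id
    vol.bboxes[new_id] = bbox
    vol.volumes[new_id] = int(painted.sum())
    vol._commit("insert", before, caches)
    return vol, new_id


def merge_cells_3d(vol: LabelVolume, ids) -> LabelVolume:
    """Merge cells into the smallest ID of the set, across the whole volume."""
    ids = {int(i) for i in ids}
    if len(ids) < 2:
        raise ValueError("merge requires at least two cell IDs")
    boxes = [vol._require(i) for i in ids]
    target = min(ids)
    others = ids - {target}
    before, caches = vol._begin(boxes)
    union = boxes[0]
    for b in boxes[1:]:
        union = _bbox_union(union, b)
    for cid in others:
        region = _bbox_slices(vol.bboxes[cid])
        sub = vol.labels[region]
        sub[sub == cid] = target
        del vol.bboxes[cid]
        del vol.volumes[cid]
    vol._rescan_region(union, [target])
    vol._commit("merge", before, caches)
    return vol


def delete_cells_3d(vol: LabelVolume, ids) -> LabelVolume:
    """Set the given cells' voxels to background."""
    ids = {int(i) for i in ids}
    boxes = [vol._require(i) for i in ids]
    before, caches = vol._begin(boxes)
    for cid in ids:
        region = _bbox_slices(vol.bboxes[cid])
        sub = vol.labels[region]
        sub[sub == cid] = 0
        del vol.bboxes[cid]
        del vol.volumes[cid]
    vol._commit("delete", before, caches)
    return vol


def _divide_slice_components(vol: LabelVolume, z: int, cell_id: int,
                             edited_mask: np.ndarray, connectivity_2d: int):
    """2D division at any slice z of the dense volume (shared core)."""
    cell_id = int(cell_id)
    bbox = vol._require(cell_id)
    if not 0 <= z < vol.labels.shape[0]:
        raise IndexError(f"slice index {z} out of range")
    plane = vol.labels[z]
    cell_pixels = plane == cell_id
    if not cell_pixels.any():
        raise CellNotFoundError(f"cell {cell_id} has no pixels in slice {z}")
    mask = np.asarray(edited_mask, dtype=bool)
    if mask.shape != plane.shape:
        raise ValueError("edited mask shape must match a slice")
    if not mask.any():
        raise ValueError("edited mask is empty")
    if (mask & ~cell_pixels).any():
        raise ValueError("edited mask must be a subset of the cell's pixels")

    structure = _conn_structure(2, connectivity_2d)
    comps, n_comp = ndi.label(mask, structure=structure)
    areas = np.bincount(comps.ravel())[1:]
    first_px = [int(np.flatnonzero(comps.ravel() == i + 1)[0])
                for i in range(n_comp)]
    order = sorted(range(n_comp), key=lambda i: (-areas[i], first_px[i]))

    plane[cell_pixels] = 0
    piece_ids, piece_masks = [], []
    for rank, i in enumerate(order):
        piece = comps == i + 1
        if rank == 0:
            pid = cell_id
        else:
            pid = vol.next_id
            vol.next_id += 1
        plane[piece] = pid
        piece_ids.append(pid)
        piece_masks.append(piece)
    vol._rescan_region(bbox, [cell_id] + piece_ids[1:])
    return bbox, piece_masks, piece_ids


def divide_cell_3d(vol: LabelVolume, z: int, cell_id: int,
                   edited_mask: np.ndarray, connectivity_2d: int = 4):
    """2D division of a cell at ANY slice of the dense volume.

    Only slice z's voxels of the cell change; the largest piece keeps the ID.
    Returns (vol, new_ids).
    """
    cell_bbox = vol._require(int(cell_id))
    before, caches = vol._begin([cell_bbox])
    _, _, piece_ids = _divide_slice_components(vol, z, cell_id, edited_mask,
                                               connectivity_2d)
    vol._commit("divide", before, caches)
    return vol, piece_ids[1:]


def divide_relink_3d(vol: LabelVolume, z: int, cell_id: int,
                     edited_mask: np.ndarray, params: LinkParams | None = None,
                     connectivity_2d: int = 4):
    """2D division at slice z followed by relinking pieces to slice z-1.

    Each piece adopts the previous-slice ID of maximal overlap coefficient
    among those exceeding the threshold; one piece per previous ID.  Returns
    (vol, piece_ids).
    """
    if z < 1:
        raise ValueError("divide_relink requires a previous slice (z >= 1)")
    params = params or LinkParams()
    cell_bbox = vol._require(int(cell_id))
    # relinking can repaint pieces to IDs whose bboxes must then grow; snapshot
    # a region wide enough for any candidate previous-slice partner
    prev_plane = vol.labels[z - 1]
    mask = np.asarray(edited_mask, dtype=bool)
    if mask.shape != prev_plane.shape:
        raise ValueError("edited mask shape must match a slice")
    candidate_prev = {int(p) for p in np.unique(prev_plane[mask]) if p != 0}
    boxes = [cell_bbox] + [vol.bboxes[p] for p in candidate_prev
                           if p in vol.bboxes]
    before, caches = vol._begin(boxes)
    _, piece_masks, piece_ids = _divide_slice_components(
        vol, z, cell_id, edited_mask, connectivity_2d
    )

    candidates = []
    for rank, piece in enumerate(piece_masks):
        area_piece = int(piece.sum())
        overlap_ids, counts = np.unique(prev_plane[piece], return_counts=True)
        for pid, n in zip(overlap_ids, counts):
            if pid == 0:
                continue
            area_prev = int((prev_plane == pid).sum())
            coeff = int(n) / min(area_piece, area_prev)
            if coeff > params.overlap_threshold:
                candidates.append((coeff, rank, int(pid)))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    assigned: dict[int, int] = {}
    used_prev: set[int] = set()
    for coeff, rank, pid in candidates:
        if rank in assigned or pid in used_prev:
            continue
        assigned[rank] = pid
        used_prev.add(pid)

    plane = vol.labels[z]
    touched = set()
    for rank in range(len(piece_ids)):
        if rank in assigned:
            fid = assigned[rank]
        elif piece_ids[rank] in used_prev:
            fid = vol.next_id
            vol.next_id += 1
        else:
            continue
        old = piece_ids[rank]
        plane[piece_masks[rank]] = fid
        touched.update((old, fid))
        piece_ids[rank] = fid
    rescan_box = cell_bbox
    for pid in touched:
        if pid in vol.bboxes:
            rescan_box = _bbox_union(rescan_box, vol.bboxes[pid])
    vol._rescan_region(rescan_box, sorted(touched | set(piece_ids)))
    vol._commit("divide_relink", before, caches)
    return vol, piece_ids


def undo_3d(vol: LabelVolume) -> LabelVolume:
    """Revert the most recent volume operation via its sub-region diffs."""
    if not vol.history:
        warnings.warn("nothing to undo", stacklevel=2)
        return vol
    delta = vol.history.pop()
    delta.apply_backward(vol)
    vol.redo_stack.append(delta)
    return vol


def redo_3d(vol: LabelVolume) -> LabelVolume:
    """Re-apply the most recently undone volume operation."""
    if not vol.redo_stack:
        warnings.warn("nothing to redo", stacklevel=2)
        return vol
    delta = vol.redo_stack.pop()
    delta.apply_forward(vol)
    vol.history.append(delta)
    return vol
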