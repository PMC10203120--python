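"""Module-1 correction commands: merge, delete, divide, divide+relink, undo/redo.

Merge and delete rewrite only the per-slice label lists (stack-wide, so a
correction made on any slice also applies to previous slices).  Division
rewrites the base label grid of the current working slice, since it changes
pixel geometry; division+relink additionally re-attaches the resulting pieces
to the previous slice by maximal overlap coefficient.  Every command records a
reversible delta on a bounded history (default 10 steps).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage as ndi

from .crosslink import LinkParams, merge_final_ids, overlap_pairs
from .label_model import (
    CellNotFoundError,
    EditDelta,
    LinkedStackState,
    SliceSeg,
    load_state,
    resolve_slice,
    save_state,
)
from .segment2d import _conn_structure

__all__ = [
    "merge_cells", "delete_cells", "divide_cell", "divide_relink",
    "undo", "redo", "autosave", "resume",
]


def _check_ids_exist(state: LinkedStackState, ids) -> set[int]:
    ids = set(int(i) for i in ids)
    known = state.all_final_ids()
    missing = ids - known
    if missing:
        raise CellNotFoundError(f"unknown or deleted cell IDs: {sorted(missing)}")
    return ids


def _finish(state: LinkedStackState, op_kind: str, backward: dict) -> None:
    state.record(EditDelta(op_kind, forward=state.snapshot(), backward=backward))
    state.maybe_autosave()


def merge_cells(state: LinkedStackState, ids) -> LinkedStackState:
    """Merge the given cells into one, keeping the smallest ID, in every slice."""
    ids = _check_ids_exist(state, ids)
    if len(ids) < 2:
        raise ValueError("merge requires at least two cell IDs")
    backward = state.snapshot()
    merge_final_ids(state, ids)
    _finish(state, "merge", backward)
    return state


def delete_cells(state: LinkedStackState, ids) -> LinkedStackState:
    """Tombstone the given cells stack-wide; their pixels resolve to 0."""
    ids = _check_ids_exist(state, ids)
    backward = state.snapshot()
    for sl in state.slices:
        sl.deleted |= ids & set(sl.groups)
    _finish(state, "delete", backward)
    return state


def _divide_components(state: LinkedStackState, z: int, cell_id: int,
                       edited_mask: np.ndarray, connectivity_2d: int):
    """Shared core of divide/divide_relink: rewrite slice z's base grid.

    Returns (piece_masks, piece_ids) where piece 0 is the largest (keeps
    cell_id) and the rest received fresh IDs, all ordered deterministically
    (area desc, then first-pixel row-major).
    """
    if not 0 <= z < len(state.slices):
        raise IndexError(f"slice index {z} out of range")
    if z != state.working_slice:
        raise ValueError(
            f"division is only allowed in the current working slice "
            f"({state.working_slice}), not slice {z}"
        )
    cell_id = int(cell_id)
    resolved = resolve_slice(state, z)
    cell_pixels = resolved == cell_id
    if not cell_pixels.any():
        raise CellNotFoundError(f"cell {cell_id} has no pixels in slice {z}")
    mask = np.asarray(edited_mask, dtype=bool)
    if mask.shape != cell_pixels.shape:
        raise ValueError("edited mask shape must match the slice")
    if not mask.any():
        raise ValueError("edited mask is empty")
    if (mask & ~cell_pixels).any():
        raise ValueError("edited mask must be a subset of the cell's pixels")

    structure = _conn_structure(2, connectivity_2d)
    comps, n_comp = ndi.label(mask, structure=structure)
    areas = np.bincount(comps.ravel())[1:]
    first_px = [int(np.flatnonzero(comps.ravel() == i + 1)[0]) for i in range(n_comp)]
    order = sorted(range(n_comp), key=lambda i: (-areas[i], first_px[i]))

    sl = state.slices[z]
    new_base = np.array(sl.base_labels)  # writable copy
    old_bases = {b for fid, bases in sl.groups.items() if fid == cell_id for b in bases}
    next_base = int(new_base.max(initial=0)) + 1
    new_base[cell_pixels] = 0  # erased pixels become background

    groups = {fid: set(b) for fid, b in sl.groups.items() if fid != cell_id}
    piece_ids, piece_masks = [], []
    for rank, i in enumerate(order):
        piece = comps == i + 1
        new_base[piece] = next_base
        if rank == 0:
            pid = cell_id
        else:
            pid = state.next_id
            state.next_id += 1
        groups[pid] = {next_base}
        piece_ids.append(pid)
        piece_masks.append(piece)
        next_base += 1

    # base labels of the old cell that vanished keep no group entry
    state.slices[z] = SliceSeg(new_base, groups=groups, deleted=set(sl.deleted))
    return piece_masks, piece_ids


def divide_cell(state: LinkedStackState, z: int, cell_id: int,
                edited_mask: np.ndarray, connectivity_2d: int = 4):
    """Divide a cell in the current working slice along user-erased boundaries.

    Connected components of ``edited_mask`` become separate cells; the largest
    keeps ``cell_id``, the others get fresh IDs; erased pixels (cell minus
    mask) become background.  Returns (state, new_ids).
    """
    backward = state.snapshot()
    _, piece_ids = _divide_components(state, z, cell_id, edited_mask, connectivity_2d)
    _finish(state, "divide", backward)
    return state, piece_ids[1:]


def divide_relink(state: LinkedStackState, z: int, cell_id: int,
                  edited_mask: np.ndarray, params: LinkParams | None = None,
                  connectivity_2d: int = 4):
    """Divide a cell, then relink each piece to the previous slice.

    A piece adopts the previous-slice ID with which its overlap coefficient is
    maximal among those exceeding the threshold; when two pieces qualify for
    the same previous ID only the higher-coefficient piece links, so the
    division is not undone.  Requires a previous slice to exist.
    """
    if z < 1:
        raise ValueError("divide_relink requires a previous slice (z >= 1)")
    params = params or LinkParams()
    backward = state.snapshot()
    piece_masks, piece_ids = _divide_components(
        state, z, cell_id, edited_mask, connectivity_2d
    )
    prev = resolve_slice(state, z - 1)

    # candidate (coefficient, piece_rank, prev_id), best-first; greedy 1:1
    candidates = []
    for rank, piece in enumerate(piece_masks):
        area_piece = int(piece.sum())
        overlap_ids, counts = np.unique(prev[piece], return_counts=True)
        for pid, n in zip(overlap_ids, counts):
            if pid == 0:
                continue
            coeff = int(n) / min(area_piece, int((prev == pid).sum()))
            if coeff > params.overlap_threshold:
                candidates.append((coeff, rank, int(pid)))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))

    assigned_piece: dict[int, int] = {}
    used_prev: set[int] = set()
    for coeff, rank, pid in candidates:
        if rank in assigned_piece or pid in used_prev:
            continue
        assigned_piece[rank] = pid
        used_prev.add(pid)

    # detach every piece, then reattach under its final ID; an unassigned
    # piece whose provisional ID was claimed by another piece gets a fresh one
    sl = state.slices[z]
    piece_bases = {rank: sl.groups.pop(pid) for rank, pid in enumerate(piece_ids)}
    taken = set(assigned_piece.values())
    for rank in range(len(piece_ids)):
        if rank in assigned_piece:
            fid = assigned_piece[rank]
        elif piece_ids[rank] in taken:
            fid = state.next_id
            state.next_id += 1
        else:
            fid = piece_ids[rank]
        sl.groups.setdefault(fid, set()).update(piece_bases[rank])
        sl.deleted.discard(fid)
        piece_ids[rank] = fid
    _finish(state, "divide_relink", backward)
    return state, piece_ids


def undo(state: LinkedStackState) -> LinkedStackState:
    """Revert the most recent operation; no-op with a warning if none remain."""
    if not state.history:
        warnings.warn("nothing to undo", stacklevel=2)
        return state
    delta = state.history.pop()
    delta.apply_backward(state)
    state.redo_stack.append(delta)
    state.maybe_autosave()
    return state


def redo(state: LinkedStackState) -> LinkedStackState:
    """Re-apply the most recently undone operation."""
    if not state.redo_stack:
        warnings.warn("nothing to redo", stacklevel=2)
        return state
    delta = state.redo_stack.pop()
    delta.apply_forward(state)
    state.history.append(delta)
    state.maybe_autosave()
    return state


def autosave(state: LinkedStackState, path) -> None:
    """Persist the project so a later session can resume it."""
    save_state(state, path)


def resume(path) -> LinkedStackState:
    """Reload a saved project; undo/redo history starts empty."""
    return load_state(path)
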