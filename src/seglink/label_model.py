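"""Slice-wise segmentation store: base label grids plus per-slice label lists.

The 3D segmentation produced by the slice-by-slice workflow is not kept as a
dense 3D array.  Each slice holds (a) the immutable 2D label image produced by
the watershed ("base labels") and (b) a small mapping from base labels to the
final cell IDs the user sees ("groups").  Linking, merging and deleting cells
then only rewrite the per-slice mappings, never the 2D arrays, which makes
those operations and their autosave cheap.  Displaying or exporting requires a
resolution pass that substitutes final IDs for base labels.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

ARCHIVE_FORMAT_VERSION = 1

__all__ = [
    "SliceSeg",
    "EditDelta",
    "LinkedStackState",
    "resolve_slice",
    "resolve_volume",
    "render_window",
    "save_state",
    "load_state",
]


class SegLinkError(Exception):
    """Base class for errors raised by this package."""


class EmptyStateError(SegLinkError):
    """Raised when an operation requires at least one segmented slice."""


class CellNotFoundError(SegLinkError, KeyError):
    """Raised when a final cell ID does not exist in the store."""


class ArchiveFormatError(SegLinkError):
    """Raised when a project archive cannot be parsed."""


@dataclass
class SliceSeg:
    """One slice: immutable base label image + mutable label list.

    Parameters
    ----------
    base_labels
        2D array of non-negative integers; 0 is background.  Treated as
        immutable by merge/delete/link operations (division replaces it).
    groups
        Mapping ``final_id -> set of base labels``.  Every nonzero base label
        belongs to exactly one group; final IDs are unique per slice by
        construction of the dict.
    deleted
        Final IDs tombstoned on this slice; their pixels resolve to 0.
    """

    base_labels: np.ndarray
    groups: dict[int, set[int]] = field(default_factory=dict)
    deleted: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.base_labels = np.asarray(self.base_labels)
        if self.base_labels.ndim != 2:
            raise ValueError("base_labels must be 2D")
        if self.base_labels.size and self.base_labels.min() < 0:
            raise ValueError("base labels must be non-negative")
        self.base_labels.setflags(write=False)
        if not self.groups:
            # identity label list: base label i -> final ID i
            self.groups = {
                int(b): {int(b)} for b in np.unique(self.base_labels) if b != 0
            }
        self._check_groups()

    def _check_groups(self) -> None:
        present = {int(b) for b in np.unique(self.base_labels) if b != 0}
        covered: set[int] = set()
        for fid, bases in self.groups.items():
            if fid <= 0:
                raise ValueError("final cell IDs must be positive")
            if 0 in bases:
                raise ValueError("groups must not contain base label 0")
            if covered & bases:
                raise ValueError("base label assigned to more than one group")
            covered |= bases
        if present - covered:
            raise ValueError(f"base labels without a group: {present - covered}")

    def copy(self) -> "SliceSeg":
        out = SliceSeg.__new__(SliceSeg)
        out.base_labels = self.base_labels  # immutable, shareable
        out.groups = {fid: set(b) for fid, b in self.groups.items()}
        out.deleted = set(self.deleted)
        return out

    def final_ids(self, include_deleted: bool = False) -> set[int]:
        ids = set(self.groups)
        return ids if include_deleted else ids - self.deleted


@dataclass
class EditDelta:
    """Reversible record of one operation.

    ``backward`` restores the state that existed before the operation;
    ``forward`` re-applies it.  For slice-wise operations both sides hold
    label-list snapshots (plus a base-grid snapshot when division rewrote it);
    volumetric stores use sub-region voxel diffs instead (see volume_ops).
    """

    op_kind: str
    forward: object = None
    backward: object = None

    def apply_backward(self, state: "LinkedStackState") -> None:
        _apply_snapshot(state, self.backward)

    def apply_forward(self, state: "LinkedStackState") -> None:
        _apply_snapshot(state, self.forward)


def _take_snapshot(state: "LinkedStackState") -> dict:
    return {
        "n_slices": len(state.slices),
        "slices": [s.copy() for s in state.slices],
        "next_id": state.next_id,
        "working_slice": state.working_slice,
    }


def _apply_snapshot(state: "LinkedStackState", snap: dict) -> None:
    state.slices = [s.copy() for s in snap["slices"]]
    state.next_id = snap["next_id"]
    state.working_slice = snap["working_slice"]


@dataclass
class LinkedStackState:
    """Ordered slice stores plus bounded edit history (the Module-1 store)."""

    slices: list[SliceSeg] = field(default_factory=list)
    next_id: int = 1
    history_capacity: int = 10
    display_window: int = 100
    working_slice: int = 0  # index of the most recently segmented slice
    history: list[EditDelta] = field(default_factory=list)
    redo_stack: list[EditDelta] = field(default_factory=list)
    autosave_path: str | None = None

    # -- bookkeeping -------------------------------------------------------

    def record(self, delta: EditDelta) -> None:
        """Push a delta, enforcing capacity and clearing the redo stack."""
        self.history.append(delta)
        if len(self.history) > self.history_capacity:
            del self.history[: len(self.history) - self.history_capacity]
        self.redo_stack.clear()

    def snapshot(self) -> dict:
        return _take_snapshot(self)

    def all_final_ids(self, include_deleted: bool = False) -> set[int]:
        ids: set[int] = set()
        for s in self.slices:
            ids |= s.final_ids(include_deleted)
        return ids

    def maybe_autosave(self) -> None:
        if self.autosave_path is not None:
            save_state(self, self.autosave_path)


# -- resolution -------------------------------------------------------------


def _resolution_lut(sl: SliceSeg) -> np.ndarray:
    """LUT mapping base label -> final ID (0 for background/deleted)."""
    max_base = int(sl.base_labels.max(initial=0))
    lut = np.zeros(max_base + 1, dtype=np.int64)
    for fid, bases in sl.groups.items():
        value = 0 if fid in sl.deleted else fid
        for b in bases:
            if b <= max_base:
                lut[b] = value
    return lut


def resolve_slice(state: LinkedStackState, z: int) -> np.ndarray:
    """Resolve slice ``z`` into a 2D grid of final cell IDs."""
    if not -len(state.slices) <= z < len(state.slices):
        raise IndexError(f"slice index {z} out of range")
    sl = state.slices[z]
    return _resolution_lut(sl)[sl.base_labels]


def resolve_volume(state: LinkedStackState) -> np.ndarray:
    """Resolve the whole stack into a dense 3D grid of final cell IDs."""
    if not state.slices:
        raise EmptyStateError("no slices have been segmented")
    return np.stack([resolve_slice(state, z) for z in range(len(state.slices))])


def render_window(state: LinkedStackState, z_center: int) -> np.ndarray:
    """Resolve only the slices within ``display_window`` of ``z_center``.

    Covers the inclusive range [z_center - w, z_center + w], clipped to the
    stack bounds.
    """
    n = len(state.slices)
    if not 0 <= z_center < n:
        raise IndexError(f"slice index {z_center} out of range")
    w = state.display_window
    lo, hi = max(0, z_center - w), min(n - 1, z_center + w)
    return np.stack([resolve_slice(state, z) for z in range(lo, hi + 1)])


# -- serialization ----------------------------------------------------------


def save_state(state: LinkedStackState, path) -> None:
    """Write the store to a single archive (internal versioned container).

    Layout: one ``.npy`` member per slice's base grid plus a JSON metadata
    member with groups, deleted sets, next_id and defaults.  Undo/redo history
    is intentionally not persisted.
    """
    meta = {
        "format_version": ARCHIVE_FORMAT_VERSION,
        "next_id": state.next_id,
        "working_slice": state.working_slice,
        "history_capacity": state.history_capacity,
        "display_window": state.display_window,
        "slices": [
            {
                "groups": {str(f): sorted(b) for f, b in s.groups.items()},
                "deleted": sorted(s.deleted),
            }
            for s in state.slices
        ],
    }
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("meta.json", json.dumps(meta))
        for z, s in enumerate(state.slices):
            buf = io.BytesIO()
            np.save(buf, s.base_labels)
            zf.writestr(f"base_{z:05d}.npy", buf.getvalue())


def load_state(path) -> LinkedStackState:
    """Load a project archive saved by :func:`save_state`.

    The resumed state has empty undo/redo stacks.
    """
    try:
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            if meta.get("format_version") != ARCHIVE_FORMAT_VERSION:
                raise ArchiveFormatError(
                    f"unsupported archive version: {meta.get('format_version')}"
                )
            slices = []
            for z, sm in enumerate(meta["slices"]):
                base = np.load(io.BytesIO(zf.read(f"base_{z:05d}.npy")))
                slices.append(
                    SliceSeg(
                        base,
                        groups={int(f): set(b) for f, b in sm["groups"].items()},
                        deleted=set(sm["deleted"]),
                    )
                )
    except (zipfile.BadZipFile, KeyError, json.JSONDecodeError) as exc:
        raise ArchiveFormatError(f"cannot read project archive {path}: {exc}") from exc
    return LinkedStackState(
        slices=slices,
        next_id=int(meta["next_id"]),
        history_capacity=int(meta["history_capacity"]),
        display_window=int(meta["display_window"]),
        working_slice=int(meta["working_slice"]),
    )
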