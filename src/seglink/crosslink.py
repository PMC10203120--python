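"""Cross-slice identity linking by the overlap coefficient.

Two cells X (slice i) and Y (slice i-1) are linked when

    overlap(X, Y) = area(X ∩ Y) / min[area(X), area(Y)]

strictly exceeds a threshold (default 0.5).  Links are resolved component-wise
on the bipartite graph between previous-slice final IDs and current-slice base
labels: every current label in a component adopts the smallest previous ID of
that component, and previous IDs joined through a shared current label are
merged across all earlier slices.  This single rule implements both ID
propagation and merge propagation (a merge performed in slice i guides the
program to auto-merge the matching fragments in slice i+1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .label_model import EditDelta, LinkedStackState, SliceSeg, resolve_slice

__all__ = ["LinkParams", "OverlapPair", "overlap_coefficient",
           "overlap_pairs", "link_slice"]


@dataclass(frozen=True)
class LinkParams:
    """overlap_threshold: links require coefficient strictly greater."""

    overlap_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap_threshold <= 1.0:
            raise ValueError("overlap_threshold must be in [0, 1]")


@dataclass(frozen=True)
class OverlapPair:
    id_prev: int
    label_curr: int
    area_prev: int
    area_curr: int
    area_intersection: int

    @property
    def coefficient(self) -> float:
        return self.area_intersection / min(self.area_prev, self.area_curr)


def overlap_coefficient(region_a: np.ndarray, region_b: np.ndarray) -> float:
    """Overlap coefficient |a ∩ b| / min(|a|, |b|) of two binary regions."""
    a = np.asarray(region_a, dtype=bool)
    b = np.asarray(region_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("regions must share a shape")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 or nb == 0:
        raise ValueError("overlap coefficient requires non-empty regions")
    return int((a & b).sum()) / min(na, nb)


def overlap_pairs(prev_resolved: np.ndarray, curr_base: np.ndarray) -> list[OverlapPair]:
    """All overlapping (previous final ID, current base label) pairs."""
    prev_flat = prev_resolved.ravel()
    curr_flat = curr_base.ravel()
    area_prev = np.bincount(prev_flat)
    area_curr = np.bincount(curr_flat)
    both = (prev_flat > 0) & (curr_flat > 0)
    if not both.any():
        return []
    pairs, counts = np.unique(
        np.stack([prev_flat[both], curr_flat[both]]), axis=1, return_counts=True
    )
    return [
        OverlapPair(
            id_prev=int(p), label_curr=int(c),
            area_prev=int(area_prev[p]), area_curr=int(area_curr[c]),
            area_intersection=int(n),
        )
        for p, c, n in zip(pairs[0], pairs[1], counts)
    ]


class _DisjointSet:
    def __init__(self) -> None:
        self.parent: dict = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a, b) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def merge_final_ids(state: LinkedStackState, ids: set[int]) -> int:
    """Collapse ``ids`` to the smallest member in every slice; returns it."""
    target = min(ids)
    others = ids - {target}
    for sl in state.slices:
        hit = others & set(sl.groups)
        if not hit:
            continue
        merged = sl.groups.setdefault(target, set())
        for fid in hit:
            merged |= sl.groups.pop(fid)
            sl.deleted.discard(fid)
    return target


def link_slice(state: LinkedStackState, new_base: np.ndarray,
               params: LinkParams | None = None) -> LinkedStackState:
    """Append a freshly segmented slice, linking it to the resolved previous one.

    The first slice is appended without linking; its base labels receive fresh
    final IDs.  Mutates and returns ``state``; records an undoable delta.
    """
    params = params or LinkParams()
    new_base = np.asarray(new_base)
    if state.slices and new_base.shape != state.slices[-1].base_labels.shape:
        raise ValueError("new slice shape does not match the stack")

    backward = state.snapshot()
    curr_labels = [int(b) for b in np.unique(new_base) if b != 0]

    if not state.slices:
        groups: dict[int, set[int]] = {}
        for b in curr_labels:
            groups[state.next_id] = {b}
            state.next_id += 1
        state.slices.append(SliceSeg(new_base, groups=groups))
    else:
        prev = resolve_slice(state, len(state.slices) - 1)
        pairs = [p for p in overlap_pairs(prev, new_base)
                 if p.coefficient > params.overlap_threshold]

        ds = _DisjointSet()
        for p in pairs:
            ds.union(("P", p.id_prev), ("C", p.label_curr))
        components: dict[object, dict[str, set[int]]] = {}
        for p in pairs:
            comp = components.setdefault(ds.find(("P", p.id_prev)),
                                         {"prev": set(), "curr": set()})
            comp["prev"].add(p.id_prev)
            comp["curr"].add(p.label_curr)

        groups = {}
        linked_curr: set[int] = set()
        for comp in components.values():
            target = (merge_final_ids(state, comp["prev"])
                      if len(comp["prev"]) > 1 else min(comp["prev"]))
            groups[target] = set(comp["curr"])
            linked_curr |= comp["curr"]
        for b in curr_labels:
            if b not in linked_curr:
                groups[state.next_id] = {b}
                state.next_id += 1
        state.slices.append(SliceSeg(new_base, groups=groups))

    state.working_slice = len(state.slices) - 1
    state.record(EditDelta("link", forward=state.snapshot(), backward=backward))
    state.maybe_autosave()
    return state
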