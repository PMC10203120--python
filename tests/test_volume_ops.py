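"""Dense 3D label store: caches, localization, corrections, diff undo."""

import numpy as np
import pytest

from seglink.label_model import CellNotFoundError
from seglink.volume_ops import (
    LabelVolume,
    build_volume,
    delete_cells_3d,
    divide_3d,
    divide_cell_3d,
    divide_relink_3d,
    insert_cell,
    locate_cell,
    merge_cells_3d,
    redo_3d,
    remove_small,
    sort_by_volume,
    undo_3d,
)


def brute_force_caches(labels):
    """Exhaustive-scan oracle for bboxes and volumes."""
    bboxes, volumes = {}, {}
    for cid in np.unique(labels):
        if cid == 0:
            continue
        zz, yy, xx = np.nonzero(labels == cid)
        bboxes[int(cid)] = (int(zz.min()), int(zz.max()), int(yy.min()),
                            int(yy.max()), int(xx.min()), int(xx.max()))
        volumes[int(cid)] = len(zz)
    return bboxes, volumes


def assert_caches_coherent(vol: LabelVolume):
    bboxes, volumes = brute_force_caches(vol.labels)
    assert vol.bboxes == bboxes
    assert vol.volumes == volumes


def random_volume(rng, shape=(8, 16, 16), n_cells=5):
    labels = np.zeros(shape, dtype=np.int32)
    for cid in range(1, n_cells + 1):
        d, h, w = rng.integers(2, 5, size=3)
        z = rng.integers(0, shape[0] - d)
        y = rng.integers(0, shape[1] - h)
        x = rng.integers(0, shape[2] - w)
        region = labels[z : z + d, y : y + h, x : x + w]
        region[region == 0] = cid
    return labels


class TestBuildVolume:
    def test_empty_volume_has_empty_caches(self):
        vol = build_volume(np.zeros((3, 3, 3), dtype=int))
        assert vol.bboxes == {} and vol.volumes == {}

    def test_cube_bbox_and_volume(self):
        labels = np.zeros((5, 5, 5), dtype=int)
        labels[0:3, 0:3, 0:3] = 4
        vol = build_volume(labels)
        assert vol.bboxes[4] == (0, 2, 0, 2, 0, 2)
        assert vol.volumes[4] == 27

    def test_random_volumes_match_exhaustive_scan_oracle(self, rng):
        for _ in range(10):
            vol = build_volume(random_volume(rng))
            assert_caches_coherent(vol)

    def test_negative_labels_rejected(self):
        with pytest.raises(ValueError):
            build_volume(np.full((2, 2, 2), -1))


class TestLocateCell:
    def test_middle_slice_is_floor_midpoint(self):
        labels = np.zeros((25, 4, 4), dtype=int)
        labels[10:21, 1, 1] = 3
        mid, bbox = locate_cell(build_volume(labels), 3)
        assert mid == 15 and bbox[:2] == (10, 20)

    def test_single_slice_cell(self):
        labels = np.zeros((10, 4, 4), dtype=int)
        labels[7, 2, 2] = 1
        mid, _ = locate_cell(build_volume(labels), 1)
        assert mid == 7

    def test_cache_equals_full_scan_on_random_volumes(self, rng):
        for _ in range(5):
            vol = build_volume(random_volume(rng))
            for cid in vol.ids():
                assert locate_cell(vol, cid) == locate_cell(vol, cid, use_cache=False)

    def test_unknown_id_raises(self):
        with pytest.raises(CellNotFoundError):
            locate_cell(build_volume(np.zeros((2, 2, 2), dtype=int)), 9)


class TestSortByVolume:
    def test_descending_relabel_with_given_volumes(self):
        labels = np.zeros((1, 1, 200), dtype=int)
        labels[0, 0, :30] = 1
        labels[0, 0, 30:130] = 2
        labels[0, 0, 130:200] = 3
        vol = sort_by_volume(build_volume(labels))
        assert vol.volumes == {1: 100, 2: 70, 3: 30}

    def test_already_sorted_is_identity(self):
        labels = np.zeros((1, 1, 10), dtype=int)
        labels[0, 0, :6] = 1
        labels[0, 0, 6:9] = 2
        before = labels.copy()
        vol = sort_by_volume(build_volume(labels))
        assert np.array_equal(vol.labels, before)

    def test_volume_multiset_invariant(self, rng):
        vol = build_volume(random_volume(rng))
        before = sorted(vol.volumes.values())
        sort_by_volume(vol)
        assert sorted(vol.volumes.values()) == before
        assert_caches_coherent(vol)


class TestRemoveSmall:
    def test_strictly_smaller_cells_removed(self):
        labels = np.zeros((1, 1, 160), dtype=int)
        labels[0, 0, :100] = 1
        labels[0, 0, 100:105] = 2
        labels[0, 0, 105:155] = 3
        vol, removed = remove_small(build_volume(labels), 10)
        assert removed == [2]
        assert set(vol.ids()) == {1, 3}

    def test_threshold_zero_removes_nothing(self, rng):
        vol = build_volume(random_volume(rng))
        _, removed = remove_small(vol, 0)
        assert removed == []

    def test_threshold_above_max_removes_all(self, rng):
        vol = build_volume(random_volume(rng))
        _, removed = remove_small(vol, max(vol.volumes.values()) + 1)
        assert vol.ids() == [] and (vol.labels == 0).all()


class TestDivide3D:
    def test_single_component_unchanged(self):
        labels = np.zeros((4, 4, 4), dtype=int)
        labels[1:3, 1:3, 1:3] = 2
        vol, new_ids = divide_3d(build_volume(labels), 2)
        assert new_ids == []
        assert np.array_equal(vol.labels, labels)
        assert len(vol.history) == 1

    def test_two_disconnected_parts_get_two_ids(self):
        labels = np.zeros((10, 6, 6), dtype=int)
        labels[1:3, 1:4, 1:4] = 5
        labels[6:9, 1:4, 1:4] = 5  # same ID, not touching
        vol, new_ids = divide_3d(build_volume(labels), 5)
        assert len(new_ids) == 1
        # larger part keeps the ID
        assert vol.volumes[5] == 27 and vol.volumes[new_ids[0]] == 18
        assert_caches_coherent(vol)

    def test_split_matches_component_oracle(self, rng):
        from scipy import ndimage as ndi

        labels = np.zeros((12, 8, 8), dtype=int)
        labels[1:4, 1:7, 1:7] = 1
        labels[8:11, 1:7, 1:7] = 1
        vol, new_ids = divide_3d(build_volume(labels), 1)
        comps, n = ndi.label(labels == 1, structure=np.ones((3, 3, 3)))
        assert n == 1 + len(new_ids)
        for cid in [1] + new_ids:
            hit = vol.labels == cid
            assert len(set(comps[hit])) == 1  # each ID is one oracle component


class TestInsertCell:
    def test_paint_in_empty_space(self):
        vol = build_volume(np.zeros((4, 4, 4), dtype=int))
        painted = np.zeros((4, 4, 4), dtype=bool)
        painted[1, 1, :5] = True
        vol, new_id = insert_cell(vol, painted)
        assert vol.volumes[new_id] == painted.sum()
        assert_caches_coherent(vol)

    def test_two_inserts_get_ascending_ids(self):
        vol = build_volume(np.zeros((4, 4, 4), dtype=int))
        a = np.zeros((4, 4, 4), dtype=bool)
        a[0, 0, 0] = True
        b = np.zeros((4, 4, 4), dtype=bool)
        b[3, 3, 3] = True
        _, id1 = insert_cell(vol, a)
        _, id2 = insert_cell(vol, b)
        assert id2 > id1

    def test_painting_over_cell_rejected(self):
        labels = np.zeros((4, 4, 4), dtype=int)
        labels[1, 1, 1] = 7
        vol = build_volume(labels)
        painted = np.zeros((4, 4, 4), dtype=bool)
        painted[1, 1, 1] = True
        with pytest.raises(ValueError, match="background"):
            insert_cell(vol, painted)

    def test_insert_then_undo_bit_identical(self):
        vol = build_volume(np.zeros((4, 4, 4), dtype=int))
        before = vol.labels.copy()
        painted = np.zeros((4, 4, 4), dtype=bool)
        painted[2, 2, 2] = True
        insert_cell(vol, painted)
        undo_3d(vol)
        assert np.array_equal(vol.labels, before)


class TestMergeDeleteDivide:
    def test_merge_makes_union_tight_bbox(self, rng):
        vol = build_volume(random_volume(rng))
        a, b = vol.ids()[:2]
        merge_cells_3d(vol, {a, b})
        assert b not in vol.bboxes
        assert_caches_coherent(vol)

    def test_delete_zeroes_voxels(self, rng):
        vol = build_volume(random_volume(rng))
        target = vol.ids()[0]
        delete_cells_3d(vol, {target})
        assert target not in vol.labels
        assert_caches_coherent(vol)

    def test_divide_at_slice_touches_only_that_slice(self):
        labels = np.zeros((6, 10, 10), dtype=int)
        labels[1:5, 2:8, 2:8] = 1
        vol = build_volume(labels)
        mask = np.zeros((10, 10), dtype=bool)
        mask[2:8, 2:8] = True
        mask[:, 5] = False
        before = vol.labels.copy()
        vol, new_ids = divide_cell_3d(vol, 3, 1, mask)
        changed = np.argwhere(vol.labels != before)
        assert set(changed[:, 0]) == {3}
        assert len(new_ids) == 1
        assert_caches_coherent(vol)

    def test_divide_relink_adopts_previous_slice_ids(self):
        # slice 0 has cells 1 and 2 side by side; slice 1 has one cell 3
        # spanning mostly cell 1's footprint plus part of 2's
        labels = np.zeros((2, 10, 20), dtype=int)
        labels[0, 1:9, 1:9] = 1
        labels[0, 1:9, 11:19] = 2
        labels[1, 1:9, 1:14] = 3
        vol = build_volume(labels)
        mask = labels[1] == 3
        mask[:, 9] = False
        vol, piece_ids = divide_relink_3d(vol, 1, 3, mask)
        assert piece_ids[0] == 1  # big piece nested in cell 1
        assert 2 in piece_ids  # small piece relinked to cell 2
        assert_caches_coherent(vol)

    def test_any_op_then_undo_bit_identical(self, rng):
        vol = build_volume(random_volume(rng))
        ids = vol.ids()
        before = vol.labels.copy()
        merge_cells_3d(vol, set(ids[:2]))
        undo_3d(vol)
        assert np.array_equal(vol.labels, before)
        assert_caches_coherent(vol)


def apply_random_op(vol: LabelVolume, rng) -> bool:
    """One random correction; returns False when nothing applied."""
    ids = vol.ids()
    op = rng.choice(
        ["merge", "delete", "divide2d", "divide3d", "insert",
         "remove_small", "sort"]
    )
    if op == "merge" and len(ids) >= 2:
        pick = rng.choice(ids, size=2, replace=False)
        merge_cells_3d(vol, {int(pick[0]), int(pick[1])})
    elif op == "delete" and ids:
        delete_cells_3d(vol, {int(rng.choice(ids))})
    elif op == "divide2d" and ids:
        cid = int(rng.choice(ids))
        z0, z1 = vol.bboxes[cid][:2]
        z = int(rng.integers(z0, z1 + 1))
        mask = vol.labels[z] == cid
        if not mask.any():
            return False
        mask = mask.copy()
        mask[:, int(rng.integers(0, mask.shape[1]))] = False
        if not mask.any():
            return False
        divide_cell_3d(vol, z, cid, mask)
    elif op == "divide3d" and ids:
        divide_3d(vol, int(rng.choice(ids)))
    elif op == "insert":
        painted = np.zeros(vol.labels.shape, dtype=bool)
        z = int(rng.integers(0, vol.labels.shape[0]))
        y = int(rng.integers(0, vol.labels.shape[1]))
        free = np.flatnonzero(vol.labels[z, y] == 0)
        if free.size == 0:
            return False
        painted[z, y, free[: int(rng.integers(1, 4))]] = True
        insert_cell(vol, painted)
    elif op == "remove_small" and ids:
        remove_small(vol, int(rng.integers(1, 10)))
    elif op == "sort" and ids:
        sort_by_volume(vol)
    else:
        return False
    return True


class TestRandomOpProperties:
    def test_cache_coherence_over_random_sequences(self, rng):
        for _ in range(25):
            vol = build_volume(random_volume(rng))
            for _ in range(6):
                if apply_random_op(vol, rng):
                    assert_caches_coherent(vol)

    def test_full_undo_restores_initial_grid_within_capacity(self, rng):
        for _ in range(15):
            vol = build_volume(random_volume(rng), history_capacity=5)
            checkpoints = [vol.labels.copy()]
            applied = 0
            while applied < 5 and vol.ids():
                if apply_random_op(vol, rng):
                    applied += 1
                    checkpoints.append(vol.labels.copy())
            while vol.history:
                undo_3d(vol)
                checkpoints.pop()
                assert np.array_equal(vol.labels, checkpoints[-1])
                assert_caches_coherent(vol)

    def test_capacity_bounds_history(self, rng):
        vol = build_volume(random_volume(rng, n_cells=8), history_capacity=5)
        applied = 0
        while applied < 8 and vol.ids():
            if apply_random_op(vol, rng):
                applied += 1
        assert len(vol.history) <= 5

    def test_deltas_touch_only_affected_subregions(self, rng):
        """The stored diff regions stay inside the affected cells' bboxes."""
        vol = build_volume(random_volume(rng))
        ids = vol.ids()
        a, b = ids[0], ids[1]
        boxes = [vol.bboxes[a], vol.bboxes[b]]
        full_voxels = vol.labels.size
        merge_cells_3d(vol, {a, b})
        delta = vol.history[-1]
        covered = 0
        for bbox, old, new in delta.regions:
            assert old.shape == new.shape
            covered += old.size
        bound = sum(
            (b[1] - b[0] + 1) * (b[3] - b[2] + 1) * (b[5] - b[4] + 1)
            for b in boxes
        )
        # union regions may merge overlapping boxes but never exceed the
        # bounding box of their union, and certainly not the full volume
        assert covered <= full_voxels
        assert all(
            any(_inside(bbox, box) for box in [_union_all(boxes)])
            for bbox, _, _ in delta.regions
        )

    def test_redo_after_undo_reapplies(self, rng):
        vol = build_volume(random_volume(rng))
        merge_cells_3d(vol, set(vol.ids()[:2]))
        after = vol.labels.copy()
        undo_3d(vol)
        redo_3d(vol)
        assert np.array_equal(vol.labels, after)
        assert_caches_coherent(vol)


def _union_all(boxes):
    z0 = min(b[0] for b in boxes)
    z1 = max(b[1] for b in boxes)
    y0 = min(b[2] for b in boxes)
    y1 = max(b[3] for b in boxes)
    x0 = min(b[4] for b in boxes)
    x1 = max(b[5] for b in boxes)
    return (z0, z1, y0, y1, x0, x1)


def _inside(inner, outer):
    return (outer[0] <= inner[0] and inner[1] <= outer[1]
            and outer[2] <= inner[2] and inner[3] <= outer[3]
            and outer[4] <= inner[4] and inner[5] <= outer[5])
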