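"""Synthetic phantoms with known ground truth, and segmentation scoring.

The phantom emulates the failure modes that slice-wise watershed plus linking
is designed to survive: densely packed touching convex-ish cells, anisotropic
voxels (z step several times the in-plane pixel size, as in serial-section EM
at e.g. 40 nm steps over 8 nm pixels), stochastic dropout of boundary pixels
(missing membrane predictions), and optional per-slice rigid displacement.

Cells are grown from randomly placed nuclei as an anisotropy-scaled,
radius-weighted nearest-seed partition (a capped additively-weighted Voronoi
tessellation), which tiles the volume with touching convex-ish cells of
controlled size.  Predictions are derived from the ground truth by painting
the in-plane inter-cell interface as non-cell ("membrane"), then flipping each
such boundary pixel back to cell with probability ``boundary_dropout_rate``.

Scoring follows a detection-style matching: a ground-truth cell is
undersegmented when its best-matching predicted cell is also the best match of
another ground-truth cell (two true cells share one label), and oversegmented
when more than one predicted cell claims at least a configurable fraction
(default 0.1) of its voxels (one true cell split into several labels).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PhantomSpec", "generate_phantom", "score_segmentation"]


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions for one synthetic volume.

    shape : (Z, Y, X) voxels.
    n_cells : number of cells grown; generation fails if the seeds cannot be
        placed with adequate separation.
    radius_range : in-plane cell radius range in pixels.
    z_anisotropy : z step expressed in xy pixels (5 mirrors 40 nm steps over
        8 nm pixels).
    boundary_dropout_rate : probability that an inter-cell boundary pixel is
        flipped back to foreground in the predictions.
    displacement : maximum per-slice rigid shift (pixels) applied to both
        ground truth and predictions; 0 disables.
    seed : RNG seed; fixed seed gives bit-identical phantoms.
    """

    shape: tuple[int, int, int] = (32, 128, 128)
    n_cells: int = 25
    radius_range: tuple[float, float] = (14.0, 26.0)
    z_anisotropy: float = 5.0
    boundary_dropout_rate: float = 0.0
    displacement: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.boundary_dropout_rate <= 1.0:
            raise ValueError("boundary_dropout_rate must be in [0, 1]")
        if self.radius_range[0] < 1:
            raise ValueError("radii must be >= 1 pixel")
        if self.z_anisotropy <= 0:
            raise ValueError("z_anisotropy must be positive")


class PhantomGenerationError(RuntimeError):
    """Raised when the requested cells cannot be placed in the volume."""


def _place_seeds(spec: PhantomSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Poisson-disk-ish seed placement in anisotropy-scaled coordinates."""
    nz, ny, nx = spec.shape
    radii = rng.uniform(*spec.radius_range, size=spec.n_cells)
    # minimum separation keeps each seed inside its own cell
    min_sep = 0.9 * spec.radius_range[0]
    seeds = np.empty((spec.n_cells, 3))
    placed = 0
    for attempt in range(spec.n_cells * 400):
        cand = np.array([
            rng.uniform(0, nz * spec.z_anisotropy),
            rng.uniform(0, ny),
            rng.uniform(0, nx),
        ])
        if placed and (np.linalg.norm(seeds[:placed] - cand, axis=1) < min_sep).any():
            continue
        seeds[placed] = cand
        placed += 1
        if placed == spec.n_cells:
            break
    if placed < spec.n_cells:
        raise PhantomGenerationError(
            f"could only place {placed}/{spec.n_cells} cells in {spec.shape}; "
            "reduce n_cells or radii"
        )
    return seeds, radii


def _grow_cells(spec: PhantomSpec, seeds: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Radius-weighted nearest-seed assignment, capped at each cell's radius."""
    nz, ny, nx = spec.shape
    zz = np.arange(nz, dtype=float) * spec.z_anisotropy
    yy = np.arange(ny, dtype=float)
    xx = np.arange(nx, dtype=float)
    best_cost = np.full(spec.shape, np.inf)
    gt = np.zeros(spec.shape, dtype=np.int32)
    for i, ((sz, sy, sx), r) in enumerate(zip(seeds, radii), start=1):
        dz2 = (zz - sz) ** 2
        dy2 = (yy - sy) ** 2
        dx2 = (xx - sx) ** 2
        dist = np.sqrt(dz2[:, None, None] + dy2[None, :, None] + dx2[None, None, :])
        cost = dist / r
        claim = (cost < best_cost) & (dist <= r)
        gt[claim] = i
        best_cost[claim] = cost[claim]
    return gt


def _interface_mask(gt: np.ndarray) -> np.ndarray:
    """Voxels face-adjacent (6-neighborhood, z included) to a different cell.

    Including the z direction matters: the membrane between two cells stacked
    along z is still non-cell signal in the slices where they touch, and it is
    what keeps their in-plane cross-sections disjoint so the linker does not
    join them.
    """
    bnd = np.zeros(gt.shape, dtype=bool)
    for axis in (0, 1, 2):
        a = np.take(gt, range(gt.shape[axis] - 1), axis=axis)
        b = np.take(gt, range(1, gt.shape[axis]), axis=axis)
        diff = (a != b) & (a > 0) & (b > 0)
        pad_lo = [(0, 0)] * 3
        pad_hi = [(0, 0)] * 3
        pad_lo[axis] = (0, 1)
        pad_hi[axis] = (1, 0)
        bnd |= np.pad(diff, pad_lo)
        bnd |= np.pad(diff, pad_hi)
    return bnd


def _shift_slice(plane: np.ndarray, dy: int, dx: int) -> np.ndarray:
    out = np.zeros_like(plane)
    h, w = plane.shape
    ys, yd = (slice(dy, h), slice(0, h - dy)) if dy >= 0 else (slice(0, h + dy), slice(-dy, h))
    xs, xd = (slice(dx, w), slice(0, w - dx)) if dx >= 0 else (slice(0, w + dx), slice(-dx, w))
    out[ys, xs] = plane[yd, xd]
    return out


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Generate (ground_truth labels 3D, binary predictions 3D).

    Predictions are the foreground with the in-plane inter-cell interface set
    to background, boundary dropout applied, and per-slice shifts applied to
    both outputs.  Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    seeds, radii = _place_seeds(spec, rng)
    gt = _grow_cells(spec, seeds, radii)

    boundary = _interface_mask(gt)
    pred = (gt > 0) & ~boundary
    if spec.boundary_dropout_rate > 0:
        flip = boundary & (rng.random(gt.shape) < spec.boundary_dropout_rate)
        pred |= flip

    pred = pred.astype(np.uint8)
    if spec.displacement > 0:
        m = spec.displacement
        for z in range(gt.shape[0]):
            dy = int(rng.integers(-m, m + 1))
            dx = int(rng.integers(-m, m + 1))
            gt[z] = _shift_slice(gt[z], dy, dx)
            pred[z] = _shift_slice(pred[z], dy, dx)
    return gt, pred


def _overlap_matrix(gt: np.ndarray, seg: np.ndarray):
    """Sparse voxel-overlap counts between GT cells and predicted cells."""
    g = gt.ravel()
    s = seg.ravel()
    keep = g > 0
    pairs, counts = np.unique(np.stack([g[keep], s[keep]]), axis=1,
                              return_counts=True)
    return pairs[0], pairs[1], counts


def score_segmentation(seg: np.ndarray, gt: np.ndarray,
                       over_fraction: float = 0.1) -> dict[str, float]:
    """Fractions of ground-truth cells under- and over-segmented.

    A GT cell is undersegmented if its best-matching predicted cell (maximum
    voxel overlap, background excluded) is also the best match of another GT
    cell, or if no predicted cell covers it.  It is oversegmented if more than
    one predicted cell contains at least ``over_fraction`` of its voxels.
    """
    seg = np.asarray(seg)
    gt = np.asarray(gt)
    if seg.shape != gt.shape:
        raise ValueError("segmentation and ground truth shapes differ")
    gt_ids = [int(i) for i in np.unique(gt) if i != 0]
    if not gt_ids:
        return {"undersegmented_fraction": 0.0, "oversegmented_fraction": 0.0}
    gt_sizes = {i: int(n) for i, n in
                zip(*np.unique(gt[gt > 0], return_counts=True))}

    g_idx, s_idx, counts = _overlap_matrix(gt, seg)
    best_match: dict[int, tuple[int, int]] = {}  # gt -> (count, seg id)
    claims: dict[int, int] = {}  # gt -> n seg cells claiming >= fraction
    for g, s, n in zip(g_idx, s_idx, counts):
        g, s, n = int(g), int(s), int(n)
        if s == 0:
            continue
        # ties broken toward the smaller seg ID for determinism
        if g not in best_match or (n, -s) > (best_match[g][0], -best_match[g][1]):
            best_match[g] = (n, s)
        if n >= over_fraction * gt_sizes[g]:
            claims[g] = claims.get(g, 0) + 1

    owner_count: dict[int, int] = {}
    for g, (_, s) in best_match.items():
        owner_count[s] = owner_count.get(s, 0) + 1

    under = 0
    over = 0
    for g in gt_ids:
        if g not in best_match or owner_count[best_match[g][1]] > 1:
            under += 1
        if claims.get(g, 0) > 1:
            over += 1
    n = len(gt_ids)
    return {
        "undersegmented_fraction": under / n,
        "oversegmented_fraction": over / n,
    }
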