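"""Stack I/O, configuration and the slice-by-slice segment+link pipeline.

Stacks are read from a directory of 2D TIFF files (natural, numeric-aware
filename order defines z) or from a single multi-page TIFF, and written back
as one 16-bit (or 32-bit when IDs exceed 65535) TIFF per slice with
zero-padded numeric filenames.  Coordinates are (z, y, x), 0-based.

``run_seg2d_link`` drives the Module-1 workflow: for every slice, watershed
segmentation, optional ROI masking, cross-slice linking from the second slice
on, and autosave after each slice so an interrupted run resumes where it
stopped.
"""

from __future__ import annotations

import logging
import re
import tomllib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .crosslink import LinkParams, link_slice
from .label_model import LinkedStackState, load_state, resolve_volume
from .segment2d import Seg2DParams, apply_mask, segment_slice

logger = logging.getLogger("seglink")

__all__ = [
    "PipelineConfig", "load_config", "read_stack", "write_stack",
    "run_seg2d_link",
]

AUTOSAVE_NAME = "seg2d_link_state.zip"


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the segment+link pipeline in one place."""

    seg: Seg2DParams = Seg2DParams()
    link: LinkParams = LinkParams()
    history_capacity: int = 10
    history_capacity_3d: int = 5
    display_window: int = 100


def load_config(path) -> PipelineConfig:
    """Read a TOML config file; missing keys keep their defaults."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    seg = Seg2DParams(**raw.get("seg2d", {}))
    link = LinkParams(**raw.get("link", {}))
    top = {k: raw[k] for k in
           ("history_capacity", "history_capacity_3d", "display_window")
           if k in raw}
    return PipelineConfig(seg=seg, link=link, **top)


def _natural_key(name: str):
    return [int(tok) if tok.isdigit() else tok
            for tok in re.split(r"(\d+)", name)]


def read_stack(path) -> np.ndarray:
    """Read a 3D stack from a TIFF-sequence directory or multi-page TIFF.

    Directory z order is natural (numeric-aware) filename order, so s2.tif
    sorts before s10.tif.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            (p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff")),
            key=lambda p: _natural_key(p.name),
        )
        if not files:
            raise ValueError(f"no TIFF files in {path}")
        planes = [tifffile.imread(f) for f in files]
        shapes = {p.shape for p in planes}
        dtypes = {p.dtype for p in planes}
        if len(shapes) > 1 or len(dtypes) > 1:
            raise ValueError(
                f"inconsistent slice shapes {shapes} or dtypes {dtypes} in {path}"
            )
        return np.stack(planes)
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"expected a 2D/3D TIFF, got shape {arr.shape}")
    return arr


def write_stack(grid: np.ndarray, path, prefix: str = "seg") -> list[Path]:
    """Write a 3D grid as a TIFF sequence, one file per slice.

    Bit depth is chosen from the maximum value (uint16, or uint32 when IDs
    exceed 65535); filenames are ``{prefix}_{z:05d}.tif``, 0-based.
    """
    grid = np.asarray(grid)
    if grid.ndim != 3:
        raise ValueError("expected a 3D grid")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if np.issubdtype(grid.dtype, np.integer):
        dtype = np.uint16 if grid.max(initial=0) <= np.iinfo(np.uint16).max else np.uint32
    else:
        dtype = grid.dtype
    out = []
    for z in range(grid.shape[0]):
        f = path / f"{prefix}_{z:05d}.tif"
        tifffile.imwrite(f, grid[z].astype(dtype))
        out.append(f)
    return out


def run_seg2d_link(
    predictions: np.ndarray | None = None,
    mask: np.ndarray | None = None,
    config: PipelineConfig | None = None,
    project_dir=None,
    resume: bool = True,
) -> LinkedStackState:
    """Run the slice-by-slice watershed + linking workflow over a stack.

    Parameters
    ----------
    predictions
        3D binary stack; if None, read from ``project_dir/predictions``.
    mask
        Optional binary ROI stack of the same shape; cells mostly outside it
        are dropped before linking.
    project_dir
        When given, the state is autosaved there after every slice and an
        interrupted run resumes from the first unsegmented slice.
    """
    config = config or PipelineConfig()
    autosave_path = None
    if project_dir is not None:
        project_dir = Path(project_dir)
        project_dir.mkdir(parents=True, exist_ok=True)
        autosave_path = project_dir / AUTOSAVE_NAME
        if predictions is None:
            pred_dir = project_dir / "predictions"
            if not pred_dir.exists():
                raise FileNotFoundError(
                    f"no predictions given and {pred_dir} does not exist"
                )
            predictions = read_stack(pred_dir)
            mask_dir = project_dir / "mask"
            if mask is None and mask_dir.exists():
                mask = read_stack(mask_dir)
    if predictions is None:
        raise ValueError("predictions are required (array or project_dir)")
    predictions = np.asarray(predictions)
    if predictions.ndim != 3:
        raise ValueError("predictions must be a 3D stack")
    if mask is not None and np.asarray(mask).shape != predictions.shape:
        raise ValueError("mask shape must match predictions")

    if autosave_path is not None and resume and autosave_path.exists():
        state = load_state(autosave_path)
        state.autosave_path = str(autosave_path)
        logger.info("resumed project at slice %d", len(state.slices))
    else:
        state = LinkedStackState(
            history_capacity=config.history_capacity,
            display_window=config.display_window,
        )
        state.autosave_path = None if autosave_path is None else str(autosave_path)

    for z in range(len(state.slices), predictions.shape[0]):
        labels = segment_slice(predictions[z], config.seg)
        if mask is not None:
            labels = apply_mask(labels, np.asarray(mask)[z],
                                config.seg.mask_threshold)
        link_slice(state, labels, config.link)
        logger.info("segmented and linked slice %d (%d cells so far)",
                    z, len(state.all_final_ids()))
    return state
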