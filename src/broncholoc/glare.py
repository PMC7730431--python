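"""Specular-glare subblock detection.

The endoscope's own light source reflects off wet tissue as saturated white
blobs that corrupt feature matching.  Frames are tiled into square subblocks
(40 px by default); each block's mean HSV saturation and mean value feed a
two-input fuzzy decision system, and blocks judged glare-dominated are
masked out of all downstream matching.  A plain value-threshold detector is
kept as the comparison baseline.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2hsv

from .anfis import AnfisModel, evaluate_batch
from .geometry import Frame

__all__ = [
    "SubblockGrid",
    "block_stats",
    "detect_glare",
    "detect_glare_threshold_baseline",
    "export_mask_png",
    "export_flagged_json",
]

log = logging.getLogger(__name__)


@dataclass
class SubblockGrid:
    """Per-subblock statistics and masks for one frame.

    Arrays are (n_rows, n_cols); edge blocks may cover fewer pixels than
    block_size**2 and their statistics average only the pixels they contain.
    """

    block_size: int
    image_shape: tuple  # (H, W)
    mean_saturation: np.ndarray
    mean_value: np.ndarray
    nonuniformity: np.ndarray = None  # filled by the saliency stage
    importance: np.ndarray = None  # defuzzified importance scores
    is_glare: np.ndarray = field(default=None)
    is_nonuniform: np.ndarray = field(default=None)
    pixels_per_block: np.ndarray = None

    def __post_init__(self) -> None:
        if self.is_glare is None:
            self.is_glare = np.zeros_like(self.mean_value, dtype=bool)
        if self.is_nonuniform is None:
            self.is_nonuniform = np.zeros_like(self.mean_value, dtype=bool)

    @property
    def n_rows(self) -> int:
        return self.mean_value.shape[0]

    @property
    def n_cols(self) -> int:
        return self.mean_value.shape[1]

    def block_centers(self) -> np.ndarray:
        """Pixel-space (x, y) centers of every block, shape (rows, cols, 2)."""
        H, W = self.image_shape
        bs = self.block_size
        ys = np.minimum(np.arange(self.n_rows) * bs + bs / 2.0, H - 0.5)
        xs = np.minimum(np.arange(self.n_cols) * bs + bs / 2.0, W - 0.5)
        X, Y = np.meshgrid(xs, ys)
        return np.stack([X, Y], axis=-1)


def _block_reduce_sum(img: np.ndarray, bs: int) -> np.ndarray:
    """Sum over bs x bs tiles (ragged edges allowed) via reduceat."""
    H, W = img.shape
    rows = np.arange(0, H, bs)
    cols = np.arange(0, W, bs)
    return np.add.reduceat(np.add.reduceat(img, rows, axis=0), cols, axis=1)


def _block_counts(shape, bs: int) -> np.ndarray:
    H, W = shape
    rh = np.diff(np.append(np.arange(0, H, bs), H))
    cw = np.diff(np.append(np.arange(0, W, bs), W))
    return rh[:, None] * cw[None, :]


def block_stats(frame: Frame, block_size: int = 40) -> SubblockGrid:
    """Tile a frame and compute per-block mean saturation and mean value."""
    if block_size < 8:
        raise ValueError("block_size must be at least 8 pixels")
    px = frame.pixels if isinstance(frame, Frame) else np.asarray(frame)
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError(
            "glare statistics need an RGB frame; convert grayscale input to "
            "3-channel RGB first"
        )
    rgb = frame.as_float() if isinstance(frame, Frame) else px.astype(float) / 255.0
    hsv = rgb2hsv(rgb)
    counts = _block_counts(rgb.shape[:2], block_size)
    mean_s = _block_reduce_sum(hsv[..., 1], block_size) / counts
    mean_v = _block_reduce_sum(hsv[..., 2], block_size) / counts
    return SubblockGrid(
        block_size=block_size,
        image_shape=rgb.shape[:2],
        mean_saturation=mean_s,
        mean_value=mean_v,
        pixels_per_block=counts,
    )


def detect_glare(
    grid: SubblockGrid, model: AnfisModel, threshold: float = 0.5
) -> SubblockGrid:
    """Flag glare blocks where the fuzzy score on (mean S, mean V) >= threshold."""
    if model.n_inputs != 2:
        raise ValueError("glare model must take (mean saturation, mean value)")
    X = np.stack(
        [grid.mean_saturation.ravel(), grid.mean_value.ravel()], axis=1
    )
    score = evaluate_batch(model, X).reshape(grid.mean_value.shape)
    grid.is_glare = score >= threshold
    log.info("glare blocks flagged: %d / %d", int(grid.is_glare.sum()), score.size)
    return grid


def detect_glare_threshold_baseline(grid: SubblockGrid, v_cut: float) -> SubblockGrid:
    """Baseline detector: glare wherever mean value >= v_cut."""
    if not 0.0 < v_cut <= 1.0:
        raise ValueError("v_cut must lie in (0, 1]")
    grid.is_glare = grid.mean_value >= v_cut
    return grid


def export_mask_png(grid: SubblockGrid, path) -> None:
    """Write the glare mask as a PNG (white = glare), one pixel per image pixel."""
    from PIL import Image

    H, W = grid.image_shape
    mask = np.kron(
        grid.is_glare.astype(np.uint8) * 255, np.ones((grid.block_size, grid.block_size), np.uint8)
    )[:H, :W]
    Image.fromarray(mask, mode="L").save(str(path))


def export_flagged_json(grid: SubblockGrid, path) -> None:
    rows, cols = np.nonzero(grid.is_glare)
    with open(path, "w") as fh:
        json.dump([[int(r), int(c)] for r, c in zip(rows, cols)], fh)
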