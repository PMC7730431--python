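"""Non-uniform (informative) subblock selection.

Uniform tiles — flat wall, the dark distal tunnel — contribute nothing to
image matching.  Each block gets a non-uniformity statistic

    I = sum_i (x_i^2 - 2 x_i u + u^2) = sum_i (x_i - u)^2 = N * SD^2

over its N pixel intensities x_i with block mean u: the squared-deviation
sum, algebraically N times the squared standard deviation but computed
without the square root.  A single-input fuzzy system maps I to an
importance score; selected blocks must score >= 0.5, not be glare, and not
sit on the boundary between uniform and non-uniform regions (any of the 8
neighbours deciding differently disqualifies a block).
"""

from __future__ import annotations

import json

import numpy as np

from .anfis import AnfisModel, evaluate_batch
from .geometry import Frame
from .glare import SubblockGrid, _block_counts, _block_reduce_sum

__all__ = ["nonuniformity", "select_nonuniform", "NoSalientBlocksError"]


class NoSalientBlocksError(ValueError):
    """Raised when a frame has no informative subblocks (caller should skip it)."""


def nonuniformity(frame: Frame, grid: SubblockGrid) -> SubblockGrid:
    """Fill grid.nonuniformity with the per-block squared-deviation sum I."""
    gray = frame.gray() if isinstance(frame, Frame) else np.asarray(frame, dtype=float)
    bs = grid.block_size
    counts = _block_counts(gray.shape, bs)
    s1 = _block_reduce_sum(gray, bs)
    s2 = _block_reduce_sum(gray * gray, bs)
    u = s1 / counts
    # sum x^2 - 2u sum x + N u^2, exactly the statistic's expanded form
    I = s2 - 2.0 * u * s1 + counts * u * u
    grid.nonuniformity = np.maximum(I, 0.0)  # clamp away negative round-off
    return grid


def select_nonuniform(
    grid: SubblockGrid, model: AnfisModel, threshold: float = 0.5
) -> SubblockGrid:
    """Select informative blocks via the importance model + boundary pruning.

    The defuzzified importance score of every block is kept on the grid as
    ``grid.importance``; a block is selected when its score >= threshold,
    it is not glare, and no 8-neighbour's thresholded decision differs
    (blocks sitting on the uniform/non-uniform boundary are unreliable).
    """
    if model.n_inputs != 1:
        raise ValueError("importance model must be single-input (the I statistic)")
    if grid.nonuniformity is None:
        raise ValueError("run nonuniformity() before selection")
    I = grid.nonuniformity
    score = evaluate_batch(model, I.ravel()[:, None]).reshape(I.shape)
    grid.importance = score
    decision = score >= threshold

    # boundary pruning: any 8-neighbour with a different raw decision
    # disqualifies a block (neighbours outside the image are ignored)
    keep = decision.copy()
    padded = np.pad(decision, 1, mode="edge")
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            neigh = padded[1 + dr : 1 + dr + I.shape[0], 1 + dc : 1 + dc + I.shape[1]]
            keep &= neigh == decision
    selected = keep & decision & ~grid.is_glare
    if not selected.any():
        raise NoSalientBlocksError(
            "no non-uniform subblocks survive selection (frame too uniform); "
            "skip this frame"
        )
    grid.is_nonuniform = selected
    return grid


def export_selected_json(grid: SubblockGrid, path) -> None:
    rows, cols = np.nonzero(grid.is_nonuniform)
    with open(path, "w") as fh:
        json.dump([[int(r), int(c)] for r, c in zip(rows, cols)], fh)


def export_overlay_png(frame: Frame, grid: SubblockGrid, path) -> None:
    """Frame with selected blocks marked white, for visual inspection."""
    from PIL import Image

    img = (frame.as_float() * 255).astype(np.uint8).copy()
    bs = grid.block_size
    for r, c in zip(*np.nonzero(grid.is_nonuniform)):
        y0, x0 = r * bs, c * bs
        img[y0 : y0 + bs, x0 : x0 + 2] = 255
        img[y0 : y0 + bs, x0 + bs - 2 : x0 + bs] = 255
        img[y0 : y0 + 2, x0 : x0 + bs] = 255
        img[y0 + bs - 2 : y0 + bs, x0 : x0 + bs] = 255
    Image.fromarray(img).save(str(path))
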