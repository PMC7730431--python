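"""Polar occupancy histograms of salient subblocks and their similarity.

The spatial layout of informative subblocks is summarized as a coarse
shape-context: the image plane around a center (by default the image
center, where the airway tunnel sits) is divided into 16 polar regions
(8 angular sectors x 2 radial rings by default) and each selected block's
center is binned.  Two layouts i, j are compared with the chi-square-style
statistic

    C_ij = 1/2 * sum_k (h_i(k) - h_j(k))^2 / (h_i(k) + h_j(k))

(empty bins contribute 0), and reported alongside the normalized similarity
s = 1 - C_ij / (n_i + n_j) in [0, 1], where n are the total counts —
higher s means a better match.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .glare import SubblockGrid

__all__ = ["PolarHistogram", "to_polar", "build_histogram", "similarity"]


@dataclass
class PolarHistogram:
    """Counts over n_angular x n_radial polar regions around ``center`` (x, y px).

    Bin order: radial ring index varies slowest (inner ring first), angular
    sector fastest, theta measured clockwise from +x (image y points down).
    """

    counts: np.ndarray
    center: tuple
    n_angular: int
    n_radial: int
    max_radius: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.size != self.n_angular * self.n_radial:
            raise ValueError("counts length must equal n_angular * n_radial")
        if np.any(self.counts < 0):
            raise ValueError("histogram counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def same_geometry(self, other: "PolarHistogram") -> bool:
        return (
            self.n_angular == other.n_angular
            and self.n_radial == other.n_radial
            and np.isclose(self.max_radius, other.max_radius)
        )


def to_polar(x: float, y: float, center) -> tuple:
    """(r, theta) of an image point about ``center``; theta in [0, 2*pi).

    Image y points down, so increasing theta sweeps clockwise on screen,
    keeping visual octants aligned with screen octants.
    """
    dx = np.asarray(x, dtype=float) - center[0]
    dy = np.asarray(y, dtype=float) - center[1]
    r = np.hypot(dx, dy)
    theta = np.mod(np.arctan2(dy, dx), 2.0 * np.pi)
    # a tiny negative angle mods to a value that rounds to exactly 2*pi
    theta = np.where(theta >= 2.0 * np.pi, 0.0, theta)
    theta = np.where(r == 0.0, 0.0, theta)
    if np.isscalar(x) or np.asarray(x).ndim == 0:
        return float(r), float(theta)
    return r, theta


def build_histogram(
    grid: SubblockGrid,
    center=None,
    n_angular: int = 8,
    n_radial: int = 2,
    max_radius: float = None,
) -> PolarHistogram:
    """Bin selected non-uniform block centers into the polar regions.

    Blocks beyond max_radius fall into the outermost ring.  Raises if the
    grid has no selected blocks (selection failed upstream).
    """
    if n_angular * n_radial != 16:
        raise ValueError("the histogram uses 16 polar regions (n_angular * n_radial)")
    H, W = grid.image_shape
    if center is None:
        center = (W / 2.0, H / 2.0)
    if max_radius is None:
        max_radius = float(np.hypot(W / 2.0, H / 2.0))
    if not grid.is_nonuniform.any():
        raise ValueError("no selected subblocks to bin; run select_nonuniform first")
    centers = grid.block_centers()[grid.is_nonuniform]  # (k, 2) as (x, y)
    r, theta = to_polar(centers[:, 0], centers[:, 1], center)
    ang_bin = np.minimum(
        (theta / (2.0 * np.pi / n_angular)).astype(int), n_angular - 1
    )
    rad_bin = np.minimum((r / (max_radius / n_radial)).astype(int), n_radial - 1)
    flat = rad_bin * n_angular + ang_bin
    counts = np.bincount(flat, minlength=n_angular * n_radial)
    return PolarHistogram(counts, tuple(center), n_angular, n_radial, float(max_radius))


def similarity(h_i: PolarHistogram, h_j: PolarHistogram) -> tuple:
    """(C_ij, s): chi-square-style distance and normalized similarity."""
    if not h_i.same_geometry(h_j):
        raise ValueError("histograms have different polar geometries")
    a = h_i.counts.astype(float)
    b = h_j.counts.astype(float)
    denom = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(denom > 0, (a - b) ** 2 / np.where(denom > 0, denom, 1.0), 0.0)
    c = 0.5 * float(terms.sum())
    n = h_i.total + h_j.total
    s = 1.0 - c / n if n > 0 else 1.0
    return c, float(s)


def export_histogram_json(h: PolarHistogram, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "counts": h.counts.tolist(),
                "center": list(h.center),
                "n_angular": h.n_angular,
                "n_radial": h.n_radial,
                "max_radius": h.max_radius,
            },
            fh,
        )
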