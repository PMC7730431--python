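"""Phase-2 position verification: render, compare, line-search correction.

The tracked pose is checked by rendering the virtual airway at that pose
and comparing the virtual frame against the real one through the
glare-pruned, saliency-filtered polar shape-context similarity.  A fuzzy
acceptance model thresholds the normalized similarity s; on rejection the
pose increment is re-scaled along its own direction (line search over a
fixed factor set) and the best-scoring candidate is taken.  Glare removal
runs on the real frame only — the renderer emits no specular saturation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .airway import AirwayModel, OutsideAirwayError, RenderConfig, render
from .anfis import AnfisModel, evaluate
from .defaults import (
    default_glare_model,
    default_importance_model,
    default_similarity_model,
)
from .geometry import CameraPose, Frame, PoseDelta, integrate, scale_delta
from .glare import block_stats, detect_glare
from .saliency import NoSalientBlocksError, nonuniformity, select_nonuniform
from .shape_context import build_histogram, similarity

__all__ = ["VerifyResult", "frame_similarity", "verify", "LINE_SEARCH_FACTORS"]

LINE_SEARCH_FACTORS = (0.25, -0.25, 0.5, -0.5, 0.75, -0.75, 1.25, 1.5)


def frame_similarity(
    real_frame: Frame,
    virtual_frame: Frame,
    block_size: int = 12,
    glare_model: AnfisModel = None,
    importance_model: AnfisModel = None,
    n_angular: int = 8,
    n_radial: int = 2,
    center_jitter: bool = True,
):
    """(C, s) between a real and a virtual frame.

    Both frames go through subblock statistics, non-uniformity scoring and
    salient-block selection; the real frame additionally has glare blocks
    masked out first.  With ``center_jitter`` the chi-square statistic and
    s are averaged over the nominal histogram center plus four half-block
    offsets, which de-aliases the block quantization of the histogram
    (identical frames still score exactly s = 1).  Frames with no salient
    blocks raise NoSalientBlocksError.
    """
    glare_model = glare_model or default_glare_model()
    importance_model = importance_model or default_importance_model(block_size**2)

    grid_r = block_stats(real_frame, block_size)
    detect_glare(grid_r, glare_model)
    nonuniformity(real_frame, grid_r)
    select_nonuniform(grid_r, importance_model)

    grid_v = block_stats(virtual_frame, block_size)
    nonuniformity(virtual_frame, grid_v)
    select_nonuniform(grid_v, importance_model)

    H, W = grid_r.image_shape
    c0 = (W / 2.0, H / 2.0)
    d = block_size / 2.0
    centers = [c0]
    if center_jitter:
        centers += [
            (c0[0] - d, c0[1]),
            (c0[0] + d, c0[1]),
            (c0[0], c0[1] - d),
            (c0[0], c0[1] + d),
        ]
    cs, ss = [], []
    for cen in centers:
        h_r = build_histogram(grid_r, center=cen, n_angular=n_angular, n_radial=n_radial)
        h_v = build_histogram(grid_v, center=cen, n_angular=n_angular, n_radial=n_radial)
        c, s = similarity(h_r, h_v)
        cs.append(c)
        ss.append(s)
    return float(np.mean(cs)), float(np.mean(ss))


@dataclass
class VerifyResult:
    pose: CameraPose
    s: float
    n_iters: int
    accepted: bool
    factor: float = 1.0  # line-search scale applied to the increment


def verify(
    real_frame: Frame,
    pose: CameraPose,
    delta: PoseDelta,
    model: AirwayModel,
    cfg: RenderConfig = None,
    sim_model: AnfisModel = None,
    budget: int = 8,
    block_size: int = 12,
    glare_model: AnfisModel = None,
    importance_model: AnfisModel = None,
    accept_threshold: float = 0.5,
) -> VerifyResult:
    """Verify a tracked pose against the real frame; correct it if needed.

    Renders at ``pose`` first; if the fuzzy decision on the similarity s
    accepts, returns immediately.  Otherwise the increment ``delta`` is
    re-applied from the pre-increment pose scaled by each line-search
    factor (at most ``budget`` re-rendered candidates), and the candidate
    with the highest s wins — accepted if its decision passes, best-effort
    otherwise.
    """
    if budget < 1:
        raise ValueError("verification budget must be >= 1")
    cfg = cfg or RenderConfig()
    sim_model = sim_model or default_similarity_model()

    def score(candidate: CameraPose):
        try:
            virt = render(model, candidate, cfg)
        except OutsideAirwayError:
            return None
        try:
            _, s = frame_similarity(
                real_frame,
                virt,
                block_size=block_size,
                glare_model=glare_model,
                importance_model=importance_model,
            )
        except NoSalientBlocksError:
            s = 0.0
        return s

    s0 = score(pose)
    n_iters = 1
    if s0 is None:
        raise OutsideAirwayError("tracked pose lies outside the lumen")
    if evaluate(sim_model, [s0]) >= accept_threshold:
        return VerifyResult(pose, s0, n_iters, True, 1.0)

    pose_pre = integrate(pose, delta.inverse())
    best = (s0, pose, 1.0)
    n_candidates = 0
    for factor in LINE_SEARCH_FACTORS:
        if n_candidates >= budget:
            break
        candidate = integrate(pose_pre, scale_delta(delta, factor))
        s = score(candidate)
        n_candidates += 1
        n_iters += 1
        if s is None:
            continue
        if s > best[0]:
            best = (s, candidate, factor)
    s_best, pose_best, factor_best = best
    accepted = evaluate(sim_model, [s_best]) >= accept_threshold
    result_pose = CameraPose(pose_best.position, pose_best.quaternion)
    return VerifyResult(result_pose, s_best, n_iters, accepted, factor_best)
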