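"""Phase-1 inter-frame camera tracking.

Two independent displacement estimators run on every consecutive frame
pair:

* sparse feature matching (SIFT by default; ORB and CENSURE+BRIEF are
  selectable for the detector-comparison harness), which is fast but can be
  thrown off by sudden scope motion, and
* dense block-matching optical flow maximizing the normalized
  cross-correlation CC(G, H) = sum (g - gbar)(h - hbar) / (M N sigma_G
  sigma_H) over a search window, slower but robust.

A two-input fuzzy arbiter keyed on the suddenness of the feature-based
motion (deviation from recent history) and its RANSAC confidence picks
which estimate becomes the pose increment.  Image-plane motion is lifted to
a 3-D increment with a depth hint from the virtual model: lateral shift
scales with depth/focal, the similarity-fit scale change gives axial
advance, and the fit angle gives roll about the view axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation
from skimage.feature import BRIEF, CENSURE, ORB, SIFT, match_descriptors

from .anfis import AnfisModel, evaluate
from .geometry import CameraPose, Frame, PoseDelta, integrate

__all__ = [
    "MatchSet",
    "FlowField",
    "InsufficientFeaturesError",
    "detect_and_match",
    "block_flow",
    "delta_from_matches",
    "arbitrate",
    "integrate",
    "track_sequence",
]

FEATURE_METHODS = ("sift", "orb", "brief")


class InsufficientFeaturesError(RuntimeError):
    """Too few feature matches survived filtering; fall back to optical flow."""


@dataclass
class MatchSet:
    """Matched point pairs between two frames, image (x, y) pixel coords."""

    points_a: np.ndarray  # (n, 2) in the earlier frame
    points_b: np.ndarray  # (n, 2) in the later frame
    distances: np.ndarray  # descriptor distances, >= 0
    method: str = "sift"

    def __post_init__(self) -> None:
        self.points_a = np.asarray(self.points_a, dtype=float).reshape(-1, 2)
        self.points_b = np.asarray(self.points_b, dtype=float).reshape(-1, 2)
        self.distances = np.asarray(self.distances, dtype=float).ravel()
        if np.any(self.distances < 0):
            raise ValueError("descriptor distances must be non-negative")

    def __len__(self) -> int:
        return self.points_a.shape[0]

    @property
    def displacements(self) -> np.ndarray:
        return self.points_b - self.points_a


@dataclass
class FlowField:
    """Block-matching flow: one displacement vector per block of frame_a."""

    block_size: int
    centers: np.ndarray  # (n, 2) block centers (x, y)
    vectors: np.ndarray  # (n, 2) displacement (dx, dy) into frame_b
    cc: np.ndarray  # peak normalized cross-correlation per block
    valid: np.ndarray  # False for zero-variance (textureless) blocks

    def __len__(self) -> int:
        return self.centers.shape[0]


def _gray(frame) -> np.ndarray:
    if isinstance(frame, Frame):
        return frame.gray()
    return np.asarray(frame, dtype=float)


# ---------------------------------------------------------------------------
# feature matching
# ---------------------------------------------------------------------------

def _detect(gray: np.ndarray, method: str):
    """Keypoints (n, 2) as (row, col) and descriptors for one image."""
    if method == "sift":
        # endoscopic frames are low-contrast (dim distal lumen); a reduced
        # DoG threshold keeps enough keypoints on the mucosal texture
        det = SIFT(c_dog=0.002)
        det.detect_and_extract(gray)
        return det.keypoints, det.descriptors, False
    if method == "orb":
        det = ORB(n_keypoints=500, fast_threshold=0.008)
        det.detect_and_extract(gray)
        return det.keypoints, det.descriptors, True
    if method == "brief":
        cen = CENSURE(non_max_threshold=0.01)
        cen.detect(gray)
        extractor = BRIEF()
        extractor.extract(gray, cen.keypoints)
        return cen.keypoints[extractor.mask], extractor.descriptors, True
    raise ValueError(f"unknown feature method {method!r}; use one of {FEATURE_METHODS}")


def detect_and_match(frame_a, frame_b, method: str = "sift") -> MatchSet:
    """Mutual-nearest-neighbour matches with Lowe ratio filtering."""
    ga, gb = _gray(frame_a), _gray(frame_b)
    if ga.shape != gb.shape:
        raise ValueError("frames must share a resolution")
    try:
        kp_a, desc_a, binary = _detect(ga, method)
        kp_b, desc_b, _ = _detect(gb, method)
    except (RuntimeError, ValueError) as exc:
        if method not in FEATURE_METHODS:
            raise
        raise InsufficientFeaturesError(f"{method}: no detectable features ({exc})")
    if len(kp_a) < 4 or len(kp_b) < 4:
        raise InsufficientFeaturesError(f"{method}: too few keypoints")
    metric = "hamming" if binary else None
    matches = match_descriptors(
        desc_a, desc_b, metric=metric, cross_check=True, max_ratio=0.8
    )
    if matches.shape[0] < 4:
        raise InsufficientFeaturesError(
            f"{method}: only {matches.shape[0]} matches survive filtering"
        )
    a = kp_a[matches[:, 0]][:, ::-1]  # (row, col) -> (x, y)
    b = kp_b[matches[:, 1]][:, ::-1]
    if binary:
        dists = np.count_nonzero(
            desc_a[matches[:, 0]] != desc_b[matches[:, 1]], axis=1
        ).astype(float)
    else:
        dists = np.linalg.norm(
            desc_a[matches[:, 0]].astype(float) - desc_b[matches[:, 1]].astype(float),
            axis=1,
        )
    return MatchSet(a, b, dists, method)


# ---------------------------------------------------------------------------
# block-matching optical flow
# ---------------------------------------------------------------------------

def block_flow(
    frame_a, frame_b, block_size: int = 16, search_radius: int = 12
) -> FlowField:
    """Displacement of each frame_a block maximizing normalized cross-correlation.

    The correlation is the block-mean/SD normalized form divided by the pixel
    count, so CC is 1 for identical blocks and lies in [-1, 1].  Zero-variance
    source blocks are flagged invalid with a null vector.
    """
    if search_radius < 1:
        raise ValueError("search_radius must be >= 1")
    ga, gb = _gray(frame_a), _gray(frame_b)
    if ga.shape != gb.shape:
        raise ValueError("frames must share a resolution")
    H, W = ga.shape
    bs, R = block_size, search_radius
    nr, nc = H // bs, W // bs
    a = ga[: nr * bs, : nc * bs]

    blocks_a = a.reshape(nr, bs, nc, bs).swapaxes(1, 2)  # (nr, nc, bs, bs)
    mean_a = blocks_a.mean(axis=(2, 3))
    dev_a = blocks_a - mean_a[..., None, None]
    var_a = (dev_a**2).mean(axis=(2, 3))
    sd_a = np.sqrt(var_a)
    valid = sd_a > 1e-9  # zero-variance up to float accumulation noise

    padded = np.full((H + 2 * R, W + 2 * R), np.nan)
    padded[R : R + H, R : R + W] = gb

    n_off = (2 * R + 1) ** 2
    best_cc = np.full((nr, nc), -np.inf)
    best_vec = np.zeros((nr, nc, 2))
    Npix = bs * bs
    for dy in range(-R, R + 1):
        for dx in range(-R, R + 1):
            win = padded[R + dy : R + dy + nr * bs, R + dx : R + dx + nc * bs]
            blocks_b = win.reshape(nr, bs, nc, bs).swapaxes(1, 2)
            mean_b = blocks_b.mean(axis=(2, 3))
            dev_b = blocks_b - mean_b[..., None, None]
            sd_b = np.sqrt((dev_b**2).mean(axis=(2, 3)))
            cross = (dev_a * dev_b).sum(axis=(2, 3))
            with np.errstate(invalid="ignore", divide="ignore"):
                cc = cross / (Npix * sd_a * sd_b)
            cc = np.where(np.isfinite(cc), cc, -np.inf)
            better = cc > best_cc
            best_cc = np.where(better, cc, best_cc)
            best_vec[better] = (dx, dy)

    ys, xs = np.mgrid[0:nr, 0:nc]
    centers = np.stack(
        [(xs * bs + bs / 2.0).ravel(), (ys * bs + bs / 2.0).ravel()], axis=1
    )
    cc_flat = best_cc.ravel()
    vec_flat = best_vec.reshape(-1, 2)
    valid_flat = valid.ravel() & np.isfinite(cc_flat)
    vec_flat[~valid_flat] = 0.0
    cc_flat = np.where(valid_flat, cc_flat, 0.0)
    return FlowField(bs, centers, vec_flat, cc_flat, valid_flat)


# ---------------------------------------------------------------------------
# 2-D similarity fit -> 3-D pose increment
# ---------------------------------------------------------------------------

def _fit_similarity(P: np.ndarray, Q: np.ndarray):
    """Least-squares 2-D similarity Q ~ s R P + t; returns (s, angle, t)."""
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    denom = (Pc**2).sum()
    if denom < 1e-12:
        raise np.linalg.LinAlgError("degenerate (coincident) points")
    a = (Pc * Qc).sum() / denom
    b = (Pc[:, 0] * Qc[:, 1] - Pc[:, 1] * Qc[:, 0]).sum() / denom
    s = float(np.hypot(a, b))
    ang = float(np.arctan2(b, a))
    R = s * np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    t = Q.mean(axis=0) - R @ P.mean(axis=0)
    return s, ang, t


def _apply_similarity(s, ang, t, P):
    R = s * np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    return P @ R.T + t


def ransac_similarity_inliers(
    P: np.ndarray,
    Q: np.ndarray,
    threshold: float = 2.0,
    iters: int = 500,
    seed: int = 12345,
) -> np.ndarray:
    """Boolean inlier mask of correspondences under the best similarity model."""
    rng = np.random.default_rng(seed)
    n = P.shape[0]
    best = np.zeros(n, dtype=bool)
    for _ in range(iters):
        i, j = rng.choice(n, size=2, replace=False)
        if np.linalg.norm(P[i] - P[j]) < 1e-9:
            continue
        try:
            s, ang, t = _fit_similarity(P[[i, j]], Q[[i, j]])
        except np.linalg.LinAlgError:
            continue
        resid = np.linalg.norm(_apply_similarity(s, ang, t, P) - Q, axis=1)
        inliers = resid < threshold
        if inliers.sum() > best.sum():
            best = inliers
    return best


def delta_from_matches(
    matches,
    prev_pose: CameraPose = None,
    depth_hint: float = 10.0,
    focal_px: float = 120.0,
    ransac_threshold: float = 2.0,
    ransac_iters: int = 500,
    seed: int = 12345,
    source: str = None,
    principal_point=None,
    point_depth=None,
) -> PoseDelta:
    """RANSAC similarity fit of the 2-D motion, lifted to a 3-D increment.

    Accepts a MatchSet or a FlowField.  The increment is expressed in the
    camera body frame (x right, y down, z forward).  The lateral shift is
    the fitted transform's displacement of the principal point (image
    center), which separates true translation from the scale/rotation
    component; without a principal point the correspondence centroid is
    used.

    ``point_depth`` optionally carries the wall depth of every
    correspondence (from the virtual model).  The least-squares scale
    weights each feature by its squared radius about the center, so the
    axial advance then uses the matching radius-squared-weighted harmonic
    mean of the inlier depths; otherwise the scalar ``depth_hint`` is used
    throughout.
    """
    if isinstance(matches, FlowField):
        sel = matches.valid
        P = matches.centers[sel]
        Q = P + matches.vectors[sel]
        source = source or "flow"
    else:
        P, Q = matches.points_a, matches.points_b
        source = source or "features"
    if P.shape[0] < 4:
        raise InsufficientFeaturesError("need at least 4 correspondences")

    spread = P.std(axis=0)
    if np.min(spread) < 1e-9 and P.shape[0] > 2:
        raise np.linalg.LinAlgError("collinear correspondence geometry")

    n = P.shape[0]
    best_inliers = ransac_similarity_inliers(P, Q, ransac_threshold, ransac_iters, seed)
    best_count = int(best_inliers.sum())
    if best_count < 2:
        raise np.linalg.LinAlgError("RANSAC found no consistent similarity model")
    s, ang, t = _fit_similarity(P[best_inliers], Q[best_inliers])
    confidence = float(best_count) / n

    pp = np.asarray(principal_point, dtype=float) if principal_point is not None else P.mean(axis=0)
    shift = _apply_similarity(s, ang, t, pp[None, :])[0] - pp

    z_axial = z_lateral = float(depth_hint)
    if point_depth is not None:
        z = np.asarray(point_depth, dtype=float)
        if isinstance(matches, FlowField):
            z = z[sel]
        z = z[best_inliers]
        w = ((P[best_inliers] - pp) ** 2).sum(axis=1)
        if w.sum() > 0 and np.all(z > 0):
            z_axial = float(w.sum() / (w / z).sum())
        z_lateral = float(np.median(z))

    # lift to 3-D: scale -> axial advance, center shift -> lateral, angle -> roll
    s = max(s, 1e-6)
    dz = z_axial * (1.0 - 1.0 / s)
    dx = -shift[0] * z_lateral / focal_px
    dy = -shift[1] * z_lateral / focal_px
    roll = -ang  # image rotates opposite to a camera roll about +z
    quat = Rotation.from_rotvec([0.0, 0.0, roll]).as_quat()
    return PoseDelta(np.array([dx, dy, dz]), quat, source, confidence)


# ---------------------------------------------------------------------------
# arbitration
# ---------------------------------------------------------------------------

def arbitrate(
    delta_features: PoseDelta,
    delta_flow: PoseDelta,
    history,
    model: AnfisModel,
    eps: float = 1e-6,
) -> PoseDelta:
    """Choose between the feature-based and flow-based increments.

    Suddenness is how far the candidate translations deviate from the mean
    of recent increments, in units of the mean historic step length; the
    larger deviation of the two candidates counts, since sudden motion can
    corrupt the feature estimate into a deceptively small vector while the
    flow still registers the shift.  With no history the motion cannot be
    judged sudden and the (faster) feature estimate is preferred.
    """
    history = list(history or [])
    if history:
        trans = np.array([h.translation for h in history])
        mean_vec = trans.mean(axis=0)
        mean_mag = float(np.linalg.norm(trans, axis=1).mean())
        suddenness = max(
            float(np.linalg.norm(d.translation - mean_vec) / (mean_mag + eps))
            for d in (delta_features, delta_flow)
        )
    else:
        suddenness = 0.0
    score = evaluate(model, [min(suddenness, 10.0), delta_features.confidence])
    chosen = delta_flow if score >= 0.5 else delta_features
    return PoseDelta(
        chosen.translation, chosen.quaternion, chosen.source, chosen.confidence
    )


# ---------------------------------------------------------------------------
# sequence tracking
# ---------------------------------------------------------------------------

def track_sequence(
    frames,
    start_pose: CameraPose,
    depth_hints=None,
    airway=None,
    render_cfg=None,
    focal_px: float = 120.0,
    model: AnfisModel = None,
    mode: str = "arbitrate",
    block_size: int = 16,
    search_radius: int = 12,
    history_window: int = 5,
):
    """Integrate per-pair increments over a frame sequence.

    mode: "arbitrate" (fuzzy choice), "features" (feature matching only) or
    "flow" (optical flow only).  The depth hint for lifting image motion to
    millimetres comes from ``depth_hints`` (one per step) if given, else
    from the virtual model's median wall distance at the current tracked
    pose, else a 10 mm constant.  Returns (poses, records); poses[k] is the
    pose at frame k, records carry per-step source/confidence.
    """
    from .defaults import default_arbitration_model

    model = model or default_arbitration_model()
    frames = list(frames)
    poses = [start_pose.copy()]
    history: list = []
    records = []
    def depths_for(points: np.ndarray, k: int):
        """(scalar hint, per-point depths or None) for the current step."""
        if depth_hints is not None:
            return float(depth_hints[k - 1]), None
        if airway is not None:
            from .airway import OutsideAirwayError, point_depths

            try:
                z = point_depths(airway, poses[-1], render_cfg, points)
                return float(np.median(z)), z
            except OutsideAirwayError:
                return 10.0, None
        return 10.0, None

    for k in range(1, len(frames)):
        shape = frames[k].shape if isinstance(frames[k], Frame) else frames[k].shape
        pp = (shape[1] / 2.0, shape[0] / 2.0)
        d_feat = d_flow = None
        if mode in ("arbitrate", "features"):
            try:
                m = detect_and_match(frames[k - 1], frames[k], "sift")
                hint, z = depths_for(m.points_a, k)
                d_feat = delta_from_matches(
                    m,
                    poses[-1],
                    depth_hint=hint,
                    focal_px=focal_px,
                    principal_point=pp,
                    point_depth=z,
                )
            except (InsufficientFeaturesError, np.linalg.LinAlgError):
                d_feat = None
        if mode in ("arbitrate", "flow") or d_feat is None:
            flow = block_flow(frames[k - 1], frames[k], block_size, search_radius)
            try:
                hint, z = depths_for(flow.centers, k)
                d_flow = delta_from_matches(
                    flow,
                    poses[-1],
                    depth_hint=hint,
                    focal_px=focal_px,
                    principal_point=pp,
                    point_depth=z,
                )
            except (InsufficientFeaturesError, np.linalg.LinAlgError):
                d_flow = PoseDelta.identity(source="flow", confidence=0.0)
        if mode == "features" and d_feat is not None:
            delta = d_feat
        elif mode == "flow" or d_feat is None:
            delta = d_flow
        else:
            delta = arbitrate(d_feat, d_flow, history, model)
        poses.append(integrate(poses[-1], delta))
        history.append(delta)
        if len(history) > history_window:
            history.pop(0)
        records.append(
            {
                "frame": k,
                "source": delta.source,
                "confidence": delta.confidence,
                "step_mm": float(np.linalg.norm(delta.translation)),
            }
        )
    return poses, records
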