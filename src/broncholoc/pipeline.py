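"""End-to-end localization runs and the comparison harnesses.

``localize`` chains the two phases over a frame sequence — arbitrated
tracking, then render-and-verify correction — and writes a trajectory CSV,
a per-frame report, and co-display images (real frame beside the airway
map with the current position dot).  The module also hosts the evaluation
harnesses: the plain MSE image distance used as the registration baseline,
a method comparison (shape-context search vs MSE search), and the feature
detector comparison table.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .airway import AirwayModel, RenderConfig, load_mesh, render
from .geometry import CameraPose, Frame, PoseDelta, integrate, scale_delta
from .registration import LINE_SEARCH_FACTORS, VerifyResult, frame_similarity, verify
from .saliency import NoSalientBlocksError
from .synthesis import SequenceResult
from .tracking import (
    InsufficientFeaturesError,
    detect_and_match,
    ransac_similarity_inliers,
    track_sequence,
)

__all__ = [
    "RunConfig",
    "localize",
    "localize_sequence",
    "mse_similarity",
    "compare_methods",
    "feature_report",
]

log = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "frames_dir",
    "airway_mesh",
    "output_dir",
    "seed",
    "start_position",
    "start_quaternion",
    "focal_px",
    "image_size",
    "tracking",
    "verify",
    "glare",
    "saliency",
    "log_level",
    "codisplay_every",
}
_KNOWN_TRACKING = {"block_size", "search_radius", "history_window", "mode"}
_KNOWN_VERIFY = {"block_size", "budget", "accept_threshold"}


@dataclass
class RunConfig:
    """Validated run configuration (YAML-loadable)."""

    frames_dir: str
    airway_mesh: str
    output_dir: str = "out"
    seed: int = 0
    start_position: tuple = (0.0, 0.0, 2.0)
    start_quaternion: tuple = None  # default: looking along +z
    focal_px: float = 120.0
    image_size: int = 200
    tracking: dict = field(default_factory=dict)
    verify: dict = field(default_factory=dict)
    glare: dict = field(default_factory=dict)
    saliency: dict = field(default_factory=dict)
    log_level: str = "INFO"
    codisplay_every: int = 10

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for sub, known in (("tracking", _KNOWN_TRACKING), ("verify", _KNOWN_VERIFY)):
            bad = set(data.get(sub, {})) - known
            if bad:
                raise ValueError(f"unknown {sub}.* keys: {sorted(bad)}")
        return cls(**data)

    def validate_paths(self) -> None:
        if not os.path.isdir(self.frames_dir):
            raise FileNotFoundError(f"frames directory {self.frames_dir!r} not found")
        if not os.path.isfile(self.airway_mesh):
            raise FileNotFoundError(f"airway mesh {self.airway_mesh!r} not found")

    def start_pose(self) -> CameraPose:
        if self.start_quaternion is None:
            return CameraPose.looking_along(np.asarray(self.start_position), [0, 0, 1])
        return CameraPose(np.asarray(self.start_position), np.asarray(self.start_quaternion))


def _load_frames(frames_dir):
    exts = (".png", ".tif", ".tiff", ".jpg", ".jpeg")
    names = sorted(n for n in os.listdir(frames_dir) if n.lower().endswith(exts))
    if not names:
        raise FileNotFoundError(f"no frames found in {frames_dir!r}")
    from PIL import Image, UnidentifiedImageError

    frames, skipped = [], 0
    for k, name in enumerate(names):
        try:
            img = np.asarray(Image.open(os.path.join(frames_dir, name)).convert("RGB"))
            frames.append(Frame(index=k, pixels=img))
        except (OSError, UnidentifiedImageError) as exc:
            log.warning("skipping unreadable frame %s: %s", name, exc)
            skipped += 1
    if skipped > 0.2 * len(names):
        raise RuntimeError(f"{skipped}/{len(names)} frames unreadable; aborting run")
    return frames


def _codisplay(frame: Frame, airway: AirwayModel, pose: CameraPose, path) -> None:
    """Real frame beside the airway map with the current position in red."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(7, 3.5))
    ax1.imshow(frame.pixels)
    ax1.set_title("bronchoscope view")
    ax1.axis("off")
    for b in airway.branches:
        ax2.plot([b.start[0], b.end[0]], [b.start[2], b.end[2]], "-", color="steelblue", lw=2)
    ax2.plot(pose.position[0], pose.position[2], "ro", ms=8)
    ax2.set_xlabel("x (mm)")
    ax2.set_ylabel("z (mm)")
    ax2.set_title("airway model")
    ax2.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(str(path), dpi=80)
    plt.close(fig)


def localize_sequence(
    frames,
    airway: AirwayModel,
    start_pose: CameraPose,
    render_cfg: RenderConfig = None,
    tracking_opts: dict = None,
    verify_opts: dict = None,
):
    """Two-phase localization over in-memory frames.

    Returns (verified_poses, tracked_poses, records): per frame the
    arbitrated tracking increment is applied, then the pose is verified and
    possibly corrected against the rendered view.
    """
    render_cfg = render_cfg or RenderConfig(
        width=frames[0].shape[1], height=frames[0].shape[0]
    )
    tracking_opts = dict(tracking_opts or {})
    verify_opts = dict(verify_opts or {})
    from .defaults import default_arbitration_model

    arb_model = default_arbitration_model()
    mode = tracking_opts.pop("mode", "arbitrate")

    tracked = [start_pose.copy()]
    verified = [start_pose.copy()]
    records = []
    history: list = []
    for k in range(1, len(frames)):
        sub_poses, sub_recs = track_sequence(
            [frames[k - 1], frames[k]],
            verified[-1],
            airway=airway,
            render_cfg=render_cfg,
            focal_px=render_cfg.focal_px,
            model=arb_model,
            mode=mode,
            **tracking_opts,
        )
        delta_rec = sub_recs[0]
        pose_tracked = sub_poses[1]
        # reconstruct the applied increment for the verifier's line search
        dt = verified[-1].rotation.inv().apply(pose_tracked.position - verified[-1].position)
        dq = (verified[-1].rotation.inv() * pose_tracked.rotation).as_quat()
        delta = PoseDelta(dt, dq, delta_rec["source"], delta_rec["confidence"])
        tracked.append(pose_tracked)
        res: VerifyResult = verify(
            frames[k], pose_tracked, delta, airway, render_cfg, **verify_opts
        )
        verified.append(res.pose)
        records.append(
            {
                "frame": k,
                "source": delta.source,
                "confidence": delta.confidence,
                "s": res.s,
                "n_iters": res.n_iters,
                "accepted": res.accepted,
                "factor": res.factor,
            }
        )
    return verified, tracked, records


def localize(cfg: RunConfig):
    """File-based end-to-end run; writes trajectory.csv, report.csv, co-displays."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    cfg.validate_paths()
    frames = _load_frames(cfg.frames_dir)
    airway = load_mesh(cfg.airway_mesh)
    render_cfg = RenderConfig(width=cfg.image_size, height=cfg.image_size, focal_px=cfg.focal_px)
    verified, tracked, records = localize_sequence(
        frames,
        airway,
        cfg.start_pose(),
        render_cfg,
        tracking_opts=cfg.tracking,
        verify_opts=cfg.verify,
    )
    os.makedirs(cfg.output_dir, exist_ok=True)
    rows = []
    for k, pose in enumerate(verified):
        qw = np.roll(pose.quaternion, 1)
        rec = records[k - 1] if k else None
        rows.append(
            {
                "frame": k,
                "x": pose.position[0],
                "y": pose.position[1],
                "z": pose.position[2],
                "qw": qw[0],
                "qx": qw[1],
                "qy": qw[2],
                "qz": qw[3],
                "source": rec["source"] if rec else "start",
                "confidence": rec["confidence"] if rec else 1.0,
            }
        )
    traj_path = os.path.join(cfg.output_dir, "trajectory.csv")
    pd.DataFrame(rows).to_csv(traj_path, index=False)
    pd.DataFrame(records).to_csv(os.path.join(cfg.output_dir, "report.csv"), index=False)
    for k in range(0, len(frames), max(cfg.codisplay_every, 1)):
        _codisplay(
            frames[k],
            airway,
            verified[k],
            os.path.join(cfg.output_dir, f"codisplay_{k:04d}.png"),
        )
    log.info("localized %d frames -> %s", len(frames), traj_path)
    return verified, records


# ---------------------------------------------------------------------------
# baselines and comparison harnesses
# ---------------------------------------------------------------------------

def mse_similarity(frame_a, frame_b) -> float:
    """Mean squared intensity difference over all pixels (intensities in [0,1])."""
    a = frame_a.as_float() if isinstance(frame_a, Frame) else np.asarray(frame_a, dtype=float)
    b = frame_b.as_float() if isinstance(frame_b, Frame) else np.asarray(frame_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"resolution mismatch: {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))


def _search_candidates(pose: CameraPose, delta: PoseDelta):
    pre = integrate(pose, delta.inverse())
    yield 1.0, pose
    for f in LINE_SEARCH_FACTORS:
        yield f, integrate(pre, scale_delta(delta, f))


def compare_methods(
    seq: SequenceResult,
    query_indices,
    perturbation_mm: float = 2.0,
    seed: int = 0,
    block_size: int = None,
) -> pd.DataFrame:
    """Shape-context-driven vs MSE-driven verification search on fixture frames.

    For each query frame the true pose is perturbed by a seeded offset and
    both methods pick their best candidate from the same line-search set;
    the report carries each method's chosen-pose similarity s and its
    position error against the fixture truth.  The subblock size defaults
    to the fixture's own (it must scale with the frame resolution).
    """
    block_size = block_size or seq.spec.block_size
    rng = np.random.default_rng(seed)
    rows = []
    for k in query_indices:
        real = seq.frames[k]
        true_pose = seq.poses[k]
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        derr = PoseDelta(perturbation_mm * u, source="features", confidence=0.8)
        tracked = integrate(true_pose, derr)
        if not seq.airway.contains(tracked.position):
            continue
        for method in ("shape_context", "mse"):
            best = None
            for factor, cand in _search_candidates(tracked, derr):
                try:
                    virt = render(seq.airway, cand, seq.render_cfg)
                except Exception:
                    continue
                if method == "shape_context":
                    try:
                        _, score = frame_similarity(real, virt, block_size=block_size)
                    except NoSalientBlocksError:
                        score = 0.0
                else:
                    score = -mse_similarity(real, virt)  # lower MSE is better
                if best is None or score > best[0]:
                    best = (score, cand, factor)
            _, chosen, _ = best
            try:
                virt = render(seq.airway, chosen, seq.render_cfg)
                _, s_chosen = frame_similarity(real, virt, block_size=block_size)
            except NoSalientBlocksError:
                s_chosen = 0.0
            rows.append(
                {
                    "frame": k,
                    "method": method,
                    "s": s_chosen,
                    "pose_error_mm": float(
                        np.linalg.norm(chosen.position - true_pose.position)
                    ),
                }
            )
    return pd.DataFrame(rows)


def feature_report(frame_a, frame_b, methods=("sift", "orb", "brief")) -> pd.DataFrame:
    """Detector comparison: matches, geometric inliers, outliers per method.

    'Correct matches' are operationalized as RANSAC inliers of the dominant
    2-D similarity transform between the frames.
    """
    rows = []
    for method in methods:
        try:
            m = detect_and_match(frame_a, frame_b, method)
            inl = ransac_similarity_inliers(m.points_a, m.points_b)
            total = len(m)
            inliers = int(inl.sum())
        except (InsufficientFeaturesError, np.linalg.LinAlgError):
            total = inliers = 0
        rows.append(
            {
                "method": method,
                "total_matches": total,
                "inliers": inliers,
                "outliers": total - inliers,
            }
        )
    return pd.DataFrame(rows)
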