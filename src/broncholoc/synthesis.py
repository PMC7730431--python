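"""Synthetic bronchoscopy sequences with per-stage ground truth.

Clinical bronchoscopy video and patient CT models cannot be redistributed,
so every test input here is generated: a procedural airway tree, a known
camera trajectory through its lumen, interior renders degraded the way a
real scope degrades them — saturated circular glare blobs from the light
source, optional single-coefficient fisheye distortion, Gaussian sensor
noise — plus the exact ground truth for each stage (true poses, per-frame
glare masks).  Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass

import numpy as np

from .airway import AirwayModel, Branch, RenderConfig, generate_tree, render
from .geometry import CameraPose, Frame

__all__ = [
    "SequenceSpec",
    "SequenceResult",
    "synthesize",
    "make_standard_fixtures",
    "standard_fixture",
    "STANDARD_FIXTURES",
]


@dataclass
class SequenceSpec:
    """Everything needed to regenerate a sequence bit-identically."""

    name: str = "sequence"
    airway_seed: int = 11
    n_generations: int = 3
    straight_tube: bool = False  # single straight branch instead of a tree
    n_steps: int = 20
    step_mm: float = 0.25
    sway_mm: float = 0.12  # lateral sinusoidal sway amplitude
    start_offset_mm: float = 2.0  # camera start, measured into the root branch
    jump_steps: tuple = ()  # ((step, magnitude_mm), ...) sudden axial jumps
    jump_blur_sigma: float = 5.0  # motion-blur proxy on jump-step frames (px)
    glare_count: int = 0
    glare_radius_px: float = 18.0
    glare_intensity: float = 1.0
    # camera response mismatch between the "real" scope video and the
    # virtual renders (clinical video never matches a CT-derived model's
    # shading); identity by default
    appearance_gamma: float = 1.0
    appearance_gain: tuple = (1.0, 1.0, 1.0)
    fisheye_k: float = 0.0
    noise_sigma: float = 0.0
    seed: int = 0
    image_size: int = 200
    block_size: int = 16

    def render_config(self) -> RenderConfig:
        return RenderConfig(width=self.image_size, height=self.image_size)


@dataclass
class SequenceResult:
    spec: SequenceSpec
    airway: AirwayModel
    frames: list  # list[Frame]
    poses: list  # ground-truth CameraPose per frame
    glare_masks: list  # bool (H, W) per frame
    render_cfg: RenderConfig = None


def _build_airway(spec: SequenceSpec) -> AirwayModel:
    if spec.straight_tube:
        return AirwayModel([Branch(0, [0.0, 0.0, 0.0], [0.0, 0.0, 80.0], 4.0, 0)])
    return generate_tree(spec.n_generations, seed=spec.airway_seed)


def _trajectory(spec: SequenceSpec, airway: AirwayModel) -> list:
    """Smooth advance down the root branch with lateral sway, plus any jumps.

    Orientation is held along the branch axis; sway is true lateral
    translation, so the image motion is a recoverable similarity transform.
    """
    root = airway.branches[0]
    d = root.direction
    perp = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    perp = perp - (perp @ d) * d
    perp /= np.linalg.norm(perp)
    jumps = dict((int(s), float(m)) for s, m in spec.jump_steps)
    poses = []
    axial = spec.start_offset_mm
    for k in range(spec.n_steps):
        if k > 0:
            axial += spec.step_mm + jumps.get(k, 0.0)
        sway = spec.sway_mm * np.sin(2.0 * np.pi * k / max(spec.n_steps, 1) * 2.0)
        pos = root.start + axial * d + sway * perp
        pose = CameraPose.looking_along(pos, d)
        if not airway.contains(pos):
            raise ValueError(f"trajectory leaves the lumen at step {k} ({pos})")
        poses.append(pose)
    return poses


def _add_glare(rgb: np.ndarray, rng, spec: SequenceSpec):
    """Composite feathered saturated blobs; returns (image, bool mask)."""
    H, W = rgb.shape[:2]
    mask = np.zeros((H, W), dtype=bool)
    ys, xs = np.mgrid[0:H, 0:W]
    out = rgb.copy()
    placed = []
    for _ in range(spec.glare_count):
        # glare clusters where the wall is close: keep blobs off-center,
        # and apart from each other so each stays one connected component
        r = spec.glare_radius_px * rng.uniform(0.8, 1.2)
        for _attempt in range(200):
            ang = rng.uniform(0.0, 2.0 * np.pi)
            rad = rng.uniform(0.25, 0.44) * min(H, W)
            cx = W / 2.0 + rad * np.cos(ang)
            cy = H / 2.0 + rad * np.sin(ang)
            if all(
                np.hypot(cx - px_, cy - py_) > 1.1 * (r + pr) for px_, py_, pr in placed
            ):
                break
        placed.append((cx, cy, r))
        dist = np.hypot(xs - cx, ys - cy)
        alpha = np.clip((r - dist) / (0.12 * r), 0.0, 1.0)  # narrow feathered edge
        out = out * (1.0 - alpha[..., None]) + alpha[..., None] * spec.glare_intensity
        mask |= alpha > 0.5
    return np.clip(out, 0.0, 1.0), mask


def _fisheye(rgb: np.ndarray, k: float) -> np.ndarray:
    """Radial distortion r' = r (1 + k r^2), r normalized to half-diagonal."""
    from skimage.transform import warp

    H, W = rgb.shape[:2]
    cx, cy = (W - 1) / 2.0, (H - 1) / 2.0
    scale = np.hypot(cx, cy)

    def inverse_map(coords):
        x = (coords[:, 0] - cx) / scale
        y = (coords[:, 1] - cy) / scale
        r = np.hypot(x, y)
        factor = 1.0 + k * r**2
        return np.stack([x * factor * scale + cx, y * factor * scale + cy], axis=1)

    return warp(rgb, inverse_map, mode="edge", preserve_range=True)


def synthesize(spec: SequenceSpec) -> SequenceResult:
    """Render the trajectory and apply the degradation chain."""
    airway = _build_airway(spec)
    poses = _trajectory(spec, airway)
    cfg = spec.render_config()
    rng = np.random.default_rng(spec.seed)
    jump_at = {int(s) for s, _ in spec.jump_steps}
    frames, masks = [], []
    for k, pose in enumerate(poses):
        raw = render(airway, pose, cfg).as_float()
        if spec.appearance_gamma != 1.0 or spec.appearance_gain != (1.0, 1.0, 1.0):
            raw = np.clip(
                np.asarray(spec.appearance_gain)[None, None, :]
                * raw**spec.appearance_gamma,
                0.0,
                1.0,
            )
        img, mask = _add_glare(raw, rng, spec)
        if spec.fisheye_k != 0.0:
            img = _fisheye(img, spec.fisheye_k)
        if k in jump_at and spec.jump_blur_sigma > 0:
            # a sudden scope movement smears the frame it lands on
            from scipy.ndimage import gaussian_filter

            img = gaussian_filter(img, sigma=(spec.jump_blur_sigma, spec.jump_blur_sigma, 0))
        if spec.noise_sigma > 0.0:
            img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
        px = (np.clip(img, 0.0, 1.0) * 255.0).round().astype(np.uint8)
        frames.append(Frame(index=k, pixels=px))
        masks.append(mask)
    return SequenceResult(spec, airway, frames, poses, masks, cfg)


# ---------------------------------------------------------------------------
# the named fixtures used across the test suite
# ---------------------------------------------------------------------------

STANDARD_FIXTURES = {
    # slow, stable advance down the trachea (smooth-motion regime)
    "slow_stable": SequenceSpec(
        name="slow_stable",
        n_steps=50,
        step_mm=0.25,
        sway_mm=0.12,
        noise_sigma=0.005,
        seed=101,
    ),
    # same regime with one sudden 5 mm axial jump at step 25
    "sudden_jump": SequenceSpec(
        name="sudden_jump",
        n_steps=50,
        step_mm=0.25,
        sway_mm=0.12,
        noise_sigma=0.005,
        jump_steps=((25, 5.0),),
        seed=102,
    ),
    # heavy specular glare: 8 blobs per frame, full-scale 40 px blocks,
    # plus the real-vs-virtual camera-response mismatch
    "glare_heavy": SequenceSpec(
        name="glare_heavy",
        n_steps=3,
        step_mm=0.4,
        glare_count=8,
        glare_radius_px=34.0,
        noise_sigma=0.005,
        appearance_gamma=0.8,
        appearance_gain=(1.08, 0.97, 0.93),
        seed=103,
        image_size=400,
        block_size=40,
    ),
    # single straight tapering-depth tube for closed-form / recovery checks
    "straight_tube": SequenceSpec(
        name="straight_tube",
        straight_tube=True,
        n_steps=10,
        step_mm=0.5,
        sway_mm=0.0,
        seed=104,
    ),
    # plain 3-generation tree flythrough
    "tree_g3": SequenceSpec(
        name="tree_g3", n_steps=10, step_mm=0.5, sway_mm=0.0, seed=105
    ),
}

_cache: dict = {}


def standard_fixture(name: str) -> SequenceResult:
    """In-memory named fixture (memoized; regenerating is deterministic)."""
    if name not in STANDARD_FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; have {sorted(STANDARD_FIXTURES)}")
    if name not in _cache:
        _cache[name] = synthesize(STANDARD_FIXTURES[name])
    return _cache[name]


def make_standard_fixtures(out_dir) -> dict:
    """Write every named fixture to disk and return the manifest."""
    from PIL import Image

    os.makedirs(out_dir, exist_ok=True)
    manifest = {"fixtures": {}}
    for name, spec in STANDARD_FIXTURES.items():
        res = synthesize(spec)
        fdir = os.path.join(out_dir, name)
        os.makedirs(os.path.join(fdir, "frames"), exist_ok=True)
        os.makedirs(os.path.join(fdir, "glare"), exist_ok=True)
        rows = []
        for k, (frame, pose, mask) in enumerate(zip(res.frames, res.poses, res.glare_masks)):
            Image.fromarray(frame.pixels).save(os.path.join(fdir, "frames", f"{k:04d}.png"))
            Image.fromarray(mask.astype(np.uint8) * 255, mode="L").save(
                os.path.join(fdir, "glare", f"{k:04d}.png")
            )
            rows.append(
                [k, *pose.position.tolist(), *np.roll(pose.quaternion, 1).tolist()]
            )
        import pandas as pd

        pd.DataFrame(
            rows, columns=["frame", "x", "y", "z", "qw", "qx", "qy", "qz"]
        ).to_csv(os.path.join(fdir, "truth.csv"), index=False)
        with open(os.path.join(fdir, "spec.json"), "w") as fh:
            json.dump(asdict(spec), fh, indent=1)
        manifest["fixtures"][name] = {"path": name, "seed": spec.seed}
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
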