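"""Camera poses, pose increments, frames, and SE(3) integration.

Conventions: world units are millimetres; the camera looks along +z of its
body frame with x right and y down (image coordinates).  A pose's rotation
maps body-frame vectors into the world frame.  Pose increments are expressed
in the body frame of the pose they are applied to, so integration is the
right-multiplication T_new = T_old @ T_delta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = ["Frame", "CameraPose", "PoseDelta", "integrate", "scale_delta"]


@dataclass
class Frame:
    """One RGB video frame: uint8 or float image plus its sequence index."""

    index: int
    pixels: np.ndarray  # (H, W, 3)
    timestamp: float = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("Frame requires an RGB (H, W, 3) raster")

    @property
    def shape(self):
        return self.pixels.shape

    def as_float(self) -> np.ndarray:
        """Pixels scaled to [0, 1] float64."""
        px = self.pixels
        if px.dtype == np.uint8:
            return px.astype(float) / 255.0
        return np.clip(px.astype(float), 0.0, 1.0)

    def gray(self) -> np.ndarray:
        """Luma (Rec. 601) intensity in [0, 1]."""
        rgb = self.as_float()
        return 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]


def _norm_quat(q) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    n = np.linalg.norm(q)
    if not np.isfinite(n) or n == 0:
        raise ValueError("quaternion must be finite and nonzero")
    return q / n


@dataclass
class CameraPose:
    """Camera position (mm, world frame) and orientation (unit quaternion xyzw)."""

    position: np.ndarray
    quaternion: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        self.quaternion = _norm_quat(np.asarray(self.quaternion, dtype=float).reshape(4))

    @property
    def rotation(self) -> Rotation:
        return Rotation.from_quat(self.quaternion)

    @classmethod
    def looking_along(cls, position, direction, up=(0.0, -1.0, 0.0)) -> "CameraPose":
        """Pose at ``position`` with the optical axis along ``direction``."""
        z = np.asarray(direction, dtype=float)
        z = z / np.linalg.norm(z)
        up = np.asarray(up, dtype=float)
        x = np.cross(up, z)
        if np.linalg.norm(x) < 1e-9:  # direction parallel to up: pick another up
            x = np.cross([1.0, 0.0, 0.0], z)
        x /= np.linalg.norm(x)
        y = np.cross(z, x)
        R = np.column_stack([x, y, z])
        return cls(np.asarray(position, dtype=float), Rotation.from_matrix(R).as_quat())

    def matrix(self) -> np.ndarray:
        """Homogeneous 4x4 body-to-world transform."""
        T = np.eye(4)
        T[:3, :3] = self.rotation.as_matrix()
        T[:3, 3] = self.position
        return T

    def copy(self) -> "CameraPose":
        return CameraPose(self.position.copy(), self.quaternion.copy())


@dataclass
class PoseDelta:
    """Incremental camera motion in the body frame of the pose it updates."""

    translation: np.ndarray
    quaternion: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 0.0, 1.0]))
    source: str = "kaze"
    confidence: float = 1.0

    def __post_init__(self) -> None:
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.translation)):
            raise ValueError("pose delta translation must be finite")
        self.quaternion = _norm_quat(np.asarray(self.quaternion, dtype=float).reshape(4))

    @property
    def rotation(self) -> Rotation:
        return Rotation.from_quat(self.quaternion)

    @classmethod
    def identity(cls, source: str = "kaze", confidence: float = 1.0) -> "PoseDelta":
        return cls(np.zeros(3), np.array([0.0, 0.0, 0.0, 1.0]), source, confidence)

    def inverse(self) -> "PoseDelta":
        Rinv = self.rotation.inv()
        return PoseDelta(-Rinv.apply(self.translation), Rinv.as_quat(), self.source, self.confidence)


def integrate(pose: CameraPose, delta: PoseDelta) -> CameraPose:
    """Apply a body-frame increment: position += R(pose) t, R_new = R R_delta."""
    R = pose.rotation
    return CameraPose(
        pose.position + R.apply(delta.translation),
        (R * delta.rotation).as_quat(),
    )


def scale_delta(delta: PoseDelta, factor: float) -> PoseDelta:
    """Scale an increment: translation linearly, rotation via rotation-vector
    scaling (geodesic interpolation/extrapolation from identity)."""
    rotvec = delta.rotation.as_rotvec() * factor
    return PoseDelta(
        delta.translation * factor,
        Rotation.from_rotvec(rotvec).as_quat(),
        delta.source,
        delta.confidence,
    )
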