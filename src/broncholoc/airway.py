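"""Procedural bronchial-tree models and an interior virtual-bronchoscopy renderer.

The airway is modelled as a binary tree of straight tubular branches
(capsules: cylinders with spherical ends) whose radii shrink geometrically
with generation.  The renderer casts one ray per pixel from an in-lumen
camera, intersects it analytically with the capsule union, and shades the
hit point with a camera-mounted headlight (Lambert term x inverse-square
falloff) over a procedural mucosa-like 3-D texture.  Everything is exact
and deterministic: no rasterization, no sampling noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import trimesh

from .geometry import CameraPose, Frame

__all__ = [
    "Branch",
    "AirwayModel",
    "RenderConfig",
    "BranchingParams",
    "generate_tree",
    "render",
    "render_depth",
    "median_depth",
    "save_mesh",
    "load_mesh",
    "OutsideAirwayError",
]


class OutsideAirwayError(ValueError):
    """Raised when a camera pose lies outside the airway lumen."""


@dataclass
class Branch:
    """One straight airway segment from ``start`` to ``end`` (mm)."""

    id: int
    start: np.ndarray
    end: np.ndarray
    radius: float
    generation: int
    parent: int = None  # parent branch id, None for the root
    label: int = 0  # fork index among siblings (0 = first child)

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=float).reshape(3)
        self.end = np.asarray(self.end, dtype=float).reshape(3)
        if self.radius <= 0:
            raise ValueError("branch radius must be positive")

    @property
    def direction(self) -> np.ndarray:
        d = self.end - self.start
        return d / np.linalg.norm(d)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.end - self.start))


@dataclass
class BranchingParams:
    """Branching statistics for the procedural generator (angles in degrees)."""

    root_length: float = 30.0
    root_radius: float = 5.0
    length_decay: float = 0.75
    radius_decay: float = 0.78
    branch_angle_mean: float = 35.0
    branch_angle_std: float = 5.0


@dataclass
class AirwayModel:
    """Branch list plus the derived junction graph and mesh."""

    branches: list
    _graph: nx.DiGraph = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self._graph = None
        # packed arrays for the renderer
        self._A = np.array([b.start for b in self.branches])
        self._B = np.array([b.end for b in self.branches])
        self._R = np.array([b.radius for b in self.branches])

    # -- junction graph ----------------------------------------------------
    @property
    def graph(self) -> nx.DiGraph:
        """Directed junction graph: nodes are branch endpoints, edges are branches.

        Node ids: "J0" is the root inlet; every branch ``b`` ends at node
        "J<b.id+1>" (its distal endpoint, a junction or a leaf tip).
        """
        if self._graph is None:
            g = nx.DiGraph()
            g.add_node("J0", position=tuple(self.branches[0].start))
            for b in self.branches:
                head = "J0" if b.parent is None else f"J{b.parent + 1}"
                tail = f"J{b.id + 1}"
                g.add_node(tail, position=tuple(b.end))
                g.add_edge(
                    head,
                    tail,
                    branch_id=b.id,
                    label=b.label,
                    polyline=[tuple(b.start), tuple(b.end)],
                    radius=b.radius,
                )
            self._graph = g
        return self._graph

    @property
    def junction_ids(self):
        """Internal junction nodes (out-degree >= 2)."""
        g = self.graph
        return [n for n in g.nodes if g.out_degree(n) >= 2]

    @property
    def leaf_ids(self):
        g = self.graph
        return [n for n in g.nodes if g.out_degree(n) == 0]

    def children_of(self, node: str):
        """Children of a node ordered by fork label (0 first)."""
        g = self.graph
        out = sorted(g.successors(node), key=lambda n: g.edges[node, n]["label"])
        return out

    # -- geometry queries --------------------------------------------------
    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """min over branches of (distance to centerline segment - radius).

        Negative inside the lumen.  For a union of convex capsules this is a
        valid (conservative inside) signed bound.
        """
        p = np.atleast_2d(np.asarray(points, dtype=float))
        A, B, R = self._A, self._B, self._R
        AB = B - A  # (n,3)
        denom = np.einsum("ij,ij->i", AB, AB)
        ap = p[:, None, :] - A[None, :, :]  # (m,n,3)
        t = np.clip(np.einsum("mnj,nj->mn", ap, AB) / denom[None, :], 0.0, 1.0)
        closest = A[None, :, :] + t[:, :, None] * AB[None, :, :]
        d = np.linalg.norm(p[:, None, :] - closest, axis=2) - R[None, :]
        return d.min(axis=1)

    def contains(self, point) -> bool:
        return bool(self.signed_distance(np.asarray(point, dtype=float))[0] < 0.0)

    def mesh(self) -> trimesh.Trimesh:
        """Triangle mesh: one watertight capsule per branch, concatenated."""
        parts = []
        for b in self.branches:
            cap = trimesh.creation.capsule(height=b.length, radius=b.radius, count=[24, 24])
            # capsule axis is +z from z=0..height; move to branch
            z = np.array([0.0, 0.0, 1.0])
            d = b.direction
            v = np.cross(z, d)
            c = float(np.dot(z, d))
            if np.linalg.norm(v) < 1e-12:
                Rm = np.eye(3) if c > 0 else trimesh.transformations.rotation_matrix(np.pi, [1, 0, 0])[:3, :3]
            else:
                vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
                Rm = np.eye(3) + vx + vx @ vx / (1.0 + c)
            T = np.eye(4)
            T[:3, :3] = Rm
            T[:3, 3] = b.start
            cap.apply_transform(T)
            parts.append(cap)
        return trimesh.util.concatenate(parts)


# ---------------------------------------------------------------------------
# procedural generation
# ---------------------------------------------------------------------------

def _perpendicular(d: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    p = np.cross(d, ref)
    return p / np.linalg.norm(p)


def generate_tree(
    n_generations: int,
    seed: int = 0,
    params: BranchingParams = None,
) -> AirwayModel:
    """Binary airway tree with per-generation geometric radius/length decay.

    Deterministic for a fixed seed.  Raises if the drawn geometry would make
    non-adjacent branches overlap (self-intersecting lumen).
    """
    if n_generations < 1:
        raise ValueError("need at least one generation")
    params = params or BranchingParams()
    rng = np.random.default_rng(seed)

    branches = []
    root = Branch(
        0,
        np.zeros(3),
        np.array([0.0, 0.0, params.root_length]),
        params.root_radius,
        0,
    )
    branches.append(root)
    frontier = [root]
    next_id = 1
    for gen in range(1, n_generations):
        new_frontier = []
        for parent in frontier:
            d = parent.direction
            perp = _perpendicular(d)
            azimuth = rng.uniform(0.0, 2 * np.pi)
            u = np.cos(azimuth) * perp + np.sin(azimuth) * np.cross(d, perp)
            length = params.root_length * params.length_decay**gen
            radius = params.root_radius * params.radius_decay**gen
            for label in (0, 1):
                ang = np.radians(
                    rng.normal(params.branch_angle_mean, params.branch_angle_std)
                )
                side = 1.0 if label == 0 else -1.0
                nd = np.cos(ang) * d + side * np.sin(ang) * u
                nd /= np.linalg.norm(nd)
                child = Branch(
                    next_id,
                    parent.end,
                    parent.end + length * nd,
                    radius,
                    gen,
                    parent=parent.id,
                    label=label,
                )
                branches.append(child)
                new_frontier.append(child)
                next_id += 1
        frontier = new_frontier

    _check_no_self_intersection(branches)
    return AirwayModel(branches)


def _segment_distance(a0, a1, b0, b1) -> float:
    """Minimum distance between two 3-D segments."""
    u = a1 - a0
    v = b1 - b0
    w = a0 - b0
    a, b, c = u @ u, u @ v, v @ v
    d, e = u @ w, v @ w
    denom = a * c - b * b
    if denom > 1e-12:
        s = np.clip((b * e - c * d) / denom, 0.0, 1.0)
    else:
        s = 0.0
    t = (b * s + e) / c if c > 1e-12 else 0.0
    t = np.clip(t, 0.0, 1.0)
    s = np.clip((b * t - d) / a, 0.0, 1.0) if a > 1e-12 else 0.0
    return float(np.linalg.norm(a0 + s * u - (b0 + t * v)))


def _check_no_self_intersection(branches) -> None:
    for i, bi in enumerate(branches):
        for bj in branches[i + 1 :]:
            if bj.parent == bi.id or bi.parent == bj.id or bi.parent == bj.parent:
                continue  # adjacent or sibling branches legitimately touch
            dist = _segment_distance(bi.start, bi.end, bj.start, bj.end)
            if dist < bi.radius + bj.radius:
                raise ValueError(
                    f"branching parameters produce a self-intersecting tree "
                    f"(branches {bi.id} and {bj.id} overlap)"
                )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

@dataclass
class RenderConfig:
    """Virtual-bronchoscope camera and headlight settings."""

    width: int = 128
    height: int = 128
    focal_px: float = None  # default 0.6 * width
    light_intensity: float = 1.0
    light_falloff_mm: float = 12.0
    ambient: float = 0.06
    near_mm: float = 0.05
    far_mm: float = 400.0
    albedo: tuple = (0.86, 0.55, 0.50)  # pinkish mucosa tint
    texture_amplitude: float = 0.22
    texture_scale_mm: float = 1.6

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("image dimensions must be positive")
        if self.focal_px is None:
            self.focal_px = 0.6 * self.width
        if not self.far_mm > self.near_mm:
            raise ValueError("far clip must exceed near clip")


def _ray_dirs(cfg: RenderConfig, pose: CameraPose) -> np.ndarray:
    """World-frame unit ray directions, shape (H*W, 3), row-major pixels."""
    xs = np.arange(cfg.width) + 0.5 - cfg.width / 2.0
    ys = np.arange(cfg.height) + 0.5 - cfg.height / 2.0
    X, Y = np.meshgrid(xs, ys)
    d_cam = np.stack(
        [X.ravel() / cfg.focal_px, Y.ravel() / cfg.focal_px, np.ones(X.size)], axis=1
    )
    d_cam /= np.linalg.norm(d_cam, axis=1, keepdims=True)
    return d_cam @ pose.rotation.as_matrix().T


def _capsule_intervals(origin, dirs, A, B, R):
    """Per-ray, per-capsule [t_in, t_out] of the ray inside each capsule.

    Rays that miss a capsule get an empty interval (t_in > t_out).  A capsule
    is convex, so its ray intersection is a single interval: the union of the
    finite-cylinder interval and the two cap-sphere intervals.
    """
    n_rays = dirs.shape[0]
    n_caps = A.shape[0]
    INF = np.inf
    t0 = np.full((n_rays, n_caps), INF)
    t1 = np.full((n_rays, n_caps), -INF)

    o = origin[None, :]
    for k in range(n_caps):
        a, b, r = A[k], B[k], R[k]
        axis = b - a
        L = np.linalg.norm(axis)
        w = axis / L
        # cylinder body: |(p - a) - ((p - a).w)w| = r, with axial coord in [0, L]
        oa = o - a[None, :]
        d_par = dirs @ w
        o_par = float((oa @ w)[0])
        d_perp = dirs - d_par[:, None] * w[None, :]
        o_perp = oa - o_par * w[None, :]
        qa = np.einsum("ij,ij->i", d_perp, d_perp)
        qb = 2.0 * np.einsum("ij,ij->i", d_perp, o_perp)
        qc = float(np.einsum("ij,ij->i", o_perp, o_perp)[0]) - r * r
        disc = qb * qb - 4.0 * qa * qc
        ok = (disc >= 0) & (qa > 1e-14)
        sq = np.sqrt(np.where(ok, disc, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            tc0 = (-qb - sq) / (2.0 * qa)
            tc1 = (-qb + sq) / (2.0 * qa)
        # clip the cylinder interval to the slab 0 <= axial <= L
        with np.errstate(divide="ignore", invalid="ignore"):
            s_lo = (0.0 - o_par) / d_par
            s_hi = (L - o_par) / d_par
        slab_lo = np.minimum(s_lo, s_hi)
        slab_hi = np.maximum(s_lo, s_hi)
        parallel = np.abs(d_par) < 1e-14
        inside_slab = (o_par >= 0.0) & (o_par <= L)
        slab_lo = np.where(parallel, np.where(inside_slab, -INF, INF), slab_lo)
        slab_hi = np.where(parallel, np.where(inside_slab, INF, -INF), slab_hi)
        cyl_lo = np.where(ok, np.maximum(tc0, slab_lo), INF)
        cyl_hi = np.where(ok, np.minimum(tc1, slab_hi), -INF)

        lo = np.where(cyl_lo <= cyl_hi, cyl_lo, INF)
        hi = np.where(cyl_lo <= cyl_hi, cyl_hi, -INF)
        # cap spheres at both ends
        for center in (a, b):
            oc = origin - center
            sb = 2.0 * dirs @ oc
            sc = float(oc @ oc) - r * r
            sdisc = sb * sb - 4.0 * sc
            sok = sdisc >= 0
            ssq = np.sqrt(np.where(sok, sdisc, 0.0))
            ts0 = np.where(sok, (-sb - ssq) / 2.0, INF)
            ts1 = np.where(sok, (-sb + ssq) / 2.0, -INF)
            lo = np.minimum(lo, ts0)
            hi = np.maximum(hi, ts1)
        t0[:, k] = lo
        t1[:, k] = hi
    return t0, t1


def _union_exit(t0, t1, eps: float = 1e-6):
    """First t >= 0 at which each ray leaves the union of capsule intervals."""
    n_rays = t0.shape[0]
    t_end = np.zeros(n_rays)
    # a ray starting outside every capsule never advances; flag those
    inside0 = np.any((t0 <= eps) & (t1 > 0.0), axis=1)
    for _ in range(t0.shape[1] + 1):
        extend = (t0 <= t_end[:, None] + eps) & (t1 > t_end[:, None])
        if not extend.any():
            break
        cand = np.where(extend, t1, -np.inf).max(axis=1)
        t_end = np.maximum(t_end, np.where(np.isfinite(cand), cand, t_end))
    return t_end, inside0


def render_depth(model: AirwayModel, pose: CameraPose, cfg: RenderConfig):
    """Per-pixel distance (mm) from the camera to the lumen wall.

    Returns (depth array (H, W), world-frame hit points (H*W, 3), ray dirs).
    """
    if not model.contains(pose.position):
        raise OutsideAirwayError(
            f"camera position {pose.position} is outside the airway lumen"
        )
    dirs = _ray_dirs(cfg, pose)
    t0, t1 = _capsule_intervals(pose.position, dirs, model._A, model._B, model._R)
    t_exit, inside0 = _union_exit(t0, t1)
    t_exit = np.clip(t_exit, cfg.near_mm, cfg.far_mm)
    hits = pose.position[None, :] + t_exit[:, None] * dirs
    depth = t_exit.reshape(cfg.height, cfg.width)
    return depth, hits, dirs


def _wall_normals(model: AirwayModel, hits: np.ndarray) -> np.ndarray:
    """Inward (lumen-facing) unit normals at wall points."""
    A, B, R = model._A, model._B, model._R
    AB = B - A
    denom = np.einsum("ij,ij->i", AB, AB)
    ap = hits[:, None, :] - A[None, :, :]
    t = np.clip(np.einsum("mnj,nj->mn", ap, AB) / denom[None, :], 0.0, 1.0)
    closest = A[None, :, :] + t[:, :, None] * AB[None, :, :]
    vec = hits[:, None, :] - closest  # outward from axis
    dist = np.linalg.norm(vec, axis=2)
    k = np.argmin(np.abs(dist - R[None, :]), axis=1)
    idx = np.arange(hits.shape[0])
    v = vec[idx, k]
    n = np.linalg.norm(v, axis=1, keepdims=True)
    n = np.where(n < 1e-12, 1.0, n)
    return -v / n  # inward


def _texture(hits: np.ndarray, cfg: RenderConfig) -> np.ndarray:
    """Deterministic mucosa-like multiplicative texture in [1-a, 1+a]."""
    w = 2.0 * np.pi / cfg.texture_scale_mm
    x, y, z = hits[:, 0], hits[:, 1], hits[:, 2]
    t = (
        0.6 * np.sin(w * x + 1.3) * np.sin(w * 1.31 * y + 0.7) * np.sin(w * 0.83 * z)
        + 0.4
        * np.sin(0.53 * w * x + 2.1)
        * np.sin(0.61 * w * y)
        * np.sin(0.47 * w * z + 1.1)
    )
    return 1.0 + cfg.texture_amplitude * t


def render(model: AirwayModel, pose: CameraPose, cfg: RenderConfig = None) -> Frame:
    """Interior perspective view: dark distal tunnel, bright textured near walls."""
    cfg = cfg or RenderConfig()
    depth, hits, dirs = render_depth(model, pose, cfg)
    t = depth.ravel()
    normals = _wall_normals(model, hits)
    lambert = np.clip(-np.einsum("ij,ij->i", normals, dirs), 0.0, 1.0)
    atten = cfg.light_intensity / (1.0 + (t / cfg.light_falloff_mm) ** 2)
    shade = np.clip(cfg.ambient + lambert * atten * _texture(hits, cfg), 0.0, 1.0)
    rgb = shade[:, None] * np.asarray(cfg.albedo)[None, :]
    img = (np.clip(rgb, 0.0, 1.0) * 255.0).round().astype(np.uint8)
    return Frame(index=0, pixels=img.reshape(cfg.height, cfg.width, 3))


def point_depths(
    model: AirwayModel, pose: CameraPose, cfg: RenderConfig, points_px: np.ndarray
) -> np.ndarray:
    """Camera-frame z of the wall seen at given (x, y) pixel positions.

    Casts exactly one ray per requested pixel; used to give the tracker a
    depth hint at its matched feature locations.
    """
    if not model.contains(pose.position):
        raise OutsideAirwayError("camera position is outside the airway lumen")
    pts = np.atleast_2d(np.asarray(points_px, dtype=float))
    d_cam = np.stack(
        [
            (pts[:, 0] - cfg.width / 2.0) / cfg.focal_px,
            (pts[:, 1] - cfg.height / 2.0) / cfg.focal_px,
            np.ones(pts.shape[0]),
        ],
        axis=1,
    )
    norms = np.linalg.norm(d_cam, axis=1, keepdims=True)
    dirs = (d_cam / norms) @ pose.rotation.as_matrix().T
    t0, t1 = _capsule_intervals(pose.position, dirs, model._A, model._B, model._R)
    t_exit, _ = _union_exit(t0, t1)
    t_exit = np.clip(t_exit, cfg.near_mm, cfg.far_mm)
    # ray length -> camera-frame z
    return t_exit / norms.ravel()


def median_depth(model: AirwayModel, pose: CameraPose, cfg: RenderConfig = None) -> float:
    """Median wall distance over a coarse ray bundle; depth hint for tracking."""
    cfg = cfg or RenderConfig()
    coarse = RenderConfig(
        width=max(cfg.width // 8, 8),
        height=max(cfg.height // 8, 8),
        focal_px=cfg.focal_px * max(cfg.width // 8, 8) / cfg.width,
        near_mm=cfg.near_mm,
        far_mm=cfg.far_mm,
    )
    depth, _, _ = render_depth(model, pose, coarse)
    return float(np.median(depth))


# ---------------------------------------------------------------------------
# mesh + centerline persistence
# ---------------------------------------------------------------------------

def _sidecar_path(mesh_path) -> str:
    import os

    base, _ = os.path.splitext(str(mesh_path))
    return base + ".centerline.json"


def save_mesh(model: AirwayModel, path) -> None:
    """OBJ/STL mesh plus a JSON centerline sidecar (nodes, edges, radii)."""
    mesh = model.mesh()
    mesh.export(str(path))
    g = model.graph
    sidecar = {
        "nodes": [
            {"id": n, "xyz": list(map(float, g.nodes[n]["position"]))} for n in g.nodes
        ],
        "edges": [
            {
                "id": int(g.edges[e]["branch_id"]),
                "from": e[0],
                "to": e[1],
                "polyline": [list(map(float, p)) for p in g.edges[e]["polyline"]],
                "radii": [float(g.edges[e]["radius"])] * 2,
                "label": int(g.edges[e]["label"]),
            }
            for e in g.edges
        ],
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def load_mesh(path) -> AirwayModel:
    """Rebuild an AirwayModel from a mesh file and its centerline sidecar."""
    import os

    sidecar = _sidecar_path(path)
    if not os.path.exists(sidecar):
        raise FileNotFoundError(
            f"mesh {path} has no centerline sidecar {sidecar}; interior rendering "
            "and path planning need the junction graph (save with save_mesh)"
        )
    trimesh.load(str(path))  # validates the mesh file itself
    with open(sidecar) as fh:
        data = json.load(fh)
    nodes = {n["id"]: np.asarray(n["xyz"], dtype=float) for n in data["nodes"]}
    branches = []
    for e in sorted(data["edges"], key=lambda e: e["id"]):
        frm, to = e["from"], e["to"]
        parent = None if frm == "J0" else int(frm[1:]) - 1
        poly = np.asarray(e["polyline"], dtype=float)
        branches.append(
            Branch(
                int(e["id"]),
                poly[0],
                poly[-1],
                float(np.mean(e["radii"])),
                generation=0,
                parent=parent,
                label=int(e["label"]),
            )
        )
    # recover generations from parent depth
    by_id = {b.id: b for b in branches}
    for b in branches:
        gen, p = 0, b.parent
        while p is not None:
            gen += 1
            p = by_id[p].parent
        b.generation = gen
    return AirwayModel(branches)
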