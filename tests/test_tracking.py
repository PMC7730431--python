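"""Inter-frame motion estimation: features, block flow, lifting, arbitration."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from broncholoc.defaults import default_arbitration_model
from broncholoc.geometry import CameraPose, Frame, PoseDelta, integrate, scale_delta
from broncholoc.tracking import (
    FlowField,
    InsufficientFeaturesError,
    MatchSet,
    arbitrate,
    block_flow,
    delta_from_matches,
    detect_and_match,
)


def textured_frame(rng, size=96):
    base = rng.uniform(0.2, 0.8, (size, size))
    from scipy.ndimage import gaussian_filter

    smooth = gaussian_filter(base, 2.0)
    px = (np.clip(smooth, 0, 1) * 255).astype(np.uint8)
    return Frame(0, np.stack([px] * 3, axis=-1))


def ncc_oracle(G, H):
    """Direct evaluation of the normalized block cross-correlation."""
    g = G.astype(float)
    h = H.astype(float)
    gm, hm = g.mean(), h.mean()
    sg = np.sqrt(((g - gm) ** 2).mean())
    sh = np.sqrt(((h - hm) ** 2).mean())
    if sg == 0 or sh == 0:
        return np.nan
    total = 0.0
    for i in range(g.shape[0]):
        for j in range(g.shape[1]):
            total += (g[i, j] - gm) * (h[i, j] - hm)
    return total / (g.size * sg * sh)


class TestBlockFlow:
    def test_identical_frames_zero_vectors_unit_correlation(self, rng):
        f = textured_frame(rng)
        flow = block_flow(f, f, block_size=16, search_radius=4)
        assert flow.valid.all()
        assert np.allclose(flow.vectors, 0.0)
        assert np.allclose(flow.cc, 1.0, atol=1e-9)

    def test_inverted_block_anticorrelates_at_zero_lag(self, rng):
        g = rng.uniform(0, 1, (16, 16))
        assert ncc_oracle(g, 1.0 - g) == pytest.approx(-1.0, abs=1e-12)

    def test_shifted_frame_recovers_shift_and_matches_oracle(self, rng):
        wide = textured_frame(rng, 192).pixels
        H, W = 96, 176
        f = Frame(0, wide[:H, 3 : 3 + W])
        shifted = Frame(1, wide[:H, 0:W])  # same content moved 3 px right
        flow = block_flow(f, shifted, block_size=16, search_radius=4)
        vecs = flow.vectors[flow.valid]
        frac = np.mean(np.all(vecs == (3, 0), axis=1))
        assert frac >= 0.9  # only the clipped border column can disagree
        # exhaustive double-loop oracle over all offsets for each block
        ga, gb = f.gray(), shifted.gray()
        R = 4
        padded = np.full((H + 2 * R, W + 2 * R), np.nan)
        padded[R:-R, R:-R] = gb
        k = 0
        for r in range(H // 16):
            for c in range(W // 16):
                blk = ga[r * 16 : (r + 1) * 16, c * 16 : (c + 1) * 16]
                best, arg = -np.inf, None
                for dy in range(-R, R + 1):
                    for dx in range(-R, R + 1):
                        win = padded[
                            R + r * 16 + dy : R + (r + 1) * 16 + dy,
                            R + c * 16 + dx : R + (c + 1) * 16 + dx,
                        ]
                        if np.isnan(win).any():
                            continue
                        cc = ncc_oracle(blk, win)
                        if np.isfinite(cc) and cc > best:
                            best, arg = cc, (dx, dy)
                if flow.valid[k]:
                    assert flow.cc[k] == pytest.approx(best, abs=1e-9)
                    assert -1.0 - 1e-9 <= flow.cc[k] <= 1.0 + 1e-9
                    assert tuple(flow.vectors[k]) == arg
                k += 1

    def test_zero_variance_blocks_flagged_invalid(self):
        flat = Frame(0, np.full((64, 64, 3), 80, dtype=np.uint8))
        flow = block_flow(flat, flat, block_size=16, search_radius=2)
        assert not flow.valid.any()
        assert np.allclose(flow.vectors, 0.0)

    def test_bad_search_radius_rejected(self, rng):
        f = textured_frame(rng)
        with pytest.raises(ValueError):
            block_flow(f, f, search_radius=0)


class TestDetectAndMatch:
    def test_self_match_has_zero_displacement(self, straight_tube):
        f = straight_tube.frames[0]
        m = detect_and_match(f, f, "sift")
        assert len(m) >= 10
        assert np.allclose(m.displacements, 0.0, atol=0.5)

    def test_five_pixel_translate_recovered(self, straight_tube):
        f = straight_tube.frames[0]
        shifted = Frame(1, np.roll(f.pixels, 5, axis=1))
        m = detect_and_match(f, shifted, "sift")
        med = np.median(m.displacements, axis=0)
        assert med[0] == pytest.approx(5.0, abs=0.5)
        assert med[1] == pytest.approx(0.0, abs=0.5)

    def test_textureless_frame_raises_insufficient_features(self):
        flat = Frame(0, np.full((96, 96, 3), 100, dtype=np.uint8))
        with pytest.raises(InsufficientFeaturesError):
            detect_and_match(flat, flat, "sift")

    def test_unknown_method_rejected(self, straight_tube):
        with pytest.raises(ValueError, match="unknown feature method"):
            detect_and_match(straight_tube.frames[0], straight_tube.frames[0], "kaze9000")


class TestDeltaFromMatches:
    def test_zero_displacement_gives_identity_delta(self, rng):
        P = rng.uniform(0, 200, (30, 2))
        m = MatchSet(P, P.copy(), np.zeros(30))
        d = delta_from_matches(m, depth_hint=10.0, focal_px=120.0, principal_point=(100, 100))
        assert np.allclose(d.translation, 0.0, atol=1e-9)
        assert d.rotation.magnitude() == pytest.approx(0.0, abs=1e-9)
        assert d.confidence == 1.0

    def test_pure_roll_fixture_recovered(self, straight_tube):
        from broncholoc.airway import render

        tube, cfg = straight_tube.airway, straight_tube.render_cfg
        p = straight_tube.poses[3]
        f0 = render(tube, p, cfg)
        q = (p.rotation * Rotation.from_euler("z", 2.0, degrees=True)).as_quat()
        f1 = render(tube, CameraPose(p.position, q), cfg)
        m = detect_and_match(f0, f1, "sift")
        d = delta_from_matches(m, depth_hint=8.0, focal_px=cfg.focal_px, principal_point=(100, 100))
        angle = np.degrees(d.rotation.as_rotvec())
        assert angle[2] == pytest.approx(2.0, abs=0.3)
        assert np.linalg.norm(d.translation) < 0.15

    def test_axial_advance_within_30_percent(self, straight_tube):
        from broncholoc.airway import point_depths, render

        tube, cfg = straight_tube.airway, straight_tube.render_cfg
        p = straight_tube.poses[3]
        f0 = render(tube, p, cfg)
        f1 = render(tube, CameraPose(p.position + [0, 0, 1.0], p.quaternion), cfg)
        m = detect_and_match(f0, f1, "sift")
        z = point_depths(tube, p, cfg, m.points_a)
        d = delta_from_matches(
            m,
            depth_hint=float(np.median(z)),
            focal_px=cfg.focal_px,
            principal_point=(100, 100),
            point_depth=z,
        )
        assert d.translation[2] == pytest.approx(1.0, rel=0.3)

    def test_collinear_geometry_rejected(self):
        P = np.stack([np.linspace(0, 100, 10), np.full(10, 50.0)], axis=1)
        m = MatchSet(P, P + (1, 0), np.zeros(10))
        with pytest.raises(np.linalg.LinAlgError):
            delta_from_matches(m, depth_hint=10.0, focal_px=120.0)

    def test_too_few_correspondences_rejected(self):
        m = MatchSet(np.zeros((3, 2)), np.zeros((3, 2)), np.zeros(3))
        with pytest.raises(InsufficientFeaturesError):
            delta_from_matches(m)


class TestArbitrate:
    def test_equal_candidates_yield_same_pose_either_way(self):
        d = PoseDelta([0.1, 0.0, 0.3], source="features")
        d2 = PoseDelta([0.1, 0.0, 0.3], source="flow")
        pose = CameraPose([0, 0, 5.0])
        chosen = arbitrate(d, d2, [], default_arbitration_model())
        assert np.allclose(
            integrate(pose, chosen).position, integrate(pose, d).position
        )

    def test_empty_history_prefers_features(self):
        d_feat = PoseDelta([0, 0, 5.0], source="features", confidence=0.9)
        d_flow = PoseDelta([0, 0, 0.2], source="flow", confidence=0.8)
        chosen = arbitrate(d_feat, d_flow, [], default_arbitration_model())
        assert chosen.source == "features"

    def test_sudden_candidate_switches_to_flow(self):
        history = [PoseDelta([0, 0, 0.25], source="features") for _ in range(5)]
        d_feat = PoseDelta([0, 0, 3.0], source="features", confidence=0.9)
        d_flow = PoseDelta([0, 0, 0.8], source="flow", confidence=0.8)
        chosen = arbitrate(d_feat, d_flow, history, default_arbitration_model())
        assert chosen.source == "flow"

    def test_low_confidence_features_distrusted(self):
        history = [PoseDelta([0, 0, 0.25], source="features") for _ in range(5)]
        d_feat = PoseDelta([0, 0, 0.25], source="features", confidence=0.1)
        d_flow = PoseDelta([0, 0, 0.26], source="flow", confidence=0.9)
        chosen = arbitrate(d_feat, d_flow, history, default_arbitration_model())
        assert chosen.source == "flow"


class TestIntegrate:
    def test_identity_delta_preserves_pose(self):
        pose = CameraPose([1, 2, 3], Rotation.from_euler("y", 0.4).as_quat())
        out = integrate(pose, PoseDelta.identity())
        assert np.allclose(out.position, pose.position)
        assert np.allclose(out.quaternion, pose.quaternion)

    def test_opposite_translations_return_home(self):
        pose = CameraPose([1, 2, 3], Rotation.from_euler("xz", [0.3, 0.5]).as_quat())
        d = PoseDelta([0.5, -0.2, 1.0])
        back = integrate(integrate(pose, d), PoseDelta(-d.translation))
        assert np.allclose(back.position, pose.position, atol=1e-9)

    def test_random_chain_matches_matrix_oracle(self, rng):
        pose = CameraPose([0, 0, 0])
        T = np.eye(4)
        for _ in range(100):
            t = rng.normal(0, 1, 3)
            q = Rotation.from_rotvec(rng.normal(0, 0.2, 3)).as_quat()
            d = PoseDelta(t, q)
            pose = integrate(pose, d)
            D = np.eye(4)
            D[:3, :3] = Rotation.from_quat(q).as_matrix()
            D[:3, 3] = t
            T = T @ D
        assert np.allclose(pose.position, T[:3, 3], atol=1e-6)
        assert np.allclose(pose.rotation.as_matrix(), T[:3, :3], atol=1e-6)

    def test_scale_delta_halving_halves_rotation_angle(self):
        d = PoseDelta([2, 0, 0], Rotation.from_euler("z", 10, degrees=True).as_quat())
        half = scale_delta(d, 0.5)
        assert np.allclose(half.translation, [1, 0, 0])
        assert np.degrees(half.rotation.magnitude()) == pytest.approx(5.0)
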