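"""NCC template matching, overlay compensation, and 3D tip tracking."""

import numpy as np
import pytest

from xrnav import (
    CArmGeometry,
    Rect,
    TemplatePatch,
    build_projection,
    compensate_overlay_2d,
    match_template,
    project,
    track_tip_3d,
    triangulate,
)
from xrnav.phantom import PhantomScene, SinusoidMotion, Sphere, make_motion_sequence
from xrnav.track import ncc_map


def brute_force_ncc(region, tpl):
    """Exhaustive double-loop zero-normalized cross-correlation oracle."""
    h, w = tpl.shape
    tz = tpl - tpl.mean()
    tn = np.sqrt((tz**2).sum())
    out = np.full((region.shape[0] - h + 1, region.shape[1] - w + 1), np.nan)
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            r = region[i : i + h, j : j + w]
            rz = r - r.mean()
            rn = np.sqrt((rz**2).sum())
            if rn > 0:
                out[i, j] = (tz * rz).sum() / (tn * rn)
    return out


class TestMatchTemplate:
    def test_template_cut_from_frame_found_exactly(self, rng):
        frame = rng.uniform(0, 255, (80, 90))
        u0, v0 = 41, 33
        tpl = TemplatePatch.cut(frame, (u0, v0), 7)
        state = match_template(frame, tpl, Rect(20, 15, 50, 45))
        assert state.position_px == (u0, v0)
        assert state.score == pytest.approx(1.0)

    def test_integer_shift_equivariance(self, rng):
        frame = rng.uniform(0, 255, (60, 60))
        tpl = TemplatePatch.cut(frame, (30, 28), 5)
        shifted = np.roll(frame, (4, -3), axis=(0, 1))  # (dv, du)
        state = match_template(shifted, tpl, Rect(5, 5, 50, 50))
        assert state.position_px == (30 - 3, 28 + 4)
        assert state.score == pytest.approx(1.0)

    def test_argmax_matches_exhaustive_oracle(self, rng):
        for _ in range(100):
            frame = rng.uniform(0, 255, (40, 40))
            th, tw = 2 * rng.integers(2, 5) + 1, 2 * rng.integers(2, 5) + 1
            tpl = TemplatePatch(rng.uniform(0, 255, (th, tw)))
            win = Rect(3, 4, 30, 28)
            region = frame[win.v0 : win.v1, win.u0 : win.u1]
            oracle = brute_force_ncc(region, tpl.pixels)
            got = ncc_map(region, tpl.pixels)
            assert np.allclose(got, oracle, atol=1e-10, equal_nan=True)
            iv, iu = np.unravel_index(np.nanargmax(oracle), oracle.shape)
            state = match_template(frame, tpl, win)
            assert state.position_px == (win.u0 + iu + tw // 2, win.v0 + iv + th // 2)
            assert state.score == pytest.approx(oracle[iv, iu])

    def test_matches_skimage_reference(self, rng):
        skimage_feature = pytest.importorskip("skimage.feature")
        frame = rng.uniform(0, 1, (50, 50))
        tpl = TemplatePatch.cut(frame, (25, 25), 6)
        ref = skimage_feature.match_template(frame, tpl.pixels)
        assert np.allclose(ncc_map(frame, tpl.pixels), ref, atol=1e-8)

    def test_invariant_to_affine_intensity_change(self, rng):
        frame = rng.uniform(0, 255, (60, 60))
        tpl = TemplatePatch.cut(frame, (30, 30), 6)
        win = Rect(10, 10, 40, 40)
        base = match_template(frame, tpl, win)
        changed = match_template(0.4 * frame + 35.0, tpl, win)
        assert changed.position_px == base.position_px
        assert changed.score == pytest.approx(base.score, abs=1e-12)

    def test_constant_template_flagged_invalid(self):
        frame = np.random.default_rng(0).uniform(0, 1, (30, 30))
        tpl = TemplatePatch(np.ones((5, 5)))
        state = match_template(frame, tpl, Rect(0, 0, 30, 30))
        assert not state.valid

    def test_constant_window_region_flagged_invalid(self, rng):
        frame = np.full((30, 30), 7.0)
        tpl = TemplatePatch(rng.uniform(0, 1, (5, 5)))
        state = match_template(frame, tpl, Rect(0, 0, 30, 30))
        assert not state.valid

    def test_ties_broken_lexicographically_smallest_v_u(self):
        frame = np.zeros((30, 40))
        patch = np.arange(25, dtype=float).reshape(5, 5)
        # identical copies: the (v, u)-smallest placement must win
        frame[20:25, 30:35] = patch
        frame[5:10, 10:15] = patch
        tpl = TemplatePatch(patch)
        state = match_template(frame, tpl, Rect(0, 0, 40, 30))
        assert state.position_px == (12, 7)

    def test_window_must_contain_template(self, rng):
        tpl = TemplatePatch(rng.uniform(0, 1, (9, 9)))
        with pytest.raises(ValueError, match="at least the template"):
            match_template(rng.uniform(0, 1, (30, 30)), tpl, Rect(0, 0, 7, 7))

    def test_subpixel_refinement_recovers_fractional_shift(self, rng):
        # smooth blob shifted by a fraction of a pixel
        v, u = np.mgrid[0:41, 0:41].astype(float)
        blob = lambda du: np.exp(-(((u - 20 - du) ** 2 + (v - 20) ** 2) / 18.0))
        tpl = TemplatePatch(blob(0.0)[13:28, 13:28])
        state = match_template(blob(0.3), tpl, Rect(5, 5, 31, 31), subpixel=True)
        assert state.position_px[0] == pytest.approx(20.3, abs=0.1)
        assert state.position_px[1] == pytest.approx(20.0, abs=0.1)


class TestCompensateOverlay2D:
    def test_no_motion_leaves_overlay(self):
        ref = cur = _state((10.0, 20.0))
        assert compensate_overlay_2d(ref, cur, (100.0, 200.0)) == (100.0, 200.0)

    def test_shift_transfers_to_overlay(self):
        ref = _state((10.0, 20.0))
        cur = _state((15.0, 17.0))
        assert compensate_overlay_2d(ref, cur, (100.0, 200.0)) == (105.0, 197.0)

    def test_sinusoidal_integer_motion_recovered_exactly(self, rng):
        frame0 = rng.uniform(0, 255, (64, 64))
        tpl = TemplatePatch.cut(frame0, (32, 32), 6)
        ref = match_template(frame0, tpl, Rect(16, 16, 32, 32))
        amplitude, period = 6, 16
        for i in range(period):
            du = int(round(amplitude * np.sin(2 * np.pi * i / period)))
            frame = np.roll(frame0, du, axis=1)
            cur = match_template(frame, tpl, Rect(8, 8, 48, 48))
            origin = compensate_overlay_2d(ref, cur, (0.0, 0.0))
            assert origin == (float(du), 0.0)


def _state(pos):
    from xrnav import TrackState

    return TrackState(position_px=pos, score=1.0, search_window=Rect(0, 0, 10, 10))


# ---------------------------------------------------------------------------
# biplane 3D tracking on simulator sequences
# ---------------------------------------------------------------------------

TRACK_GEOM_A = CArmGeometry(sid=1200.0, fd=380.0, spd=810.0, n_u=220, n_v=220)
TRACK_GEOM_B = CArmGeometry(
    primary_angle=90.0, sid=1300.0, fd=380.0, spd=765.0, n_u=220, n_v=220
)

#: tip and reference structures, separated so their projections stay disjoint
TRACK_SCENE = PhantomScene(
    spheres=(
        Sphere((12.0, 2.0, 14.0), 8.0, attenuation=0.25),   # tip
        Sphere((-18.0, -6.0, -18.0), 12.0, attenuation=0.2),  # reference
    )
)


def _setup_tracking(seq):
    tip_a0, tip_b0 = seq.truth_2d_a[0, 0], seq.truth_2d_b[0, 0]
    ref_a0, ref_b0 = seq.truth_2d_a[0, 1], seq.truth_2d_b[0, 1]
    cut = lambda frame, uv: TemplatePatch.cut(frame, uv, 9)
    return dict(
        tip_template_a=cut(seq.frames_a[0], tip_a0),
        tip_template_b=cut(seq.frames_b[0], tip_b0),
        ref_template_a=cut(seq.frames_a[0], ref_a0),
        ref_template_b=cut(seq.frames_b[0], ref_b0),
        tip_init_a=tuple(tip_a0),
        tip_init_b=tuple(tip_b0),
        ref_init_a=tuple(ref_a0),
        ref_init_b=tuple(ref_b0),
    )


def quantization_noise_mm(pm_a, pm_b, p):
    """3D triangulation error induced by half-pixel quantization in both views."""
    q_a = project(pm_a, p) + 0.5
    q_b = project(pm_b, p) + 0.5
    return np.linalg.norm(triangulate(pm_a, q_a, pm_b, q_b).p - p)


class TestTrackTip3D:
    def test_static_scene_recovers_ground_truth(self):
        seq = make_motion_sequence(TRACK_SCENE, TRACK_GEOM_A, TRACK_GEOM_B, {}, 5, seed=1)
        kwargs = _setup_tracking(seq)
        pm_a, pm_b = build_projection(TRACK_GEOM_A), build_projection(TRACK_GEOM_B)
        tracks = track_tip_3d(seq.frames_a, seq.frames_b, pm_a=pm_a, pm_b=pm_b, **kwargs)
        for t in tracks:
            assert np.linalg.norm(t.tip_mm - seq.truth_3d[0, 0]) < 0.5
            assert np.allclose(t.compensated_tip_mm, t.tip_mm)

    def test_comoving_tip_is_stationary_after_compensation(self):
        motion = SinusoidMotion((5.0, 0.0, 3.0), period_frames=20.0)
        seq = make_motion_sequence(
            TRACK_SCENE, TRACK_GEOM_A, TRACK_GEOM_B, {0: motion, 1: motion}, 40, seed=2
        )
        pm_a, pm_b = build_projection(TRACK_GEOM_A), build_projection(TRACK_GEOM_B)
        tracks = track_tip_3d(
            seq.frames_a, seq.frames_b, pm_a=pm_a, pm_b=pm_b,
            subpixel=True, **_setup_tracking(seq)
        )
        tip0 = seq.truth_3d[0, 0]
        tol = 1.5 * quantization_noise_mm(pm_a, pm_b, tip0)
        for t in tracks:
            assert np.linalg.norm(t.compensated_tip_mm - tip0) < tol
        # and the uncompensated tip did move by the injected amplitude
        excursion = max(np.linalg.norm(t.tip_mm - tip0) for t in tracks)
        assert excursion > 4.0

    def test_relative_motion_recovered_after_compensation(self):
        tip_motion = SinusoidMotion((4.0, 0.0, 0.0), period_frames=12.0)
        seq = make_motion_sequence(
            TRACK_SCENE, TRACK_GEOM_A, TRACK_GEOM_B, {0: tip_motion}, 24, seed=3
        )
        pm_a, pm_b = build_projection(TRACK_GEOM_A), build_projection(TRACK_GEOM_B)
        tracks = track_tip_3d(
            seq.frames_a, seq.frames_b, pm_a=pm_a, pm_b=pm_b,
            subpixel=True, **_setup_tracking(seq)
        )
        tol = 1.5 * quantization_noise_mm(pm_a, pm_b, seq.truth_3d[0, 0]) + 0.3
        for i, t in enumerate(tracks):
            # the reference is static, so compensated == raw tip == truth
            assert np.linalg.norm(t.compensated_tip_mm - seq.truth_3d[i, 0]) < tol
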