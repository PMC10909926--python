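"""Joint coordinate systems and angle computations."""

import numpy as np
import pytest

from conftest import rigid_transform
from fmaue.datamodel import GeometryError, JointSample, MotionClip
from fmaue.kinematics import (
    angle_traces,
    elbow_flexion,
    finger_bend_angle,
    shoulder_angles,
    shoulder_elevation_retraction,
    shoulder_frame,
    thorax_frame,
)
from fmaue.synthetic import ImpairmentProfile, gen_clip


def _sample(**joints):
    return JointSample(t=0.0, joints={k: np.asarray(v, float) for k, v in joints.items()})


TRUNK = dict(
    SPINE_CHEST=[0, 1.25, 0],
    NECK=[0, 1.45, 0],
    SHOULDER_L=[0, 1.4, -0.2],
    SHOULDER_R=[0, 1.4, 0.2],
)


class TestThoraxFrame:
    def test_axis_aligned_pose(self):
        tf = thorax_frame(_sample(**TRUNK))
        assert np.allclose(tf.y, [0, 1, 0], atol=1e-12)
        assert np.allclose(tf.x, [1, 0, 0], atol=1e-12)  # anterior
        assert np.allclose(tf.z, [0, 0, 1], atol=1e-12)  # right-lateral

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(0)
        q, t = rigid_transform(rng)
        base = _sample(**TRUNK)
        moved = _sample(**{k: q @ np.asarray(v, float) + t for k, v in TRUNK.items()})
        f0, f1 = thorax_frame(base), thorax_frame(moved)
        for a0, a1 in [(f0.x, f1.x), (f0.y, f1.y), (f0.z, f1.z)]:
            assert np.allclose(q @ a0, a1, atol=1e-9)

    def test_trunk_lean_tilts_y(self):
        # lean 30 degrees about the right-lateral (z) axis
        c, s = np.cos(np.radians(30)), np.sin(np.radians(30))
        rz = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
        leaned = _sample(**{k: rz @ np.asarray(v, float) for k, v in TRUNK.items()})
        tf = thorax_frame(leaned)
        angle = np.degrees(np.arccos(np.dot(tf.y, [0, 1, 0])))
        assert angle == pytest.approx(30.0, abs=1e-9)

    def test_degenerate_rejected(self):
        bad = dict(TRUNK, NECK=TRUNK["SPINE_CHEST"])
        with pytest.raises(GeometryError):
            thorax_frame(_sample(**bad))


class TestShoulderFrame:
    def test_arm_hanging_y_points_up(self):
        sf = shoulder_frame(
            _sample(SHOULDER_R=[0, 1.4, 0.2], ELBOW_R=[0, 1.12, 0.2], WRIST_R=[0.1, 0.9, 0.2])
        )
        assert np.allclose(sf.y, [0, 1, 0], atol=1e-9)

    def test_arm_abducted_y_horizontal(self):
        sf = shoulder_frame(
            _sample(SHOULDER_R=[0, 1.4, 0.2], ELBOW_R=[0, 1.4, 0.48], WRIST_R=[0.1, 1.3, 0.6])
        )
        assert np.allclose(sf.y, [0, 0, -1], atol=1e-9)

    def test_frame_is_right_handed_orthonormal(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            sh = rng.normal(size=3)
            el = sh + rng.normal(size=3)
            wr = el + rng.normal(size=3)
            sf = shoulder_frame(_sample(SHOULDER_R=sh, ELBOW_R=el, WRIST_R=wr))
            r = sf.rotation
            assert np.allclose(r.T @ r, np.eye(3), atol=1e-9)
            assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-9)

    def test_zero_length_humerus_rejected(self):
        with pytest.raises(GeometryError):
            shoulder_frame(_sample(SHOULDER_R=[0, 1.4, 0.2], ELBOW_R=[0, 1.4, 0.2]))


class TestShoulderAngles:
    def test_identical_frames_zero(self):
        tf = thorax_frame(_sample(**TRUNK))
        assert shoulder_angles(tf, tf) == pytest.approx((0.0, 0.0, 0.0), abs=1e-9)

    def test_pure_abduction_pose(self):
        tf = thorax_frame(_sample(**TRUNK))
        # humerus straight lateral: distal direction +z, elbow flexed forward
        sf = shoulder_frame(
            _sample(SHOULDER_R=[0, 1.4, 0.2], ELBOW_R=[0, 1.4, 0.48], WRIST_R=[0.25, 1.4, 0.48])
        )
        plane, elevation, _ = shoulder_angles(tf, sf)
        assert elevation == pytest.approx(90.0, abs=1e-6)
        assert plane == pytest.approx(0.0, abs=1e-6)

    def test_pure_flexion_pose(self):
        tf = thorax_frame(_sample(**TRUNK))
        sf = shoulder_frame(
            _sample(SHOULDER_R=[0, 1.4, 0.2], ELBOW_R=[0.28, 1.4, 0.2], WRIST_R=[0.28, 1.65, 0.2])
        )
        plane, elevation, _ = shoulder_angles(tf, sf)
        assert elevation == pytest.approx(90.0, abs=1e-6)
        assert plane == pytest.approx(90.0, abs=1e-6)

    def test_round_trip_reconstruction(self):
        # angles -> rotation -> angles is the identity away from gimbal lock
        rng = np.random.default_rng(5)
        tf = thorax_frame(_sample(**TRUNK))

        def ry(a):
            c, s = np.cos(a), np.sin(a)
            return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])

        def rx(a):
            c, s = np.cos(a), np.sin(a)
            return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])

        from fmaue.kinematics import FrameTriad

        for _ in range(20):
            plane = rng.uniform(-170, 170)
            elev = rng.uniform(5, 175)
            axial = rng.uniform(-170, 170)
            r = ry(np.radians(plane)) @ rx(-np.radians(elev)) @ ry(np.radians(axial))
            sf = FrameTriad(origin=np.zeros(3), x=r[:, 0], y=r[:, 1], z=r[:, 2])
            tf_id = FrameTriad(
                origin=np.zeros(3), x=np.eye(3)[0], y=np.eye(3)[1], z=np.eye(3)[2]
            )
            got = shoulder_angles(tf_id, sf)
            assert got[0] == pytest.approx(plane, abs=1e-6)
            assert got[1] == pytest.approx(elev, abs=1e-6)
            assert got[2] == pytest.approx(axial, abs=1e-6)


class TestElbowAndShoulderGirdle:
    def test_straight_arm_zero_flexion(self):
        s = _sample(SHOULDER_R=[0, 1.4, 0.2], ELBOW_R=[0, 1.1, 0.2], WRIST_R=[0, 0.8, 0.2])
        assert elbow_flexion(s) == pytest.approx(0.0, abs=1e-9)

    def test_right_angle_bend(self):
        s = _sample(SHOULDER_R=[0, 1.4, 0.2], ELBOW_R=[0, 1.1, 0.2], WRIST_R=[0.3, 1.1, 0.2])
        assert elbow_flexion(s) == pytest.approx(90.0, abs=1e-9)

    def test_matches_acos_oracle_on_random_triples(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            sh, el, wr = rng.normal(size=(3, 3))
            if min(np.linalg.norm(sh - el), np.linalg.norm(wr - el)) < 1e-3:
                continue
            ua = (sh - el) / np.linalg.norm(sh - el)
            fa = (wr - el) / np.linalg.norm(wr - el)
            expected = 180.0 - np.degrees(np.arccos(np.clip(np.dot(ua, fa), -1, 1)))
            got = elbow_flexion(_sample(SHOULDER_R=sh, ELBOW_R=el, WRIST_R=wr))
            assert got == pytest.approx(expected, abs=1e-9)

    GIRDLE = dict(
        TRUNK,
        SHOULDER_R=[0, 1.45, 0.2],  # SN vector purely horizontal-lateral
        HIP_L=[0, 0.92, -0.1],
        HIP_R=[0, 0.92, 0.1],
    )

    def test_shoulder_girdle_neutral(self):
        elev, retr = shoulder_elevation_retraction(_sample(**self.GIRDLE))
        assert (elev, retr) == pytest.approx((0.0, 0.0), abs=1e-9)

    @pytest.mark.parametrize("elev_deg,retr_deg", [(20.0, 0.0), (0.0, 15.0), (10.0, 5.0)])
    def test_constructed_girdle_angles_recovered(self, elev_deg, retr_deg):
        e, r = np.radians(elev_deg), np.radians(retr_deg)
        neck = np.array([0, 1.45, 0.0])
        d = np.array([-np.sin(r) * np.cos(e), np.sin(e), np.cos(r) * np.cos(e)])
        joints = dict(self.GIRDLE)
        joints["SHOULDER_R"] = neck + 0.206 * d
        elev, retr = shoulder_elevation_retraction(_sample(**joints))
        assert elev == pytest.approx(elev_deg, abs=1e-6)
        # retraction couples with elevation through the spherical parameterisation
        expected_retr = np.degrees(np.arcsin(np.sin(r) * np.cos(e)))
        assert retr == pytest.approx(expected_retr, abs=1e-6)


class TestFingerBend:
    def _straight(self):
        lm = np.zeros((21, 3))
        d = np.array([0.0, 0.0, 1.0])
        chains = {1: d, 5: d, 9: d, 13: d, 17: d}
        for base, direction in chains.items():
            for j in range(4):
                lm[base + j] = (0.3 + 0.1 * j) * direction
        return lm

    def test_straight_fingers_zero(self):
        lm = self._straight()
        for f in ("thumb", "index", "middle", "ring", "little"):
            assert finger_bend_angle(lm, f) == pytest.approx(0.0, abs=1e-9)

    def test_perpendicular_vectors_ninety(self):
        lm = self._straight()
        lm[8] = lm[7] + np.array([0.1, 0.0, 0.0])  # distal index segment bent 90
        assert finger_bend_angle(lm, "index") == pytest.approx(90.0, abs=1e-9)

    def test_planar_landmarks_match_two_dim_arccos_formula(self):
        # with z = 0 the 3-D implementation must equal the printed planar form
        rng = np.random.default_rng(11)
        for _ in range(20):
            lm = np.zeros((21, 3))
            lm[:, :2] = rng.normal(size=(21, 2))
            v1 = lm[4] - lm[3]
            v2 = lm[2] - lm[0]
            num = v1[0] * v2[0] + v1[1] * v2[1]
            den = np.hypot(v1[0], v1[1]) * np.hypot(v2[0], v2[1])
            expected = np.degrees(np.arccos(np.clip(num / den, -1, 1)))
            assert finger_bend_angle(lm, "thumb") == pytest.approx(expected, abs=1e-9)


class TestTraces:
    LABELS_BY_MOTION = {
        "M1": ["shoulder_elevation", "shoulder_retraction", "shoulder_abduction",
               "shoulder_external_rotation", "elbow_flexion", "forearm_supination"],
        "M9": ["shoulder_abduction"],
        "M12": ["wrist_dorsiflexion"],
        "M14": ["finger_bend_thumb", "finger_bend_four_mean"],
    }

    @pytest.mark.parametrize("motion_id", sorted(LABELS_BY_MOTION))
    def test_rigid_motion_invariance(self, motion_id):
        profile = ImpairmentProfile(noise_sd=0.0, seed=0)
        clip = gen_clip(motion_id, "healthy", profile)
        labels = self.LABELS_BY_MOTION[motion_id]
        base = angle_traces(clip, labels)
        rng = np.random.default_rng(13)
        q, t = rigid_transform(rng)
        joints = {k: v @ q.T + t for k, v in clip.joints.items()}
        hand = None
        if clip.hand is not None:
            from fmaue.datamodel import HandTrack

            hand = HandTrack(t=clip.hand.t, landmarks=clip.hand.landmarks @ q.T + t)
        moved = MotionClip(
            motion_id=clip.motion_id, side=clip.side, fs=clip.fs, t=clip.t,
            joints=joints, hand=hand,
        )
        for label, trace in angle_traces(moved, labels).items():
            assert np.allclose(trace.value, base[label].value, atol=1e-6), label

    def test_static_pose_gives_constant_traces(self):
        profile = ImpairmentProfile(rom_scale=0.0, velocity_scale=0.0, noise_sd=0.0, seed=0)
        clip = gen_clip("M1", "affected", profile)
        traces = angle_traces(clip, self.LABELS_BY_MOTION["M1"])
        for label, trace in traces.items():
            assert np.ptp(trace.value) == pytest.approx(0.0, abs=1e-9), label

    def test_generated_amplitudes_recovered(self):
        # the generator commands known excursions; the measured traces must
        # reproduce them exactly in the noise-free limit
        profile = ImpairmentProfile(noise_sd=0.0, seed=0)
        clip = gen_clip("M1", "healthy", profile)
        traces = angle_traces(clip, self.LABELS_BY_MOTION["M1"])
        expected = {
            "shoulder_elevation": 25.0,
            "shoulder_retraction": 20.0,
            "shoulder_abduction": 95.0,
            "shoulder_external_rotation": 35.0,
            "elbow_flexion": 60.0,
            "forearm_supination": 50.0,
        }
        for label, amp in expected.items():
            got = np.ptp(traces[label].value)
            assert got == pytest.approx(amp, abs=0.05), label

    def test_unknown_label_rejected(self):
        clip = gen_clip("M9", "healthy", ImpairmentProfile(seed=0))
        with pytest.raises(Exception):
            angle_traces(clip, ["no_such_angle"])
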