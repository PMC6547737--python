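"""Movement-state discretization, joint entropy, speeds, and coactivation."""

import numpy as np
import pytest

from polyhand import entropy as ent
from polyhand.errors import DegenerateDataError, ParameterError
from polyhand.preprocessing import edge_margin
from polyhand.synthetic import six_finger_spec, simulate_hand

from conftest import make_hand_recording


def states_from_array(arr, fingers):
    arr = np.asarray(arr, dtype=np.int8)
    return ent.MovementStateSequence(fingers=list(fingers), states=arr,
                                     mu_factor=0.3, mu=np.zeros(arr.shape[1]))


class TestDiscretize:
    def test_stationary_hand_is_all_rest(self):
        n = 200
        pos = {"T": {"distal": np.tile([9.0, 0.0, 1.0], (n, 1)),
                     "proximal": np.tile([5.0, 0.0, 0.0], (n, 1))}}
        rec = make_hand_recording(pos)
        with pytest.warns(UserWarning, match="stationary"):
            states = ent.discretize_states(rec)
        assert np.all(states.states == ent.REST)

    def test_monotone_ramp_single_nonrest_state(self):
        # polar angle sweeps monotonically: v has constant sign and |v| > mu
        n = 400
        theta = np.linspace(0.2, 1.2, n)
        distal = np.column_stack([4 * np.sin(theta), np.zeros(n), 4 * np.cos(theta)])
        pos = {"T": {"distal": distal + [5.0, 0.0, 0.0],
                     "proximal": np.tile([5.0, 0.0, 0.0], (n, 1))}}
        rec = make_hand_recording(pos)
        states = ent.discretize_states(rec, smoothed=False)
        col = states.column("T")
        assert len(set(col.tolist())) == 1
        assert col[0] != ent.REST

    def test_sign_flip_leaves_entropy_unchanged(self):
        rec, _ = simulate_hand(six_finger_spec(seed=11, duration_s=30))
        states = ent.discretize_states(rec)
        h = ent.joint_entropy(states, rec.fingers).bits
        # relabeling flexion <-> extension (the arbitrary PCA sign) per finger
        flipped = states.states.copy()
        swap = {ent.FLEXION: ent.EXTENSION, ent.EXTENSION: ent.FLEXION}
        for a, b in swap.items():
            flipped[states.states == a] = b
        h_flipped = ent.joint_entropy(states_from_array(flipped, rec.fingers),
                                      rec.fingers).bits
        assert h_flipped == pytest.approx(h, abs=1e-12)

    def test_matches_brute_force_reimplementation(self):
        rec, _ = simulate_hand(six_finger_spec(seed=12, duration_s=20))
        states = ent.discretize_states(rec, mu_factor=0.3, smoothed=False)
        # independent recomputation of steps 1-4 for one finger
        from numpy.linalg import eigh

        d = rec.positions["M"]["distal"] - rec.positions["M"]["proximal"]
        r = np.linalg.norm(d, axis=1)
        polar = np.arccos(d[:, 2] / r)
        azim = np.arctan2(d[:, 1], d[:, 0])
        ang = np.column_stack([polar, azim])
        ang = ang - ang.mean(axis=0)
        evals, evecs = eigh(np.cov(ang, rowvar=False))
        pc = ang @ evecs[:, np.argmax(evals)]
        v = np.diff(pc)
        mu = 0.3 * np.std(v)
        expect = np.where(v < -mu, ent.FLEXION, np.where(v > mu, ent.EXTENSION, ent.REST))
        got = states.column("M")
        # PCA sign is arbitrary: accept the label-swapped version too
        swapped = np.where(expect == ent.FLEXION, ent.EXTENSION,
                           np.where(expect == ent.EXTENSION, ent.FLEXION, ent.REST))
        assert np.array_equal(got, expect) or np.array_equal(got, swapped)

    def test_two_state_variant_has_no_rest(self):
        rec, _ = simulate_hand(six_finger_spec(seed=13, duration_s=10))
        states = ent.discretize_states(rec, n_states=2)
        assert ent.REST not in states.states

    def test_parameter_errors(self, two_finger_recording):
        with pytest.raises(ParameterError):
            ent.discretize_states(two_finger_recording, mu_factor=-0.1)
        with pytest.raises(ParameterError):
            ent.discretize_states(two_finger_recording, n_states=4)


class TestJointEntropy:
    def test_always_rest_is_zero_bits(self):
        states = states_from_array(np.zeros((500, 1)), ["T"])
        assert ent.joint_entropy(states, ["T"]).bits == 0.0

    def test_uniform_two_fingers_log2_nine(self):
        tuples = np.array([[a, b] for a in range(3) for b in range(3)])
        arr = np.tile(tuples, (50, 1))
        states = states_from_array(arr, ["T", "I"])
        res = ent.joint_entropy(states, ["T", "I"])
        assert res.bits == pytest.approx(np.log2(9), abs=1e-12)
        assert res.n_state_combinations == 9

    def test_iid_uniform_six_fingers_near_max(self, rng):
        arr = rng.integers(0, 3, size=(100_000, 6))
        states = states_from_array(arr, ["T", "I", "M", "R", "L", "S"])
        h = ent.joint_entropy(states, states.fingers).bits
        assert abs(h - 6 * np.log2(3)) < 0.05
        assert h <= 6 * np.log2(3)

    def test_small_sample_warning(self, rng):
        arr = rng.integers(0, 3, size=(100, 5))
        states = states_from_array(arr, ["T", "I", "M", "R", "L"])
        with pytest.warns(UserWarning, match="biased"):
            ent.joint_entropy(states, states.fingers)

    def test_empty_subset_error(self, rng):
        states = states_from_array(rng.integers(0, 3, size=(50, 2)), ["T", "I"])
        with pytest.raises(ParameterError):
            ent.joint_entropy(states, [])


class TestEntropyCurve:
    def test_all_rest_curve_of_zeros(self):
        states = states_from_array(np.zeros((200, 6)),
                                   ["T", "I", "M", "R", "L", "S"])
        curve = ent.entropy_curve(states)
        assert [r.bits for r in curve] == [0.0] * 6

    def test_monotone_nondecreasing(self):
        rec, _ = simulate_hand(six_finger_spec(seed=14, duration_s=30))
        states = ent.discretize_states(rec)
        curve = ent.entropy_curve(states)
        bits = [r.bits for r in curve]
        assert all(b2 >= b1 - 1e-12 for b1, b2 in zip(bits, bits[1:]))
        assert curve[0].fingers == ["T"]
        assert curve[-1].fingers[-1] == "S"

    def test_independent_uniform_curve_analytic(self, rng):
        arr = rng.integers(0, 3, size=(60_000, 6))
        states = states_from_array(arr, ["T", "I", "M", "R", "L", "S"])
        curve = ent.entropy_curve(states)
        for i, res in enumerate(curve, start=1):
            assert res.bits == pytest.approx(i * np.log2(3), abs=0.05)


class TestSpeedAndCoactivation:
    def test_velocity_norm_example(self):
        # constant-velocity motion: speed = |(3, 4, 0)| = 5 cm/s
        n = 300
        t = np.arange(n) / 120.0
        distal = np.column_stack([3 * t, 4 * t, np.zeros(n)])
        pos = {"T": {"distal": distal, "proximal": distal - [4.0, 0.0, 1.0]}}
        rec = make_hand_recording(pos)
        fingers, speeds = ent.fingertip_speed(rec)
        margin = edge_margin()
        np.testing.assert_allclose(speeds[margin:-margin, 0], 5.0, rtol=1e-9)

    def test_circular_motion_constant_speed(self):
        n = 1200
        t = np.arange(n) / 120.0
        r, omega = 2.0, 2 * np.pi * 0.5
        distal = np.column_stack([r * np.cos(omega * t), r * np.sin(omega * t),
                                  np.zeros(n)])
        rec = make_hand_recording({"T": {"distal": distal,
                                         "proximal": np.zeros((n, 3))}})
        _, speeds = ent.fingertip_speed(rec)
        margin = edge_margin()
        np.testing.assert_allclose(speeds[margin:-margin, 0], r * omega, rtol=0.02)

    def test_moving_mask_percentile_conventions(self, rng):
        equal = np.full((10, 3), 2.5)
        assert not ent.moving_mask(equal, 50).any()  # ties count as rest
        distinct = rng.permutation(np.arange(60.0)).reshape(20, 3)
        mask = ent.moving_mask(distinct, 50)
        assert mask.sum() == 30  # exactly half strictly above the median
        thr = np.percentile(distinct, 30)
        np.testing.assert_array_equal(ent.moving_mask(distinct, 30), distinct > thr)

    def test_coactivation_trivial_cases(self):
        fingers = ["T", "I", "S"]
        all_moving = np.ones((50, 3), dtype=bool)
        co = ent.sf_coactivation(all_moving, fingers, 50)
        assert (co.p_thumb_and_index, co.p_thumb_only, co.p_index_only) == (1.0, 0.0, 0.0)
        t_only = np.column_stack([np.ones(50, bool), np.zeros(50, bool),
                                  np.ones(50, bool)])
        co = ent.sf_coactivation(t_only, fingers, 50)
        assert (co.p_thumb_and_index, co.p_thumb_only, co.p_index_only) == (0.0, 1.0, 0.0)

    def test_coactivation_matches_hand_enumeration(self):
        fingers = ["T", "I", "S"]
        mask = np.array([
            [1, 1, 1], [1, 0, 1], [0, 1, 1], [0, 0, 1], [1, 1, 1],
            [1, 1, 0], [0, 0, 0], [1, 0, 0], [0, 1, 1], [1, 1, 1],
        ], dtype=bool)
        co = ent.sf_coactivation(mask, fingers, 10)
        # S moving in rows 0,1,2,3,4,8,9 (7 samples): T&I in 0,4,9; T only 1; I only 2,8
        assert co.p_thumb_and_index == pytest.approx(3 / 7)
        assert co.p_thumb_only == pytest.approx(1 / 7)
        assert co.p_index_only == pytest.approx(2 / 7)
        assert co.p_thumb_and_index + co.p_thumb_only + co.p_index_only <= 1.0

    def test_s_never_moving_undefined(self):
        mask = np.zeros((10, 3), dtype=bool)
        mask[:, 0] = True
        with pytest.raises(DegenerateDataError):
            ent.sf_coactivation(mask, ["T", "I", "S"], 50)
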