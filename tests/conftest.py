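import numpy as np
import pytest

from polyhand.recordings import FIVE_FINGER_ORDER, ForceRecording, ForceTrial, HandRecording


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


def make_hand_recording(positions_per_finger, sampling_rate=120.0, subject="toy",
                        hand="right", task="object_manipulation"):
    """Build a HandRecording from {finger: {sensor: (T, 3) array}}."""
    fingers = list(positions_per_finger)
    return HandRecording(subject_id=subject, hand=hand, fingers=fingers,
                         sampling_rate=sampling_rate,
                         positions={f: {s: np.asarray(a, dtype=float)
                                        for s, a in sensors.items()}
                                    for f, sensors in positions_per_finger.items()},
                         task_label=task)


@pytest.fixture
def two_finger_recording(rng):
    """Small valid two-finger recording with smooth motion."""
    t = np.arange(300) / 120.0
    pos = {}
    for i, f in enumerate(("T", "I")):
        base = np.column_stack([np.sin(2 * np.pi * 0.8 * t + i),
                                np.cos(2 * np.pi * 0.5 * t), 0.3 * t])
        pos[f] = {"distal": base + [9.0, 2.0 * i, 1.0],
                  "proximal": 0.5 * base + [5.0, 2.0 * i, 0.0]}
    return make_hand_recording(pos)


def make_force_trial(instructed, level, force, rate=128.0):
    force = np.asarray(force, dtype=float)
    return ForceTrial(instructed_finger=instructed, level=level, force=force,
                      duration=force.shape[0] / rate)


def make_force_recording(fingers, trials, rate=128.0):
    return ForceRecording(subject_id="toy", fingers=list(fingers),
                          sampling_rate=rate, trials=trials)


@pytest.fixture
def five_fingers():
    return list(FIVE_FINGER_ORDER)
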