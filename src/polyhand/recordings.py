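"""Domain containers for hand-function recordings.

The analyses operate on four kinds of raw data:

* motion-capture hand recordings — two electromagnetic sensors per finger
  (distal and proximal phalanx), 3-D positions in cm expressed relative to a
  reference sensor on the back of the hand, sampled at 120 Hz;
* isometric force recordings — per-finger force traces at 128 Hz organised as
  instructed-finger trials at maximal force (MF) or 10/20/30 % of MF;
* 2-D finger-localization pointing data (reported vs. true grid positions);
* video-game session logs (level reached vs. cumulative practice time).

Finger labels run radial-to-ulnar: a five-fingered hand is ``[T, I, M, R, L]``
(thumb, index, middle, ring, little); a six-fingered hand inserts the
supernumerary finger ``S`` between thumb and index: ``[T, S, I, M, R, L]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

FIVE_FINGER_ORDER = ("T", "I", "M", "R", "L")
SIX_FINGER_ORDER = ("T", "S", "I", "M", "R", "L")
SENSORS = ("distal", "proximal")
LEVELS = ("MF", "10", "20", "30")

#: Fraction of maximal force targeted at each submaximal level.
LEVEL_FRACTION = {"10": 0.10, "20": 0.20, "30": 0.30}


def level_fraction(level: str) -> float:
    """Return the MF fraction for a level token; 1.0 for "MF"."""
    if level == "MF":
        return 1.0
    return LEVEL_FRACTION[level]


@dataclass
class HandRecording:
    """Per-finger two-sensor 3-D position time series at a fixed rate.

    ``positions[finger][sensor]`` is a (T, 3) array in cm, reference-relative.
    """

    subject_id: str
    hand: str  # "left" | "right"
    fingers: list[str]
    sampling_rate: float  # Hz
    positions: dict[str, dict[str, np.ndarray]]
    task_label: str = "object_manipulation"

    @property
    def n_samples(self) -> int:
        first = self.positions[self.fingers[0]][SENSORS[0]]
        return first.shape[0]

    @property
    def n_fingers(self) -> int:
        return len(self.fingers)

    def as_matrix(self, fingers: list[str] | None = None) -> np.ndarray:
        """Assemble a samples x (fingers*2*3) matrix.

        Column order: for each finger (given order), distal x,y,z then
        proximal x,y,z — the layout used for PCA and prediction.
        """
        fingers = list(self.fingers) if fingers is None else list(fingers)
        cols = [self.positions[f][s] for f in fingers for s in SENSORS]
        return np.hstack(cols)

    def subset(self, fingers: list[str]) -> "HandRecording":
        """A new recording restricted to the given fingers (order preserved)."""
        return HandRecording(
            subject_id=self.subject_id,
            hand=self.hand,
            fingers=list(fingers),
            sampling_rate=self.sampling_rate,
            positions={f: dict(self.positions[f]) for f in fingers},
            task_label=self.task_label,
        )


@dataclass
class ForceTrial:
    """One instructed-finger trial: time x finger force matrix in newtons."""

    instructed_finger: str
    level: str  # one of LEVELS
    force: np.ndarray  # (T, n_fingers)
    duration: float  # s

    @property
    def n_samples(self) -> int:
        return self.force.shape[0]


@dataclass
class ForceRecording:
    """Isometric force session: ordered trials across fingers and levels."""

    subject_id: str
    fingers: list[str]
    sampling_rate: float = 128.0
    trials: list[ForceTrial] = field(default_factory=list)

    def trials_for(self, finger: str | None = None, level: str | None = None) -> list[ForceTrial]:
        out = self.trials
        if finger is not None:
            out = [t for t in out if t.instructed_finger == finger]
        if level is not None:
            out = [t for t in out if t.level == level]
        return out


LANDMARKS = ("knuckle1", "knuckle2", "tip")


@dataclass
class LocalizationDataset:
    """Finger-localization pointing data.

    ``points[(finger, landmark)]`` is a list of (reported_xy, true_xy) pairs in
    cm on the response grid.
    """

    points: dict[tuple[str, str], list[tuple[np.ndarray, np.ndarray]]]
    cue_mode: str = "tactile"  # "tactile" | "verbal"

    @property
    def fingers(self) -> list[str]:
        seen: list[str] = []
        for f, _ in self.points:
            if f not in seen:
                seen.append(f)
        return seen


@dataclass
class GameSessionLog:
    """Video-game practice log for one finger-use condition.

    ``events`` are ordered (cumulative practice time in minutes, level index)
    pairs; accuracy and error rate are per-trial fractions in [0, 1].
    """

    condition: str  # "six_finger" | "five_plus_one"
    events: list[tuple[float, int]]
    accuracy: list[float] = field(default_factory=list)
    error_rate: list[float] = field(default_factory=list)

    @property
    def times_min(self) -> np.ndarray:
        return np.array([t for t, _ in self.events], dtype=float)

    @property
    def levels(self) -> np.ndarray:
        return np.array([lv for _, lv in self.events], dtype=float)


def validate_recording(rec: HandRecording) -> list[str]:
    """Check a HandRecording against its invariants; return violation messages.

    Reporting, not raising: an empty list means the recording is valid.
    """
    violations: list[str] = []
    if rec.sampling_rate <= 0:
        violations.append(f"sampling_rate must be > 0, got {rec.sampling_rate}")
    if len(set(rec.fingers)) != len(rec.fingers):
        violations.append(f"finger labels not unique: {rec.fingers}")
    if len(rec.fingers) == 6 and "S" not in rec.fingers:
        violations.append("six-fingered recording lacks supernumerary label 'S'")
    if len(rec.fingers) == 5 and "S" in rec.fingers:
        violations.append("five-fingered recording contains label 'S'")

    lengths = set()
    for f in rec.fingers:
        sensors = rec.positions.get(f, {})
        for s in SENSORS:
            if s not in sensors:
                violations.append(f"finger {f} missing {s} sensor series")
                continue
            arr = np.asarray(sensors[s])
            if arr.ndim != 2 or arr.shape[1] != 3:
                violations.append(f"finger {f} {s} series is not (T, 3)")
                continue
            lengths.add(arr.shape[0])
            if not np.all(np.isfinite(arr)):
                violations.append(f"finger {f} {s} series contains non-finite values")
    if len(lengths) > 1:
        violations.append(f"series lengths differ: {sorted(lengths)}")
    if lengths and min(lengths) < 2:
        violations.append("series shorter than 2 samples")
    return violations
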