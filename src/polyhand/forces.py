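"""Isometric force analysis: maximal force, enslaving, variability, exclusion.

Enslaving quantifies the involuntary force of non-instructed fingers. With
finger *i* instructed to produce (a fraction of) its maximal force MF_i, the
enslaving of finger *j* is

    e_ij = F_j(i) / MF_j,

where F_j(i) is the force finger *j* produces simultaneously; at submaximal
levels the denominator MF_j is replaced by level * MF_j. F_j(i) is read out
as the mean force in a 500 ms window centered on the instructed finger's
smoothed force peak, and MF is the maximum of the 250 ms moving-average
force — windowed read-outs keep single-sample sensor spikes from defining
either quantity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import CoverageError, DataError, InsufficientDataError, LengthError
from .recordings import ForceRecording, ForceTrial, level_fraction

#: moving-average length used before peak picking, seconds
MF_SMOOTH_S = 0.250
#: read-out window for the simultaneous force of every finger, seconds
READOUT_WINDOW_S = 0.500
#: force-variability analysis window, samples at 128 Hz (inclusive bounds)
VARIABILITY_WINDOW = (1300, 1800)


@dataclass
class MaximalForceVector:
    fingers: list[str]
    mf: np.ndarray  # newtons, > 0

    def __getitem__(self, finger: str) -> float:
        return float(self.mf[self.fingers.index(finger)])


@dataclass
class EnslavingMatrix:
    """finger x finger matrix e_ij; row = instructed finger i, column =
    measured finger j. Unit diagonal at level MF by construction."""

    fingers: list[str]
    values: np.ndarray
    level: str = "MF"

    def off_diagonal(self, fingers: list[str] | None = None) -> np.ndarray:
        """Flattened off-diagonal entries restricted to ``fingers`` (row-major
        order of ordered pairs)."""
        fingers = self.fingers if fingers is None else list(fingers)
        idx = [self.fingers.index(f) for f in fingers]
        return np.array([self.values[i, j] for i in idx for j in idx if i != j])


def _boxcar(series: np.ndarray, width: int) -> np.ndarray:
    width = max(1, width)
    kernel = np.ones(width) / width
    return np.convolve(series, kernel, mode="same")


def maximal_force(rec: ForceRecording) -> MaximalForceVector:
    """MF_j = max over finger-j MF trials of the 250 ms moving-average force."""
    width = int(round(MF_SMOOTH_S * rec.sampling_rate))
    mf = np.empty(len(rec.fingers))
    for jf, finger in enumerate(rec.fingers):
        trials = rec.trials_for(finger=finger, level="MF")
        if not trials:
            raise CoverageError(f"no MF trial for finger {finger}")
        peaks = [float(_boxcar(t.force[:, jf], width).max()) for t in trials]
        mf[jf] = max(peaks)
    return MaximalForceVector(fingers=list(rec.fingers), mf=mf)


def _instructed_peak_index(trial: ForceTrial, finger_index: int, sampling_rate: float) -> int:
    """Index of the smoothed-force peak; on a plateau of tied maxima, its midpoint."""
    width = int(round(MF_SMOOTH_S * sampling_rate))
    smoothed = _boxcar(trial.force[:, finger_index], width)
    at_max = np.flatnonzero(smoothed == smoothed.max())
    return int(at_max[(len(at_max) - 1) // 2])


def _readout_mean(trial: ForceTrial, finger_index: int, sampling_rate: float) -> np.ndarray:
    """Simultaneous force of every finger during the instructed finger's effort.

    MF trials: mean over a 500 ms window centered on the instructed finger's
    smoothed peak. Submaximal hold trials: mean over the stable analysis
    window (the same [1300-1800]/128 s window used for force variability),
    which avoids centering on a noise-selected peak of a constant hold.
    """
    lo_stable, hi_stable = VARIABILITY_WINDOW
    if trial.level != "MF" and trial.n_samples > hi_stable:
        return trial.force[lo_stable:hi_stable + 1].mean(axis=0)
    center = _instructed_peak_index(trial, finger_index, sampling_rate)
    half = int(round(READOUT_WINDOW_S * sampling_rate / 2))
    lo = max(0, center - half)
    hi = min(trial.n_samples, center + half + 1)
    return trial.force[lo:hi].mean(axis=0)


def enslaving_matrix(
    rec: ForceRecording,
    mf: MaximalForceVector,
    level: str = "MF",
) -> EnslavingMatrix:
    """Estimate e_ij at the requested level, averaging replicate trials.

    At level MF the diagonal is 1 by construction (a finger's simultaneous
    force at its own peak is its MF).
    """
    if mf.fingers != rec.fingers:
        raise DataError("maximal-force vector fingers do not match recording")
    if np.any(mf.mf <= 0):
        raise DataError("non-positive maximal force")
    frac = level_fraction(level)
    n = len(rec.fingers)
    values = np.zeros((n, n))
    for i, instructed in enumerate(rec.fingers):
        trials = rec.trials_for(finger=instructed, level=level)
        if not trials:
            raise CoverageError(f"no trials for finger {instructed} at level {level}")
        per_trial = []
        for trial in trials:
            f_simultaneous = _readout_mean(trial, i, rec.sampling_rate)
            per_trial.append(f_simultaneous / (frac * mf.mf))
        values[i] = np.mean(per_trial, axis=0)
    values = np.abs(values)
    if level == "MF":
        np.fill_diagonal(values, 1.0)
    return EnslavingMatrix(fingers=list(rec.fingers), values=values, level=level)


def force_variability(trial: ForceTrial, finger_index: int | None = None,
                      fingers: list[str] | None = None) -> float:
    """SD of the instructed finger's force over samples 1300..1800 inclusive
    (the [1300-1800]/128 s window at 128 Hz)."""
    lo, hi = VARIABILITY_WINDOW
    if trial.n_samples <= hi:
        raise LengthError(
            f"trial has {trial.n_samples} samples; needs > {hi} for the analysis window"
        )
    if finger_index is None:
        if fingers is None:
            raise DataError("need finger_index or the recording's finger order")
        finger_index = fingers.index(trial.instructed_finger)
    window = trial.force[lo:hi + 1, finger_index]
    return float(np.std(window, ddof=1))


def exclude_unstable_trials(
    trials: list[ForceTrial],
    fingers: list[str],
    threshold: float = 3.0,
) -> tuple[list[ForceTrial], list[ForceTrial]]:
    """Split trials into (kept, excluded).

    A trial is excluded iff its analysis-window SD exceeds ``threshold`` times
    the median SD of its (instructed finger, level) cell — the operational
    form of discarding trials with extraordinarily high force fluctuations.
    """
    cells: dict[tuple[str, str], list[int]] = {}
    sds = np.empty(len(trials))
    for idx, trial in enumerate(trials):
        sds[idx] = force_variability(trial, fingers=fingers)
        cells.setdefault((trial.instructed_finger, trial.level), []).append(idx)
    kept, excluded = [], []
    for key, members in cells.items():
        if len(members) < 3:
            warnings.warn(f"cell {key} has < 3 trials; none excluded", stacklevel=2)
            kept.extend(trials[i] for i in members)
            continue
        med = float(np.median(sds[members]))
        for i in members:
            (excluded if sds[i] > threshold * med else kept).append(trials[i])
    return kept, excluded


def enslaving_correlation(
    a: EnslavingMatrix,
    b: EnslavingMatrix,
    common_fingers: list[str],
) -> float:
    """Pearson r between two enslaving matrices over the off-diagonal ordered
    pairs of the common fingers (5 common fingers -> N = 20 pairs)."""
    for f in common_fingers:
        if f not in a.fingers or f not in b.fingers:
            raise DataError(f"finger {f} absent from one of the matrices")
    va = a.off_diagonal(common_fingers)
    vb = b.off_diagonal(common_fingers)
    if len(va) < 3:
        raise InsufficientDataError(f"only {len(va)} finger pairs; need >= 3")
    from .stats import pearson

    return pearson(va, vb)
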