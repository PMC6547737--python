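"""Movement-state discretization, joint Shannon entropy, fingertip speed, and
supernumerary-finger coactivation.

Each finger's movement is collapsed to one scalar: spherical coordinates
(distance, polar, azimuth) of the distal sensor relative to the proximal
sensor are computed, a per-finger PCA of the (polar, azimuth) series keeps
the first principal component, and its one-sample difference v is thresholded
at mu = mu_factor * SD(v):

    flexion  : v < -mu
    extension: v > +mu
    rest     : otherwise

(the two-state variant splits at v < 0 / v > 0). The joint Shannon entropy
of the empirical distribution of state tuples,

    H = - sum_s p(s) log2 p(s)     (bits),

measures how rich the ensemble of movement patterns is; with n fingers there
are 3^n states and the maximum is n * log2(3). The first PC's sign is
arbitrary, which only swaps the flexion/extension labels and leaves every
entropy value unchanged.

Coactivation: a finger is "moving" at a sample when its fingertip speed
exceeds a pooled percentile threshold (10th/30th/50th across all fingers and
samples); conditional on the supernumerary finger moving, we report the
probabilities that thumb and index move together, thumb alone, or index
alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateDataError, ParameterError
from .preprocessing import recording_velocities, smooth_recording, spherical_from_pair
from .recordings import HandRecording

REST, FLEXION, EXTENSION = 0, 1, 2
STATE_NAMES = {REST: "rest", FLEXION: "flexion", EXTENSION: "extension"}
DEFAULT_MU_FACTOR = 0.3
ENTROPY_ORDER = ("T", "I", "M", "R", "L", "S")
PERCENTILES = (10, 30, 50)


@dataclass
class MovementStateSequence:
    """time x finger matrix of movement states (codes in STATE_NAMES)."""

    fingers: list[str]
    states: np.ndarray  # (T, n_fingers) int8
    mu_factor: float
    mu: np.ndarray  # per-finger threshold, first-PC units per sample
    n_states: int = 3

    def column(self, finger: str) -> np.ndarray:
        return self.states[:, self.fingers.index(finger)]


@dataclass
class EntropyResult:
    fingers: list[str]
    bits: float

    @property
    def n_state_combinations(self) -> int:
        return 3 ** len(self.fingers)

    @property
    def max_bits(self) -> float:
        return len(self.fingers) * np.log2(3.0)


@dataclass
class CoactivationResult:
    percentile: int
    p_thumb_and_index: float
    p_thumb_only: float
    p_index_only: float


def first_pc_scores(angles: np.ndarray) -> np.ndarray:
    """Scores along the first PC of a mean-centered (T, 2) angle series.

    No variance scaling (both columns are radians). The component's sign is
    arbitrary. A zero-variance series (stationary finger) yields all-zero
    scores — downstream this classifies every sample as rest.
    """
    centered = angles - angles.mean(axis=0)
    cov = centered.T @ centered / (len(centered) - 1)
    # tolerance relative to the angle magnitude: rounding wobble on a
    # constant series must not masquerade as movement
    floor = 1e-24 * max(float(np.mean(angles ** 2)), 1e-12)
    if float(np.trace(cov)) <= floor:
        warnings.warn("zero-variance angle series: finger treated as stationary",
                      stacklevel=2)
        return np.zeros(len(angles))
    eigvals, eigvecs = np.linalg.eigh(cov)
    return centered @ eigvecs[:, int(np.argmax(eigvals))]


def discretize_states(
    rec: HandRecording,
    mu_factor: float = DEFAULT_MU_FACTOR,
    n_states: int = 3,
    smoothed: bool = True,
) -> MovementStateSequence:
    """Classify each finger's movement at each sample into rest/flexion/extension.

    The first sample carries no derivative and is dropped, so all fingers'
    state series align on length T - 1.
    """
    if mu_factor < 0:
        raise ParameterError(f"mu_factor must be >= 0, got {mu_factor}")
    if n_states not in (2, 3):
        raise ParameterError(f"n_states must be 2 or 3, got {n_states}")
    work = smooth_recording(rec) if smoothed else rec
    n = rec.n_samples - 1
    states = np.empty((n, rec.n_fingers), dtype=np.int8)
    mus = np.empty(rec.n_fingers)
    for jf, finger in enumerate(rec.fingers):
        sph = spherical_from_pair(work.positions[finger]["distal"],
                                  work.positions[finger]["proximal"])
        scores = first_pc_scores(sph.angles())
        v = np.diff(scores)
        if n_states == 3:
            mu = mu_factor * float(np.std(v))
            col = np.full(n, REST, dtype=np.int8)
            col[v < -mu] = FLEXION
            col[v > mu] = EXTENSION
        else:
            mu = 0.0
            col = np.where(v < 0, FLEXION, EXTENSION).astype(np.int8)
        states[:, jf] = col
        mus[jf] = mu
    return MovementStateSequence(fingers=list(rec.fingers), states=states,
                                 mu_factor=mu_factor, mu=mus, n_states=n_states)


def joint_entropy(states: MovementStateSequence, subset: list[str]) -> EntropyResult:
    """Plug-in Shannon entropy (bits) of the empirical joint state distribution
    over the given finger subset. Unobserved state tuples contribute zero."""
    if not subset:
        raise ParameterError("finger subset must be non-empty")
    for f in subset:
        if f not in states.fingers:
            raise ParameterError(f"finger {f} not in state sequence")
    cols = [states.fingers.index(f) for f in subset]
    n_f = len(cols)
    if states.states.shape[0] < 10 * 3 ** n_f:
        warnings.warn(
            f"{states.states.shape[0]} samples for 3^{n_f} state combinations; "
            "plug-in entropy may be biased low",
            stacklevel=2,
        )
    codes = np.zeros(states.states.shape[0], dtype=np.int64)
    for c in cols:
        codes = codes * 3 + states.states[:, c]
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    h = float(-np.sum(p * np.log2(p)))
    return EntropyResult(fingers=list(subset), bits=h)


def entropy_curve(
    states: MovementStateSequence,
    ordering: tuple[str, ...] = ENTROPY_ORDER,
) -> list[EntropyResult]:
    """Joint entropies of the prefixes of ``ordering`` (thumb first, then
    successively adding fingers), restricted to fingers present."""
    ordering = tuple(f for f in ordering if f in states.fingers)
    if not ordering:
        raise ParameterError("ordering shares no fingers with the sequence")
    return [joint_entropy(states, list(ordering[:i + 1])) for i in range(len(ordering))]


def fingertip_speed(rec: HandRecording) -> tuple[list[str], np.ndarray]:
    """Per-finger fingertip speed in cm/s (distal sensor as fingertip proxy).

    Returns (finger labels, (T, n_fingers) array of Euclidean velocity norms).
    """
    vel = recording_velocities(rec)
    speeds = np.column_stack([
        np.linalg.norm(vel[f]["distal"], axis=1) for f in rec.fingers
    ])
    return list(rec.fingers), speeds


def moving_mask(speeds: np.ndarray, percentile: int) -> np.ndarray:
    """Boolean time x finger mask: moving iff speed strictly exceeds the
    pooled percentile of the speed distribution across all samples and fingers."""
    speeds = np.asarray(speeds, dtype=float)
    if speeds.size == 0:
        raise ParameterError("empty speed array")
    threshold = float(np.percentile(speeds, percentile))
    return speeds > threshold


def sf_coactivation(
    mask: np.ndarray,
    fingers: list[str],
    percentile: int,
) -> CoactivationResult:
    """Conditional coactivation of thumb and index given the supernumerary
    finger is moving.

    "Thumb only" means thumb moving and index not (and conversely); the three
    reported events are pairwise disjoint.
    """
    for f in ("T", "I", "S"):
        if f not in fingers:
            raise ParameterError(f"mask lacks finger {f}")
    t = mask[:, fingers.index("T")]
    i = mask[:, fingers.index("I")]
    s = mask[:, fingers.index("S")]
    if not np.any(s):
        raise DegenerateDataError("supernumerary finger never moving; conditional undefined")
    t, i = t[s], i[s]
    return CoactivationResult(
        percentile=percentile,
        p_thumb_and_index=float(np.mean(t & i)),
        p_thumb_only=float(np.mean(t & ~i)),
        p_index_only=float(np.mean(~t & i)),
    )
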