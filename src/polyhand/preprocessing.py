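"""Signal conditioning for motion-capture position series.

Raw positions are smoothed with a Savitzky-Golay filter (third order, 41
samples, i.e. 341.67 ms at 120 Hz) and velocities are obtained from the same
filter's first derivative. Spherical coordinates of the distal sensor
relative to its proximal sensor feed the movement-state discretization, and
decimation by a factor of 20 takes 120 Hz data to 6 Hz for the prediction
analysis.

Edge handling: the filter fits the local polynomial on the available
one-sided window at the series ends (scipy's ``interp`` mode); the first and
last ``(window - 1) // 2`` samples are the edge region and downstream
statistics exclude them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .errors import DegenerateDataError, LengthError, ParameterError
from .recordings import SENSORS, HandRecording

SG_ORDER = 3
SG_WINDOW = 41
DOWNSAMPLE_FACTOR = 20


def edge_margin(window: int = SG_WINDOW) -> int:
    """Number of samples at each end of a filtered series lying in the edge region."""
    return (window - 1) // 2


def _check_savgol_args(n: int, order: int, window: int) -> None:
    if window % 2 != 1:
        raise ParameterError(f"window must be odd, got {window}")
    if order >= window:
        raise ParameterError(f"order ({order}) must be < window ({window})")
    if n < window:
        raise LengthError(f"series length {n} shorter than window {window}")


def savgol_smooth(series: np.ndarray, order: int = SG_ORDER, window: int = SG_WINDOW) -> np.ndarray:
    """Savitzky-Golay smoothing of a uniformly sampled scalar series.

    Output length equals input length; interior samples are least-squares
    local polynomial fits, exact on polynomials of degree <= order.
    """
    series = np.asarray(series, dtype=float)
    _check_savgol_args(series.shape[0], order, window)
    return savgol_filter(series, window, order, axis=0, mode="interp")


def savgol_velocity(
    series: np.ndarray,
    sampling_rate: float,
    order: int = SG_ORDER,
    window: int = SG_WINDOW,
) -> np.ndarray:
    """First-derivative Savitzky-Golay filter, in input-units per second."""
    series = np.asarray(series, dtype=float)
    _check_savgol_args(series.shape[0], order, window)
    if sampling_rate <= 0:
        raise ParameterError(f"sampling_rate must be > 0, got {sampling_rate}")
    return savgol_filter(series, window, order, deriv=1, delta=1.0 / sampling_rate,
                         axis=0, mode="interp")


def downsample(series: np.ndarray, factor: int = DOWNSAMPLE_FACTOR) -> np.ndarray:
    """Keep every ``factor``-th sample starting at index 0 (applied after smoothing)."""
    if factor < 1 or int(factor) != factor:
        raise ParameterError(f"factor must be a positive integer, got {factor}")
    return np.asarray(series)[:: int(factor)]


@dataclass
class SphericalSeries:
    """(distance cm, polar rad, azimuth rad) of the distal sensor relative to
    its proximal sensor; polar is measured from the +z axis of the
    reference-sensor frame, azimuth = atan2(y, x)."""

    distance: np.ndarray
    polar: np.ndarray
    azimuth: np.ndarray

    def angles(self) -> np.ndarray:
        """(T, 2) array of (polar, azimuth) for downstream PCA."""
        return np.column_stack([self.polar, self.azimuth])


def spherical_from_pair(distal: np.ndarray, proximal: np.ndarray) -> SphericalSeries:
    """Spherical coordinates of distal relative to proximal, sample by sample."""
    distal = np.asarray(distal, dtype=float)
    proximal = np.asarray(proximal, dtype=float)
    if distal.shape != proximal.shape:
        raise ParameterError(
            f"distal and proximal shapes differ: {distal.shape} vs {proximal.shape}"
        )
    diff = distal - proximal
    distance = np.linalg.norm(diff, axis=1)
    zero = np.flatnonzero(distance == 0.0)
    if len(zero):
        raise DegenerateDataError(f"coincident distal/proximal sensors at sample {zero[0]}")
    polar = np.arccos(np.clip(diff[:, 2] / distance, -1.0, 1.0))
    azimuth = np.arctan2(diff[:, 1], diff[:, 0])
    return SphericalSeries(distance=distance, polar=polar, azimuth=azimuth)


def cartesian_from_spherical(sph: SphericalSeries) -> np.ndarray:
    """Inverse transform: the (T, 3) difference vector distal - proximal."""
    r, th, ph = sph.distance, sph.polar, sph.azimuth
    return np.column_stack([
        r * np.sin(th) * np.cos(ph),
        r * np.sin(th) * np.sin(ph),
        r * np.cos(th),
    ])


def smooth_recording(rec: HandRecording, order: int = SG_ORDER, window: int = SG_WINDOW) -> HandRecording:
    """Return a copy of the recording with every position series SG-smoothed."""
    positions = {
        f: {s: savgol_smooth(rec.positions[f][s], order=order, window=window)
            for s in SENSORS}
        for f in rec.fingers
    }
    return HandRecording(
        subject_id=rec.subject_id,
        hand=rec.hand,
        fingers=list(rec.fingers),
        sampling_rate=rec.sampling_rate,
        positions=positions,
        task_label=rec.task_label,
    )


def recording_velocities(
    rec: HandRecording, order: int = SG_ORDER, window: int = SG_WINDOW
) -> dict[str, dict[str, np.ndarray]]:
    """Per finger x sensor (T, 3) velocity series in cm/s (SG first derivative
    of the raw positions)."""
    return {
        f: {s: savgol_velocity(rec.positions[f][s], rec.sampling_rate,
                               order=order, window=window)
            for s in SENSORS}
        for f in rec.fingers
    }
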