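"""Synthetic generators for every input the pipeline consumes.

The recordings behind the original analyses are withheld to protect the
participants, so every pipeline stage is exercised on generated data with
known ground truth: latent movement dimensionality, pairwise coupling,
enslaving matrix, signal-dependent force noise, and learning-curve slopes.

Hand kinematics are modelled as k independent band-limited latent sources
(white noise low-passed at 2 Hz — the band where manipulation movements
live, and comfortably inside the Savitzky-Golay passband) mixed linearly
into the (fingers x 2 sensors x 3 coordinates) sensor space, plus isotropic
Gaussian sensor noise. The sources are sample-whitened (exactly unit
covariance in-sample), so the noise-free data covariance equals the mixing
Gram matrix exactly and population quantities (pairwise Gaussian mutual
information, latent rank) are available in closed form as oracles.

All generators are pure functions of (spec, seed): the same seed reproduces
the same dataset bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .errors import ParameterError
from .recordings import (
    FIVE_FINGER_ORDER,
    SENSORS,
    SIX_FINGER_ORDER,
    ForceRecording,
    ForceTrial,
    GameSessionLog,
    HandRecording,
    LANDMARKS,
    LocalizationDataset,
)

DEFAULT_RATE = 120.0
DEFAULT_SOURCE_BAND_HZ = 2.0
#: independent per-coordinate noise, cm: measurement noise plus idiosyncratic
#: per-finger movement not captured by the shared latent sources
DEFAULT_SENSOR_NOISE_SD = 0.25
DEFAULT_DURATION_S = 300.0


# ---------------------------------------------------------------------------
# Hand kinematics
# ---------------------------------------------------------------------------

@dataclass
class HandModelSpec:
    """Generative model of a five- or six-fingered hand recording."""

    n_fingers: int
    latent_dof: int
    mixing: np.ndarray  # (n_fingers * 6, latent_dof), full column rank
    noise_sd: float = DEFAULT_SENSOR_NOISE_SD  # cm
    source_band_hz: float = DEFAULT_SOURCE_BAND_HZ
    duration_s: float = DEFAULT_DURATION_S
    sampling_rate: float = DEFAULT_RATE
    seed: int = 0
    subject_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_fingers not in (5, 6):
            raise ParameterError(f"n_fingers must be 5 or 6, got {self.n_fingers}")
        if self.latent_dof < 1:
            raise ParameterError("latent_dof must be >= 1")
        self.mixing = np.asarray(self.mixing, dtype=float)
        expected = (self.n_fingers * 6, self.latent_dof)
        if self.mixing.shape != expected:
            raise ParameterError(f"mixing must be {expected}, got {self.mixing.shape}")
        if np.linalg.matrix_rank(self.mixing) < self.latent_dof:
            raise ParameterError("mixing matrix is rank deficient")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")

    @property
    def fingers(self) -> list[str]:
        return list(SIX_FINGER_ORDER if self.n_fingers == 6 else FIVE_FINGER_ORDER)


@dataclass
class HandGroundTruth:
    """Closed-form properties of the generated ensemble."""

    latent_dof: int
    mixing: np.ndarray
    noise_sd: float
    fingers: list[str]
    population_cov: np.ndarray  # mixing @ mixing.T + noise_sd^2 I

    def population_mi(self, finger_a: str, finger_b: str) -> float:
        """Population Gaussian MI (bits) between two fingers' 6-D signals."""
        ia, ib = self.fingers.index(finger_a), self.fingers.index(finger_b)
        idx = np.r_[6 * ia:6 * ia + 6, 6 * ib:6 * ib + 6]
        joint = self.population_cov[np.ix_(idx, idx)]
        _, ld_joint = np.linalg.slogdet(joint)
        _, ld_a = np.linalg.slogdet(joint[:6, :6])
        _, ld_b = np.linalg.slogdet(joint[6:, 6:])
        return max(0.0, 0.5 * (ld_a + ld_b - ld_joint) / np.log(2.0))


def band_limited_sources(
    n: int, k: int, rng: np.random.Generator,
    sampling_rate: float = DEFAULT_RATE,
    band_hz: float = DEFAULT_SOURCE_BAND_HZ,
    whiten: bool = True,
) -> np.ndarray:
    """k independent band-limited unit-variance sources of length n.

    With ``whiten`` the columns are made exactly zero-mean with identity
    sample covariance, so downstream covariances equal their population
    values by construction.
    """
    raw = rng.standard_normal((n, k))
    sos = butter(4, band_hz, btype="low", fs=sampling_rate, output="sos")
    src = sosfiltfilt(sos, raw, axis=0)
    src = src - src.mean(axis=0)
    if whiten:
        cov = src.T @ src / (n - 1)
        chol = np.linalg.cholesky(cov)
        src = np.linalg.solve(chol, src.T).T
    else:
        src = src / src.std(axis=0, ddof=1)
    return src


#: relative loading of each finger on the shared latent sources.
#: s0 = whole-hand source; s1 = thumb source; s2 = index/middle source;
#: s3 = ring/little source; s4 (six-fingered only) = private supernumerary
#: source. The supernumerary finger loads weakly on the thumb source —
#: some dependence with the thumb, none with the rest.
_FIVE_FINGER_WEIGHTS = {
    "T": {0: 0.4, 1: 1.0},
    "I": {0: 0.5, 2: 1.0},
    "M": {0: 0.7, 2: 0.5, 3: 0.7},
    "R": {0: 0.7, 3: 1.0},
    "L": {0: 0.6, 3: 0.95},
}
_SIX_FINGER_WEIGHTS = dict(_FIVE_FINGER_WEIGHTS, S={0: 0.3, 1: 0.4, 4: 1.0})


def _structured_mixing(
    fingers: list[str],
    weights: dict[str, dict[int, float]],
    latent_dof: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Mixing rows per finger: 3 distal then 3 proximal coordinates.

    The two sensors of a finger co-move: each distal coordinate is a scaled
    copy of its proximal counterpart plus a small flexion perturbation, so
    the distal-proximal difference vector stays well away from zero and the
    spherical angles never wrap.
    """
    def draw_row(w, norm):
        row = np.zeros(latent_dof)
        for src, weight in w.items():
            row[src] = weight * rng.standard_normal()
        return row * (norm / np.linalg.norm(row))

    rows = []
    for finger in fingers:
        w = weights[finger]
        proximal = [draw_row(w, rng.uniform(0.7, 1.0)) for _ in range(3)]
        distal = [1.3 * p + draw_row(w, rng.uniform(0.2, 0.35)) for p in proximal]
        rows.extend(distal)
        rows.extend(proximal)
    return np.array(rows)


def five_finger_spec(seed: int = 0, **overrides) -> HandModelSpec:
    """Default five-fingered hand: four shared latent degrees of freedom."""
    rng = np.random.default_rng(seed + 1_000_003)
    mixing = _structured_mixing(list(FIVE_FINGER_ORDER), _FIVE_FINGER_WEIGHTS, 4, rng)
    return HandModelSpec(n_fingers=5, latent_dof=4, mixing=mixing, seed=seed,
                         subject_id="synthetic-five", **overrides)


def six_finger_spec(seed: int = 0, **overrides) -> HandModelSpec:
    """Default six-fingered hand: the five-fingered model plus a supernumerary
    finger carrying one private latent source and weak coupling to the thumb."""
    rng = np.random.default_rng(seed + 1_000_003)
    mixing = _structured_mixing(list(SIX_FINGER_ORDER), _SIX_FINGER_WEIGHTS, 5, rng)
    return HandModelSpec(n_fingers=6, latent_dof=5, mixing=mixing, seed=seed,
                         subject_id="synthetic-six", **overrides)


def linearly_coupled_spec(seed: int = 0, **overrides) -> HandModelSpec:
    """Five fingers all mixing the same four shared sources — every finger is
    an exact linear function of the others (given zero noise)."""
    rng = np.random.default_rng(seed + 3_000_003)
    weights = {
        "T": {0: 1.0, 1: 0.7, 2: 0.5, 3: 0.4},
        "I": {0: 0.8, 1: 1.0, 2: 0.3},
        "M": {0: 0.8, 1: 0.5, 2: 1.0},
        "R": {0: 0.8, 2: 0.6, 3: 1.0},
        "L": {0: 0.7, 3: 1.0},
    }
    mixing = _structured_mixing(list(FIVE_FINGER_ORDER), weights, 4, rng)
    overrides.setdefault("noise_sd", 0.0)
    return HandModelSpec(n_fingers=5, latent_dof=4, mixing=mixing, seed=seed,
                         subject_id="synthetic-coupled", **overrides)


def independent_fingers_spec(n_fingers: int = 5, seed: int = 0, **overrides) -> HandModelSpec:
    """Each finger driven by its own two private sources — zero inter-finger MI."""
    fingers = list(SIX_FINGER_ORDER if n_fingers == 6 else FIVE_FINGER_ORDER)
    rng = np.random.default_rng(seed + 2_000_003)
    weights = {f: {2 * i: 1.0, 2 * i + 1: 0.8} for i, f in enumerate(fingers)}
    mixing = _structured_mixing(fingers, weights, 2 * n_fingers, rng)
    return HandModelSpec(n_fingers=n_fingers, latent_dof=2 * n_fingers,
                         mixing=mixing, seed=seed,
                         subject_id="synthetic-independent", **overrides)


#: static sensor geometry, cm: fingers fan out along y, distal sensors sit
#: 4 cm further along x and 1 cm above the proximal ones.
def _sensor_offset(finger_index: int, sensor: str) -> np.ndarray:
    base = np.array([5.0, 2.0 * finger_index, 0.0])
    if sensor == "distal":
        return base + np.array([4.0, 0.0, 1.0])
    return base


def simulate_hand(spec: HandModelSpec) -> tuple[HandRecording, HandGroundTruth]:
    """Generate a hand recording: sources -> mixing -> sensor noise."""
    n = int(round(spec.duration_s * spec.sampling_rate))
    rng = np.random.default_rng(spec.seed)
    sources = band_limited_sources(n, spec.latent_dof, rng,
                                   sampling_rate=spec.sampling_rate,
                                   band_hz=spec.source_band_hz)
    data = sources @ spec.mixing.T
    if spec.noise_sd > 0:
        data = data + spec.noise_sd * rng.standard_normal(data.shape)

    fingers = spec.fingers
    positions: dict[str, dict[str, np.ndarray]] = {}
    for fi, finger in enumerate(fingers):
        positions[finger] = {}
        for si, sensor in enumerate(SENSORS):
            cols = data[:, 6 * fi + 3 * si: 6 * fi + 3 * si + 3]
            positions[finger][sensor] = cols + _sensor_offset(fi, sensor)

    rec = HandRecording(
        subject_id=spec.subject_id,
        hand="right",
        fingers=fingers,
        sampling_rate=spec.sampling_rate,
        positions=positions,
        task_label="object_manipulation",
    )
    truth = HandGroundTruth(
        latent_dof=spec.latent_dof,
        mixing=spec.mixing.copy(),
        noise_sd=spec.noise_sd,
        fingers=fingers,
        population_cov=spec.mixing @ spec.mixing.T
        + spec.noise_sd ** 2 * np.eye(spec.mixing.shape[0]),
    )
    return rec, truth


def simulate_lowrank_matrix(
    n: int,
    dims: int,
    k: int,
    snr: float,
    seed: int = 0,
    sampling_rate: float = DEFAULT_RATE,
    band_hz: float = DEFAULT_SOURCE_BAND_HZ,
) -> tuple[np.ndarray, np.ndarray]:
    """Rank-k band-limited signal in ``dims`` dimensions plus isotropic noise.

    Rows of the mixing have unit norm so each coordinate carries unit signal
    variance; ``snr`` is the per-coordinate signal-to-noise variance ratio
    (``snr = inf`` for noiseless data). Returns (data, mixing) — the
    dimensionality benchmark for the cross-validated PCA methods.
    """
    rng = np.random.default_rng(seed)
    mixing = rng.standard_normal((dims, k))
    mixing /= np.linalg.norm(mixing, axis=1, keepdims=True)
    sources = band_limited_sources(n, k, rng, sampling_rate=sampling_rate,
                                   band_hz=band_hz)
    data = sources @ mixing.T
    if np.isfinite(snr):
        data = data + np.sqrt(1.0 / snr) * rng.standard_normal(data.shape)
    return data, mixing


# ---------------------------------------------------------------------------
# Isometric force sessions
# ---------------------------------------------------------------------------

@dataclass
class ForceModelSpec:
    """Generative model of an isometric force session.

    Finger j's force while finger i is instructed tracks
    ``E*_ij * (f_i(t) / MF_i) * MF_j`` — the coupling matrix E* is exactly
    the enslaving matrix the analysis should recover. Force noise is
    signal-dependent: SD = c * instantaneous mean force (variability grows
    with force level).
    """

    fingers: list[str] = field(default_factory=lambda: list(FIVE_FINGER_ORDER))
    mf: np.ndarray | None = None  # newtons
    coupling: np.ndarray | None = None  # E*, unit diagonal, >= 0
    noise_coeff: float = 0.05  # c
    mf_trial_s: float = 5.0
    submax_trial_s: float = 15.0
    sampling_rate: float = 128.0
    seed: int = 0
    subject_id: str = "synthetic"

    def __post_init__(self) -> None:
        n = len(self.fingers)
        if self.mf is None:
            # thumb strongest, little weakest — typical ordering
            base = {"T": 55.0, "S": 30.0, "I": 35.0, "M": 32.0, "R": 22.0, "L": 18.0}
            self.mf = np.array([base.get(f, 30.0) for f in self.fingers])
        self.mf = np.asarray(self.mf, dtype=float)
        if self.coupling is None:
            self.coupling = default_coupling(self.fingers, seed=self.seed)
        self.coupling = np.asarray(self.coupling, dtype=float)
        if self.coupling.shape != (n, n):
            raise ParameterError(f"coupling must be ({n}, {n})")
        if np.any(self.coupling < 0) or not np.allclose(np.diag(self.coupling), 1.0):
            raise ParameterError("coupling must be >= 0 with unit diagonal")
        if self.noise_coeff < 0:
            raise ParameterError("noise_coeff must be >= 0")


#: radial-to-ulnar anatomical position of each finger; the supernumerary
#: finger sits between thumb and index
_FINGER_POSITION = {"T": 0.0, "S": 0.5, "I": 1.0, "M": 2.0, "R": 3.0, "L": 4.0}


def default_coupling(fingers: list[str], seed: int | None = None) -> np.ndarray:
    """Anatomically structured enslaving ground truth.

    Enslaving decays with inter-finger distance (neighbours enslave most);
    the supernumerary finger is comparatively independent — its couplings
    are halved except the residual dependence on the thumb. Common-finger
    blocks are therefore identical across five- and six-fingered hands, as
    observed empirically. A small seed-dependent jitter differentiates
    subjects.
    """
    n = len(fingers)
    e = np.empty((n, n))
    for i, fi in enumerate(fingers):
        for j, fj in enumerate(fingers):
            d = abs(_FINGER_POSITION[fi] - _FINGER_POSITION[fj])
            e[i, j] = 0.04 + 0.28 * np.exp(-d / 1.2)
            if "S" in (fi, fj) and fi != fj and "T" not in (fi, fj):
                e[i, j] *= 0.5
    np.fill_diagonal(e, 1.0)
    if seed is not None:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 987]))
        jitter = rng.uniform(-0.02, 0.02, size=(n, n))
        np.fill_diagonal(jitter, 0.0)
        e = np.clip(e + jitter, 0.0, None)
    return e


def _force_profile(n: int, target: float, sampling_rate: float) -> np.ndarray:
    """Half-cosine rise over 1 s, then hold at target."""
    rise = int(round(1.0 * sampling_rate))
    rise = min(rise, n)
    profile = np.full(n, target)
    ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(rise) / rise))
    profile[:rise] = target * ramp
    return profile


def simulate_force_session(
    spec: ForceModelSpec,
    levels: tuple[str, ...] = ("MF", "10", "20", "30"),
    reps: int = 3,
) -> ForceRecording:
    """Generate an instructed-finger force session.

    One MF trial per finger (maximal force is recorded once per finger);
    ``reps`` replicate trials per finger at each submaximal level, mirroring
    the 3 x 3 x fingers session arithmetic of the protocol.
    """
    rng = np.random.default_rng(spec.seed)
    n_f = len(spec.fingers)
    trials: list[ForceTrial] = []
    from .recordings import level_fraction

    for level in levels:
        frac = level_fraction(level)
        n_reps = 1 if level == "MF" else reps
        duration = spec.mf_trial_s if level == "MF" else spec.submax_trial_s
        n = int(round(duration * spec.sampling_rate))
        for i in range(n_f):
            for _ in range(n_reps):
                instructed = _force_profile(n, frac * spec.mf[i], spec.sampling_rate)
                force = np.empty((n, n_f))
                for j in range(n_f):
                    mean_force = spec.coupling[i, j] * (instructed / spec.mf[i]) * spec.mf[j]
                    noise = spec.noise_coeff * mean_force * rng.standard_normal(n)
                    force[:, j] = mean_force + noise
                trials.append(ForceTrial(
                    instructed_finger=spec.fingers[i],
                    level=level,
                    force=force,
                    duration=duration,
                ))
    return ForceRecording(subject_id=spec.subject_id, fingers=list(spec.fingers),
                          sampling_rate=spec.sampling_rate, trials=trials)


# ---------------------------------------------------------------------------
# Finger localization
# ---------------------------------------------------------------------------

def default_localization_layout(fingers: list[str] | None = None) -> dict[tuple[str, str], np.ndarray]:
    """True grid positions: fingers fan out along x, the three landmarks of
    each finger (knuckle1, knuckle2, tip) stack along y. 18 landmarks for a
    six-fingered hand."""
    fingers = list(SIX_FINGER_ORDER) if fingers is None else list(fingers)
    return {
        (f, lm): np.array([2.0 * fi, 2.5 * li])
        for fi, f in enumerate(fingers)
        for li, lm in enumerate(LANDMARKS)
    }


def simulate_localization(
    n_reps: int = 6,
    layout: dict[tuple[str, str], np.ndarray] | None = None,
    error_sd: float = 1.0,
    seed: int = 0,
    cue_mode: str = "tactile",
) -> LocalizationDataset:
    """Reported position = true position + isotropic 2-D Gaussian error.

    With error SD sigma the mean Euclidean error is sigma * sqrt(pi / 2)
    (Rayleigh mean).
    """
    if error_sd < 0:
        raise ParameterError("error_sd must be >= 0")
    layout = default_localization_layout() if layout is None else layout
    rng = np.random.default_rng(seed)
    points = {
        key: [(true + error_sd * rng.standard_normal(2), true.copy())
              for _ in range(n_reps)]
        for key, true in layout.items()
    }
    return LocalizationDataset(points=points, cue_mode=cue_mode)


# ---------------------------------------------------------------------------
# Video-game logs
# ---------------------------------------------------------------------------

@dataclass
class GameModelSpec:
    """Generative model of the video-game learning logs.

    Level at a practice checkpoint is ``1 + slope * hours + noise``, rounded
    to an integer level, floored at 1, non-decreasing within a day. The
    schedule follows the protocol: five consecutive practice days plus a
    follow-up on day 15, one hour per day. By default one checkpoint closes
    each practice hour (the level reached that day), so checkpoint noise is
    independent across events; finer within-day logging is available via
    ``checkpoints_per_hour``.
    """

    slopes: dict[str, float] = field(default_factory=lambda: {
        "six_finger": 2.0, "five_plus_one": 2.0})
    noise_sd: float = 1.0  # levels
    days: tuple[int, ...] = (1, 2, 3, 4, 5, 15)
    checkpoints_per_hour: int = 1
    seed: int = 0


def simulate_game(spec: GameModelSpec) -> dict[str, GameSessionLog]:
    """One GameSessionLog per condition, seed-deterministic."""
    rng = np.random.default_rng(spec.seed)
    logs: dict[str, GameSessionLog] = {}
    step_min = 60.0 / spec.checkpoints_per_hour
    for condition, slope in spec.slopes.items():
        events: list[tuple[float, int]] = []
        accuracy: list[float] = []
        error_rate: list[float] = []
        cumulative_min = 0.0
        for _day in spec.days:
            day_levels: list[int] = []
            for _c in range(spec.checkpoints_per_hour):
                cumulative_min += step_min
                hours = cumulative_min / 60.0
                raw = 1.0 + slope * hours + spec.noise_sd * rng.standard_normal()
                level = max(1, int(round(raw)))
                if day_levels:
                    level = max(level, day_levels[-1])  # no within-day regression
                day_levels.append(level)
                events.append((cumulative_min, level))
                accuracy.append(float(np.clip(0.6 + 0.05 * rng.standard_normal(), 0, 1)))
                error_rate.append(float(np.clip(0.25 + 0.05 * rng.standard_normal(), 0, 1)))
        logs[condition] = GameSessionLog(condition=condition, events=events,
                                         accuracy=accuracy, error_rate=error_rate)
    return logs
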