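"""Pairwise finger dependence via Gaussian mutual information, and prediction
of each finger's movement from the remaining fingers.

Each finger is represented by the six-dimensional time series formed by the
(x, y, z) positions of its distal and proximal sensors. Under a multivariate
Gaussian model the mutual information between two fingers X and Y is

    I(X, Y) = 1/2 * log2[ det(S_X) det(S_Y) / det(S_XY) ]   (bits),

with S_X, S_Y the marginal sample covariances and S_XY the joint covariance.
For univariate normal signals this reduces to the closed form
I = log2 sqrt(1 / (1 - r^2)) in the Pearson correlation r. Fischer's
inequality (det S_XY <= det S_X det S_Y for positive-definite S_XY)
guarantees non-negative estimates.

Prediction uses linear least squares or Gaussian-kernel support vector
regression on data decimated to 6 Hz, with twofold chronological
cross-validation (first half / second half) so that temporal autocorrelation
cannot leak between train and test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .errors import DegenerateDataError, InsufficientDataError, ParameterError
from .preprocessing import DOWNSAMPLE_FACTOR, downsample, smooth_recording
from .recordings import HandRecording

#: relative ridge added to ill-conditioned covariances before determinants
COV_EPS = 1e-8
#: relative eigenvalue below which the joint covariance counts as singular
SINGULAR_TOL = 1e-12


def gaussian_mi(x: np.ndarray, y: np.ndarray) -> float:
    """Mutual information in bits between two multivariate time series.

    ``x`` and ``y`` are (T, d) arrays (columns are signal dimensions). The
    sample covariances are the unbiased estimates of the mean-centered series.
    Raises :class:`DegenerateDataError` if the joint covariance is not
    positive definite after regularization (linearly dependent signals).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.ndim == 2 and x.shape[0] == 1:
        x = x.T
    if y.ndim == 2 and y.shape[0] == 1:
        y = y.T
    if x.shape[0] != y.shape[0]:
        raise ParameterError(f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    n = x.shape[0]
    if n < x.shape[1] + y.shape[1] + 2:
        raise InsufficientDataError(f"{n} samples too few for covariance estimation")

    joint = np.hstack([x, y])
    joint = joint - joint.mean(axis=0)
    s_joint = np.cov(joint, rowvar=False)
    scale = float(np.mean(np.diag(s_joint)))
    eigmin = float(np.linalg.eigvalsh(s_joint).min())
    if eigmin <= SINGULAR_TOL * scale:
        raise DegenerateDataError(
            "joint covariance singular (linearly dependent signals)"
        )
    if eigmin < COV_EPS * scale:
        # near-collinear motion data: ridge keeps the determinants stable
        s_joint = s_joint + COV_EPS * scale * np.eye(s_joint.shape[0])
    dx = x.shape[1]
    s_x = s_joint[:dx, :dx]
    s_y = s_joint[dx:, dx:]
    sign, ld_joint = np.linalg.slogdet(s_joint)
    _, ld_x = np.linalg.slogdet(s_x)
    _, ld_y = np.linalg.slogdet(s_y)
    if sign <= 0:
        raise DegenerateDataError("joint covariance determinant non-positive")
    mi = 0.5 * (ld_x + ld_y - ld_joint) / np.log(2.0)
    # Fischer's inequality makes this >= 0 up to floating-point error.
    return max(float(mi), 0.0)


def mi_univariate_closed_form(r: float) -> float:
    """Closed-form Gaussian MI in bits for univariate signals with correlation r."""
    if not np.abs(r) < 1:
        raise ParameterError(f"|r| must be < 1, got {r}")
    return float(np.log2(np.sqrt(1.0 / (1.0 - r * r))))


@dataclass
class MIMatrix:
    """Symmetric finger x finger mutual-information matrix in bits.

    The diagonal is undefined and masked with NaN; pairs whose estimate
    failed (degenerate covariance) are also NaN and listed in ``failed``.
    """

    fingers: list[str]
    values: np.ndarray
    failed: list[tuple[str, str]] = field(default_factory=list)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.fingers.index(pair[0])
        j = self.fingers.index(pair[1])
        return float(self.values[i, j])

    def off_diagonal(self, fingers: list[str] | None = None) -> np.ndarray:
        fingers = self.fingers if fingers is None else list(fingers)
        idx = [self.fingers.index(f) for f in fingers]
        return np.array([self.values[i, j] for i in idx for j in idx if i != j])


def finger_signal(rec: HandRecording, finger: str) -> np.ndarray:
    """The finger's 6-D signal: distal (x,y,z) then proximal (x,y,z), in cm."""
    return np.hstack([rec.positions[finger]["distal"], rec.positions[finger]["proximal"]])


def mi_matrix(rec: HandRecording, smoothed: bool = True) -> MIMatrix:
    """Pairwise Gaussian MI between all fingers' 6-D signals at the native rate.

    ``smoothed`` applies the standard Savitzky-Golay smoothing first (the
    default); each unordered pair is computed once and mirrored.
    """
    if rec.n_fingers < 2:
        raise ParameterError("need at least two fingers")
    work = smooth_recording(rec) if smoothed else rec
    n = rec.n_fingers
    values = np.full((n, n), np.nan)
    failed: list[tuple[str, str]] = []
    signals = {f: finger_signal(work, f) for f in rec.fingers}
    for i, j in combinations(range(n), 2):
        fi, fj = rec.fingers[i], rec.fingers[j]
        try:
            values[i, j] = values[j, i] = gaussian_mi(signals[fi], signals[fj])
        except DegenerateDataError as exc:
            warnings.warn(f"MI({fi},{fj}) masked: {exc}", stacklevel=2)
            failed.append((fi, fj))
    return MIMatrix(fingers=list(rec.fingers), values=values, failed=failed)


# ---------------------------------------------------------------------------
# Prediction of individual finger movements
# ---------------------------------------------------------------------------

#: kernel-width grid, multiples of the median pairwise predictor distance
SVR_WIDTH_GRID = (0.1, 0.3, 1.0, 3.0, 10.0)
SVR_C_GRID = (0.1, 1.0, 10.0, 100.0)


@dataclass
class PredictionResult:
    target: str
    predictors: list[str]
    method: str  # "linear" | "kernel_svr"
    r2_per_dimension: np.ndarray  # 6 values, NaN where undefined
    mean_r2: float


def _chrono_half_split(n: int) -> tuple[np.ndarray, np.ndarray]:
    cut = n // 2
    return np.arange(cut), np.arange(cut, n)


def _linear_predict(xtr, ytr, xte):
    design_tr = np.column_stack([np.ones(len(xtr)), xtr])
    design_te = np.column_stack([np.ones(len(xte)), xte])
    beta, *_ = np.linalg.lstsq(design_tr, ytr, rcond=None)
    return design_te @ beta


def _median_pairwise_distance(x: np.ndarray, rng: np.random.Generator) -> float:
    n = len(x)
    m = min(n, 500)
    idx = rng.choice(n, size=m, replace=False) if n > m else np.arange(n)
    sub = x[idx]
    d2 = np.sum((sub[:, None, :] - sub[None, :, :]) ** 2, axis=-1)
    vals = np.sqrt(d2[np.triu_indices(m, k=1)])
    med = float(np.median(vals))
    return med if med > 0 else 1.0


def _svr_predict(xtr, ytr, xte):
    """Gaussian-kernel SVR with hyperparameters grid-searched on the training
    fold only (inner twofold chronological split)."""
    from sklearn.svm import SVR

    mu, sd = xtr.mean(axis=0), xtr.std(axis=0)
    sd[sd == 0] = 1.0
    xtr_s, xte_s = (xtr - mu) / sd, (xte - mu) / sd
    y_mu, y_sd = ytr.mean(), ytr.std()
    y_sd = y_sd if y_sd > 0 else 1.0
    ytr_s = (ytr - y_mu) / y_sd

    med = _median_pairwise_distance(xtr_s, np.random.default_rng(0))
    inner_a, inner_b = _chrono_half_split(len(xtr_s))
    best, best_score = None, -np.inf
    for width_mult in SVR_WIDTH_GRID:
        gamma = 1.0 / (2.0 * (width_mult * med) ** 2)
        for c in SVR_C_GRID:
            score = 0.0
            for tr_idx, te_idx in ((inner_a, inner_b), (inner_b, inner_a)):
                model = SVR(kernel="rbf", gamma=gamma, C=c)
                model.fit(xtr_s[tr_idx], ytr_s[tr_idx])
                pred = model.predict(xtr_s[te_idx])
                sst = float(np.sum((ytr_s[te_idx] - ytr_s[te_idx].mean()) ** 2))
                sse = float(np.sum((ytr_s[te_idx] - pred) ** 2))
                score += 1.0 - sse / sst if sst > 0 else 0.0
            if score > best_score:
                best_score, best = score, (gamma, c)
    gamma, c = best
    model = SVR(kernel="rbf", gamma=gamma, C=c)
    model.fit(xtr_s, ytr_s)
    return model.predict(xte_s) * y_sd + y_mu


def predict_finger(
    rec: HandRecording,
    target: str,
    method: str = "linear",
    exclude: set[str] | None = None,
    downsample_factor: int = DOWNSAMPLE_FACTOR,
    smoothed: bool = True,
) -> PredictionResult:
    """Predict a finger's 6-D movement from the other fingers' movements.

    The six target dimensions are regressed individually on the concatenated
    6-D signals of the remaining fingers (24- or 30-dimensional predictors).
    Twofold chronological cross-validation: train on one half, test on the
    other, both directions; held-out R^2 = 1 - SSE/SST per dimension with SST
    about the test-set mean, averaged over 6 dimensions and 2 folds.
    """
    if method not in ("linear", "kernel_svr"):
        raise ParameterError(f"unknown method '{method}'")
    exclude = set(exclude or ())
    predictors = [f for f in rec.fingers if f != target and f not in exclude]
    if len(predictors) < 2:
        raise ParameterError("need at least two predictor fingers")

    work = smooth_recording(rec) if smoothed else rec
    y_full = downsample(finger_signal(work, target), downsample_factor)
    x_full = downsample(
        np.hstack([finger_signal(work, f) for f in predictors]), downsample_factor
    )

    first, second = _chrono_half_split(len(y_full))
    r2 = np.zeros((2, y_full.shape[1]))
    for fold, (tr, te) in enumerate(((first, second), (second, first))):
        for dim in range(y_full.shape[1]):
            ytr, yte = y_full[tr, dim], y_full[te, dim]
            sst = float(np.sum((yte - yte.mean()) ** 2))
            if sst == 0:
                warnings.warn(
                    f"target {target} dimension {dim} constant in test fold; omitted",
                    stacklevel=2,
                )
                r2[fold, dim] = np.nan
                continue
            if method == "linear":
                pred = _linear_predict(x_full[tr], ytr, x_full[te])
            else:
                pred = _svr_predict(x_full[tr], ytr, x_full[te])
            r2[fold, dim] = 1.0 - float(np.sum((yte - pred) ** 2)) / sst

    per_dim = np.nanmean(r2, axis=0)
    return PredictionResult(
        target=target,
        predictors=predictors,
        method=method,
        r2_per_dimension=per_dim,
        mean_r2=float(np.nanmean(r2)),
    )
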