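"""Effective degrees of freedom of hand movement via cross-validated PCA.

The kinematic data matrix (samples x (fingers * 2 sensors * 3 coordinates))
is analysed with two PRESS-based model-selection procedures, both using
chronological folds so that temporal autocorrelation cannot leak from
training into test blocks:

* **eigenvector method** — loadings are estimated on the training folds; each
  held-out sample coordinate is predicted from the sample's *other*
  coordinates by least-squares projection onto the k-dimensional loading
  subspace with the corresponding loading row removed (so the predicted
  coordinate never sees its own value);

* **EM-imputation method** — held-out elements are deleted in a speckled
  pattern (each test row loses one coordinate per sub-round; across the d
  sub-rounds every coordinate of every test row is deleted exactly once) and
  reconstructed by iterative EM-PCA imputation on the full matrix.

PRESS(k) is the total squared prediction error over all folds and elements;
the minimizing k estimates the effective number of degrees of freedom, and
the two methods' optima are averaged into a combined estimate (possibly
half-integer). Ties in the argmin break toward smaller k (parsimony).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateDataError, LengthError, ParameterError
from .preprocessing import downsample, smooth_recording
from .recordings import HandRecording

#: default trim of each test block, seconds (guards against autocorrelation)
DEFAULT_TRIM_S = 10.0
DEFAULT_FOLDS = 10


@dataclass
class VarianceCurve:
    """Cumulative fraction of variance explained per component count."""

    cumulative: np.ndarray

    def components_for(self, fraction: float) -> int:
        """Smallest component count whose cumulative fraction reaches ``fraction``."""
        return int(np.searchsorted(self.cumulative, fraction) + 1)


@dataclass
class DofEstimate:
    method: str  # "eigenvector" | "em_imputation"
    press: np.ndarray  # PRESS(k) for k = 1..kmax
    optimal_k: int
    folds: int
    trim: int
    converged: bool = True


@dataclass
class CombinedDof:
    eigenvector: DofEstimate
    em_imputation: DofEstimate
    combined_dof: float  # mean of the two optimal_k values


def pca_variance_curve(data: np.ndarray) -> VarianceCurve:
    """Cumulative explained-variance fractions of the (internally centered) data."""
    data = np.asarray(data, dtype=float)
    if data.shape[0] < 2:
        raise LengthError("need at least two samples")
    centered = data - data.mean(axis=0)
    cov = centered.T @ centered / (len(centered) - 1)
    eigvals = np.linalg.eigvalsh(cov)[::-1]
    eigvals = np.clip(eigvals, 0.0, None)
    total = eigvals.sum()
    if total <= 0:
        raise DegenerateDataError("zero total variance")
    return VarianceCurve(cumulative=np.cumsum(eigvals) / total)


def chronological_folds(
    n: int, folds: int = DEFAULT_FOLDS, trim: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Contiguous, disjoint, time-ordered test blocks tiling [0, n).

    Each test block loses ``trim`` samples at both ends; the training set is
    the complement of the *untrimmed* block, so trimmed samples are used
    nowhere in that fold.
    """
    if folds < 2:
        raise ParameterError("need at least two folds")
    if n < folds * (2 * trim + 1):
        raise LengthError(
            f"n={n} too small for {folds} folds with trim={trim}"
        )
    blocks = np.array_split(np.arange(n), folds)
    out = []
    for block in blocks:
        test = block[trim: len(block) - trim] if trim else block
        train = np.concatenate([np.arange(block[0]), np.arange(block[-1] + 1, n)])
        out.append((train, test))
    return out


def _argmin_parsimonious(press: np.ndarray, data_ss: float, rtol: float = 1e-9) -> int:
    """Smallest k whose PRESS is numerically indistinguishable from the minimum.

    ``data_ss`` (total sum of squares of the data) sets the scale: on
    noiseless rank-k data every PRESS at or beyond the true rank is a
    rounding-level residual, and all of them count as tied, implementing the
    break-toward-smaller-k (parsimony) convention.
    """
    lo = press.min() * (1.0 + rtol) + rtol * data_ss
    return int(np.flatnonzero(press <= lo)[0]) + 1


def _train_loadings(train: np.ndarray, kmax: int) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvectors (columns, descending eigenvalue order) of the train covariance."""
    cov = train.T @ train / (len(train) - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    return eigvecs[:, order[:kmax]], eigvals[order]


def cv_press_eigenvector(
    data: np.ndarray,
    folds: int = DEFAULT_FOLDS,
    kmax: int | None = None,
    trim: int = 0,
) -> DofEstimate:
    """Row-deleted projection PRESS (eigenvector method)."""
    data = np.asarray(data, dtype=float)
    n, d = data.shape
    kmax = d - 1 if kmax is None else kmax
    if not 1 <= kmax < d:
        raise ParameterError(f"kmax must be in [1, {d - 1}], got {kmax}")
    press = np.zeros(kmax)
    for train_idx, test_idx in chronological_folds(n, folds, trim):
        mean = data[train_idx].mean(axis=0)
        xtr = data[train_idx] - mean
        xte = data[test_idx] - mean
        loadings, _ = _train_loadings(xtr, kmax)
        for k in range(1, kmax + 1):
            v = loadings[:, :k]
            for j in range(d):
                w = np.delete(v, j, axis=0)  # (d-1, k)
                gram = w.T @ w
                rhs = w.T @ np.delete(xte, j, axis=1).T  # (k, n_test)
                try:
                    cond = np.linalg.cond(gram)
                    if not np.isfinite(cond) or cond > 1e12:
                        raise np.linalg.LinAlgError
                    scores = np.linalg.solve(gram, rhs)
                except np.linalg.LinAlgError:
                    warnings.warn(
                        f"ill-conditioned reduced projection at k={k}, coord {j}; "
                        "ridge fallback applied",
                        stacklevel=2,
                    )
                    ridge = 1e-10 * float(np.trace(gram)) * np.eye(k)
                    scores = np.linalg.solve(gram + ridge, rhs)
                pred_j = v[j] @ scores
                press[k - 1] += float(np.sum((xte[:, j] - pred_j) ** 2))
    return DofEstimate(method="eigenvector", press=press,
                       optimal_k=_argmin_parsimonious(press, float(np.sum(data ** 2))),
                       folds=folds, trim=trim)


def _speckle_missing(test_idx: np.ndarray, sub_round: int, d: int) -> np.ndarray:
    """Column index deleted for each test row in this sub-round."""
    return (np.arange(len(test_idx)) + sub_round) % d


def _em_impute(
    x: np.ndarray,
    rows: np.ndarray,
    cols: np.ndarray,
    k: int,
    tol: float,
    max_iter: int,
    init: np.ndarray | None = None,
) -> tuple[np.ndarray, bool]:
    """Iterative EM-PCA imputation of the entries (rows, cols) of centered x.

    Alternates an exact E-step with a PCA M-step: given the current k
    leading eigenvectors V, a row with its single coordinate j missing is
    imputed by the self-consistent rank-k reconstruction

        x_j = sum_{l != j} (V V^T)_{jl} x_l / (1 - (V V^T)_{jj}),

    then V is re-fit on the imputed matrix. Stops when the imputed entries
    change by less than ``tol`` relative to the data scale, or when the
    change has stalled (limit cycle in a degenerate eigen-direction): the
    last iterate is then used and the cell is flagged unconverged.

    The Gram matrix is maintained incrementally as imputed entries change
    (one rank-style update per iteration) and re-synchronized periodically
    against floating-point drift.
    """
    work = x.copy()
    work[rows, cols] = 0.0 if init is None else init
    scale = float(np.sqrt(np.mean(x ** 2) * len(rows))) + 1e-300
    col_groups = [(c, rows[cols == c], np.flatnonzero(cols == c))
                  for c in np.unique(cols)]
    gram = work.T @ work
    denom_n = len(work) - 1
    new_vals = work[rows, cols].copy()
    prev_change = np.inf
    stall = 0
    for it in range(max_iter):
        if it and it % 64 == 0:
            gram = work.T @ work
        eigvals, eigvecs = np.linalg.eigh(gram / denom_n)
        v = eigvecs[:, np.argsort(eigvals)[::-1][:k]]
        for c, grp_rows, grp_pos in col_groups:
            w = work[grp_rows] @ v - np.outer(work[grp_rows, c], v[c])
            p_cc = float(v[c] @ v[c])
            new_vals[grp_pos] = w @ v[c] / max(1.0 - p_cc, 1e-12)
        old_vals = work[rows, cols]
        delta = new_vals - old_vals
        change = float(np.linalg.norm(delta)) / scale
        # Gram update: G += X_old^T D + D^T X_old + D^T D, D sparse at (rows, cols)
        for c, grp_rows, grp_pos in col_groups:
            u = work[grp_rows].T @ delta[grp_pos]
            gram[:, c] += u
            gram[c, :] += u
            gram[c, c] += float(delta[grp_pos] @ delta[grp_pos])
        work[rows, cols] = new_vals
        if change < tol:
            return new_vals.copy(), True
        stall = stall + 1 if change > 0.99 * prev_change else 0
        if stall >= 10:
            break
        prev_change = change
    return new_vals.copy(), False


def cv_press_em(
    data: np.ndarray,
    folds: int = DEFAULT_FOLDS,
    kmax: int | None = None,
    trim: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> DofEstimate:
    """Speckled-deletion EM-imputation PRESS."""
    data = np.asarray(data, dtype=float)
    n, d = data.shape
    kmax = d - 1 if kmax is None else kmax
    if not 1 <= kmax < d:
        raise ParameterError(f"kmax must be in [1, {d - 1}], got {kmax}")
    press = np.zeros(kmax)
    all_converged = True
    for train_idx, test_idx in chronological_folds(n, folds, trim):
        mean = data[train_idx].mean(axis=0)
        x = data - mean
        for sub_round in range(d):
            cols = _speckle_missing(test_idx, sub_round, d)
            truth = x[test_idx, cols].copy()
            init = None
            for k in range(1, kmax + 1):
                imputed, ok = _em_impute(x, test_idx, cols, k, tol, max_iter, init=init)
                all_converged &= ok
                init = imputed  # warm start the next k
                press[k - 1] += float(np.sum((imputed - truth) ** 2))
    if not all_converged:
        warnings.warn("EM imputation hit max_iter in at least one cell; "
                      "last iterate used", stacklevel=2)
    return DofEstimate(method="em_imputation", press=press,
                       optimal_k=_argmin_parsimonious(press, float(np.sum(data ** 2))),
                       folds=folds, trim=trim, converged=all_converged)


def effective_dof(
    rec: HandRecording,
    folds: int = DEFAULT_FOLDS,
    trim_s: float = DEFAULT_TRIM_S,
    kmax: int | None = None,
    downsample_factor: int = 1,
    smoothed: bool = True,
) -> CombinedDof:
    """Combined effective-dof estimate for a hand recording.

    Runs both CV-PCA methods with tenfold chronological cross-validation and
    a 10 s trim at each end of every test block; the combined estimate is the
    mean of the two optimal component counts. ``downsample_factor`` decimates
    the (smoothed) positions first — the trim is re-expressed in decimated
    samples.
    """
    work = smooth_recording(rec) if smoothed else rec
    data = downsample(work.as_matrix(), downsample_factor)
    rate = rec.sampling_rate / downsample_factor
    trim = int(round(trim_s * rate))
    eig = cv_press_eigenvector(data, folds=folds, kmax=kmax, trim=trim)
    em = cv_press_em(data, folds=folds, kmax=kmax, trim=trim)
    return CombinedDof(
        eigenvector=eig,
        em_imputation=em,
        combined_dof=(eig.optimal_k + em.optimal_k) / 2.0,
    )
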