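# Methods

This note records the models implemented in `polyhand`, the conventions
chosen where the analysis protocol left the details open, the synthetic-data
generators' assumptions, and the numerical choices that matter.

## Recordings and preprocessing

Motion capture delivers, per finger, two sensors (distal and proximal
phalanx) with 3-D positions in cm at 120 Hz, expressed relative to a
reference sensor on the metacarpals. Sensor orientations are accepted on
input but ignored: every analysis uses positions only. Forces are sampled at
128 Hz, organized as instructed-finger trials at maximal force (MF) or
10/20/30 % of MF (15 s holds).

Positions are smoothed with a Savitzky-Golay filter (3rd order, 41 samples =
341.67 ms at 120 Hz); velocities come from the same filter's first
derivative, scaled to cm/s. Edges are fitted on the available one-sided
window (scipy's `interp` mode) and the first/last 20 samples are flagged as
edge region; interior-sensitive checks exclude them. Decimation to 6 Hz
(factor 20, keeping indices 0, 20, 40, ...) follows smoothing, with no extra
anti-alias stage: the smoother is the only low-pass step of the protocol,
and the generators put all signal content below 2 Hz.

Spherical coordinates of the distal sensor relative to its proximal sensor
use polar angle from the +z axis of the reference frame and azimuth
`atan2(y, x)`. The axis convention is arbitrary; everything downstream is
either invariant to it (distances, speeds) or symmetric under it (the angle
PCA below).

## Force analyses

* **MF** per finger = maximum of the 250 ms moving-average force over that
  finger's MF trials. The moving average stops single-sample spikes from
  defining MF; on a plateau of tied maxima the peak index is the plateau
  midpoint.
* **Enslaving** `e_ij = F_j(i) / (level * MF_j)`. F_j(i) is read out as the
  mean force over a 500 ms window centered on the instructed finger's
  smoothed peak for MF trials; for submaximal holds it is the mean over the
  stable window (samples 1300..1800 at 128 Hz, the same window used for
  force variability), because centering a window on the noise-selected
  "peak" of a constant hold biases the instructed finger's own read-out
  upward by 1-3 %. Replicates are combined by the arithmetic mean; the MF
  diagonal is 1 by construction. Known property: the *diagonal* of
  submaximal matrices still inherits the upward bias of the MF estimate
  (max-of-smoothed-noise, about +2 % at noise coefficient 0.05), so
  submaximal diagonals are accurate to ~0.03 while all off-diagonals recover
  to <0.01.
* **Variability** = sample SD of the instructed finger's force over samples
  1300..1800. **Exclusion**: within each (finger, level) cell of at least
  three trials, a trial is dropped iff its window SD exceeds 3x the cell
  median — the operational form of "extraordinarily high fluctuations";
  the factor 3 is a convention, validated only by not firing on clean
  synthetic sessions.

## Kinematic dependence

Gaussian MI uses unbiased sample covariances of the mean-centered 6-D
signals at the native 120 Hz, smoothed by default (a switch exposes the raw
variant; population-recovery tests use raw signals so the closed-form oracle
is exact). If the joint covariance's smallest eigenvalue is at or below
1e-12 of the mean diagonal the signals are declared linearly dependent; if
it is positive but below 1e-8 of the mean diagonal a ridge of that size is
added before the determinants (motion data are near-collinear). The ridge is
applied to the joint matrix and its marginal blocks consistently, so the
univariate determinant form still agrees with the `1/(1-r^2)` closed form to
1e-9 on well-conditioned data. Estimates are clipped at zero (Fischer's
inequality guarantees non-negativity up to rounding).

Prediction regresses each of the target finger's 6 dimensions on the
concatenated signals of the remaining fingers (24- or 30-dim predictors) at
6 Hz, with twofold chronological cross-validation (split at floor(n/2), both
directions) and R^2 = 1 - SSE/SST about the test-set mean, averaged over
dimensions and folds. A test-constant dimension is dropped with a warning.
The kernel method is epsilon-SVR with a Gaussian kernel; kernel width in
{0.1, 0.3, 1, 3, 10} x median pairwise predictor distance and regularization
C in {0.1, 1, 10, 100}, selected by an inner twofold chronological split of
the training fold only. Predictors and target are z-scored on the training
fold. The fixed grid trades a little accuracy for reproducibility.

## Effective degrees of freedom

Both PRESS procedures use chronological folds: contiguous test blocks tiling
the series, each trimmed by 10 s at both ends (the trim is excluded from
train and test in that fold) against leakage through autocorrelation;
centering uses the training-fold mean.

* **Eigenvector method**: loadings from the training covariance; held-out
  coordinate j of each test sample is predicted by least-squares projection
  of the remaining coordinates onto the k-dim loading subspace with row j
  removed. An ill-conditioned reduced Gram matrix (condition > 1e12) falls
  back to a ridge of 1e-10 x trace with a warning.
* **EM-imputation method**: speckled deletion — in sub-round r, test row i
  loses coordinate (i + r) mod d, so each test sample contributes each
  coordinate exactly once across the d sub-rounds. Missing entries are
  imputed by EM-PCA: an exact E-step (the self-consistent rank-k
  reconstruction of a single missing coordinate has a closed form) and a
  PCA M-step on the imputed matrix, iterated to relative tolerance 1e-6
  (with respect to the data scale) or max_iter 500; a stalled iteration
  (limit cycle in a degenerate eigen-direction) exits early, flagged
  unconverged, and the last iterate is scored. The Gram matrix is updated
  incrementally and re-synchronized every 64 iterations.

PRESS(k) is the total squared prediction error over folds and elements.
The argmin uses a numerical-tie rule: any k whose PRESS is within 1e-9
(relative, and relative to the data's total sum of squares) of the minimum
counts as tied, and the smallest wins — on noiseless rank-k data all
PRESS values at or beyond k are rounding residue, and parsimony picks k.
Note that the row-deleted PRESS is invariant under signed coordinate
permutations but *not* under general rotations: the per-coordinate residual
weights 1/(1 - P_jj)^2 are axis-dependent. The combined estimate is the mean
of the two methods' optima (possibly half-integer).

For the presets the dof analysis runs at 6 Hz (the same decimation as the
prediction analysis); 300 s of recording then gives 1800 samples against 30
or 36 dimensions with kmax = 12, which tenfold CV handles comfortably. This
is the package's desk-scale choice of problem size, stated here once; the
recovery benchmark (n = 5000, 10 dims, SNR 10, fivefold, kmax 9) likewise.

## Movement-state entropy and coactivation

Per finger: spherical angles of distal vs proximal sensor; PCA on the
mean-centered (polar, azimuth) pair without variance scaling (both radians);
first-PC scores; v = one-sample difference; threshold mu = mu_factor x SD(v)
with mu_factor 0.3 by default (0.1/0.4 and a two-state variant, flexion
v < 0 vs extension v > 0, are exposed as sensitivity switches). The first
sample is dropped so all fingers align. The PCA sign is arbitrary, which at
most swaps the flexion/extension labels; every downstream statistic is
label-symmetric (tested). A zero-variance angle series is a stationary
finger: scores are zero and every sample classifies as rest, with a warning.

Joint entropy is the plug-in estimate over the subset's state tuples, no
bias correction, with a warning when fewer than 10 x 3^n samples are
available. Curves add fingers in the order T, I, M, R, L, S.

A finger is "moving" when its fingertip speed (norm of the distal sensor's
SG velocity) strictly exceeds the pooled 10th/30th/50th percentile across
all fingers and samples; ties rest. Coactivation conditions on the
supernumerary finger moving and reports P(T and I), P(T only), P(I only) —
disjoint events; "thumb only" means thumb moving and index not.

## Behavioral statistics

Localization error is the mean 2-D Euclidean distance between reported and
true grid points, per landmark / per finger / overall. Learning curves are
OLS fits of level against cumulative practice hours. The slope comparison
resamples each condition's (time, level) events with replacement, refits,
and takes p = 2 min(P(diff* <= 0), P(diff* >= 0)), floored at 1/n_boot;
degenerate replicates are discarded and counted. Wilcoxon rank-sum reports
W = rank sum of the first (six-fingered) sample with midranks; p is exact
(scipy's enumeration) for combined n <= 12 without ties, else the
tie-corrected normal approximation with continuity correction. The
signed-rank W is the positive-rank sum, exact for n <= 12 after dropping
zero differences. Confidence intervals are pooled-variance or paired
t-intervals on mean(six) - mean(five); a zero-variance interval degenerates
to a point with a warning.

## Synthetic generators

The generators define the study conditions; all tests and the acceptance
script run exclusively on them.

* **Hands**: k latent sources — white noise low-passed at 2 Hz (4th-order
  Butterworth, forward-backward) — mixed linearly into sensor space plus
  isotropic Gaussian noise, 120 Hz, 300 s by default. Sources are
  sample-whitened (exactly unit covariance), so the noise-free sample
  covariance equals the mixing Gram matrix and population MI / latent rank
  are exact oracles rather than asymptotic ones. Each finger's distal rows
  are 1.3x its proximal rows plus a small perturbation: the sensors co-move
  as real phalanges do, keeping the distal-proximal vector away from zero so
  spherical angles never wrap. The noise SD of 0.25 cm stands for
  measurement noise plus idiosyncratic per-finger movement outside the
  shared synergies; electromagnetic-tracker noise alone (~5e-4 cm) would
  make the mixture nearly deterministic and every pairwise MI implausibly
  large. Presets: five-fingered = 4 shared sources (whole-hand, thumb,
  index/middle, ring/little); six-fingered adds a supernumerary finger with
  one private source and a weak (0.4) loading on the thumb source — some
  dependence on the thumb, none elsewhere — plus presets with all-shared
  sources (every finger linearly reconstructable) and with fully private
  sources (zero inter-finger MI) for the prediction and MI contracts.
* **Forces**: instructed finger follows a 1 s half-cosine rise to its
  target, then holds; finger j tracks `E*_ij (f_i(t)/MF_i) MF_j`, so E* is
  exactly the enslaving matrix the analysis should recover; noise SD is
  c x instantaneous mean force (signal-dependent, c = 0.05 by default).
  Default E* is anatomically structured: decaying with inter-finger
  distance, supernumerary couplings halved except toward the thumb,
  identical common-finger blocks across hand sizes, ±0.02 per-subject
  jitter. One MF trial per finger; three replicates per submaximal level
  (3 x 3 x 5 = 45 submaximal trials for a five-fingered session).
* **Localization**: reported = true + isotropic 2-D Gaussian error (mean
  error sigma sqrt(pi/2)); 3 landmarks per finger, 18 for six fingers.
* **Game logs**: level at a checkpoint = 1 + slope x hours + Gaussian noise
  (SD 1 level), rounded, floored at 1, non-decreasing within a day;
  schedule = five consecutive days plus day 15, one hour per day. The
  default log records one checkpoint per practice hour (the day's final
  level), making checkpoint noise independent across events — finer
  within-day logging is available, but then the monotonicity constraint
  correlates events and the event-resampling bootstrap becomes
  anti-conservative, which is why day-end logging is the default.

All generators are pure functions of (spec, seed) and bit-reproducible.

## What the synthetic tests do and do not show

Passing parameter-recovery tests shows the estimators are correct under the
generators' assumptions: linear mixing of band-limited Gaussian sources,
stationarity, instantaneous coupling, signal-dependent but white force
noise, and iid event noise in the game logs. Real hand data violate several
of these — nonstationary task structure, non-Gaussian movement
distributions, temporally structured noise, within-day performance
dependence — so the tests validate the machinery, not the empirical claims
about real hands. The qualitative six- vs five-fingered contrasts (one
extra effective dof, higher movement-state entropy, thumb+index-dominant
coactivation of the supernumerary finger) hold by construction of the
presets and demonstrate the pipeline's end-to-end sensitivity to them.

## Known limitations

* Gaussian MI captures only second-order dependence; the discretized
  entropy analysis is the nonlinear complement, and no k-NN/binned MI
  estimator is provided.
* Effective sample sizes are not autocorrelation-corrected; consistency
  tolerances in the tests account for slow signals instead.
* The exact deletion pattern of the EM CV-PCA and the 500 ms/stable-window
  force read-outs are conventions; the recovery tests pin their behavior.
* Plug-in entropy is biased low in small samples (warned, not corrected).
* HDF5 support covers hand recordings only; CSV is the primary dialect.
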