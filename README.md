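# polyhand

Quantitative analysis of multi-finger hand function, built around the
question of what an extra finger buys its owner: does a congenital
supernumerary finger (SF) act as a mere duplicate, or does it add an
independent, fully controllable degree of freedom to the hand?

The package implements the complete analysis chain for four kinds of
recordings — isometric finger forces, motion-capture hand kinematics, 2-D
finger-localization pointing, and video-game practice logs — together with
synthetic-data generators that emulate each of them with known ground truth,
because recordings of polydactyly subjects cannot be shared without
compromising their anonymity. Every estimator is validated by parameter
recovery against those generators.

## The quantities at the core

**Force enslaving.** With finger *i* instructed to produce its maximal force
MF_i, the involuntary force of finger *j* defines the enslaving matrix

    e_ij = F_j(i) / MF_j ,

with the denominator replaced by `level * MF_j` for 10/20/30 % MF holds.

**Gaussian mutual information.** Each finger is a 6-D signal (x, y, z of its
distal and proximal sensors). Dependence between fingers X and Y is

    I(X, Y) = 1/2 log2[ det(S_X) det(S_Y) / det(S_XY) ]   (bits),

which for univariate signals reduces to `log2 sqrt(1 / (1 - r^2))`.

**Effective degrees of freedom.** PRESS-based cross-validated PCA with
chronological folds, by two procedures: row-deleted eigenvector projection
(each held-out coordinate predicted from the sample's other coordinates) and
speckled-deletion EM imputation. The PRESS-minimizing component count k is
the estimate; the two methods' optima are averaged.

**Movement-state entropy.** Each finger's movement collapses to the first
principal component of its distal-vs-proximal spherical angles; the
one-sample derivative v is thresholded at mu = 0.3 SD(v) into
{rest, flexion, extension} and the joint Shannon entropy
`H = -sum p(s) log2 p(s)` over the 3^n state tuples measures the richness of
the movement repertoire (maximum n log2 3).

**Behavioral statistics.** Finger-localization error (2-D Euclidean),
OLS learning slopes of game level vs practice hours with an event-resampling
bootstrap comparison, two-sided Wilcoxon tests (exact for small tie-free
samples), pooled/paired t-intervals with the six-minus-five sign convention,
and Pearson correlations.

## Worked example

```python
>>> from polyhand import synthetic as syn, dimensionality as dim, entropy as ent
>>> rec6, truth = syn.simulate_hand(syn.six_finger_spec(seed=1))   # 300 s at 120 Hz
>>> d = dim.effective_dof(rec6, downsample_factor=20, kmax=12)
>>> d.eigenvector.optimal_k, d.em_imputation.optimal_k, truth.latent_dof
(5, 5, 5)
>>> round(ent.joint_entropy(ent.discretize_states(rec6), rec6.fingers).bits, 3)
9.155
```

The numbered drivers under `analysis/` run the full narrative and write
tables under `results/`. For example `python analysis/03_degrees_of_freedom.py`
prints

```
six-fingered hand: true latent dof 5, eigenvector 5, EM 5, combined 5.0
  components for 90% variance: 4
five-fingered hand: true latent dof 4, eigenvector 4, EM 4, combined 4.0
  components for 90% variance: 4
six minus five combined dof: +1.0
```

— both cross-validated PCA procedures recover the generating dimensionality,
and the six-fingered hand carries one extra effective degree of freedom.
`python analysis/04_movement_entropy.py` shows the corresponding
information-theoretic contrast (9.15 bits vs 7.52 bits, the former above the
7.92-bit theoretical cap of any five-fingered hand) and the coactivation
profile of the supernumerary finger (thumb + index moving together dominate
whenever the SF moves). `01`, `02`, `05` and `06` cover forces, kinematic
dependence, behavior, and the group comparison.

## Layout

```
src/polyhand/      library: io, preprocessing, forces, independence,
                   dimensionality, entropy, stats, synthetic, pipeline
analysis/          numbered narrative drivers (write results/*.csv)
scripts/           acceptance.py (see above)
tests/             pytest suite, including end-to-end property checks
docs/methods.md    models, conventions, parameter choices, limitations
```
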