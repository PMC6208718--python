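# Methods

## Forward model and its surrogate

The package works with the standard potential-based formulation of the
inverse problem of electrocardiography: body-surface potentials are a
linear, instantaneous image of epicardial potentials, Φ_B = A Φ_H + N,
with i.i.d. Gaussian measurement noise. In experimental work A comes from
a CT-derived torso–heart geometry and a boundary-element solve; here the
synthetic generator replaces it with an *infinite-homogeneous-medium
monopole kernel*: entry (i, j) ∝ 1/(4π σ d_ij) with d_ij the Euclidean
distance from torso electrode i to heart node j, followed by row
normalization (each row sums to 1, so a uniform epicardial potential maps
to the same uniform body-surface potential). This surrogate keeps the
properties the inverse methods are sensitive to — linearity,
instantaneity, smoothing, and severe ill-conditioning (condition number
≈ 1.2 × 10⁴ for the 30/40-node test geometry, larger for the 99/192
configuration) — at a small fraction of the engineering cost of a BEM
solver. It does not model torso inhomogeneities, cardiac motion, or
non-epicardial sources; conclusions about those effects cannot be drawn
from this test bed.

Geometries are concentric spheres with quasi-uniform Fibonacci-lattice
nodes (heart triangulated by its convex hull, a valid sphere mesh), with
a seeded random rotation per surface. Radii default to 30 mm (heart) and
120 mm (torso). With very few torso nodes the hull containment of the
heart requires a torso several times larger than the heart (a 4-vertex
hull has inradius ≈ ⅓ of its circumradius).

## Synthetic beats

A paced beat propagates from a pacing node over the heart-mesh edge graph
at constant conduction velocity `cv`; the activation time of node j is
the geodesic (Dijkstra) distance divided by `cv`. Recovery follows after
an action-potential duration `apd_base` plus a smooth spatial dispersion
field (sum of three seeded Gaussian radial-basis bumps, rescaled to peak
magnitude `apd_dispersion`). Each electrogram is a difference-of-tanh
template

    Φ_j(t) = −(amplitude/2) [tanh((t − AT_j)/w_d) − tanh((t − RT_j)/w_r)]

chosen so that the maximum negative slope is analytically at AT_j and the
maximum positive slope at RT_j — this closes the loop between the
simulator and the slope-based timing estimators, which is the test bed's
central self-consistency property. Measurement noise is added at a target
SNR in dB (noise variance = signal power / 10^(SNR/10)); a zero-power
signal falls back to an absolute noise SD of 0.01 mV rather than dividing
by zero.

Package defaults are physiological full-scale values: 1000 Hz sampling,
512 ms records (length divisible by 2³ for the 3-level stationary
transform), APD 250 ms, conduction velocity 0.8 mm/ms, 20 dB SNR. The
test suite and the acceptance script run a scaled-down frozen study —
30 heart nodes / 40 electrodes, 256 ms beats, APD 100 ms, dispersion
10 ms, cv 1 mm/ms, SNR 20 dB, pacing node (7·seed mod q) — so the whole
suite completes in minutes on one CPU. What these beats emulate:
propagating wavefront structure, dispersed recovery, white measurement
noise. What they do not: fractionation, multi-deflection far-field
morphology, baseline wander, correlated electrode noise, beat-to-beat
variability. Passing tests therefore demonstrate correctness of the
machinery and the *direction* of method differences, not clinical
accuracy on real electrograms.

## Wavelet transforms

The orthogonal discrete wavelet transform with periodized boundaries is
exposed in matrix form (`dwt_matrix`): W is orthogonal, W⁻¹ = Wᵀ, and
Parseval holds exactly; signal lengths must divide by 2^levels. The
working transform is the *stationary* (undecimated) wavelet transform,
applied row-wise: redundant by a factor levels+1, shift-equivariant, with
exact reconstruction by the canonical average-of-shifts inverse. With an
orthogonal filter pair the undecimated band energies grow by a factor 2^j
with scale coarseness (a constant signal's approximation band carries
2^N × the signal energy). Default wavelet: Daubechies-2 (two vanishing
moments, filter length 4); default depth: 3 levels. Band layout is
coarsest-first: [a_N | d_N | … | d_1]. Inputs whose length does not
divide 2^N are padded by periodic extension, and the original length is
recorded so inversion truncates exactly. No per-band 2^j reweighting is
applied inside the penalty by default; a per-column `band_weights` vector
is exposed for the column-grouped variant, where each group is a single
column and the weighted proximal step stays exact.

## Reconstruction engines

All objectives are implemented exactly as written below — no 1/(2n) loss
factor. To cross-check against packaged solvers (scikit-learn, glmnet)
use `alpha_pkg = λ/(2r)` and `l1_ratio = α`, where r is the electrode
count.

* **Tikhonov** (reference): min ‖AP − B‖_F² + λ‖P‖_F², closed form via
  the SVD of A for all time samples simultaneously; λ = 0 gives the
  minimum-norm least-squares solution.
* **Columnwise elastic net**: m decoupled problems
  min ‖Aw − b_k‖² + λ[(1−α)½‖w‖² + α‖w‖₁], solved by cyclic coordinate
  descent with soft thresholding and a KKT residual check at exit.
* **Multitask group elastic net**: min ‖AP − B‖_F² + λ[(1−α)½‖P‖_F² +
  α Σ_g ‖P_g‖₂]. Two group structures are supported, because the column
  sum of ℓ2 norms (the literal mixed-norm penalty) makes the problem
  separable per column, while the coupling that standard multitask
  solvers implement groups the rows (one group per heart node, a node's
  whole coefficient vector). The default is `node-rows`; the literal
  column variant is one flag away (`grouping="coefficient-columns"`).
  Solver: accelerated proximal gradient (FISTA) on the smooth quadratic
  + ridge part with block soft-thresholding prox, step 1/L with L from
  deterministic power iteration on AᵀA, zero initialization, and a
  monotone restart (an increase triggers a plain proximal step from the
  best iterate and a momentum reset), so the recorded objective trace is
  non-increasing by construction. Stopping: relative objective change
  below `tol` (default 1e-8, 10⁴ iteration cap); non-convergence flags
  the result rather than raising. Degenerate groups stay at zero unless
  the gradient block norm exceeds λα (the subgradient condition);
  `lambda_max` computes the smallest λ with an all-zero solution.
* **Wavelet elastic net** (the full pipeline): SWT of each body-surface
  electrogram → multitask elastic net on the coefficients → inverse SWT.

Predictors are never standardized. The engines are scikit-learn style
estimators (`fit(A, Φ_B)`, `coef_`/`phi_h_`, `get_params`); the
functional wrappers return a `ReconstructionResult` with the estimate,
the sparse coefficients, the objective trace, iteration count,
convergence flag and the data mismatch in microvolts (potentials are mV
internally; mismatch reporting converts to µV).

Solver accuracy: on small random instances the FISTA path agrees with
independent solvers (scikit-learn coordinate descent after the λ
conversion above; a closed-form SVD + scalar-root-finding solution of the
separable single-group problems) to ~10⁻¹⁴ relative objective at tight
tolerance; the test suite asserts 10⁻⁶.

## Post-processing

Activation time = argmin of the smoothed electrogram derivative inside
the depolarization (QRS) window; recovery time = argmax inside the
repolarization (T-wave) window; ties take the earliest instant. The
derivative comes from a cubic smoothing spline fitted per electrogram,
with the penalty chosen by generalized cross-validation by default
(overridable; 0 = interpolating natural spline, exact for linear trends).
Windows are supplied explicitly — in the synthetic study from ground
truth as [0, split] and [split, end] with split midway between the last
activation and the first recovery; automatic beat segmentation is out of
scope. The pacing origin is the node of earliest activation, ties broken
by lowest index. Detected times always lie inside their windows, and
detections are invariant to baseline offsets and positive amplitude
scaling.

## Evaluation and parameter selection

Metrics: Pearson CC per electrogram over time; spatial CC per instant;
Pearson r of activation and recovery timing maps (pooled over beats);
Euclidean pacing localization error; data mismatch = entrywise RMS of
AΦ̂_H − Φ_B in µV (pooling across beats is entrywise RMS per beat, then
averaged). Zero-variance pairs are flagged as undefined, never silently
dropped; in mean-CC summaries undefined pairs count as 0 (a flat
reconstruction explains nothing).

The (α, λ) plane is searched exhaustively on mean data mismatch over a
beat set. Because the mismatch is monotone in λ for fixed α, its raw
argmin degenerates to the smallest λ on the grid; the grid search
therefore also reports a reproducible *operating point*: among cells
within a factor 1.1 of the minimum mismatch, the smallest α, then the
lowest mismatch. For method comparisons on synthetic data (where ground
truth exists) each arm is instead tuned by mean electrogram CC over a
frozen λ grid (wavelet-EN: 13 points log-spaced 10⁻³…10¹; Tikhonov: 16
points 10⁻⁵…10⁰) — the strongest fair baseline; `selection="mismatch"`
remains the default for truth-free use. Paired per-beat deltas are
reported alongside each arm's distribution summary (median, IQR).

On the frozen study this comparison shows a small but consistent CC
advantage for the wavelet-domain elastic net with node-row grouping and a
clear advantage (≈ +0.05 CC) for the column-grouped variant, whose
per-coefficient shrinkage also yields the lower entrywise ℓ1 norm in the
sparsity comparison. The node-row variant's shrinkage acts on whole node
rows and does not reduce entrywise coefficient ℓ1 below the Tikhonov
level on these very smooth synthetic electrograms; the sparsity
comparison is therefore defined with the column-grouped penalty, the one
that acts on exactly the measured magnitudes.

## Numerical choices and limitations

* Deterministic everywhere: all randomness flows through integer seeds;
  grid searches are bit-reproducible.
* λ = 0 Tikhonov uses a relative singular-value cutoff (10⁻¹³ × s_max)
  for the pseudoinverse.
* The SWT operator is never materialized as a matrix (it would be
  m × (N+1)m); the solver only ever needs A, because the unknown is the
  coefficient matrix itself.
* Known limitations: the monopole surrogate understates the geometric
  complexity of real transfer operators; the smooth tanh electrograms
  favor any smoothing regularizer, so absolute CC levels here (~0.89)
  exceed experimental values and method differences are compressed;
  localization error on the 30-node test mesh is bounded below by its
  ~20 mm internode spacing; recovery-time estimation inherits the
  T-wave window choice.
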