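# Methods

`megenum` estimates the number of simultaneously active equivalent current
dipoles (ECDs) in MEG sensor data by a sequential F-ratio procedure built on
Alternating-Projections (AP) least-squares dipole fitting. This note
documents the model, the algorithms, the synthetic-data generator, the
numerical choices, and the known limitations.

## Measurement model

An array of M sensors observes

    y(t) = Σ_{q=1..Q} l(p_q) s_q(t) + n(t),    Q < M,

where l(p) = L(p)·o is the topography of a dipole at position p with
orientation o, L(p) ∈ ℝ^{M×3} is the lead field, s_q(t) the amplitude time
course in A·m, and n(t) additive noise. The forward model is the analytic
Sarvas solution for a current dipole inside a homogeneous conducting
sphere, with the sphere center at the origin of a right-handed head frame
(SI units throughout). Magnetometers measure the field along their coil
normal; planar gradiometers are modeled as a two-point finite difference of
the normal field at two virtual coils separated by a 16.8 mm baseline along
the stored channel orientation, divided by the baseline (output in T/m).
Radial dipoles are exactly silent in this model, so every 3-column lead
field block has a numerical null direction that the fitting code removes by
an eigenvalue cutoff (1e-10 relative) rather than by regularization.

The forward implementation is validated against an independent numeric
oracle in the test suite: the Geselowitz surface integral over a
triangulated sphere (5120 faces), with the surface potential obtained by a
spherical-harmonic Neumann solve; agreement is required to better than 1%
(measured ≈0.2%).

## Source-count statistic

For a K-dipole ("reduced") and a (K+1)-dipole ("full") least-squares fit,

    F_{K→K+1} = (SSR_R / DOF_R) / (SSR_F / DOF_F),

the plain ratio of mean residual sums of squares — not the incremental
nested-F form. Residual degrees of freedom are DOF = MN − (3+N)K for
fixed-oriented dipoles and MN − (4+N)K for freely-oriented ones (3 position
parameters, 1 orientation when free, N amplitudes per dipole). Starting
from K = 0 (SSR_R = ‖Y‖²_F, DOF = MN), the reduced model is rejected while
F exceeds a threshold; the first non-rejection gives the estimate q̂.

Two statistical facts shape the implementation:

- **The ratio is not F-distributed under the null.** The two residual sums
  are nested, hence dependent. Comparing the ratio against the nominal
  F(DOF_R, DOF_F) quantile is severely conservative (empirical rejection
  rate ≈ 0 at α = 0.05) — which is why thresholds must be calibrated rather
  than taken from tables. In the one tractable sub-case (nested linear
  models with *known* topographies, amplitude-only fits, DOF = MN − NK) the
  ratio is a monotone map of an exactly F-distributed incremental
  statistic, T = (DOF_F/DOF_R)(1 + F_inc (DOF_R−DOF_F)/DOF_F), and
  `exact_nested_threshold` transforms the F_inc quantile into an exact
  cutoff for T; a Monte-Carlo test confirms the α-level is hit to within
  binomial error. This validates the SSR/DOF machinery end to end.
- **A perfect reduced model stops the sequence.** When SSR_R falls below
  1e-12 of ‖Y‖²_F (possible only for noiseless on-grid constructions; an
  exact least-squares fit bottoms out around 1e-25 relative, while any
  realistic noise floor is ≥1e-6), no additional source is justifiable and
  the step records F = 1. Without this guard the ratio of two
  machine-noise-sized residuals is meaningless.

## AP dipole fitting

`ap_fit` places K dipoles on a candidate grid:

1. **Greedy initialization** — sources added one at a time; each addition
   is an exact one-source scan of the whole grid against the already-placed
   set.
2. **Cyclic coordinate descent** — each source's position re-optimized with
   the others fixed until a sweep changes nothing. In fixed-orientation
   mode an orientation-refresh pass (analytic 3×3 generalized eigensolves)
   follows each sweep, because a position scan holds the *other* sources'
   orientations fixed and can otherwise stall on a stale orientation.
3. **Runner-up polish** — each source restarted from the best few
   alternates of its conditional scan (default 3), the descent re-run, and
   the restart kept only if it strictly lowers the SSR. With multistart
   enabled (`n_starts`), the greedy phase is repeated from the best
   `n_starts` first-source candidates and the few best distinct solutions
   are each polished.

Every accepted step is an exact single-source least-squares scan, so the
SSR never increases; with warm starts (the previous K-fit supplies the
first K−1 sources) the SSR is monotone in K, which the sequential F-test
requires. Ties in any scan break toward the lowest grid index.

The scan itself is algebraic, not iterative: for a candidate block B̃ (the
lead field projected off the placed topographies), the energy explained by
the best single orientation is the top generalized eigenvalue of
(B̃ᵀYᵣYᵣᵀB̃, B̃ᵀB̃) — solved batched over all grid points — and the full
3-column subspace criterion (freely-oriented scanning) is the corresponding
trace. Scans against the same data reuse cached products (Gram blocks
L(p)ᵀL(p) and data products L(p)ᵀF, with F an M×r factor of YYᵀ), so a
conditional scan costs only rank-k corrections. In freely-oriented mode a
fixed orientation per dipole is extracted after convergence as the dominant
left singular vector of its 3×N moment time course, and amplitudes are
refit; `ssr` refers to this rank-1-consistent refit (matching the 4+N
parameter count), while `ssr_subspace` keeps the 3K-column criterion value.

`exhaustive_fit` (K ≤ 2) enumerates all index subsets as a validation
oracle: exact subspace least squares per pair in free mode; in fixed mode
per-pair orientations are solved by a short alternating sequence of the
same analytic orientation optimization (8 rounds). On 100 noiseless
two-dipole problems (32 sensors, ~150-point grid, ≥3 cm separation) AP with
full first-source multistart matches the oracle's index pair 99/100 with
worst SSR ratio 1.0000.

## Synthetic data

The generator reproduces the statistical structure the method is calibrated
under:

- **Waveforms** — cosines with frequency ~ U[10, 30] Hz and phase ~
  U[0, 2π), mean-centered and Gram–Schmidt orthonormalized, then mixed by
  the Cholesky factor of the target correlation matrix. Because the rows
  are exactly orthonormal, the sample Pearson correlations equal the target
  to ~1e-15 — correlation is a controlled factor, not a random one. Default
  RMS amplitude 200 nAm (converted to A·m internally).
- **Noise** — i.i.d. Gaussian per channel, or independent AR(6) processes
  (stability-checked, 500-sample burn-in). The noise matrix is rescaled so
  the Frobenius-norm SNR, 20·log10(‖signal‖_F/‖noise‖_F) dB, equals the
  request exactly. No channel-type-dependent noise scaling is applied;
  spatial whitening is the principled equalizer for mixed-unit arrays.
- **Geometry** — synthetic Fibonacci-spiral arrays on a spherical cap
  (102 positions × [1 magnetometer + 2 orthogonal planar gradiometers] =
  306 channels, or decimated magnetometer-only variants with 32/64
  channels). Simulation and reconstruction grids are a cubic lattice and
  its half-spacing-shifted copy inside the sphere, so they share no point
  (the "inverse crime" is avoided: simulated sources never lie on the
  reconstruction grid). Registration error is emulated by translating the
  reconstruction grid (default ±1 mm) before lead-field computation.
- **Source draws** — positions drawn uniformly from the simulation grid
  *excluding* points whose lead-field norm is below 10% of the grid median:
  the lattice contains the sphere center, where the lead field is exactly
  zero, and a "source" there is invisible to every estimator, making the
  true count unidentifiable by construction. Orientations are random
  tangentials (radial component projected out and renormalized). Minimum
  inter-source separation defaults to 0 (unconstrained); tests that probe
  localization use 3 cm.
- **Phantom-style mixing** — `delayed_mixing` sums single-source recordings
  after independent circular delays of 0–50 ms, emulating multi-source data
  assembled from individually activated dipoles.

What the generator does **not** emulate: realistic brain-noise spectra and
spatial correlation structure, ocular/cardiac artifacts, cortical geometry
(sources live in a volumetric sphere, not on a cortical surface), BEM
forward models, and coil-level field integration. Passing tests therefore
demonstrate the statistical machinery under the stated model, not
performance on recorded MEG.

## Prewhitening

The DOF formulas assume independent data points. For structured noise the
two-step whitening restores approximate independence: per-sensor LPC
coefficients of order 6 are fitted on a pre-stimulus baseline
(Levinson–Durbin on the biased autocorrelation — guaranteed minimum-phase),
averaged across sensors, and applied to the post-stimulus data as an MA
prediction-error filter (the first 6 output samples use zero-padded history
and can be dropped); trials are averaged; then data are multiplied by
(C + λI)^{−1/2} with C the baseline sample covariance and λ = 10% of its
largest eigenvalue. Whitening is applied identically to the lead fields
(W·L(p)) so least squares stays consistent. The DOF formulas are left
unchanged after whitening — the whitening exists precisely to license the
independence assumption behind them. The SNR estimator used for threshold
lookup subtracts per-sample baseline power from per-sample data power
(floored at 1e-12 of data power) and reports 10·log10 of the power ratio,
which equals the amplitude-convention dB of the implied Frobenius ratio.

## Threshold calibration

`optimal_threshold(Q, snr)` simulates `n_reps` datasets per nuisance
setting (correlation set × translation set), computes each repetition's F
sequence once, scores exact-match accuracy (q̂ = Q) for every threshold on
a search grid, and returns the threshold maximizing the accuracy averaged
over settings. Two calibration-design choices matter:

- **Ties break toward the plateau's lower edge.** The accuracy-vs-threshold
  curve has a plateau whose lower edge sits just above the overfitting
  statistic (F at the step past the true order) — a quantity stable across
  correlation levels and across true source counts — while the upper edge
  tracks the weakest sub-Q rejection statistic of the calibration data,
  which is specific to Q = k and does not transfer to data with more
  sources. Since a table column k is applied at step K+1 = k of data whose
  true count is unknown, only the lower edge generalizes.
- **Grid resolution near 1.** With MN-sized DOFs the statistic concentrates
  very near 1, and useful thresholds sit at 1.01–1.3. The default search
  grid is 60 log-spaced points on [1, 50]; threshold-table calibration for
  method comparisons uses a finer grid, log-spaced in (threshold − 1) from
  0.005 to 49, because the coarse grid has no point between 1.0 and 1.07
  and cannot resolve the step-2/3 optima at desk scale.

`build_threshold_table` assembles optimal thresholds over an (SNR, source
count) grid; lookup uses the nearest tested count and linear interpolation
in dB, clamped at the edges. `sequential_enumerate` resolves, at step
K→K+1, the threshold for (estimated SNR, K+1 tested sources). Calibration
runs use a desk-scale geometry — 64 magnetometers, ~500-point
reconstruction grid (12 mm spacing, 60 mm radius), N = 100 samples at
1 kHz, 30–100 Monte-Carlo repetitions per cell — chosen as the package's
working scale for a single-workstation calibration; the procedure is
dimension-agnostic and a full 306-channel configuration is in the geometry
registry. All repetitions are seeded as SeedSequence([scenario_seed, rep]),
so thresholds, accuracy curves, and method comparisons are paired across
settings and bit-reproducible.

Calibrated behavior at this scale reproduces the expected trends: optimal
thresholds increase with SNR, decrease with the number of sources, and are
insensitive (within one search-grid step) to the inter-source correlation
and to ±1 mm registration error.

## AIC and MDL comparators

The eigenvalue criteria operate on λ₁ ≥ … ≥ λ_M of (1/N)YYᵀ:
L(k) = N(M−k)·ln(a_k/g_k) with a_k, g_k the arithmetic/geometric means of
the M−k smallest eigenvalues; AIC(k) = 2L(k) + 2k(2M−k) and MDL(k) = L(k) +
½k(2M−k)·ln N, minimized over k. A closed-form example (λ = (4,1,1,1),
N = 100) pins the constants in a unit test. Two practical behaviors are
worth knowing: AIC's overestimation probability does not vanish with N (its
penalty is O(1) against the fluctuation scale of the tail statistic), so
even in easy uncorrelated settings it misses ~15–20% of cases; and with
strongly correlated sources the second covariance eigenvalue shrinks toward
the noise bulk, so both criteria under-count where the calibrated F-ratio
procedure — which scans topographies rather than eigenvalues — still
detects the second source.

## Numerical choices

- Collinear candidates in a scan (projected block norm < 1e-12 of the
  original) are skipped.
- Scan ties (explained energies within 1e-12 of the data energy of the
  maximum) resolve to the lowest grid index, making all fits deterministic.
- Batched 3×3 eigensolves carry a relative eigenvalue cutoff of 1e-10 for
  block null directions (the radial silent axis).
- Descent convergence: no index change and orientation change < 1e-9, or a
  relative SSR change below 1e-9, with a 10-sweep cap.
- `exhaustive_fit` refuses problems with more than 1e6 subsets.
- Scans depend on the data only through YYᵀ, so recordings longer than M
  samples are compressed to an M×r factor before scanning.
- All randomness flows through `numpy.random.Generator` seeds; every
  simulation function is a pure function of (inputs, seed).

## Limitations

- Spherical-conductor forward model only; no BEM/FEM, no EEG.
- The sequential statistic's null distribution with *estimated* dipole
  positions is unknown; thresholds are strictly empirical and specific to
  the geometry, SNR, data length, and localization settings used in
  calibration (applying a table calibrated under different settings is
  unsupported).
- The early steps of the sequence are variance-explained ratios: for Q
  equal-amplitude sources, F_{0→1} ≈ 1/(1 − captured fraction) is a small
  number (2–12) even with no noise at all, so thresholds far above this
  range under-count regardless of data quality.
- Freely-oriented SSR uses the rank-1 refit; its monotonicity in K is not
  formally guaranteed (the subspace SSR is monotone and is also stored).
- AP is a local search with global-search aids; pathological two-dipole
  geometries can still require full multistart to reach the global optimum.
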