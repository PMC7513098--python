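# Methods

## Model and assumptions

The package models binarized spike trains as stationary ergodic Markov
chains of finite memory.  Stationarity is assumed throughout: empirical
averages are meaningful estimators of stationary expectations only if the
recording's statistics do not drift (no stimulus-locked nonstationarity,
no slow adaptation).  Ergodicity and primitivity of the transfer matrix
are guaranteed by construction as long as every energy coefficient is
finite, which the constructors enforce.

Features are binary spatiotemporal monomials.  The maximal feature range
R sets the chain's memory R−1 and the state space: 2^{N·max(R−1,1)}
memory words.  The implementation is deliberately dense and exact — it
targets desk-scale populations (N·max(R−1,1) ≤ 20 bits, dense
eigensolves up to 4096 states) rather than the large-N regime, where
mean-field or pseudolikelihood approximations would be needed (out of
scope here).

### Conventions

- Neuron indices are 0-based; blocks are time-major arrays
  `(length, n_neurons)`; in state integers, neuron 0 is the
  least-significant bit and earlier patterns occupy lower-order groups.
- Time bins are half-open `[t·Δ, (t+1)·Δ)`; multiple spikes in one bin
  collapse to a single 1; a spike exactly at the recording boundary is
  rejected rather than wrapped.
- For range-one energies the transfer entry is e^{H(destination)}.  The
  two conventions (energy of source vs destination pattern) give the
  same eigenvalue, invariant measure and i.i.d. law; the destination
  form is used because it makes the right Perron eigenvector constant
  for range-one models, matching the matrices usually displayed for
  synchronous (Ising-type) examples.  For R ≥ 2 the entry is e^H of the
  transition's full R-block, which is convention-free.
- Printed example matrices in the literature sometimes order pattern
  states with the opposite neuron-bit significance;
  `match_state_order` tries both orders and reports the matching
  permutation instead of guessing.

## Fitting

Fitting maximizes entropy rate under moment constraints via the convex
dual: minimize P[H_β] − βᵀc with analytic gradient E_β[f_k] − c_k
(pressure derivative identity).  A BFGS quasi-Newton iteration starts at
β = 0; convergence is declared when max_k |E[f_k] − c_k| ≤ 1e−8
(default).  Constraints exactly at 0 or 1 are rejected — the
corresponding multiplier diverges; constraints within 1e−6 of the
boundary produce a warning and a loosened tolerance of 1e−5.  Duplicate
features (identical value on every block) are rejected after an
exhaustive evaluation table; near-dependence is reported through the
table's condition number.

## Eigenproblems

Perron data are computed by dense nonsymmetric eigendecomposition for up
to 4096 states and ARPACK (`scipy.sparse.linalg.eigs`) above.  Vectors
are normalized with max(V) = 1 and ⟨U, V⟩ = 1; the relative eigenresidual
must be below 1e−10 or the solve raises.  Entropy sums use the 0·ln 0 = 0
convention.

## Large deviations

The SCGF λ_f(k) is the log spectral radius of the tilted matrix.  To
avoid overflow at large |k| the observable is shifted so the largest tilt
exponent is zero and the shift is restored additively
(λ(k) = k·c + ln ρ(P e^{k(f−c)})); tilts up to |k| of several hundred are
then computed in range for bounded observables.

The Legendre transform is done by grid maximization with bounded local
refinement rather than by solving λ'(k) = s, which is robust to flat
stretches of λ'; ties break toward smaller |k|.  When the model is
available the refinement step evaluates λ spectrally (accuracy limited by
the eigensolver, not the grid); the curve-only variant interpolates the
sampled SCGF with a cubic spline.  Slope targets outside the attainable
range report I = +∞.  The default k-grid is 401 points on [−5, 5].

Cumulants are Richardson-extrapolated central differences of λ at 0 with
order-dependent step sizes h = (1e−4, 1e−3, 2e−2, 5e−2) for orders 1–4.
The steps balance truncation (suppressed to ~h⁴ by extrapolation)
against eigensolver round-off amplified by h^{−n}; with ~1e−14 noise in
λ this places κ₁ and κ₂ near 1e−8 absolute accuracy, while κ₃ and κ₄ are
good to roughly 1e−5 and are the method's accuracy bottleneck.
Asymptotic covariances between two observables use the polarization
identity on the SCGF of the sum, with the same κ₂ accuracy.

## Entropy production

The pairwise formula for the IEP and the tilted matrix
F_ij(k) = P_ij (π_i P_ij / π_j P_ji)^k require every visited transition
to have a positive reverse, which holds structurally for chains of
memory ≤ 1 (R ≤ 2).  For memory ≥ 2 the reversal of an admissible word
sequence is generally inadmissible (structural zeros), the pairwise
formula diverges, and the functions refuse rather than silently
substituting a block-reversal definition.  The fluctuation symmetry is
tested in the standard Markov-chain form λ_W(k) = λ_W(−1−k) and verified
numerically to ~1e−15 on randomized models; the default k-grid for λ_W
is symmetric about −1/2 so the check reduces to an exact grid reversal.
The running estimator W_T uses the model's own π for the initial-state
factor of both the forward and the reversed path.

## Geometry

Relative entropy between chains is computed two ways — the
pressure/entropy-rate form d(q|p) = P[H_p] − S_KS(q) − E_q{H_p}, valid
for any ergodic q on p's state space, and the pure-pressure form valid
when q is itself a MEMC — and the test suite checks they agree.  The
pressure Hessian is a Richardson-extrapolated central second difference
in β (step 1e−4), symmetrized by averaging with its transpose; analytic
second derivatives of the eigenvalue were deliberately avoided for
simplicity at these problem sizes.  The ε-indistinguishability region is
the ellipsoid ½ δβᵀLδβ ≤ ε/T, where T is identified with the sample
length in bins; its volume is V_K ∏_k (2ε/(T λ_k))^{1/2}.  A singular L
yields infinite volume and the null-space basis is returned.

## Synthetic data

The sampler is the package's synthetic-data generator.  It draws the
initial memory word from π — the chain starts exactly stationary, so the
default burn-in is 0 — and advances by inverse-CDF draws on precomputed
cumulative rows using numpy's PCG64 generator with an explicit integer
seed recorded in the raster metadata.  Default study conditions follow
the worked examples: sample length T = 20,000 bins with sliding windows
of 50 bins (disjoint by default, giving T/W = 400 window averages; a
stride-1 overlapping mode exists behind a flag), and T = 50,000 for
parameter-recovery experiments, where refitted coefficients are compared
against delta-method standard errors Cov(β̂) ≈ L⁻¹/T (for a single
feature this reduces to σ² = λ''(0)/T).

What the generator emulates is exactly the model class: stationary
finite-memory binary chains.  Real recordings additionally contain
nonstationarity, slow rate drift, refractory structure beyond the bin
width, and spike-sorting errors — none of which are simulated — so
passing recovery tests demonstrates correctness of the inference
machinery under the model's own assumptions, not robustness to model
misspecification.

## Degenerate inputs and edge cases

- All-zero or all-one rasters give boundary constraints and are rejected
  by the fitter with an explicit message.
- Constant observables produce a linear SCGF; the rate function is
  finite only at the constant's value (∞ markers elsewhere).
- The Gibbs-band diagnostic enumerates all blocks up to a requested
  length (capped at 22 bits) and checks that
  ln p{block} − (Σ H(sub-blocks) − n·P[H]) stays in a band that neither
  drifts nor widens with n; only boundedness is asserted, since the
  additive constant depends on the boundary terms ln π − ln V.  For
  range-one chains the band collapses to zero width.

## Known limitations

- Dense state-space enumeration limits N·(R−1) to ~20 bits; no sparse
  or variational large-N path is provided.
- Entropy-production analysis is restricted to memory ≤ 1 as discussed.
- Non-differentiable SCGFs (dynamical phase transitions) and non-steep
  Gärtner–Ellis edge cases are out of scope; all provided energies have
  analytic, strictly convex pressures.
- κ₃/κ₄ accuracy is finite-difference limited (~1e−5).
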