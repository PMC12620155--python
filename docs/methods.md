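# Methods

## The problem

MR acoustic radiation force imaging (MR-ARFI) visualizes a focused
ultrasound (FUS) focus by encoding the tissue displacement produced by an
ultrasound pulse into MR image phase: a motion-encoding gradient (MEG) of
strength G (mT/m) and duration T (ms) applied along the propagation axis
converts a displacement d (meters) into a phase

    θ = 2π · 42.58 · G · T · d   [rad],

so that, e.g., 200 nm at G = 40 mT/m, T = 7 ms encodes ≈ 0.015 rad.  At
transcranial-safe pressure levels the focal displacement is on the order
of 100–200 nm, i.e. hundredths of a radian — far smaller than the
physiological and instrumental phase drift of an in-vivo timeseries.  The
sign of θ depends on which of the two MEGs in the spin-echo pair receives
the ultrasound trigger; switching the trigger every repetition
("alternating contrast", indicator 1[n] ∈ {0,1} per timepoint n) makes
each consecutive image pair a complete "average" and minimizes the time
separating the two contrasts.

## The model and estimator

Each complex image I_n(x_j) (n time, j space) is modeled as

    Î_n(x_j) = m_j · exp(i[(A c_n)_j + (−1)^{1[n]} θ_j]),

with m a complex baseline image common to all timepoints, A a spatial
polynomial design matrix (second order by default, six terms), c_n a
per-timepoint coefficient vector absorbing smooth phase drift, and θ the
displacement phase map.  The parameters minimize

    L = (1/Nt) Σ_n Σ_j |I_n(x_j) − Î_n(x_j)|² + λ Σ_j |θ_j|.

The L1 penalty encodes the prior that focal displacement occupies few
voxels; it is what separates a compact focal phase from smooth, non-sparse
drift, which the polynomial absorbs.  For fixed {c_n}, θ the baseline has
the closed form

    m̂_j = (1/Nt) Σ_n I_n(x_j) · exp(−i[(A c_n)_j + (−1)^{1[n]} θ_j]),

the mean of the phase-demodulated images, which is substituted at every
loss evaluation.  Because m̂ exactly minimizes the data term, the
concentrated loss simplifies to (1/Nt) Σ_n ||I_n||² − ||m̂||² + penalty,
with the closed-form gradient

    ∂L/∂φ_nj = −(2/Nt) · Im( conj(m̂_j) · I_nj · e^{−iφ_nj} ),

chained onto θ (via the contrast signs) and c_n (via Aᵀ).  A quasi-Newton
L-BFGS optimizer (SciPy's L-BFGS-B, strong-Wolfe line search) runs over θ
and {c_n} with these exact gradients.

### Numerical choices

- **Normalization.**  The optimizer works on data divided by its mean
  magnitude; this scales the loss by a positive constant (identical
  minimizer) and makes tolerances amplitude-invariant.  The reported loss
  trace is rescaled to raw units.
- **λ auto-scaling.**  A unit penalty λ₀ = 0.2 (default) is multiplied by
  the series' mean magnitude, giving λ = 2000 at the reference mean
  amplitude of 1e4 — the regime the default was calibrated for — while
  staying amplitude-invariant.  `auto_scale_lambda=False` applies
  `lambda_sparsity` verbatim.
- **Smoothed L1.**  |θ| ≈ sqrt(θ² + ε) − sqrt(ε) with ε = 1e-8, because
  quasi-Newton line searches misbehave on non-smooth objectives.  The
  −sqrt(ε) anchor is a constant offset (identical gradients) that makes an
  all-zero map cost exactly zero.  Results are insensitive to ε ≤ 1e-6.
- **Initialization.**  θ = 0, c_n = 0 (the natural basin for sub-0.1-rad
  signals); m̂ from its closed form at the first evaluation.
- **Stopping.**  History size 10, max 200 iterations, gradient tolerance
  1e-8 on the normalized loss.  Hitting the iteration cap returns
  `converged=False`, never an exception.  The fit is deterministic for
  identical inputs and options.
- **Gauge fixing.**  Adding any polynomial field Aβ to θ while moving
  −(−1)^{1[n]}β into each c_n leaves every predicted image unchanged, so θ
  is identified only modulo the basis span at λ = 0, and the penalty
  resolves the ambiguity only slowly at small λ.  After optimization the
  L1-minimizing polynomial component of θ (computed by iteratively
  reweighted least squares, effectively median regression; a compact focal
  bump is an outlier the polynomial does not chase) is moved into the
  coefficients.  This is the λ→0⁺ limit: the data term is untouched and
  the penalty cannot increase.
- **No spatial mask during fitting.**  The data term is magnitude-
  weighted, so air voxels contribute negligibly — and, by the same token,
  their θ values are essentially unconstrained and should not be
  over-interpreted.  Masks apply in the metrics only.
- **Coordinates.**  The polynomial basis uses plain monomials on
  pixel-center coordinates normalized to [−1, 1] per axis; normalization
  keeps the joint problem well conditioned (design condition number far
  below 1e6 up to 256² grids).  Any full-rank reparameterization of the
  basis would yield identical fitted phase fields.
- **Conversion constant.**  42.58 is used verbatim in 2π·42.58·G·T (not
  the CODATA 42.5764) to match the convention the conversion was defined
  with.
- **Odd Nt** is allowed (the schedule need not be balanced); the 1/Nt
  normalization handles it.  A schedule with only one contrast value is
  refused at construction — θ would be unidentifiable.

### Reference estimators

- **ROI-corrected:** the phase of the complex mean over a manually chosen
  out-of-focus rectangle is subtracted per image; positive- and
  negative-contrast images are then averaged separately and
  θ = angle(mean_pos · conj(mean_neg)) / 2.  The /2 makes θ the per-image
  contrast phase, so every estimator in the package shares one θ
  convention and one displacement conversion.  The correction removes
  per-timepoint constant offsets exactly but passes spatial drift
  gradients through to the map.
- **Four-image (EPI-style):** from repeating cycles (FUS off/positive MEG,
  on/positive, off/negative, on/negative), the on−off phase difference is
  formed per polarity and θ is half their difference, with complex
  products averaged over cycles.  The cycle ordering is a fixed convention
  of this package.
- All phase differences use complex-conjugate products, never
  wrapped-phase subtraction, avoiding ±π wrap errors.

### Per-slice fitting

The model is fit per 2D slice (time is the slowest axis of a series);
multi-slice data are handled by looping over slice files.  Whether a joint
multi-slice fit would help is untested here and out of scope.

## The simulator

`simulate()` generates the structure the estimator assumes, with known
ground truth:

- **Baseline**: a disk phantom (smooth tanh edge, mild polynomial shading,
  low-order random phase) or a smooth Gaussian-random-field image, scaled
  so the mean magnitude equals `baseline_amplitude` (default 1e4, the
  reference amplitude for λ auto-scaling).
- **Focus**: an isotropic 2D Gaussian displacement-phase bump, default
  200 nm peak and 2.2 mm lateral FWHM (the transducer's lateral focal
  width) at 1 mm pixels — a few-voxel spot, peak phase ≈ 0.015 rad at the
  default MEGs.  Real foci are elliptical in 3D; the reconstruction is
  agnostic to focal shape, so in-plane isotropy is sufficient.
- **Drift**: per-timepoint smooth phase with two components, each
  temporally AR(1)-correlated (default ρ = 0.9, slow respiratory-scale
  wander): random second-order polynomial coefficients (std 0.05 rad) the
  model can absorb exactly, and a super-polynomial component built from a
  fourth-order random field minus its best second-order approximation
  (std 0.02 rad) — content guaranteed to lie outside the model's span,
  which is the regime where the trigger schedule matters.
- **Noise**: i.i.d. circular complex Gaussian, default std 100 per channel
  — per-image phase noise of ≈ 0.01 rad at amplitude 1e4, placing a
  24-average map's background in the ~15–20 nm regime the method targets.
  No coil structure.
- **Schedules**: alternating (0,1,0,1,…), blocked (first half positive),
  or the four-phase cycle (ultrasound off at the off frames).
- All draws come from one `numpy` generator seeded by the mandatory
  config seed; output is bit-identical across runs.

What the simulator does **not** emulate: k-space/spiral sampling and its
off-resonance or T2′ blurring, ghosting, coil sensitivities, sharp
pulsatile features (vessels) that are spatially high-frequency, bulk
motion, and any realistic physiological drift spectrum — the AR(1)
polynomial drift is a stand-in.  Passing tests therefore demonstrate the
estimator's behavior under its own model class plus controlled violations
(super-polynomial drift), not performance on scanner data.

## Evaluation metrics

An average is a consecutive (positive, negative) pair; subsampling selects
pairs (or whole four-image cycles) uniformly without replacement, keeping
pairs intact.  Background statistics are computed in nm over a brain mask
minus a focus-exclusion disk (default radius 3× the focal FWHM — a
conservative reading of "outside the focus").  The precision curve repeats
subsample → reconstruct → background stats over a grid of averages levels
(default analysis: ten repeats per level), with per-cell seeds derived as
`SeedSequence([root_seed, n_averages, repeat])`.  CNR is the map value at
the focal peak voxel divided by the background std.

## Problem sizes

Library defaults target 64×64 single-slice grids; the test suite and the
bundled analyses run Monte-Carlo comparisons (parameter recovery,
alternating-vs-blocked, 1/√N averaging) on 32×32 grids with 40–96
timepoints and 20 seeds or 10 resamples per condition — sizes at which a
full suite completes in a couple of minutes while the Monte-Carlo margins
remain wide.  The noiseless exact-recovery check runs at 64×64, Nt = 20.

## Known limitations

- The fit is 2D+t per slice; no joint 3D or multi-slice estimation.
- Convergence at the default 200 iterations leaves θ accurate to roughly
  1e-3 rad in noiseless conditions; analyses needing 1e-6-level agreement
  (e.g. estimator-consistency checks) must raise `max_iterations` and
  tighten `gradient_tolerance`.
- Air voxels are essentially unconstrained by the data term; their θ is
  reported but meaningful only inside the object.
- The L1 penalty slightly shrinks focal amplitude; at the default
  auto-scaled λ the shrinkage is ≈ 1e-5 rad, negligible against 0.015 rad
  signals, but grows with λ.
- Blocked schedules are supported by the estimator, but their robustness
  to temporally correlated drift is intrinsically worse; the package
  reproduces that gap qualitatively, not the in-vivo magnitudes.
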