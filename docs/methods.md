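# Methods

## The model

Observed neural traces `y_t ∈ R^n` (dF/F fluorescence, one value per trace and
timepoint) are modeled by latent states `x_t ∈ R^p` through a constant linear
observation map,

    y_t = D x_t,          D ∈ R^{n×p},

and the latent trajectory by a *time-varying* linear dynamical system whose
transition matrix at each instant is a sparse linear combination of a small
dictionary of dynamics operators `{f_m}`:

    x_t = F_t x_{t-1},    F_t = Σ_m c_mt f_m,   f_m ∈ R^{p×p}.

The coefficients `c_t ∈ R^M` are mostly zero at every timepoint: a few
stereotyped interaction patterns drive the dynamics at any instant, and their
identity and strength drift smoothly in time.  This decomposed form sits
between a switching linear system (one discrete regime at a time, abrupt
transitions) and a generic nonlinear model: regimes can overlap, mix in
continuous ratios, and hand over gradually.

### Inference

States and coefficients are inferred sequentially in `t` by minimizing, per
timepoint,

    J(x_t, c_t) = ‖y_t − D x_t‖² + λ0 ‖x_t − F̃_t c_t‖²
                  + λ1 ‖x_t‖₁ + λ2 ‖c_t‖₁ + λ3 ‖c_t − ĉ_{t−1}‖²,

where `F̃_t = [f_1 x̂_{t−1} | … | f_M x̂_{t−1}]` stacks each operator's action on
the previous state.  Because `F̃_t` depends only on the already-fixed previous
estimate, `J` is jointly convex in `(x_t, c_t)`: a quadratic plus a separable
ℓ1 over the stacked variable.  The solver runs cyclic coordinate descent on
`z = (x_t, c_t)` warm-started at `(x̂_{t−1}, ĉ_{t−1})`; every coordinate step is
an exact scalar soft-threshold, so the objective is monotonically
non-increasing and converges to the global per-timepoint optimum (verified
against an independent split-variable L-BFGS-B solve to ~1e−15; see
`dlds.validate.inference_oracle_gap`).  At `t = 0` there is no previous state:
`x_0` is a sparse regression of `y_0` on `D` alone and `c_0 = 0`.  Timepoints
where the sweep cap is hit are flagged, never silently accepted.

### Learning

Fitting alternates (i) full-trajectory inference with (ii) projected gradient
updates of `D` and the dictionary:

    D  ← Π_D ( D + η Σ_t (y_t − D x_t) x_tᵀ ),
    f_m ← Π_f ( f_m + η Σ_{t≥2} c_mt (x_t − F̃_t c_t) x_{t−1}ᵀ ),

with `Π_D` normalizing columns of `D` to unit Euclidean norm and `Π_f`
projecting each operator onto the unit Frobenius ball — the standard
dictionary-learning normalizations that pin down the scale split between
`D`/`f` and `x`/`c` (the constraint sets are configurable via
`Hyperparameters.projection_spec` in spirit; the projections live in
`dlds.model.project_*`).

Both block losses are quadratic in their parameter, so inside `fit` the step
size is chosen by exact line search along the gradient direction rather than
a fixed `η`; the operator block additionally takes a few repeated steps per
outer iteration (`n_operator_steps`, default 5).  This matters because the
operator subproblem's normal equations are badly conditioned on trajectory
data (measured condition numbers 1e5–1e6): fixed small steps cannot converge
its weak directions in any realistic iteration budget, while line-searched
steps do.  The standalone `update_observation` / `update_operators` functions
keep the literal single-gradient-step contract with an explicit `η` for use
as building blocks.  Fitting stops when the per-iteration Frobenius change of
both `D` and the stacked dictionary falls below `conv_tol` (default 1e−3) or
at `max_iter`; a final inference pass with the converged parameters produces
the reported trajectories.  A >10× growth of the objective aborts with a
diagnostic.  Identical seeds give bit-identical fits.

### Multi-subject aligned fitting

`fit_aligned` learns **one** operator dictionary across subjects while every
subject keeps its own observation matrix, states and coefficients.  The
dictionary gradient accumulates each subject's dynamics terms, with the
`t ≥ 2` window restarting at each subject boundary (no dynamics link across
animals).  A single-subject aligned fit is bit-identical to `fit`.

### Hyperparameters

| name | meaning | default | notes |
|------|---------|---------|-------|
| `p` | latent dimensions | 10 | ≈ number of operators |
| `M` | operators | 10 | start at 2× the PCs for 95% variance (`select_num_operators`), or 2× the behavioral-state count, then decrease while the median active-coefficient count is stable |
| `lam_dyn` (λ0) | dynamics fidelity | 0.9 | couples `x_t` to `F̃_t c_t`; higher = smoother states |
| `lam_x_sparse` (λ1) | ℓ1 on states | 0.1 | moderately sensitive |
| `lam_c_sparse` (λ2) | ℓ1 on coefficients | 0.01 | sensitive; raise to reduce concurrently active operators |
| `lam_c_smooth` (λ3) | coefficient continuity | 0.0 | raise for smoothly drifting coefficients (e.g. the Duffing demo uses 0.5) |
| `conv_tol` | convergence on ‖ΔD‖, ‖ΔF‖ | 1e-3 | change norms reach ~1e-3 within a few hundred iterations on fixture data |
| `activity_threshold` | \|c\| level counted "active" | 1e-6 | lasso zeros are exact only to solver tolerance |

The λ defaults mirror the settings used for whole-brain worm models.  All
regularizers are in the units of the (max-scaled, dimensionless) traces.

## Preprocessing

Calcium fluorescence is a nonnegative activity proxy: negative dF/F excursions
(typically ≤3% of a trace) are clipped to zero, and all traces of a subject
are divided by the single per-subject maximum so recordings live in [0, 1]
and reconstruction error is comparable across traces.  The report records
per-trace clip fractions and flags traces clipped beyond the expected level.
Savitzky–Golay smoothing (default window 15 samples = 5 s at 3 Hz, cubic) is
display-only and never enters fitting.

## Dynamic connectivity

Freezing the coefficients at an instant (or choosing any operator mixture)
gives an equivalent linear time-invariant system; its trace-space interaction
structure is the directed map `D F Dᵀ` (rows = source traces, columns =
targets).  Mixtures are rescaled to unit Frobenius norm *after* combining, so
maps and impulse responses are scale-comparable across mixtures; the norm is
Frobenius by choice (the natural matrix norm here).  The impulse response
iterates the normalized mixture from an all-ones latent state for 500 steps
and averages `D x_t` over steps 1..500 (the impulse itself is excluded — the
iteration begins after the kick).  Thresholding keeps exactly
`ceil(fraction · n²)` strongest-magnitude entries with a deterministic
row-major tie-break.  Comparison against a user-supplied reference adjacency
recodes signs as matched (+) / novel (−) while preserving magnitudes exactly
— a display convention, kept separate from the excitatory/inhibitory sign of
raw maps.  Presence tallies resolve neuron names through the per-trace label
sets (a name matches a trace if it appears anywhere in the trace's label
list) and count a neuron as participating when one of its traces touches a
surviving edge or its |node activity| exceeds a configurable quantile
(default top 5%).  In practice active coefficient traces are often picked
out visually from plots; the explicit threshold here is the reproducible
substitute for that judgment call.

## Evaluation

Activity/connectivity series are binarized at a weak (median) or strong
(median + 3 SD) threshold, strictly-above counting as active.  Contingency
tables against categorical factors are tested with the Pearson χ² statistic
(scipy), Bonferroni-adjusted (`alpha / n_tests`; a realistic per-animal
burden of ≈555 tests gives the conservative 9e−5 level).  Decoding uses an off-the-shelf
linear classifier (linear SVM by default; LDA and logistic regression
available) on individual timepoints with stratified 5-fold cross-validation,
and always reports the majority-class base rate next to the accuracy.
ANOVA/MANOVA run in external statistical routines; this package only builds
their tidy design frames (`manova_design`).

## Synthetic data

`generate_dlds_data` samples the generative model itself with known ground
truth.  Operators are identity plus a sparse nonnegative interaction pattern,
normalized to unit Frobenius norm: nonnegative operators preserve the
positive orthant, so latent trajectories (and hence observations under the
nonnegative `D`) stay sign-consistent the way dF/F does, while near-identity
structure keeps consecutive states close (smooth 3 Hz-like dynamics).
Coefficients keep at most `k_active` operators on at a time (persistent
random support, one member resampled with probability `1 − smoothness` per
step) with first-order-autoregressive magnitudes.  Latents are renormalized
to constant norm at each step to prevent blow-up/decay; the rescaling is
folded into the stored effective coefficients so `x_t = Σ c_mt f_m x_{t−1}`
holds *exactly* in the ground truth.  Observations are `D x + noise`, clipped
at zero; with the default noise the clipped fraction is below 1% (0 for
noiseless data), matching the ≤3% negative-value level of real dF/F.

`generate_multi_subject` shares one dictionary object across subjects with
independent observation matrices, coefficients and durations.
`generate_worm_fixture` emulates the shape of whole-brain worm recordings:
~100 traces at 3 Hz, ~40 labeled with neuron names (some traces multi-name,
some names duplicated), a sticky 4-state behavior chain (FWD/REV/REVSUS/TURN,
~15 s dwell) driving distinct sparse coefficient motifs, and a two-phase
oxygen-like schedule (constant 21% first half; 21%/4% alternating every 30 s
after the midpoint).  What these generators do **not** emulate: measurement
nonlinearities and calcium-indicator kinetics, missing/duplicated ROIs,
non-stationary noise, and any real anatomical structure in `D` — so passing
recovery tests demonstrates correctness of the algorithms, not fidelity on
real worms.

The Duffing simulator iterates the printed discrete-time map exactly: the
undamped two-by-two recursion with drive `γ·cos(t)` at integer step index
`t`.  Note two properties inherited from that form: (i) the drive has a fixed
period of 2π samples, i.e. it acts as fast dither relative to the slow
natural oscillation at any stable `dt`; (ii) without damping, explicit-Euler
energy growth makes large-amplitude or large-`dt` regimes blow up (the
simulator truncates with a flag).  An optional `continuous_consistent` mode
implements the full Euler discretization of the underlying second-order
equation instead (damping `−δ y dt`, slow dt-scaled drive
`dt·γ·cos(ω t dt)`), off by default.

## Validation experiments

`duffing_decomposition_demo` fits `p = M = 2` to the default driven
trajectory (γ = −1, T = 2000).  Because the fitted dictionary depends on the
random initialization — standard practice for dictionary learning is to fit
several initializations and compare them — the demo fits 8 restarts and
reports the clearest decomposition: the restart whose coefficient trace,
smoothed with the package's display filter, correlates most strongly with
`x_t²`.  Smoothing is applied before correlating because the integer-step
drive injects per-sample dither into the raw coefficients that is an artifact
of the printed discretization, not of the slow nonlinear component being
tracked.  Typical results: reconstruction R² ≈ 0.995–1.0 in every restart;
best |r| ≈ 0.75–0.8.

`inference_oracle_gap` certifies solver optimality against an independent
convex solve (worst gaps ~1e−15 on 20 random small instances).

Parameter recovery on noiseless generated data (p = M = 5, T = 300) reaches
reconstruction R² ≈ 0.999.  Recovering the *operator span* is a different
matter, and a known limitation: with `M ≥ p`, the per-timepoint coefficient
solve has at least as many free coefficients as latent equations, so any
full-rank dictionary can reproduce every observed transition exactly — the
data never contradict the random initialization, and the only pressure on
the dictionary is the ℓ1 coefficient penalty, which at useful strengths
biases the operators with trajectory outer products.  Measured consequence:
after aligning latent bases (the model is identifiable only up to an
invertible change of basis `D → DR`, `f → R⁻¹ f R`; alignment uses the
least-squares map `R = D⁺_learned D_true`), the largest principal angle
between learned and generating operator spans stays large (20–90°) across
regularization strengths, initializations and iteration counts, even though
the same projected-gradient machinery recovers the span to ~5° when the true
states and coefficients are supplied.  Span recovery should therefore only
be expected in the overdetermined regime (`M < p` with strong excitation) or
with additional structure; reconstruction quality, coefficient sparsity
patterns and the derived connectivity analyses do not depend on span
identifiability.

## Numerical choices and edge cases

* Time is 0-based with half-open ranges throughout.
* "Active" coefficient: |c| > 1e−6 by default (lasso zeros are exact only to
  solver tolerance); stored on `CoefficientTrajectory`.
* Projections are exactly idempotent (unit-norm columns within fp tolerance
  pass through bit-identically).
* `update_*` with η = 0 is a legal null step; negative η raises.
* T = 1 recordings carry no dynamics information: the dictionary stays at its
  initialization and only `D`/`x` are estimated.
* Zero operator mixtures are returned as zero maps with an explicit flag;
  coactivation probability conditioned on a never-active trace is NaN
  (undefined), distinct from 0.
* Threshold ties break deterministically in row-major order.
* HDF5 artifacts are written without object timestamps, and
  `dlds.io.hash_artifact` hashes logical content, so identically seeded runs
  produce identical artifacts.

## Problem sizes

The bundled experiments run on one CPU in minutes: the Duffing demo fits
8 restarts of a T = 2000 two-trace series (~2 min), recovery and alignment
fits use T = 250–300 with 25–30 traces and 300 outer iterations (~10 s
each), and the worm fixture used in tests is down-sampled to a few hundred
timepoints.  Full-scale worm recordings (~100 traces, ~3000 timepoints,
p = M = 10, thousands of iterations) are within reach of the same code but
take correspondingly longer.
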