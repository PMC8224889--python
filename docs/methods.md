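# Methods

## Problem and model

`tfkit` estimates the transfer function (TF) linking two discretized
real-valued time series: an input x(t) (e.g. a neuronal calcium
fluorescence trace) and an output y(t) (e.g. red blood cell velocity
in a nearby capillary). The working model is a linear time-invariant
convolution,

    y(t) = (x * h)(t) + ε(t),

where h is the TF — in neurovascular coupling, the lumped
representation of every cellular cascade between neuronal activation
and the vascular response — and ε is measurement noise. Discretely,
`predict` computes `pred[i] = dt · Σ_j x[i−j] h[j]`, a Riemann
approximation of the integral; the `dt` scaling makes the kernel's
amplitude independent of the sampling step. Predictions are truncated
to the observation window so costs compare like-for-like sample
counts.

Fits are scored with two metrics: the residual sum of squares
(`rss`, the cost function of every optimizer — sensitive to amplitude)
and the Pearson coefficient (`pearson` — invariant to positive affine
rescaling, so it isolates the dynamics and permits inter-subject
comparison). No hidden normalisation (z-scoring, baselining) is
applied before either metric.

## The one-Γ kernel

The parametric family is the gamma-variate kernel standard in
blood-flow-based neuroimaging:

    TF(t; p1, p2, p3, p4) = H(t − p3) · p4 · (t − p3)^(p1−1) · p2^p1
                            · exp(−p2 (t − p3)) / Γ(p1)

with shape p1 (dimensionless), rate p2 (1/s), time shift p3 (s) and
amplitude scale p4 (the kernel's area tends to p4 as its duration
grows, because the Γ density is normalised). The peak sits at
p3 + (p1 − 1)/p2. Evaluation is done in log space
(`exp((p1−1)·log(t−p3) + p1·log p2 − p2(t−p3) − lnΓ(p1))`) for
numerical stability at large p1.

Choices made where the design was open:

* **p1 > 1 by default.** For p1 < 1 the kernel diverges at t = p3 and
  for p1 = 1 it jumps discontinuously; physiological kernels rise
  smoothly from zero. Custom models may lift this.
* **H(0) = 1** (t = p3 belongs to the support). With p1 > 1 the value
  there is 0 anyway; the convention only matters for custom families.
* **Default bounds** p1 ∈ (1, 20], p2 ∈ (0, 20] s⁻¹, p3 ∈ [0, 2] s,
  p4 ∈ [−100, 100]: a deliberately generous box covering hemodynamic
  kernels peaking anywhere from ~0.1 s (fast microvascular coupling)
  to ~20 s.
* **Default initial values** p = (2, 0.2, 0, 1): the canonical slow
  one-Γ HRF peaking at (p1 − 1)/p2 = 5 s. Starting the stochastic
  protocol from a kernel much slower than the expected optimum helps
  the run pool collect distinct local minima.
* **Default TF duration 10 s**, sampled at the data's Δt.

User-defined families are `ParametricModel` objects (name, parameter
names, bounds, defaults, evaluator) registered in memory or persisted
to a plain-text JSON registry as numpy expression strings.

## Pre-treatment

Recorded pairs pass, in order: crop (closed interval) → median filter
(outlier removal; window shrinks symmetrically at the edges) →
Savitzky-Golay smoothing (local least-squares polynomial; at the
boundaries the same degree is refitted over the truncated one-sided
window, so length is preserved without fabricating data) → linear
resampling to a common Δt (grid anchored at the first sample; linear
interpolation is overshoot-free and exact on lines). Outlier removal
precedes smoothing, and interpolation comes last so the filters see
the raw sampling; the ordering is this package's choice, as is each
edge-handling rule. A grid counts as uniform when successive steps
deviate by less than 10⁻⁶·Δt. A 0/1 boxcar stimulus on the half-open
interval [onset, onset + duration) can replace a recorded input; the
half-open convention makes `sum(values)·dt` equal the duration
exactly on aligned grids.

## Direct deconvolution

`toeplitz_deconvolve` solves `min_h ‖A h dt − y‖² + λ‖h‖²` where A is
the causal lower-triangular Toeplitz matrix of the input (causality is
imposed because the physiology cannot anticipate its input). λ = 0
uses a rank-revealing least-squares solver (minimum-norm solution and
a logged warning when rank deficient); the ridge option λ > 0 is an
addition of this package that makes the method's ill-conditioning
controllable. `fourier_deconvolve` computes
`H(f) = Y·conj(X)/(|X|² + (eps·max|X|)²)` with a water level `eps`
relative to the input's peak spectral magnitude (default 10⁻³),
keeps the real part of the inverse transform and scales by 1/dt.
Plain signal-length FFTs are used; on data whose signals relax to
numerical zero inside the window, circular wrap-around is negligible
and both routes agree to ~10⁻⁷ relative.

Deconvolution is unbiased but noise-amplifying: on noisy data the
estimated kernel carries the inverted noise spectrum, so training-set
predictions are nearly perfect while the kernel itself is rough,
generalises worse to fresh noise realisations, and fails the
biological-consistency screen. The acceptance script measures all of
this explicitly.

## Parametric optimization and the run/iteration protocol

All optimizers minimise the RSS cost; the model evaluator is total, and
parameter regions where it produces non-finite values receive an
infinite cost rather than an exception.

* **Nelder-Mead simplex** and **BFGS quasi-Newton** (finite-difference
  gradients) via `scipy.optimize.minimize`: deterministic — identical
  initial values give bitwise-identical results — but attracted to the
  nearest local minimum of an ill-posed surface (p1, p2, p4 jointly set
  the amplitude, so minima abound). The quasi-Newton route is
  unconstrained and may return p3 < 0 (an anticipatory shift) when the
  data favour it. A search that reaches a non-finite cost is recorded
  as a failed run, not raised.
* **Simulated annealing** via `scipy.optimize.dual_annealing`
  (generalized annealing with a bounded local polish): requires finite
  bounds, is reproducible per seed, and explores different minima
  across seeds. The per-run cost-evaluation cap defaults to 2·10⁴;
  other hyperparameters are the routine's defaults.

The protocol: an *iteration* is `n_runs` (default 50) annealing runs
sharing initial values, with per-run seeds derived deterministically
from `master_seed` (seeding is this package's addition, needed for
reproducibility). The iteration's best is the lowest-residual run
among those passing the consistency screen; if none passes, the
lowest-residual run overall is selected and flagged. Successive
iterations warm-start from the previous best, and since every
annealing run evaluates its starting point, each run's residual is
bounded by the incumbent's. The previous best also remains a selection
candidate, which makes the selected residual non-increasing by
construction even when new low-residual runs fail the screen. The
sequence stops when the relative improvement of the selected residual
falls below `improvement_tol` (default 5% — a quantification of
"no clear improvement"), or at `max_iterations`.

## Biological-consistency screen

Two rules, both motivated by the physiology: (1) the onset delay must
be strictly positive (the cellular cascades take time, so a TF cannot
start at 0 s) — read from the time-shift parameter when the family has
one, otherwise from the first sample exceeding 1% of the kernel's peak
magnitude; (2) the kernel may have at most one non-derivable point.
A sample counts as non-derivable when the normalised second difference
`|h[i−1] − 2h[i] + h[i+1]| / (dt · max|Δh|)` exceeds a threshold
(default 10). For smooth kernels this statistic approaches the
dt-independent curvature-to-slope ratio and stays small; at a slope
discontinuity it grows as 1/dt. The single permitted point accommodates
the onset kink of Γ kernels with 1 < p1 ≤ 2. The numerical definition
of a kink and both thresholds are this package's operationalisation;
counts near the threshold are implementation-defined.

## Method selection

`recommend_method` encodes the practical guidance: with no shape prior,
direct (Toeplitz) deconvolution — best when the goal is prediction
quality within the training dataset; with a prior and a need for
trustworthy dynamics, or high noise, or no time pressure, the annealing
protocol — the best trade-off between prediction performance and
biological consistency, at the cost of computation time; with a prior,
low noise and a need for speed, a deterministic optimizer.

## Synthetic data

The generators emulate the structure of the targeted recordings while
staying inside the linear-convolution model the evaluation assumes:
the input is a sum of unit-amplitude exponential transients
(instantaneous onset, default decay 0.5 s — the shape of a fast
calcium indicator during discrete activation events), the output is
the convolution with a known one-Γ kernel plus additive noise (white
Gaussian by default; a 1/f "pink" flavour is available to mimic slow
physiological drifts). Every generator is a pure function of its
arguments including the seed.

The reference dataset used throughout testing: 20 s at Δt = 50 ms,
six events at 0, 1.5, …, 7.5 s (the first at t = 0 keeps the Toeplitz
system well conditioned; all early enough that both signals relax to
numerical zero inside the window), true kernel
p = (2.5, 2.0, 0.2, 1.5) — onset delay 0.2 s, peak at 0.95 s, the
fast dynamics characteristic of microvascular coupling. The noisy
variant adds white noise with σ = 10% of the clean output's peak.

What passing tests on these data do **not** show: robustness to
non-linear or non-stationary coupling, to indicator saturation or
photobleaching, to correlated physiological noise beyond the 1/f
option, or to model mismatch between the true kernel family and the
fitted one — real recordings contain all of these.

## Problem sizes and numerical choices

The test and acceptance workloads use the reference dataset
(401 samples, 201-tap kernels) with protocols of 50 runs × ≤2
iterations at the default 2·10⁴ evaluation cap; auxiliary contract
checks (determinism, monotonicity) use reduced budgets (300–2000
evaluations, 4-run protocols) since they probe invariants rather than
recovery accuracy. Uniform-grid tolerance is 10⁻⁶·Δt; the Fourier
route's agreement checks use eps = 10⁻⁹ on noiseless data; floats are
written to text at full `repr` precision and to HDF5 as 64-bit,
making round trips bitwise.

## Known limitations

* Complex-valued signals are not handled.
* The two-Γ difference kernel used for oxygen-level-dependent signals
  is not built in; it is expressible as a custom model.
* Deconvolution offers no noise model beyond ridge/water-level
  regularisation; blind deconvolution is out of scope.
* The kink detector's count near its threshold is grid-dependent; on
  coarse grids (Δt ≳ 0.2 s) a genuine slope break may fall under the
  default threshold.
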