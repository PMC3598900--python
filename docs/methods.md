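# Methods

`subunitscope` infers the subunit structure of visual cortical neurons from
extracellularly recorded spike trains and a known stimulus movie. This note
documents the models, the estimation procedures, the numerical choices, and
what the simulated validation scenarios do and do not establish.

## Encoding models

All analyses operate on a time-embedded design matrix **S**: row *t*
concatenates the stimulus frames at lags 0..L−1 (lag 0 shares the bin with
the response), columns ordered space-major / lag-minor. Displays that start
at "10 ms before the spike" correspond to lags 1..L−1; keeping lag 0 makes
the design causal and complete. The first L−1 rows are zero-padded, flagged,
and excluded from every estimator, which preserves frame-to-row alignment.

Spike trains are per-frame counts (bin width = one stimulus frame; 10 ms at
100 Hz). Bins with *k* spikes enter all spike-triggered moments with weight
*k*, consistent with the Poisson likelihood used for model fitting.

### Generative model neurons

The `neurons` module provides ground-truth cells for validation:

- **ln_simple** — rate = F(g·(k·s) + θ);
- **separable_simple** — rate = F(g·Σᵢ f(kᵢ·s) + θ) with two
  space-time-separable filters and a per-subunit nonlinearity f ∈
  {linear, halfwave, square}. With `halfwave` this is the *de novo*
  construction of direction selectivity (DS) from rectified non-DS inputs;
  with `linear` the DS arises purely from summation plus the spiking
  threshold;
- **energy_complex** — rate = F(g·((k₁·s)² + (k₂·s)²) + θ) with a quadrature
  pair: the classical motion-energy model, phase-invariant and DS;
- **pooled_complex** — spatially shifted copies of a multi-filter prototype
  simple cell are combined with Gaussian envelope weights
  w(σ) = exp(−(σ−c)²/2·sd²) before the spiking stage. Shifted filters are
  truncated at the stimulus border and not renormalized (a finite
  receptive-field envelope); envelope weights are likewise not renormalized.

F is softplus, log(1+exp), the same function used in fitting; a hard
half-wave (`relu`) output is available for cells whose response modulation
should be exactly that of a rectified sinusoid. Spikes are drawn per frame
from independent Poisson distributions with the model rate as mean.

Default gains and offsets are chosen so simulated recordings land at
physiological rates, roughly 0.1–0.5 spikes per 10 ms bin, i.e. tens of
thousands of spikes for 10–30 minute recordings — the range typical of
extracellular V1 datasets (a few thousand to a quarter million spikes).

### Stimuli

- **Random bars**: ±1 bar contrasts read off a binary maximal-length
  shift-register (m-)sequence in successive windows of `n_bars` bits per
  frame. Primitive polynomials for orders 2–16 are a fixed built-in table,
  so movies are bit-reproducible without an RNG. The generated sequences
  have the ideal two-level autocorrelation (−1 at every nonzero lag).
- **Drifting gratings**: value(x,t) = cos(2π(νₓ·x/n − d·ν_t·t/r)), unit
  contrast, with an aliasing guard ν_t < r/2.
- **Pink noise**: seeded Gaussian white noise shaped in the 3-D Fourier
  domain so amplitude ∝ 1/f^α of the radial spatiotemporal frequency
  (α = 1 by default), DC zeroed, then standardized to zero mean and unit
  variance.

**A caveat on m-sequences and quadratic cells.** The columns of an
m-sequence design matrix are circular shifts of one ±1 sequence, and the
product of two shifts is *exactly* another shift (the shift-and-add
property). A neuron with a quadratic generator (an energy-model cell)
therefore has a deterministic, non-vanishing STA under this stimulus —
about 0.3 in units of the unit-norm leading STC filter in our settings,
versus ~0.03 under an iid binary ensemble of the same size. Binary
ensembles of either kind additionally fix ‖s‖² per frame exactly, so a
genuine variance *increase* along the driven subspace forces a compensatory
variance *decrease* elsewhere, producing real (not spurious) negative STC
eigenvalues for energy-model cells. The validation scenarios consequently
use the m-sequence for first-order (STA) recovery, and seeded iid Gaussian
bar noise wherever second-order structure is the object of study. For the
pooled-subunit complex cell the binary-ensemble suppression is part of the
phenomenon under study (opposing-DS suppressive filters emerge with no
suppressive inputs) and iid binary bars are used.

## Spike-triggered estimation

The STA is the spike-weighted mean of the valid design rows minus their
unweighted mean. STC diagonalizes ΔC = C_spike − C_all, where both
covariances are mean-subtracted (C_spike about the spike-triggered mean)
and C_all is taken over the entire experiment. The STA is *not* projected
out of the STC filters. Eigenvector signs are fixed by making the
largest-magnitude entry positive, so results are deterministic.

Significant filters are selected either by fixed counts (N_pos largest /
N_neg smallest eigenvalues; in practice N_pos = 2–8 for simple cells and
4–10 for complex cells) or by a shuffle null: the spike train is circularly
time-shifted (shift ≥ 20 bins, preserving both stimulus statistics and
spike autostructure), ΔC is recomputed, and eigenvalues outside the
[α/2, 1−α/2] envelope of the null extremes are kept. 100 shuffles at
α = 0.01 is the default.

### Whitening for correlated stimuli

For pink noise and naturalistic movies the design is first whitened on its
leading M principal components, Z = (S − mean)·V·D^(−1/2); M = 600 by
default (balancing estimate reliability against filter resolution), reduced
proportionally at desk scales. Whitened-space filters are mapped back with

- `smoothing=True` (default): b = V·D^(1/2)·b_w, which *accentuates
  well-sampled stimulus dimensions*. For an LN-type cell this returns the
  correlation-weighted pattern C·k rather than the filter k — a deliberate,
  noise-robust display convention, but one that cannot undo stimulus
  correlations.
- `smoothing=False`: b = V·D^(−1/2)·b_w, the exact inverse of the whitening
  map. This is the choice whenever a recovered filter is compared against a
  known ground-truth filter, at the cost of amplifying noise in weakly
  sampled dimensions.

The whitened-recovery scenario plants a 3-D quadrature pair in an
energy-model cell because a (near-linear) LN cell's second-order signature
is far too weak for STC at 10⁴-spike scales; its filter would be estimated
from the (whitened) STA instead.

## Localized filters

The STC eigenvectors are one orthonormal basis for the recovered stimulus
subspace; any unit-norm combination k_β = Σᵢ βᵢ bᵢ (Σβᵢ² = 1) lies in the
same subspace. The *temporal power* of a candidate filter at position x is
R_β(x) = (1/T)·Σ_t(⟨k_β(x,·)⟩ − k_β(x,t))², and its localization at target
c is scored by L(c, β) = Σₓ R_β(x)·(c−x)², with (c−x) in bar-index units
(squared Euclidean pixel distance for 2-D stimuli). Because R is quadratic
in the filter, L is a Rayleigh quotient β'Q(c)β/β'β; the implementation
still follows the prescribed multi-restart scheme — β parameterized
unconstrained, normalized inside the cost, minimized by L-BFGS from 20
random unit-sphere starts per target, 40 targets evenly covering the
stimulus including endpoints — and the test suite checks the optimizer
against the closed-form smallest-eigenvector solution. Ties across restarts
(< 1e−10) resolve to the earliest restart. Excitatory and suppressive
subspaces are localized separately by default.

Additional filters at one location come from repeating the search in the
orthogonal complement of the previous solutions' β vectors.

A localized set is summarized by aligning each filter's power centroid to
the integer grid center (nearest-integer shift, no interpolation — avoiding
resampling artifacts) and running *uncentered* PCA on the stack. Uncentered
PCA is used because filters carry an arbitrary sign: a set of identical
±copies should be rank 1, which mean-centering would destroy.

## The nonlinear cascade model (GNM)

r(t) = F[Σᵢ Σ_τ h_{iτ}·fᵢ(kᵢ·s_{t−τ}) − θ], F = softplus. Filters are held
fixed (from STC/localization); each fᵢ is piecewise linear on 20 knots at
empirical quantiles of its filter output (constant extension outside the
knot range), and each temporal kernel hᵢ has length 1 by default
(instantaneous integration — appropriate at 100 Hz bins), configurable up
to the lag count. Identifiability: fᵢ(median input) = 0 with the constant
absorbed into θ, and ‖hᵢ‖ = 1 with the scale absorbed into fᵢ.

Fitting maximizes the Poisson log-likelihood Σ_t[n_t·log r_t − r_t] (bin
width 1 frame) minus λ_f·Σᵢ‖Δ²fᵢ‖² and λ_h·Σᵢ‖Δ²hᵢ‖² (squared second
differences; λ_f = λ_h = 1 by default). Optimization alternates blocks —
all fᵢ plus θ jointly, then all hᵢ — each by L-BFGS-B with analytic
gradients, until the relative objective change falls below 1e−6 or 200
outer iterations; with h of length 1 a single L-BFGS solve is the full
problem. Rates are floored at 1e−12 inside the log. With 2 knots the model
reduces exactly to a softplus GLM over the data range, which the tests
exploit as an independent oracle.

Model comparison reports the cross-validated log-likelihood improvement
over a constant-rate model fitted on the training folds, in nats per spike,
on contiguous time-block folds (10 by default; random-frame folds would be
optimistic under temporal dependence). Folds without spikes are skipped
with a warning.

### Sparse selection of localized filters

Candidate localized filters are pruned by L1-penalized logistic regression
on the standardized half-wave-rectified outputs of each filter *and its
negative* (so ON- and OFF-driven contributions select independently); the
target is the binarized count (≥ 1 spike; multi-spike bins are rare at
100 Hz). The penalty weight is chosen on contiguous CV folds by the
one-standard-error rule — the sparsest λ within one SE of the minimum mean
held-out deviance — which is what keeps the selected set small when many
near-duplicate candidates are offered.

## Tuning indices

- **DSI** = (R_p − R_np)/(R_p + R_np) from mean rates at the preferred
  grating in the two directions; the preferred grating maximizes the mean
  rate over the (spatial frequency, temporal frequency, direction) grid.
- **MI** = F1/DC at the preferred grating; F1 is the discrete Fourier
  amplitude at the grating temporal frequency over an integer number of
  steady-state cycles after discarding one transient cycle plus the padded
  frames.
- **DSI_RF** = (Q1 − Q2)/(Q1 + Q2), with Q1/Q2 the *power* (squared
  magnitude — the standard choice for motion energy; amplitude sums are the
  unflagged alternative) in the two upper quadrants of the filter's 2-D
  DFT. The shared zero-frequency axes are excluded, and so are the unpaired
  Nyquist bins of even-sized grids — without the latter exclusion a
  separable filter's index is biased away from zero by the Nyquist column.
  The quadrant orientation is fixed so that DSI_RF agrees in sign with the
  direction-signed rate DSI of the same filter in an LN cascade.
- **Separability**: SVD of the x–t weight matrix; a tilted cosine filter is
  exactly rank 2 (cosine addition), and every rank-1 term is non-DS.
- **3-D filters** are reduced to x–t plots by rotating the spatial frame so
  the preferred-motion axis is horizontal (bilinear rotation per lag) and
  summing over the orthogonal coordinate. The axis is estimated, when not
  supplied, from the structure tensor of the spatial power spectrum at the
  lag of maximal spatial power; near-isotropic spectra (anisotropy < 0.1)
  raise instead of guessing.

## Validation scenarios and their scope

`subunitscope.scenarios` holds seven seeded end-to-end scenarios (LN STA
recovery; quadrature-pair STC recovery; pooled-subunit localization
recovery; tuning-index contracts; separable construction of DS;
nonlinearity-shape recovery; whitened STC on 1/f movies). They are run both
by `tests/test_acceptance.py` and by `scripts/acceptance.py`. Problem sizes
(2×10⁵ bar frames, 16×16×2×10⁴ pink-noise frames, 10-fold cross-validation
on 6×10⁴–10⁵ frames) are chosen so the full set completes in minutes on one
CPU while leaving comfortable statistical margins.

For the separable-construction scenario, the "one-DS-filter LN versus
two-separable-filter" comparison uses the linear-subunit generator and
gives the LN model the true DS filter (the sum of the separable
components): the claim under test is that the two *descriptions* are
equivalent accounts of the same spike train, and an STA-estimated filter
would contaminate that comparison with estimation noise (with half-wave
subunits the generator is genuinely outside the LN class and the two-filter
model wins by ~0.15 nats/spike at any data size — the corresponding
scenario for *rectifying* nonlinearity recovery therefore uses the
half-wave generator).

What passing these scenarios shows: the estimators recover the structure of
neurons that match the model class, at realistic rates and recording
lengths, under the stated stimulus ensembles. What they do not show:
robustness to non-Poisson variability, slow nonstationarity, correlated
network input, eye movements, or model mismatch beyond the generator
classes above — all present in real recordings and outside the scope of
these synthetic conditions.

## Known limitations

- Localization assumes the informative subspace is well estimated first;
  with badly undersampled STC the localized filters inherit that noise.
- The GNM holds filters fixed; joint refitting of filters and
  nonlinearities is out of scope.
- Per-filter scalar nonlinearities cannot represent joint (2-D)
  interactions between filter outputs.
- The shuffle null assumes stationarity of the stimulus ensemble over
  circular shifts.
- 2-D localization uses a single per-axis grid of target centers; very
  anisotropic receptive fields may warrant a custom grid.
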