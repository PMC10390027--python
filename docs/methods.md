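# Methods

## Model

The package works with linear brain network models of the form

    dx = (-x + k W x) dt + sigma dB,

the firing rate model (FRM): each of `n` cortical regions carries a scalar
activity `x_i`, relaxes with unit rate, and receives network input through a
symmetric, nonnegative, zero-diagonal structural connectome `W` scaled by a
global coupling `k`. `W` is spectrally normalized (divided by its largest
eigenvalue), so the drift matrix `kW - I` is strictly stable for every
`k < 1`: without noise every trajectory decays to the origin, with noise the
system fluctuates around the origin with a spatial covariance shaped by `W`.
Model state is identified directly with the conditioned BOLD signal; no
hemodynamic forward model is applied, which is consistent with scoring the
state against the signal by r².

Null variants share the same interface: the autoregressive (AR) null sets
the connectivity to the identity with `k = 1`, so the drift is identically
zero and the forecast is `x(n+1) = x(n)`; the exponential-decay null sets
`k = 0`. A 2-D spiral system `dx = A x dt` (complex eigenvalues, negative
real part) provides a ground-truth benchmark. An "inference" null — the
recurrent network rolled out autoregressively, sampling each next input
from a learned diagonal Gaussian — gives an empirical upper bound on
short-window predictability but has no mechanistic interpretation.

Time is measured in seconds. The default sampling interval is 0.72 s (the
repetition time of the modeled acquisitions); the decay term has unit rate
1/s. Per-region noise can be tied to cortical geometry by
`sigma_i = 0.35 * area_i / 858 mm²`, i.e. a parcel of the mean surface area
receives sigma 0.35, making noise a property of the cortex rather than of a
particular model.

## Integration

`simulate` uses an exponential Euler–Maruyama scheme: within each sampling
interval the linear drift is propagated exactly with the precomputed
matrix exponential of one substep (10 substeps per interval by default) and
diffusion enters as `sigma * sqrt(dt_sub) * N(0,1)` per substep, so `sigma`
is interpreted per unit time. For `sigma = 0` the emitted path coincides
with the closed-form flow `expm((kW - I) t) x0` to machine precision, which
the test suite checks against the independent matrix-exponential oracle.
A plain first-order Euler drift update was rejected: at the default substep
it deviates from the closed form by ~3e-2 over 50 sampled steps of a
20-region network, far above the 1e-4 agreement the integrator contract
requires. Integration aborts with the step index once any state magnitude
exceeds 1e6 (unstable parameterizations, e.g. `k > 1` on an unnormalized
matrix).

## Conditioning chain

Region-by-time matrices are conditioned with band-pass (0.0008–0.125 Hz) →
global signal regression → per-region z-scoring (population denominator),
in that order. The band-pass is a zero-phase hard spectral mask: the mean
is removed, the real FFT is taken along time, bins outside the band are
zeroed. A forward–backward Butterworth realization was rejected on
numerical grounds: with the lower band edge at ~1e-3 of Nyquist its poles
sit on the unit circle in double precision, and the measured stop-band
attenuation on windows of a few hundred to a few thousand samples is only
~3x, versus the >= 20 dB the contract requires (the spectral mask meets it
exactly). Global signal regression residualizes each region on an intercept
plus the mean-across-regions series of the filtered data; residuals are
orthogonal to the global series by construction.

The chain is deterministic and its first two stages are projections (exactly
idempotent). The full chain is *not* idempotent: z-scoring reweights regions
and thereby reintroduces a small global-mean component that a second
regression would remove. This is a property of the stage order (the order
follows standard practice: filter, regress, standardize), not of the filter.

Conditioned series are cut into non-overlapping 50-timepoint windows,
dropping the trailing remainder. Windows from two datasets (e.g. task and
rest surrogates) can be interleaved for training.

## Initial-condition estimator

A single-layer LSTM (default hidden size 64; Glorot initialization, forget
bias +1) consumes a window one timepoint at a time in forward time and at
every timepoint emits a candidate state of the bound dynamical system. The
network never sees the true state. The loss at timepoint `t` (for
`t >= warmup`, default 10) is the mean squared error between the
observation at `t+1` and the one-sampling-interval noiseless propagation of
the emitted state, `P x̂_t` with `P = expm((kW - I) * TR)` — exact and cheap
for linear systems, so no substepping appears inside the loss. Gradients
flow through `P` into the LSTM via exact backpropagation through time
(verified against central finite differences in the unit tests). The
forward pass is teacher-forced: the observation, not the model's
prediction, is the next input.

Training uses Adam (default learning rate 3e-3), gradient-norm clipping at
5, 300 epochs with early stopping after 30 epochs without improvement, all
randomness drawn from one seeded generator so runs are bit-reproducible.
One estimator is trained per (k, W) pair; noise is never used in training.
The exponential-decay estimator is independent of `W`, so sweep grids train
it once and share it across perturbation cells. The inference null uses an
output head twice the state width (mean and log-variance, the latter
clipped to ±10) trained by Gaussian negative log-likelihood of the next
observation.

At evaluation, `predict_horizon` infers the state at a timepoint from the
observed prefix and integrates forward: with evaluation noise `sigma = 0`
the exact propagator is iterated (so a horizon-1 prediction equals the
quantity the training loss scored), otherwise the stochastic integrator is
used.

## Scoring and model selection

r² is the coefficient of determination across regions at one predicted
timepoint, `1 - SSE/SST`; it can be negative, which deliberately ranks
models below the trivial mean predictor. The default comparison horizon is
the fourth sampled step (2.88 s): earlier steps are dominated by the
estimator's one-step fit and hardly differentiate systems; much later steps
are noise-dominated. Group aggregation pools squared errors across all
windows of a batch at a given timepoint before forming r² — per-trial
spread is markedly lower than individual-window scoring, and the package
treats the group metric as the default. With evaluation noise, r² is
averaged over 10 noise realizations per timepoint, seeds logged.

The structural sensitivity slope is the least-squares slope of mean
horizon-4 r² against the fraction of connectome edges swapped (the grid
must include fraction 0). Slopes are ranked by magnitude and reported
signed. The (k, sigma) cell maximizing |slope| is the selected
parameterization: the model most dependent on the true connectome.
Edge swapping moves a uniformly chosen existing edge onto a uniformly
chosen currently-empty pair (weight carried over, upper triangle mirrored),
preserving edge count and the weight multiset and never creating self-loops
or duplicate edges.

A known limitation, measured on matched surrogate data: the evaluation-noise
penalty to r² is additive and essentially independent of the perturbation
fraction, so the slope is nearly invariant along the sigma axis and the
sigma component of the argmax is a statistical near-tie between grid values;
the coupling component and the fraction-0-best ordering are robust across
seeds. On measured data, where the model is mismatched, the noise axis
carries more information.

The classical long-term criterion is also provided: simulate each (k,
sigma) cell for ~20 min of model time (1667 sampled steps by default),
condition the simulation like the data, and correlate the upper triangle of
its functional connectivity (region-pair Pearson correlations) with a
reference FC. Unstable or degenerate cells are flagged, not fatal. Note
that for a linear system the stationary correlation structure is invariant
to the overall noise scale, so this criterion identifies `k` but cannot
distinguish sigma values on surrogate data.

The Region of Predictability compares estimator-derived initial conditions
with null conditions (the previous observation used as the state) over the
first 3.6 s — five horizons at TR 0.72 s — by a paired two-sided Wilcoxon
signed-rank test per horizon at alpha 0.05, on matched (window, timepoint)
trials; a horizon counts as significant only when the estimator's mean r²
is also the larger one.

## Synthetic data

The spiral generator simulates sequences from the exact closed-form flow of
`A = [[-0.1, 2], [-2, -0.1]]` (100 points at dt 0.1 s by default), adds
i.i.d. Gaussian observation noise (std 0.1), and attaches candidate
matrices: the generating matrix plus versions perturbed along one shared
random direction with increasing scale (0.25, 0.5). A shared direction
makes the candidate ladder monotone — independent draws per candidate can
otherwise make the *more* perturbed system drift back toward the attractor
and invert the distance ordering at long horizons.

The surrogate BOLD generator simulates the FRM at its canonical operating
point (k = 0.9, sigma = 0.3 on a spectrally normalized connectome), from
N(0,1) initial states with a 100-step burn-in so the stationary regime
dominates, then applies the full conditioning chain. Ground truth (k,
sigma, W, seed) is recorded in the dataset provenance. It refuses
`sigma = 0`, since the noiseless stable system decays to the origin and
standardization degenerates — noise is constitutive, not a nuisance.
The synthetic connectome emulates a bilateral parcellation: two mirrored
hemisphere blocks (33 + 33 regions in the reference configuration),
homotopic inter-hemisphere edges, sparse heterotopic edges, log-normal
weights mimicking the heavy tail of fiber counts.

What the surrogates do *not* emulate: hemodynamic convolution and
measurement noise, head-motion artifacts, non-stationarities, subcortical
input, and any model mismatch — the generating model is by construction in
the candidate family. Passing recovery tests therefore demonstrates the
machinery's correctness, not that the FRM describes measured data. One
consequence is measured directly: on matched surrogate data the generating
coupled model also wins the *noiseless* horizon-4 comparison against the
exponential-decay null (the null is far worse), whereas on measured data,
where every candidate is mismatched, noise-free evaluation favors trivial
nulls.

## Problem sizes and defaults

The canonical test-scale experiment uses a 20-region bilateral connectome
at density 0.3, 4 surrogate subjects of 500 timepoints (40 windows of 50),
estimators with hidden size 64 trained for up to 200–300 epochs, a grid of
k in {0, 0.45, 0.9} x sigma in {0.0001, 0.3} x fractions {0, 0.25, 0.5},
horizon-4 scoring with 10 noise realizations, and a 1667-step FC
simulation. The full experiment runs in about a minute on one CPU core.
The 66-region configuration and larger subject counts are available through
the same interfaces.

## Degenerate inputs and tie-breaks

Zero connectomes cannot be normalized (no positive eigenvalue); edge swaps
exceeding the number of empty pairs report the feasible maximum fraction;
constant regions are rejected by z-scoring with the offending index;
constant global signals are rejected as degenerate regressors; zero-variance
observation vectors are rejected by r²; all-zero paired differences in the
Wilcoxon comparison yield p = 1 rather than an error. Checkpoints embed the
estimator's config and a fingerprint (kind, k, SHA-256 of the drift matrix)
and refuse to load against a mismatched system.
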