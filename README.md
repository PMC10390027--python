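# bnmic

Initial-condition estimation and short-horizon model selection for linear
brain network models.

Brain network models (BNMs) couple a neural-mass description of each
cortical region through a structural connectome measured by tractography.
They are usually validated against resting-state fMRI with long-time-average
statistics such as functional connectivity, which says nothing about whether
a simulated *trajectory* resembles the measured one timepoint by timepoint.
`bnmic` is for modelers who want that direct comparison: it synchronizes a
model to a measured multivariate window by estimating the model state
("initial condition") with a recurrent network, integrates the model
forward, and scores how quickly its trajectory diverges from the data —
turning short-horizon prediction into a model-selection instrument.

## Model and method

The core dynamical system is the firing rate model on `n` regions,

    dx = (-x + k W x) dt + σ dB,

with global coupling `k`, noise amplitude `σ`, and a symmetric structural
matrix `W` normalized by its largest eigenvalue so the system is stable for
`k < 1` (canonical operating point: `k = 0.9`, `σ = 0.3`). Null variants —
the autoregressive model (`W = I`, `k = 1`, forecast `x(n+1) = x(n)`) and
the pure exponential decay (`k = 0`) — and a 2-D spiral benchmark share the
same interface.

A forward-time LSTM consumes an observed window one timepoint at a time and
emits, at every timepoint `t`, a candidate state `x̂_t` of a *prescribed*
system. It is trained without ever seeing a true state: the loss is
`‖ P x̂_t − x_{t+1} ‖²` where `P = expm((kW − I)·TR)` is the system's exact
one-interval propagator, so the only way to predict the next observation is
to output a state the model can be integrated from. One estimator is
trained per (k, W). Candidates are then compared by the coefficient of
determination r² between prediction and observation at each horizon
(horizon 4 ≈ 2.88 s is the default discriminator), by the *sensitivity
slope* — how fast horizon-4 r² degrades as connectome edges are randomly
swapped, whose maximizer over (k, σ) selects the parameterization most
dependent on the true structure — and by the classical long-run functional
connectivity fit. The *Region of Predictability* quantifies, over the first
3.6 s, where estimator-derived states beat the naive choice of the previous
observation.

Everything runs offline: a synthetic-data module generates spiral datasets
with known ground-truth states and surrogate BOLD from a known
(k, σ, W) passed through the same conditioning chain as measured data
(band-pass 0.0008–0.125 Hz, global signal regression, z-scoring,
50-timepoint windows), so the full pipeline is testable end to end. See
`docs/methods.md` for assumptions, numerical choices and limitations.

## Worked example

Generate surrogate data from a known model, train an estimator per
candidate system, and compare them at one and four sampled steps:

```python
import bnmic

conn = bnmic.normalize_spectral(
    bnmic.synth_connectome(n_regions=20, density=0.3, seed=7))
data = bnmic.make_surrogate_bold(bnmic.SurrogateSpec(
    connectome=conn, k_true=0.9, sigma_true=0.3,
    n_subjects=4, timepoints=500, seed=7))

config = bnmic.EstimatorConfig(hidden_size=64, n_epochs=200, seed=7)
candidates = {
    "frm k=0.9 (generating)": bnmic.frm_system(conn, k=0.9),
    "frm k=0.45": bnmic.frm_system(conn, k=0.45),
    "exp decay (k=0)": bnmic.exp_decay_system(conn.n_regions),
}
for name, system in candidates.items():
    est = bnmic.train(data.segments(), system, config)
    scores = bnmic.horizon_scores(est, system, data, horizons=(1, 4),
                                  sigma=0.3, seed=7)
    print(f"{name:24s} r2@1 = {scores.mean_r2(1):.3f}   "
          f"r2@4 = {scores.mean_r2(4):.3f}")
```

Output:

```
frm k=0.9 (generating)   r2@1 = 0.954   r2@4 = 0.112
frm k=0.45               r2@1 = 0.955   r2@4 = 0.095
exp decay (k=0)          r2@1 = 0.955   r2@4 = 0.075
```

At horizon 1 every candidate fits equally well (~0.95): the estimator
minimizes exactly that one-step error, for any system. Four steps out the
trajectories have diverged and the generating model ranks first — the
short-horizon score carries the model identity, which is the premise of the
whole approach.

The same experiments are available from the shell: `bnmic
synth-connectome`, `synth-data`, `preprocess`, `train`, `evaluate`,
`sweep`, `fc-fit` and `spiral-validate` (see `bnmic --help`); every command
writes a provenance block with its arguments and seeds.

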