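# Methods

## Neuron model and integration

Neurons follow discrete-time leaky integrate-and-fire dynamics under
forward-Euler integration: `v ← (1 − α)·v + I` with leak factor
`α = Δt/τ_m`, a spike whenever the pre-reset potential reaches `v_th`
(inclusive, `≥`), and a reset applied **exactly once per step** according
to the configured mode — *hard* (clamp to `v_reset`, the default) or
*soft* (subtract `v_th`). Writing the leak term and the reset term as a
single recursion would reset twice; keeping reset as a mode-selected
single operation avoids that. The integration step defaults to
Δt = 1 ms, so α = 1/τ_m with τ_m in ms; the sweep's lower bound
τ_m = 1.001 ms then keeps α < 1. An absolute refractory period `t_ref`
(integer steps, default 0) freezes integration and spiking after a spike.
Membranes initialise exactly at `v_reset` (an optional uniform jitter
exists but is off by default so tests are deterministic).

Between input samples the state is handled by one of two policies:
**reset** reinitialises every membrane to `v_reset` and clears refractory
counters, **carry** propagates the final state of one sample into the
next. Carry models continuous streaming deployment, where a global reset
signal does not exist.

## Networks and training

Two families share the LIF dynamics and a single neuron configuration
across all layers:

* **MLP-SNN** — hidden Linear → BatchNorm → LIF blocks (reference sizes
  512-256-64 for 784-dimensional inputs) and a Linear → LIF output layer
  without normalisation.
* **ConvSNN** — two Conv(3×3, stride 1, pad 1) → BatchNorm → LIF →
  MaxPool(2×2) blocks (64 and 128 channels), global average pooling, and
  a 128→64→classes dense head.

Decisions accumulate output-layer spikes as an average over the T-step
window (default T = 10); ties argmax to the lowest class index, and a
sample with no output spikes at all is flagged degenerate in its activity
record.

Training is backpropagation through time over the unrolled dynamics with
cross-entropy on the averaged output counts and Adam
(lr 1e-3, β = (0.9, 0.999), ε = 1e-8 — conventional values, exposed in
the config). The spike indicator's derivative is replaced by the
arctangent pseudo-derivative `g(u) = s/(1 + (π s u)²)` with
`u = v_pre − v_th` and slope `s = 2.0` by default; the slope affects
gradients only, never the forward pass. Gradients flow through the reset
term as well (the hard-reset Jacobian uses the same surrogate at the
spike site). Batch-norm statistics are shared across timesteps (computed
over batch × time), use running estimates at inference, and start as the
identity transform so untrained networks are analytically predictable.
The recurrent variant adds `W_rec · S[t−1]` (initialised near zero) to
the last hidden layer's post-normalisation current.

Correctness of the backward pass is established by a finite-difference
check: in a *smoothed* mode the hard indicator is replaced by
`h(u) = 1/2 + arctan(π s u)/π`, whose exact derivative is `g`, so the
shared backward code computes exact gradients that are compared with
central differences (relative error < 1e-4). Training requires
`t_ref = 0` (refractoriness is supported in inference only); the sweeps
vary only τ_m and V_th.

## Operational manifold

For each grid point θ = (τ_m, V_th) the sweep trains a fresh network with
the same base seed (`train_then_eval`, the default) or re-evaluates one
provided network (`eval_only`), then records test accuracy, the mean
firing rate r̄ (spikes per neuron per timestep, averaged over all spiking
layers including the output layer, all timesteps and all evaluation
samples), the total spike count, and SOP. Membership requires
`r_min ≤ r̄ ≤ r_max` and `A ≥ A_thr`; defaults are r_min = 0.01,
r_max = 0.5 and a *relative* accuracy floor of 0.9 × the best accuracy
observed in the sweep, since the bounds are task-driven quantities with
no canonical values. The boundary marks members with an axis-adjacent
neighbour outside M; cells on the grid edge count as boundary because
off-grid behaviour is uncertified. Genuinely one-dimensional grids use
only left/right neighbours. Default ranges are τ_m ∈ [1.001, 5] ms and
V_th ∈ [0.01, 3] V with uniform spacing; both are configurable, as some
settings require wider ranges before degenerate regimes appear.

A structural note on saturation: batch normalisation before the spiking
nonlinearity centres every unit's input current at zero over batch and
time. With `v_reset = 0` and a near-zero threshold, a zero-mean-driven
LIF unit fires in at most about half the steps, so the network mean rate
plateaus just below 0.5 at the high-τ_m/low-V_th corner rather than
approaching tonic firing. Our desk-scale MLP reproduces exactly this:
the silent corner is unambiguous (r̄ < 0.01), while the "saturated"
corner saturates the BN-induced ceiling (r̄ ≈ 0.4) instead of exceeding
0.5. True tonic saturation requires architectures whose effective drive
acquires a positive mean (e.g. deeper unnormalised heads).

## Energy proxy and composite scores

SOP counts each spike entering a layer once per synapse it fans out to.
Fan-out is the output width for dense layers and `k·k·out_channels` for
convolutions — an interior approximation that ignores image-boundary
truncation; it is constant across a sweep, so rankings are unaffected.
For the dense head behind global average pooling, the layer input is a
rate vector rather than binary spikes, and its (fractional) sum is used
as the incoming-spike mass. In a small MLP the input-layer term (encoded
pixels × first-layer fan-out) dominates SOP, so normalised energy varies
less across the grid than total spike count does; min-max normalisation
over the observed extrema restores a usable [0, 1] scale. Degenerate
normalisation (flat dimension) maps to 0 — a flat dimension carries no
cost signal.

`BES_λ = A_norm − λ·E_norm` and
`EAS_β = (1+β²)·A_norm·(1−E_norm)/(β²·(1−E_norm) + A_norm)`, defined as 0
when the denominator vanishes. In this F_β form accuracy occupies the
emphasised (recall) slot: β > 1 stresses accuracy, β < 1 stresses energy,
and the β → ∞ ranking converges to the accuracy ranking — the form
consistent with the published semantics of the trade-off parameters.
Reported operating points are the per-score argmaxes plus the Pareto
front of (A_norm, 1 − E_norm) under weak domination.

## Reset-vs-carry evaluation

Policy curves re-encode the test images at each horizon T (per-sample
seeds, so encodings are tied to samples rather than stream positions) and
stream the set in one seeded shuffle, applying the state policy between
samples; the stream starts from a fresh state. Under reset, accuracy is a
per-sample property and is invariant to the stream order; under carry it
is not, and the shuffle seed is recorded in the result. Class-conditional
output histograms average the output layer's spikes at each step over the
samples of one class under the chosen policy.

## Drift diagnostics

The perturbation probe evaluates each correctly classified test sample
under progressively disordered inputs: round k applies k uniformly random
transpositions of whole time-frames to the clean input (monotone in
expected disorder, trivially terminating), re-evaluating from a fresh
state each round, until the prediction flips (the clean/perturbed
activity pair is stored with its flip level) or a cap of 3·T swaps is
reached. Collection stops at 2000 pairs or dataset exhaustion. Stored
activity is the deepest **hidden** spiking layer — the output layer is
the readout itself.

Pairwise Pearson correlations between that layer's binary trains are
summarised, per condition, on the element-wise average of the per-sample
correlation matrices (undefined entries from zero-variance trains are
excluded and counted). The eight statistics use excess kurtosis and a
linearly interpolated 99th percentile; (near-)constant coefficient sets
get skewness = kurtosis = 0 by convention. Mutual information between
each feature and the condition label is computed in bits over quantile
bins (10 by default; features with few distinct values get one bin per
value), deterministic and seedless. The condition classifier is XGBoost
with default trees on the eight features under a seeded stratified 80/20
split, reporting held-out accuracy and importances normalised to sum 1.

## Synthetic data

The static task assigns each class an oriented-bar template (horizontal,
vertical, two diagonals, at class-specific offsets) over a dim background
(0.05), adds Gaussian pixel noise and clips to [0, 1]; classes are
linearly separable at zero noise. Defaults — 4 classes, 12×12 pixels,
50 train / 25 test per class, contrast 0.5, noise σ = 0.45 — are
calibrated so the trained reference MLP operates at benchmark-like test
accuracy (~0.95–0.98) rather than a saturated 100 %: robustness probes
are uninformative when every decision margin is wide, and deployed models
do not enjoy such margins. The event task emits events along
class-specific moving-edge trajectories (direction encodes class) with
both polarities plus uniform background events; binned streams train a
reduced ConvSNN to above-chance accuracy in seconds. Correlated spike
trains follow a common-input mixture: per step each neuron copies a
shared Bernoulli(p) source with probability c, else draws independently —
expected pairwise correlation c², so c = 0 gives independent trains and
c = 1 identical ones. Fixture defaults p = 0.1 per 1 ms step (a plausibly
driven cortical rate), T = 100, 30 neurons.

What the generators do **not** emulate: digit-like within-class shape
variation, temporally structured static encodings (Poisson frames are
i.i.d. in time, so frame permutation changes only the realised order, not
the input statistics), sensor noise correlations, or heterogeneous
noise-induced synchronisation. Consequently, passing tests demonstrate
the machinery and the qualitative regime/policy phenomena at desk scale,
not benchmark-level claims; in particular, the clean-vs-flipped
correlation shift is small here (the permutation is distribution-
preserving for i.i.d. encodings), and under the two-level common-input
fixture the first-order statistics (mean/median) separate conditions
perfectly by construction, so tree-ensemble importance concentrates on
them rather than on the higher-order statistics that dominate with
heterogeneous real-data degradation.

## Problem sizes and reproducibility

The default experiments use a 144→32→4 MLP, T = 10, 200 training and 100
test samples, a 5×5 sweep grid (25 trainings, ~3 s total), five-seed
policy comparisons, a 2000-sample evaluation pool for pair collection,
and 1000 samples per condition for the diagnostics nulls — sizes chosen
so the full pipeline and test suite run in well under a minute each on a
single CPU while keeping every phenomenon measurable. One global seed
expands into per-stage seeds via `SeedSequence([seed, stage_id])`
(`snnmanifold.reporting.derive_seed`), so stages are independently
reproducible; all CSV/JSON artifacts are written with stable ordering and
fixed float precision and reproduce byte-for-byte on rerun.

## Known limitations

* Conductance-based, adaptive-threshold and multi-compartment neurons,
  event-driven (continuous-time) integration, and deep backbones are out
  of scope.
* Training assumes `t_ref = 0`; refractoriness is inference-only.
* SOP is a first-order proxy: no memory traffic, leakage or routing
  costs.
* The BN-induced rate ceiling (~0.5) means the saturated regime is
  expressed as "at the ceiling", not tonic firing, for normalised MLPs.
* Carry-policy training truncates gradients at sample boundaries and
  carries state between equal-sized minibatch lanes, not across an
  arbitrary-length stream.
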