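# Methods

## Circuit dynamics

The network is a stack of L hidden LIF layers over a sensory layer of J_0
Bernoulli spike generators. One integration step of layer ℓ proceeds
current → voltage → spikes/reset → adaptive threshold → trace, and reads
only the *previous* step's spikes of the neighbouring layers (bottom-up
W, top-down V, hollow-masked lateral inhibition M, optional class
modulation B). Because each step writes into a fresh state container, the
trajectory is bit-identical under any layer evaluation order; the test
suite asserts this directly, which is the practical meaning of the
"layer-parallel, no forward locking" design.

Conventions that the source formulation leaves open, fixed here:

* **Spike condition is strict** (`v̂ > v_thr`); an exact tie does not spike.
* **Reset is a binary gate to 0** (the resting potential); the invariant
  v ∘ s = 0 holds at every step.
* **The adaptive threshold is one scalar per layer**, clipped nonnegative,
  moved by λ_v (Σ_j s_j − 1) — for minibatches the increment is the batch
  mean, so threshold dynamics are batch-size independent in expectation.
  Thresholds are slow homeostatic state: they persist across patterns,
  batches and epochs, reset only when a model is freshly initialized, and
  are frozen during evaluation. Fast state (current, voltage, spikes,
  traces, head voltages) resets at every new stimulus window.
* **No refractory period, no self-excitation** — both deliberately out of
  scope.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| Δt | 3 ms | integration step |
| τ_m | 30 ms | membrane time constant (not pinned upstream; 10·Δt) |
| τ_tr | 3 ms | trace time constant; with τ_tr = Δt the trace is exactly γ·s |
| γ | 0.05 | trace increment per spike |
| θ_z | 10 | goodness threshold |
| λ_v | 0.001 | threshold adaptation rate |
| λ_d | 5·10⁻⁵ | synaptic decay factor |
| R_E, R_I | 1.0 | excitatory / inhibitory resistances (not pinned; dimensionless) |
| T | 90 ms | stimulus window (configurable up to 150) |
| v_thr(0) | 1.0 | initial threshold (not pinned) |
| η (Adam) | 0.002 | optimizer step size; β = (0.9, 0.999), ε = 10⁻⁸ |
| η (mixing) | 0.55 | convex weight of the original pattern in mixture negatives |

With the default τ_tr = Δt the trace recurrence degenerates to z(t) = γ·s(t)
exactly; whether a slower trace was intended upstream is unknowable, so the
default follows the printed constants and τ_tr stays configurable.

**Scale coupling of γ and θ_z.** A layer's goodness Σ_k z_k² is bounded by
γ²·J. With γ = 0.05 the bound is 0.0025·J, so θ_z = 10 presupposes layers
of several thousand units (where ~4000 concurrently active neurons reach
the threshold). For desk-scale circuits these two constants must be
rescaled together or the goodness probability pins near σ(−θ_z) for every
input and the contrastive signal lives only in the gradient, not in the
probability. The desk-scale study configuration used throughout the test
suite (layers [64, 32]) therefore sets γ = 0.5 and θ_z = 1.0: the decision
boundary sits at four concurrently active neurons — reachable under the
homeostatic spike constraint — and a single spike moves the goodness
argument by 0.25, enough for the logistic to discriminate. Library
defaults keep the full-scale values.

## Plasticity

The modulator is the exact gradient of the per-layer logistic goodness
loss with respect to the traces, δ_i = 2 z_i (p − y_type); the
implementation is verified against central finite differences (relative
error < 10⁻⁵ over random states). All four bundle updates share one form —
leading factor (R_E, or R_I for lateral M) times δ_i times the
*previous-step* presynaptic spike, plus a decay term λ_d s_i(t)(1 − s_j):

* Updates are **gradients of a loss to be minimized** and are handed to a
  minimizing Adam step. Flipping the sign convention silently inverts
  learning; this is the single most damaging mistake a re-implementation
  can make, hence the finite-difference test and the descent-direction
  property test (one descent step on the traces never lowers p for a
  positive sample).
* Updates are applied **at every simulation step** within the window
  (online adaptation), batch-averaged over the combined positive+negative
  minibatch so λ_d's scale is batch-size independent.
* At the first step of a window there is no spike history; presynaptic
  vectors default to zero, so the first step contributes only the decay
  term where postsynaptic spikes occur.
* The decay term applies identically to all four bundles, as printed
  upstream (whether M and B were meant to share λ_d is not stated there).
* After every optimizer step all bundles are truncated to their ranges
  (W, V, B, G, A ∈ [−1,1]; M ∈ [0,1]).

## Negative synthesis

Supervised: the image is kept and the clamped label is replaced by a
uniformly drawn wrong class. Unsupervised: each image is mixed with a
distinct, randomly rotated batch partner (rotation about the image centre,
bilinear interpolation, zero fill, result clipped to [0,1]; the
interpolation policy sits behind one function so alternatives are
pluggable). Rotated images stay graded and are re-encoded by Bernoulli
sampling like any pattern. Exactly one negative is made per positive and
appended to the minibatch with y_type = 0.

## Heads

The generative head predicts each layer's lower neighbour with LIF units
of identical dynamics (including the λ_v threshold rule) and adapts by
ΔG = R_E e s^T on the ternary mismatch e = s_pred − s_target. The
classifier head aggregates all hidden layers' spikes into C class LIF
units; its counts, softmaxed over the window, approximate the posterior.
Both heads adapt **on positive samples only** (switchable): negatives
carry deliberately wrong labels and confabulated images, and training the
heads on them would teach the inverse mapping. In the trainer, the head
updates use the previous-step source spikes (the ones that actually drove
the prediction voltage), matching the t−Δt presynaptic convention of the
main rule.

Reconstruction uses the bottom predictor's spike train through a clipped
unit-increment trace (z jumps to 1 on a spike, leaks only where silent,
hard-clipped to [0,1] — unclipped, a persistently spiking unit would grow
without bound) and averages it over the window; no class input is clamped
during reconstruction, so class information can enter only through what
the synapses have stored. The slow goodness-scan classifier clamps each
candidate class in turn and picks the class with maximal time-averaged
total goodness summed over all hidden layers.

## Synthetic data

`make_synthetic_dataset` emulates the small-grayscale-image regime: each
class is a distinct binary stroke/blob glyph on a side×side grid, and each
sample flips every pixel independently with the noise probability. It
reproduces the statistical shape the encoder cares about — [0,1]
intensities, class-templated structure, i.i.d. pixel noise — but not the
stroke variability, translation, or correlated deformations of real
handwriting. Passing the learning tests here demonstrates that the
dynamics, objective and heads interact correctly at desk scale; it does
not certify full-size benchmark accuracy, which additionally depends on
capacity and data diversity. The desk-scale study conditions are 2
classes, 100 samples per class, 12×12 pixels, 5% flip noise, a
[144, 64, 32] circuit, T = 90 ms, minibatches of 20, 10 epochs — small
enough that the whole study re-runs in seconds on one CPU.

## Determinism

Every stochastic step derives its generator from the user seed: parameter
initialization from (seed, 0), each minibatch's encoding and negative
synthesis from (seed, global batch index), shuffling from (seed, epoch),
evaluation encoding from fixed offsets. Two runs with the same seed
produce hash-identical checkpoints, and batch-level parallelism cannot
reorder draws.

## Known limitations

* The supervised positive-negative goodness probability *gap* is
  structurally small at desk scale: positives and negatives share the same
  image, so separation flows only through the B columns, while the
  homeostatic threshold — adapted on the batch mean over positive and
  negative rows alike — caps achievable trace-energy differences at a few
  spikes' worth (measured ≈ 0.4 in Σz², i.e. a probability gap near 0.05
  under the desk-scale constants). The gradient of the contrastive loss
  separates the classes long before the probabilities do, which is why
  classification reaches 100% while the probability gap stays modest.
* Synapses are unconstrained in sign (no Dale's law), thresholds are
  per-layer rather than per-neuron, and there is no refractoriness — all
  deliberate simplifications of the upstream formulation.
* Checkpoints store synapses, thresholds and config, but not optimizer
  moments; training resumption is fresh-optimizer only.
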