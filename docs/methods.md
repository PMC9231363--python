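# Methods

## Model and algorithm

The selector treats single-stimulus decoding as Bayesian linear
regression of the target/non-target label on the flattened epoch,
`y = Xw + ε`, `ε ~ N(0, σ²I)`, with one prior block per channel:
`w_b ~ N(0, γ_b B_b)`.  The relevance scale `γ_b` controls whether a
channel survives; `B_b` is the within-channel temporal correlation of
the weights.  Four tying modes for `B` are implemented:

| mode        | meaning                                              |
|-------------|------------------------------------------------------|
| `identity`  | `B = I`: no temporal correlation modelled            |
| `shared`    | one `B` for every channel                            |
| `per_block` | independent `B` per channel (no spatial pooling)     |
| `regional`  | one `B` per scalp region (the headline configuration)|

Each EM iteration computes the weight posterior under the current
hyperparameters and then updates, in this order:

1. `σ² ← (‖y − Xμ‖² + σ²_old·[D_active − Tr(Σ_w Σ0⁻¹)]) / N`, using the
   old `σ²` and old prior covariance;
2. `γ_b ← Tr[B_b⁻¹(Σ_w^b + μ_b μ_bᵀ)] / d_b`, using the old `B`;
3. `B_group ← mean over the group's blocks of (Σ_w^b + μ_b μ_bᵀ)/γ_b`,
   using the freshly updated `γ` (each term then has unit scale), and
   projected onto the AR(1) family `Toeplitz([1, r, …, r^(d−1)])` with
   `r = m₁/m₀` (mean first sub-diagonal over mean diagonal), clipped to
   `|r| ≤ 0.98`;
4. pruning: among blocks with `γ_b < τ`, the five smallest are set to
   exactly zero (ties to the lower channel index) and removed from the
   model — matrices shrink, nothing is zero-padded.

The posterior itself is computed by the `D×D` route when `N ≥ D_active`
and by the `N×N` Woodbury route otherwise, so the matrix inverted never
exceeds `min(N, D)`.  Inside the fit loop only the block diagonal of
`Σ_w` is materialised (that is all the updates consume), which keeps the
Woodbury route at `O(N²D)` per iteration.  Both full-matrix routes are
exposed as public functions and are property-tested to agree to 1e-8
relative error.

Convergence is declared when the active-γ vector changes by less than
`tol` (default 1e-4) in relative L2 norm with no pruning in that
iteration; hitting `max_iter` (default 200) flags the result rather than
raising.  Pruning makes the marginal likelihood non-monotone in general,
so the per-iteration log evidence is reported as a diagnostic only.

### Target centering

The regression has no intercept.  With ±1 labels at the speller's 5:1
non-target ratio, the label mean (−2/3) is unrepresentable by zero-mean
features; left in place it dominates the residual and drowns the
relevance signal.  The engine therefore centers `y` before fitting
(`center_targets=True`, switchable off).  This is an implicit intercept
and changes nothing when classes are balanced.

### Numerical choices and degenerate inputs

* Initialisation: `γ = 1`, `B = I`, `σ² = 0.1·var(y)` (floored at
  1e-10).  The fit is deterministic; no randomness enters the engine.
* `σ²` is floored at 1e-10: on separable toy data the update can
  underflow at a perfect fit.
* A raw `B` estimate with non-positive diagonal mean falls back to the
  identity; `|r|` is clamped below 1 to keep `B` positive definite.
* A region whose blocks are all pruned keeps its previous `B`.
* If every channel is pruned the fit raises a "degenerate selection"
  error advising a smaller τ.
* {1, 0} labels are coerced to {+1, −1} on input.

### Selection and the shear threshold τ

Automatic selection keeps channels with final `γ_b > τ`; weights are the
posterior mean of the surviving blocks.  Channel importance is the sum
of absolute weights over the channel's time points.  Fixed-M selection
takes the top M by importance (ties to the lower index) and, when only
M′ < M channels survived, backfills with the most recently pruned
channels in reverse pruning order; the downstream classifier is then
retrained, the selector is not refitted.  `crossvalidate_tau` picks τ by
stratified k-fold cross-validation (default 10-fold) on target/
non-target ROC AUC, ties resolved toward the larger τ (fewer channels).
τ is the one parameter that matters: the selected-channel count is
non-increasing in τ, the count saturates at the full montage for
τ ≲ 1e-6, and everything is pruned once τ exceeds the γ scale of the
data (about 1e-3 for unit-variance features and centered ±1 labels —
note that γ scales inversely with the squared feature scale, so τ must
be chosen per dataset, which is what the cross-validation does).

Folds are stratified by stimulus label, not by character; stimuli from
one trial can land in different folds, so validation AUC is mildly
optimistic.  This only tunes τ and does not touch the final test split.

### Classifier

BLDA is Bayesian linear regression on class-balanced targets `+N/N₁`,
`−N/N₂` with an isotropic zero-mean weight prior; prior precision α and
noise precision β are estimated by MacKay evidence fixed-point updates
(tolerance 1e-6, at most 500 iterations), equivalent to an automatically
tuned ridge discriminant.  α and β are clipped (α ∈ [1e-12, 1e12],
β ≤ 1e10) because on perfectly separable N < D data the residual
collapses and β diverges.  A per-feature (ARD) prior and fixed (α, β)
are available as options.  Character decoding sums scores per stimulus
code over the first `n_epochs_used` repetitions and takes the argmax row
and column codes, ties toward the lower code.

### Preprocessing

Continuous recordings are band-pass filtered with a zero-phase
4th-order Butterworth (default 0.5–20 Hz), decimated by an integer
factor (the band edge must sit below the post-decimation Nyquist, which
makes the band-pass the anti-alias filter), and epoched on half-open
windows `[onset, onset+window)` with 0-based sample indexing.  Defaults
reproduce the standard speller settings: 240 Hz → decimate 5 → 32 points
in 0–667 ms, or 250 Hz → 50 Hz → 30 points in 0–600 ms.

## Region maps

A region map is a strict partition of the montage into regions of at
least three channels.  The built-in 13-region schemes for the 64- and
59-channel 10–20 montages follow standard neighbourhood strips
(prefrontal, frontal left/mid/right, frontocentral, central, temporal,
centro-parietal, parietal, parieto-occipital); they are a reasonable
default, not an anatomical ground truth, and are replaceable by a plain
text file (one region per line, comma-separated channel names).
`auto_region_map` clusters montage coordinates with k-means
(deterministic for a fixed seed) and merges undersized clusters.

## Synthetic data: what it emulates and what it does not

`gen_block_sparse` draws instances exactly from the model's prior
(AR(1)-correlated Gaussian block weights, iid Gaussian design, additive
noise at a target SNR), so planted-support recovery is a direct test of
the estimator.  Defaults: 40 blocks × 8 points, 8 active, N = 500,
10 dB.

`gen_p300_session` emulates the statistical structure of a speller
session: 12 stimulus codes per epoch in random order, two target codes
per character (1:5 oddball ratio), AR(1) channel noise, and a Gaussian
ERP bump (latency 300 ms, width 80 ms) confined to 8 parieto-occipital
channels with a spatially smooth amplitude profile.  Session defaults —
59 channels, 18 characters × 8 epochs (N = 1728), 32 Hz epochs of
0.625 s (D = 1180), ERP peak 0.4 against noise σ = 0.5 — were fixed once
after an initial calibration pass and give an identifiable selection
problem: single-trial ERPs weaker than the background noise, as in real
recordings, with enough stimuli for the evidence to separate planted
from noise channels.  Two properties of this generator matter for
interpreting results:

* With a one-dimensional decoding target, spatially redundant
  informative channels carry little *marginal* evidence each; stronger
  ERPs actually shrink the discriminant weights (w ∼ 1/amplitude) and
  make the support *less* identifiable.  The defaults sit in the regime
  where recovery is reliable (median support-F1 1.0 at τ = 7e-4 over ten
  seeds); real data need τ cross-validated.
* Noise is independent across channels.  Real EEG noise is spatially
  correlated, which lets neighbouring channels help cancel noise and
  blurs the very notion of an exact informative support.  Passing
  recovery tests here therefore demonstrates correctness of the
  estimator on its own model class, not field performance.

Distractor channels (`n_distractors`) carry noise at 3× the base σ and
make the all-channel baseline measurably worse, which is what the
end-to-end benefit check exercises.

## Problem sizes used in tests and the acceptance script

Simulation sizes were chosen as desk-scale versions of the application:
the session mirrors a lab recording's structure (59 channels, ~1.7k
stimuli, N > D for the direct route; cross-validation folds drop N below
D and exercise the Woodbury route), and the block-sparse instances are
small enough that a ten-seed median runs in seconds.  The ablation of
`B` modes uses deliberately hard instances (0 dB, N = 200, r = 0.9)
where temporal-correlation modelling matters; at the defaults all four
modes saturate and the comparison is uninformative.

## Known limitations

* Pruning is irreversible; a channel pruned during the early transient
  cannot return.  The five-per-iteration cap limits, but does not
  eliminate, premature pruning when τ sits near the equilibrium γ scale.
* γ (hence τ) is not scale-free: rescaling features rescales γ
  quadratically.  Cross-validate τ per dataset.
* The engine stores the feature matrix densely and materialises the
  active Gram (direct route) or an N×N system (Woodbury route); with
  both N and D in the several-thousands, per-iteration cost grows
  cubically and other tooling should be considered.
* `compare_methods` uses the standard exact/asymptotic signed-rank
  implementation; with fewer than six pairs it warns and has little
  power.
* Kernelised designs, variational or fast-marginalised solvers, LASSO
  or group-LASSO baselines, artifact correction and online operation are
  out of scope; external importance vectors can still be plugged into
  `baseline_auto_threshold` and `select_top_m`.
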