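# Methods

This note records the model, the numerical choices, and the open design
decisions behind `lemmap`, in the spirit of a model-documentation page: what
is computed, under which assumptions, and what the synthetic benchmark does
and does not show.

## Model

**Score map.** A convolutional feature extractor ends in a feature map
`M ∈ R^{C×W×H}`; a 1×1 projection with weights `V ∈ R^C` (bias supported,
default 0) produces the score map `S_{ij} = Σ_c M_{c,ij} V_c + b`. No
activation is applied to `S`. Because projection and spatial averaging
commute, σ(mean(S)) is exactly the classical GAP-then-linear head; the
package exposes both paths and tests the identity to 1e-6.

**Extrema.** A cell is a local maximum (minimum) when its score equals the
maximum (minimum) over its boundary-clipped 3×3 window, *centre included*:
4 cells at corners, 6 at non-corner borders, 9 in the interior. Comparisons
are non-strict, so tied plateaus are flagged everywhere and a cell can be
both a maximum and a minimum (constant maps flag every cell both ways). The
implementation uses a 3×3 max/min filter with replicated edges, which equals
the clipped-window scan; tests verify agreement with a brute-force oracle on
1000 random maps.

**Aggregation.** Only correctly signed extremum evidence enters the
probability: `a_m = Σ S^max·max(S,0) ≥ 0`, `a_b = Σ S^min·min(S,0) ≤ 0`,
`y_lem = σ((a_m+a_b)/n)` with `n = Σ(S^max+S^min)`. A both-ways-flagged cell
counts twice in `n` (the literal denominator; the alternative — counting it
once — differs only on plateaus, which the sparse loss suppresses).

**Sparse loss.** `L_eli = Σ S^max·σ(min(S,0)) + S^min·σ(−max(S,0))`
penalises wrongly signed extrema; descent pushes a negative maximum further
down (a positive minimum further up) until it stops being an extremum.
`L_pna = Σ σ(max(S,τ)) + σ(−min(S,−τ))` is constant for |S| ≤ τ and pushes
scores back toward the band otherwise; τ = 3. `L_pna` is summed over **all**
positions (the literal formula), not only non-extreme ones; extrema are few,
so the difference is second order. The outer L1 norms wrap nonnegative
scalars and reduce to the values themselves.

**Objective and schedules.** `J = α(μ L_spa + L_lem) + (1−α) L_gap +
(λ/2)‖θ‖²` with binary cross-entropies for `L_lem`/`L_gap` (the
cross-entropy is implemented as the standard negative log-likelihood;
probabilities are clipped to [1e-7, 1−1e-7]). `λ = 1e-5` applies to weight
tensors only, not biases. α ramps linearly from 0.1 at epoch 0 to 1.0 at
half of training (ramp length configurable), then stays flat — the simplest
monotone schedule with the published endpoints. The learning rate is
`lr(e) = 1e-4 · 0.98^⌊e/8⌋`.

**Training.** Per step: forward pass, extremum detection (the indicator maps
are constants of the step — they are piecewise constant in `S`), analytic
`dJ/dS`, backpropagation, parameter update. Per-sample objectives are
*summed* within a mini-batch of 32, with one L2 term per update; this keeps
the published per-sample learning rate meaningful at desk scale. The update
is stochastic gradient descent with heavy-ball momentum 0.9 by default:
measured on the bundled benchmark, the plain update at lr 1e-4 moves the
GAP loss by less than 0.001 in 30 epochs, while momentum 0.9 trains to
convergence; `momentum=0` restores the vanilla rule. Gradients of every
term are finite-difference checked in the test suite.

**Localization.** If `y_lem` exceeds the decision threshold (0.5 — the
natural reading of the malignant branch for a sigmoid output), all flagged
maxima with positive scores are propagated; otherwise all flagged minima
with negative scores. Each selected extremum starts with unit importance,
distributed over feature channels by `ReLU(V_c)·M_c` (maxima) or
`ReLU(−V_c)·M_c` (minima, the magnitude of the printed negative branch so
importance stays nonnegative), normalised per extremum. Below the head,
importance flows through positive-weight × activation fractions normalised
per neuron (`Z_j = Σ ReLU(U_ij)M_i`; biases excluded). Max pooling routes
importance to each window's argmax, ties split equally; average pooling is
treated as a uniform positive-weight convolution; ReLU and fixed positive
scalings are one-to-one and pass importance through. If some `Z_j = 0`, the
incoming mass is dropped and recorded (`mass_delivered`); otherwise each
extremum delivers exactly unit mass (tested to 1e-5, with an exhaustive
path-enumeration oracle on small nets). Propagation is linear in the
initial importance, so the multi-extremum map is computed in one pass and
equals the sum of single-extremum maps. Supported layers: stride-1
convolution, ReLU, max/average pooling, fixed scaling, and the 1×1 head;
anything else raises a capability error (the bundled backbone contains
nothing else — in particular no normalisation layers or skip connections).

**Binarization and metrics.** Importance maps are thresholded at 0.2 × map
maximum (configurable, reported with every result; no published rule
exists). DSC = 2|A∩B|/(|A|+|B|), recall = |A∩B|/|B|; both averaged
unweighted over images that carry masks (macro averaging; the pooled-pixel
alternative is not used). AUC is the midrank Mann–Whitney statistic —
identical to trapezoidal ROC area, and directly testable against exhaustive
pair counting. Accuracy is measured at threshold 0.5.

## Backbone and initialisation

The bundled backbone is deliberately small: a fixed positive input scaling
(×8), then one 3×3 convolution + ReLU + 2×2 max-pool block per entry of
`channels=(8,16,32)`, then the 1×1 head — about 6k parameters, an 8×8 score
map for 64×64 input. Three choices matter and were made after measuring
their failure modes on the benchmark:

* **Input scaling ×8.** Pixels live in [0,1] with standard deviation ≈0.1
  (mostly flat background); without rescaling, activations and gradients
  are an order of magnitude too small for the published learning rate. A
  positive one-to-one scaling is also transparent to importance
  propagation (unlike mean-centering, which would break the nonnegativity
  that the propagation rules assume).
* **Replicate ("edge") convolution padding.** Zero padding surrounds the
  image with a dark frame whose features are unlike anything in the
  interior; the trained head scored that frame systematically positive,
  and the spurious border maxima captured roughly half of the localization
  mass. Replicate padding removes the artificial frame; the gradient of
  the padded convolution folds border contributions back onto edge pixels
  exactly (finite-difference tested).
* **Head calibration at initialisation.** The projection weights are
  initialised half-normal (nonnegative), so the initial score map is an
  activation-energy map — salient regions start as positive maxima rather
  than inheriting an arbitrary sign pattern that the elimination loss
  would amplify. One forward pass on the first batch then rescales `V` to
  unit score spread and centres the bias, so training starts calibrated
  (probabilities near 0.5, scores inside the penalty band). Without this
  the initial offset of several score units cannot be absorbed within a
  30-epoch run.

## Unpublished hyperparameters

`γ` (penalty weight inside `L_spa`) and `μ` (sparse-loss weight in `J`)
have no published value. Defaults: `γ = 0.1`, `μ = 0.05`. The choice of μ
follows from gradient magnitudes: a wrongly signed extremum contributes up
to ≈0.25 to `dL_eli/dS` while the classification losses contribute
≈|y−t|/n ≈ 0.03 per flagged cell, so μ near 1 lets the elimination term
drown the label signal entirely (on the benchmark, μ = 1 drives every map
to a uniform saturated state and classification collapses to chance). With
μ = 0.05 the sparse term acts as the intended regulariser: across a sweep
(μ ∈ {0, 0.05, 0.1, 0.2, 0.5}, three seeds) classification AUC is ≈1.0
throughout and localization DSC improves over μ = 0 for every μ > 0 —
the same qualitative ablation picture as with the published method
(localization gains, classification essentially unchanged). Both values
are mandatory in config files so no run hides them.

## Synthetic benchmark

The generator emulates the weak-supervision regime: exactly one lesion per
image, occupying ≤5% of the pixels, on a textured background (three
low-frequency cosine gratings, amplitude 0.02–0.045, plus Gaussian noise,
sd 0.02). Benign lesions are radially smooth Gaussian bumps with additive
contrast U(0.10, 0.18); malignant lesions are Gaussian cores with contrast
U(0.38, 0.60) plus 5–9 radial spicule ridges. Core radius is 4.7–7.0% of
the image side for both classes, so lesion *size* is not a class shortcut;
the signal is contrast and spiculation. The ground-truth mask is where the
additive lesion field exceeds 15% of its contrast. The contrast separation
is chosen so that the intended architecture — a ~6k-parameter from-scratch
backbone trained for 30 epochs — can learn the task; the generator is the
benchmark's definition, not a tuning dial, and all tests run against these
fixed conditions.

The default benchmark is 400 training and 100 held-out images at 64×64,
30 epochs, batch 32 — sized so a full run takes about a minute on one CPU.
Augmentation (horizontal flip, ±30° rotation, contrast jitter, gamma jitter
as the single-channel analogue of a saturation jitter, additive noise) is
implemented and label/mask-consistent but disabled by default; the
benchmark is learnable without it and determinism of the default run is
simpler to reason about.

What passing means — and does not mean: the benchmark shows the machinery
is correct (identities, gradients, conservation) and that the method
behaves as described end-to-end (extremum classification works where dense
pooling under-performs; the sparse loss trades a little classification
headroom for better localization). It does not show clinical performance:
real mammograms have vastly richer texture, lesion morphology and
inter-device variation than the phantom generator, pretrained backbones at
high resolution behave differently from the tiny backbone, and absolute
metric values here (AUC ≈ 1.0, DSC ≈ 0.18) do not transfer.

## Degenerate inputs and edge cases

* Score maps must be finite and at least 2×2 (the 4/6/9 neighbourhood
  taxonomy presumes 2-D extent); aggregation alone accepts any shape.
* Empty extremum selection (e.g. a benign call with no negative minima)
  returns a zero map with an `empty-selection` status, never a crash.
* Probabilities are clipped at 1e-7 before logs; a non-finite training
  loss aborts with diagnostics; single-class datasets are refused.
* Checkpoint, dataset and config files round-trip bit-exactly; identical
  seeds give bit-identical datasets and training runs.

## Known limitations

* The backbone supports no residual connections or normalisation layers;
  the localizer raises a capability error for unsupported layers.
* One lesion per image; multi-lesion images are out of scope.
* The DSC of the binarized maps depends on the fixed-fraction threshold;
  no per-image threshold search is performed.
* Heavy-ball momentum and the calibration step are pragmatic desk-scale
  choices; at the published scale (pretrained backbone, 800×800, 400
  epochs) the plain update may be preferable.
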