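# Methods

`contiseg` is a desk-scale toolkit for studying *continual learning* in
semantic segmentation: a single compact network is trained over an ordered
sequence of tasks (acquisition sites), and the package measures how training
on later tasks degrades — or transfers to — earlier ones. This note records
the models, conventions and numerical choices the implementation rests on,
and what the synthetic benchmarks can and cannot show.

## The setting

A *task* 𝒯ᵢ is one dataset: a set of grayscale images with integer
segmentation masks, drawn from one generating distribution. The scenario is
*domain-incremental*: every task shares the same label set (after
alignment), but the input distribution shifts between tasks. Task identity
is assumed known at inference time; inferring it from image statistics is
out of scope.

Training is staged: the model trains on task 1, then task 2, and so on,
never revisiting earlier data except through an explicit rehearsal buffer.
*Catastrophic forgetting* is the collapse of earlier-task performance after
later stages.

## Synthetic task generator

Each task is generated deterministically from a declarative `TaskSpec` and a
seed. Per-task sub-seeds are derived by hashing the task id together with
the sequence seed, so permuting a task list permutes the datasets without
changing per-task content.

* **Anatomy.** Foreground objects are parametric shapes rasterised at random
  position/orientation: a single ellipsoid; a *bilobed* structure (two
  overlapping lobes, optionally annotated as two raw sub-labels that must be
  merged downstream); or a *ring* (annulus) whose interior is a distinct
  structure when a second raw label is declared — the natural "irrelevant
  label" to drop to background during alignment. Shape volume is solved from
  the spec's target foreground fraction (`roi_fraction`), so the realised
  foreground fraction tracks the target up to rasterisation and aspect
  jitter.
* **Intensity model.** Piecewise-constant class means (drawn per case from
  the spec's `(mean, std)`), a smooth multiplicative bias field (Gaussian-
  filtered white noise, default ±8% gain), and additive Gaussian voxel
  noise. This is a minimal model of inter-scanner shift in contrast and
  gain; it does not emulate MRI physics, resolution/spacing differences, or
  anatomical population variation.
* **Domain shift dial.** The packaged *high-shift pair* swaps foreground and
  background intensity means between the two sites (a contrast inversion).
  The shift survives per-case z-scoring, so it cannot be normalised away,
  and it reliably induces catastrophic forgetting at this scale. The
  *no-shift pair* draws both sites from identical distributions and serves
  as the null control. The generator's "shift level" is this package's own
  construct; it is not calibrated against any real multi-site corpus.
* **Scale defaults.** 2-D 64×64 images, 30 cases per task (3-D at small
  cubes is supported); 20% of cases are held out per task
  (round-half-away-from-zero on the test side, clamped to leave at least one
  case per side for tiny datasets), and the split persists with the dataset
  across all experiments. These sizes were chosen once so that a full
  two-task stage (200 SGD steps) trains to ≈0.99 in-distribution Dice in a
  few seconds on one CPU core.

Because the desk-scale datasets are split train/test only, the test split
doubles as the per-epoch validation set for trajectory tracking.

## Label alignment

Raw label schemes differ across sites (sub-regions to merge, irrelevant
structures to discard). Alignment is an explicit, user-supplied voxel-wise
remap (JSON: raw → target, background 0 → 0 implicitly), applied once at
preprocessing; trainers only ever see aligned data. Mappings are never
inferred from label statistics — which structure is "the same" across sites
is semantic knowledge. `validate_alignment` checks that all tasks land on
one contiguous target set {0..K} and reports per-class voxel counts.
Growing label sets over time (incremental label learning) is excluded.

## Segmentation network

A small U-Net-style fully-convolutional network written directly in NumPy
(forward and backward passes by hand, im2col convolutions):

* three resolution levels, base 8 channels (8/16/32), 3×3 kernels, leaky
  ReLU (slope 0.01), 2× average pooling, nearest-neighbour upsampling with
  skip connections; ≈14k parameters;
* inputs are whole images, z-scored per case (this replaces per-layer
  instance normalisation: at whole-image scale the two have the same
  normalising role, and the hand-written backward pass stays simple);
* the final per-class 1×1 projection (`seg_head.*`) is the *head*; all
  other parameters are the shared *body*. The split point is configurable
  by name prefix.

The architecture is fixed from the **first** task and never changes —
in a prospective continual setting only the first dataset exists when the
model is built.

**Loss** is voxel-wise cross-entropy plus batch-level soft Dice (averaged
unweighted over classes, ε = 1e-5), the standard composite segmentation
loss. **Optimiser** is plain SGD at a fixed learning rate (default 0.2,
chosen once from loss trajectories on a single static task) — no momentum
or schedule, to keep continual-method comparisons free of optimiser state
confounds and every run bitwise reproducible under a seed.

Arg-max prediction breaks ties toward the lowest class index.

### Multi-head bookkeeping

In multi-head mode each task owns a head: at a task boundary the active
head is value-copied for the new task (so predictions are identical at the
moment of replication), and inference selects the head matching the sample's
task. In single-head mode the boundary operation merely re-keys the shared
head. With a single task the two modes are bitwise identical by
construction. The body can optionally be frozen after the first stage;
frozen means bitwise constant under any further training. During later
stages only the active head receives task-loss gradient; earlier heads are
touched only by LwF's distillation term.

## Continual-learning strategies

All six regimes run through one SGD loop with a shared batch-sampling
stream, which makes the reduction identities exact: rehearsal at fraction 0,
EWC at λ = 0 and RW at λ = 0 are bitwise identical to sequential training
under equal seeds.

* **Sequential** — plain fine-tuning on each task in turn.
* **Rehearsal** — before each stage, `round(fraction · |train_j|)` cases
  are drawn uniformly without replacement from every previous task's train
  split (default fraction 0.25) and pooled with the current task's training
  cases at equal per-case sampling weight. No oversampling correction or
  buffer optimisation.
* **EWC** — after each stage, a diagonal empirical Fisher is computed (mean
  over sampled train cases of the squared gradient of the log-likelihood at
  the model's own arg-max predictions, one backward pass per case) and
  stored with a value-copy of the parameters as an anchor. Later stages pay
  the quadratic penalty (λ/2)·Σₜ Σₖ Ωₜₖ(θₖ − θ*ₜₖ)², summed over all
  completed tasks (canonical multi-task EWC). Default λ = 0.4.
* **LwF** — three phases per stage: the previous model's outputs on the new
  task's training images are recorded once; the new head is warmed up with
  body and old heads frozen (10% of epochs); then body and all heads are
  fine-tuned, old heads supervised by the recorded outputs through
  temperature-T distillation (default T = 8). The distillation value is
  T²·KL(teacher‖student) at temperature T — zero when the student matches
  the recording, equivalent to the soft cross-entropy up to the constant
  teacher entropy, and T-independent in gradient magnitude. Requires
  multi-head mode.
* **RW** — an online variant of the quadratic-penalty family: a running
  Fisher Fₖ ← α·gₖ² + (1−α)·Fₖ (default α = 0.9) plus a path-integral score
  accumulating the per-step first-order loss decrease attributed to each
  parameter's motion, clipped at ≥ 0; total importance Ω = F + s, anchored
  at stage boundaries and penalised exactly as in EWC. The exact
  normalisation of the path score varies across the literature; the update
  is isolated in one function (`rw_update`) for easy substitution.
* **MiB** — unbiased cross-entropy plus distillation against the previous
  network's outputs *hardened* by exponent 1/α with renormalisation
  (default α = 0.9, KD weight 1.0). The unbiased CE folds probability mass
  of classes absent from the current task into the background; in the
  domain-incremental setting that set is empty, so it reduces exactly to
  standard cross-entropy (the code path still takes the general form).

### Numerical choices for the quadratic penalties

Two choices matter at this scale and are deliberate:

1. **Importance normalisation.** Raw empirical Fisher values of squared
   per-voxel-mean gradients are ~1e-8 here, which would make any literature
   λ inert. Importance weights (EWC Fisher, RW Ω) are rescaled to [0, 1] by
   their global maximum when stored as anchors, making λ comparable across
   loss scales and parameter counts. `compute_fisher` itself returns the
   raw empirical Fisher.
2. **Proximal application.** An explicit gradient step on a quadratic
   penalty diverges once lr·λ·Ω > 2 (observable at λ = 40). The penalty is
   therefore applied as an implicit (proximal) update,
   θ ← (θ + lr·λ·ΣΩθ*)/(1 + lr·λ·ΣΩ), which minimises the same objective,
   is unconditionally stable for any λ, and is an exact no-op at λ = 0 (so
   the reduction identity stays bitwise). Model *rigidity* is therefore
   monotone in λ in the importance-weighted drift metric
   √(ΣΩ(θ−θ*)²) — the quantity the penalty controls; the unweighted
   parameter distance need not be monotone, because the optimiser can route
   adaptation through low-importance parameters.

In multi-head mode the penalties anchor body parameters only (per-task
heads have no meaningful cross-task anchor); in single-head mode they cover
body and the shared head.

## Evaluation

* **Dice** 2|A∩B|/(|A|+|B|) per class. Both sets empty → 1.0 (perfect
  agreement on absence); one side empty → 0.0. These conventions are fixed
  because thin-ROI tasks regularly produce empty predictions.
* **Performance matrix.** After every stage the model is evaluated on every
  task's test split (per class, mean over cases), plus one row of
  independently trained per-task reference models.
* **BWT** = final-model Dice on task i minus the Dice right after task i's
  own stage; negative = forgetting. **FWT** = Dice right after task i's
  stage minus the matched independent model's Dice on task i; negative =
  plasticity loss. The independent reference uses the same architecture,
  budget and seed stream as the continual run, so FWT of the first task is
  exactly 0 by construction. Relative forms are percentages of the
  reference value, undefined (NaN) when the reference is below 1e-3 Dice.
  "Mean Dice" across classes is unweighted; per-class values are kept.
  Reported ± values are standard deviations over test cases.
* **Trajectories** record the mean foreground Dice on every task's
  validation set after every epoch of every stage.
* **Inter-task matrix** trains one independent model per task and
  cross-evaluates all pairs; the gap between diagonal and off-diagonal
  entries is the package's operational measure of domain shift.

## The packaged benchmarks

`run_forgetting_benchmark` is the standard study: the high-shift pair
(64×64, 30 cases/task), 200 SGD steps per stage, three seeds, under
sequential / rehearsal (0.25) / rigid EWC (λ = 4). Expected behaviour, which
the acceptance suite asserts: sequential training collapses task-1 Dice
after the boundary (drop ≥ 0.15); rehearsal removes most of that drop
(≥ 50% reduction); rigid EWC costs final-task Dice relative to sequential
(plasticity loss). The no-shift control keeps the inter-task matrix
off-diagonals within 0.05 Dice of the diagonals, and BWT/FWT sit at zero up
to sampling noise.

These synthetic results demonstrate the *mechanics* of forgetting and the
relative ordering of strategies under a controlled, strong, low-dimensional
domain shift. They do not predict absolute Dice levels, method rankings
under the weaker and higher-dimensional shifts of real multi-site MRI, or
any behaviour that depends on 3-D patch-based training.

## Degenerate inputs and edge rules

* Specs that cannot be realised (ROI does not fit the image with margins)
  raise a generation error; masks are guaranteed at least one foreground
  voxel per case.
* Unmapped nonzero labels abort alignment, naming the label and case.
* Splits that would leave a side empty raise, except the generator's own
  default split which clamps to one case minimum per side.
* Tie-breaking, empty-set Dice, and the relative-metric guard are fixed as
  above and tested.

## Known limitations

* Whole-image 2-D/3-D training at toy resolution; no patching, deep
  supervision, augmentation or architecture search.
* Single-threaded NumPy; bitwise reproducibility is guaranteed only with a
  deterministic BLAS thread configuration.
* LwF records one output map per old head per training case per stage; at
  desk scale this is megabytes, but it grows linearly with sequence length.
* The RW path-integral normalisation follows this package's documented form;
  other published variants differ.
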