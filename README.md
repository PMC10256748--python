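# contiseg

Continual learning for semantic segmentation, at desk scale.

Clinical segmentation models are rarely trained once: data arrives site by
site, scanner by scanner, and retraining on each new dataset erases what the
model knew about earlier ones (*catastrophic forgetting*). `contiseg` is a
small, fully deterministic toolkit for studying this problem end to end on
one CPU: it generates sequences of domain-shifted synthetic segmentation
tasks, aligns heterogeneous label schemes, trains a compact encoder–decoder
network sequentially under six regimes, and scores the result with the
continual-learning metrics used in the field.

It is aimed at researchers who want a controlled, minutes-not-days sandbox
for continual-segmentation mechanics — not a replacement for full-scale
pipelines.

## What is inside

* **Synthetic task generator** — seeded sequences of tasks 𝒯₁…𝒯ₙ sharing
  anatomy (parametric ellipsoid / bilobed / ring foregrounds) but differing
  in intensity statistics, noise and raw label scheme; NIfTI + JSON-manifest
  persistence so real volumetric datasets plug in identically.
* **Label alignment** — explicit raw→target label remapping (merge
  sub-regions, drop irrelevant structures to background) with sequence-level
  validation that all tasks land on one consistent scheme.
* **Segmentation network** — a small U-Net-style net (NumPy, hand-written
  backprop, ≈14k parameters) with an explicit shared-*body* / per-task-*head*
  split, head replication at task boundaries, optional body freezing, and
  head-selected inference.
* **Six training regimes** — plain sequential fine-tuning plus five
  continual-learning strategies over one shared loop:
  rehearsal (memory buffer, default 25%), EWC (diagonal-Fisher quadratic
  penalty, λ = 0.4), LwF (temperature-T distillation of recorded outputs,
  T = 8), RW (online Fisher + path-integral importance), and MiB
  (background-modelling cross-entropy + hardened distillation, α = 0.9).
* **Continual evaluation** — per-class Dice (Eq. `2|A∩B|/(|A|+|B|)`),
  backward transfer `BWT = F_[…,i,…](𝒯ᵢ) − F_[…,i](𝒯ᵢ)` (negative ⇒
  forgetting), forward transfer `FWT = F_[…,i](𝒯ᵢ) − F_i(𝒯ᵢ)` (negative ⇒
  plasticity loss), their relative forms, inter-task matrices of independent
  per-task models, and per-epoch multi-task validation trajectories.

See `docs/methods.md` for the model, conventions and numerical choices.

## Worked example

Two synthetic "sites" share anatomy but have swapped foreground/background
contrast — a strong domain shift that survives per-case normalisation. Train
over them sequentially, with and without rehearsal:

```python
import contiseg as cs
from contiseg.model import TrainConfig
from contiseg.trainers import run_sequence
from contiseg.evaluation import PerfMatrix, backward_transfer

datasets = cs.generate_sequence(cs.high_shift_pair(), seed=0)

for method in ("sequential", "rehearsal"):
    cfg = TrainConfig(method=method, seed=0)   # 10 epochs x 20 steps per stage
    model, trajectory, stage_evals = run_sequence(datasets, cfg)
    pm = PerfMatrix.from_stage_evals(stage_evals)
    print(f"{method:10s}  siteA after own stage: {pm.at_training('siteA', 1):.3f}"
          f"   siteA final: {pm.final('siteA', 1):.3f}"
          f"   BWT(siteA): {backward_transfer(pm, 'siteA'):+.3f}")
```

Output (≈30 s on one CPU core):

```
sequential  siteA after own stage: 0.998   siteA final: 0.000   BWT(siteA): -0.998
rehearsal   siteA after own stage: 0.998   siteA final: 0.982   BWT(siteA): -0.016
```

Read: the network masters site A (Dice 0.998), then sequential fine-tuning
on the contrast-inverted site B erases it completely (final Dice 0.000,
backward transfer −0.998). Interleaving a 25% buffer of site-A cases while
training on site B retains a 0.982 Dice — rehearsal prevents nearly all
forgetting at this scale.

The same experiment is available from the shell:

```sh
contiseg simulate --preset high_shift_pair --seed 0 --out tasks/
contiseg train --method rehearsal --tasks tasks/siteA --tasks tasks/siteB \
    --seed 0 --rehearsal-fraction 0.25 --out runs/rehearsal
contiseg heads --model runs/rehearsal/model_final.npz
```

Subcommands: `simulate`, `align`, `split`, `train`, `evaluate`, `matrix`,
`compare`, `heads`.

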