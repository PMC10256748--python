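"""Training regimes: trivial sequential plus five continual-learning
strategies (Rehearsal, EWC, LwF, RW, MiB) over one shared SGD loop.

All strategies run through the same batch-sampling stream, so the reduction
identities hold bitwise: rehearsal at fraction 0, EWC at lambda 0 and RW at
lambda 0 each reproduce sequential training exactly under equal seeds.

Method state is external to the model: a rehearsal :class:`MemoryBuffer`,
an :class:`ImportanceStore` of per-task (anchor, importance) pairs for the
quadratic penalties, and a frozen :class:`TeacherSnapshot` of the previous
model state for the distillation methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import evaluation
from .model import (HEAD_PREFIX, SegModel, TrainConfig, add_head, backward,
                    build_model, conv_backward, forward_features,
                    forward_logits, freeze_body, head_logits, loss_and_grad,
                    softmax, zscore)
from .synthetic import TaskDataset, derive_seed

__all__ = [
    "MemoryBuffer", "ImportanceStore", "TeacherSnapshot", "MethodState",
    "rehearsal_sample", "empirical_fisher", "compute_fisher",
    "ewc_penalty", "penalty_gradients", "lwf_distillation",
    "harden", "mib_losses", "rw_update",
    "train_stage", "run_sequence", "train_independent",
]


# ---------------------------------------------------------------------------
# method state containers
# ---------------------------------------------------------------------------

@dataclass
class MemoryBuffer:
    """Cases sampled without replacement from previous tasks' train splits."""

    entries: list[tuple[str, str, np.ndarray, np.ndarray]]  # (task, case, image, mask)
    fraction: float
    seed: int

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class ImportanceStore:
    """Per completed task: anchor parameters theta* (value-copies) and
    nonnegative importance weights Omega with congruent named shapes.
    Entries are append-only: anchors never change after their task ends."""

    anchors: list[tuple[str, dict[str, np.ndarray], dict[str, np.ndarray]]] = field(
        default_factory=list)

    def append(self, task_id: str, theta: dict[str, np.ndarray],
               omega: dict[str, np.ndarray]) -> None:
        if set(theta) != set(omega):
            raise ValueError("anchor and importance must share parameter names")
        for k in omega:
            if omega[k].shape != theta[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            if (omega[k] < 0).any():
                raise ValueError(f"negative importance for {k}")
        self.anchors.append((task_id,
                             {k: v.copy() for k, v in theta.items()},
                             {k: v.copy() for k, v in omega.items()}))

    def __len__(self) -> int:
        return len(self.anchors)


@dataclass
class TeacherSnapshot:
    """Frozen value-copy of the model at the previous task boundary."""

    model: SegModel

    @classmethod
    def of(cls, model: SegModel) -> "TeacherSnapshot":
        return cls(model=model.copy())


@dataclass
class MethodState:
    """Everything a strategy carries across stages."""

    importance: ImportanceStore = field(default_factory=ImportanceStore)
    buffer: MemoryBuffer | None = None
    teacher: TeacherSnapshot | None = None
    rw_running: dict | None = None
    previous_tasks: list[TaskDataset] = field(default_factory=list)


# ---------------------------------------------------------------------------
# rehearsal
# ---------------------------------------------------------------------------

def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5))


def rehearsal_sample(previous: list[TaskDataset], fraction: float, seed: int) -> MemoryBuffer:
    """Uniform without-replacement sample of round(fraction * |train_j|)
    cases from each previous task's train split."""
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("rehearsal fraction must lie in [0, 1]")
    entries = []
    for task in previous:
        train = task.train_cases()
        k = _round_half_away(fraction * len(train))
        rng = np.random.default_rng(derive_seed("buffer", seed, task.task_id))
        for i in sorted(rng.choice(len(train), size=k, replace=False).tolist()):
            cid, img, mask = train[i]
            entries.append((task.task_id, cid, img, mask))
    return MemoryBuffer(entries=entries, fraction=fraction, seed=seed)


# ---------------------------------------------------------------------------
# Fisher information and quadratic penalties
# ---------------------------------------------------------------------------

def empirical_fisher(weighted_grads) -> dict[str, np.ndarray]:
    """Diagonal Fisher accumulator: weighted mean of elementwise squared
    log-likelihood gradients.

    ``weighted_grads`` iterates over (weight, named-gradient-dict) pairs.
    With unit weights over sampled cases this is the empirical Fisher; with
    class-probability weights over an enumeration of outcomes it is the
    exact expected Fisher of a small model.
    """
    total_w = 0.0
    acc: dict[str, np.ndarray] = {}
    for w, grads in weighted_grads:
        total_w += w
        for k, g in grads.items():
            sq = w * np.square(g.astype(np.float64))
            acc[k] = acc.get(k, 0.0) + sq
    if total_w == 0.0:
        raise ValueError("empirical_fisher needs a nonempty weighted sample")
    return {k: (v / total_w) for k, v in acc.items()}


def compute_fisher(model: SegModel, task: TaskDataset, n_samples: int,
                   seed: int = 0) -> dict[str, np.ndarray]:
    """Empirical diagonal Fisher over sampled train cases.

    The log-likelihood is evaluated at the model's own arg-max predicted
    labels (how far outputs are from their one-hot predictions), one
    backward pass per case.
    """
    train = task.train_cases()
    if n_samples <= 0 or not train:
        raise ValueError("compute_fisher needs a nonempty sample")
    n_samples = min(n_samples, len(train))
    rng = np.random.default_rng(derive_seed("fisher", seed, task.task_id))
    idx = rng.choice(len(train), size=n_samples, replace=False)
    head = model.heads[model.active_head]

    def iter_grads():
        for i in idx:
            _, img, _ = train[i]
            x = zscore(img)[None, None]
            logits, cache = forward_logits(model.body, head, x)
            pred = np.argmax(logits, axis=1)
            p = softmax(logits, axis=1)
            onehot = np.moveaxis(
                np.eye(model.arch.n_classes, dtype=np.float32)[pred], -1, 1)
            dlogits = (p - onehot) / float(pred.size)
            yield 1.0, backward(model.body, head, cache, dlogits)

    return {k: v.astype(np.float32) for k, v in empirical_fisher(iter_grads()).items()}


def ewc_penalty(params: dict[str, np.ndarray], store: ImportanceStore,
                lam: float) -> float:
    """(lam/2) * sum over completed tasks t, parameters k of
    Omega_t,k (theta_k - theta*_t,k)^2, over the names shared with ``params``."""
    total = 0.0
    for _, theta, omega in store.anchors:
        for k in theta:
            if k not in params:
                continue
            if params[k].shape != theta[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            d = params[k].astype(np.float64) - theta[k].astype(np.float64)
            total += float((omega[k].astype(np.float64) * d * d).sum())
    return 0.5 * lam * total


def penalty_gradients(params: dict[str, np.ndarray], store: ImportanceStore,
                      lam: float) -> dict[str, np.ndarray]:
    """Gradient of :func:`ewc_penalty`: lam * Omega * (theta - theta*)."""
    grads: dict[str, np.ndarray] = {}
    for _, theta, omega in store.anchors:
        for k in theta:
            if k not in params:
                continue
            g = lam * omega[k] * (params[k] - theta[k])
            grads[k] = grads.get(k, 0.0) + g
    return grads


def apply_proximal_penalty(params: dict[str, np.ndarray], store: ImportanceStore,
                           lam: float, lr: float) -> None:
    """Implicit (proximal) SGD step on the quadratic penalty, in place:

    theta <- (theta + lr*lam*sum_t Omega_t theta*_t) / (1 + lr*lam*sum_t Omega_t)

    This minimises the same penalty as the explicit gradient but is
    unconditionally stable for arbitrarily large lambda (an explicit step
    diverges once lr*lam*Omega > 2)."""
    coeff: dict[str, np.ndarray] = {}
    pull: dict[str, np.ndarray] = {}
    for _, theta, omega in store.anchors:
        for k in theta:
            if k not in params:
                continue
            coeff[k] = coeff.get(k, 0.0) + omega[k]
            pull[k] = pull.get(k, 0.0) + omega[k] * theta[k]
    for k in coeff:
        denom = 1.0 + lr * lam * coeff[k]
        params[k][...] = (params[k] + lr * lam * pull[k]) / denom


# ---------------------------------------------------------------------------
# distillation losses
# ---------------------------------------------------------------------------

def lwf_distillation(teacher_logits: np.ndarray, student_logits: np.ndarray,
                     temperature: float):
    """Temperature-scaled distillation of recorded teacher outputs.

    Returns ``(value, dlogits_student)`` where the value is
    T^2 * KL(softmax(t/T) || softmax(s/T)) averaged over voxels — zero when
    the student reproduces the recorded outputs, and equivalent (up to the
    constant teacher entropy) to the soft cross-entropy at any T.  The T^2
    factor keeps gradient magnitude independent of T.
    """
    T = float(temperature)
    pt = softmax(teacher_logits / T, axis=1)
    ps = softmax(student_logits / T, axis=1)
    nvox = float(teacher_logits.size / teacher_logits.shape[1])
    kl = float((pt * (np.log(np.maximum(pt, 1e-12)) -
                      np.log(np.maximum(ps, 1e-12)))).sum() / nvox)
    value = T * T * kl
    dlogits = (T * (ps - pt) / nvox).astype(np.float32)
    return value, dlogits


def harden(probs: np.ndarray, alpha: float, axis: int = 1) -> np.ndarray:
    """Sharpen a probability vector: p^(1/alpha), renormalised.

    alpha = 1 is the identity; alpha < 1 pushes mass toward the mode."""
    if alpha <= 0:
        raise ValueError("hardening alpha must be > 0")
    q = np.power(np.maximum(probs, 1e-12), 1.0 / alpha)
    return q / q.sum(axis=axis, keepdims=True)


def mib_ce(student_logits: np.ndarray, targets: np.ndarray, n_classes: int,
           old_exclusive: tuple[int, ...] = ()) -> float:
    """Unbiased cross-entropy: probability mass of classes absent from the
    current task's label space is folded into the background.  In the
    domain-incremental setting the old-exclusive set is empty and this
    reduces exactly to standard cross-entropy."""
    p = softmax(student_logits, axis=1)
    if old_exclusive:
        p = p.copy()
        p[:, 0] = p[:, 0] + p[:, list(old_exclusive)].sum(axis=1)
        p[:, list(old_exclusive)] = 0.0
    p_true = np.take_along_axis(p, targets[:, None], axis=1)
    return float(-np.log(np.maximum(p_true, 1e-12)).mean())


def mib_losses(student_logits: np.ndarray, targets: np.ndarray,
               teacher_logits: np.ndarray, alpha: float,
               old_exclusive: tuple[int, ...] = ()):
    """MiB loss pair: (unbiased CE, distillation vs hardened teacher).

    The KD term is the cross-entropy between the teacher's softmax outputs
    hardened by exponent 1/alpha (renormalised) and the student's softmax;
    its minimum over students equals the hardened-teacher entropy.  Returns
    ``(ce, kd, dlogits_kd)``.
    """
    q = harden(softmax(teacher_logits, axis=1), alpha)
    ps = softmax(student_logits, axis=1)
    nvox = float(targets.size)
    kd = float(-(q * np.log(np.maximum(ps, 1e-12))).sum() / nvox)
    ce = mib_ce(student_logits, targets, student_logits.shape[1], old_exclusive)
    dlogits_kd = ((ps - q) / nvox).astype(np.float32)
    return ce, kd, dlogits_kd


# ---------------------------------------------------------------------------
# Riemannian-walk online importance
# ---------------------------------------------------------------------------

def rw_update(state: dict | None, gradients: dict[str, np.ndarray],
              params_before: dict[str, np.ndarray],
              params_after: dict[str, np.ndarray], alpha: float) -> dict:
    """One optimisation-step update of the online RW importance.

    Running Fisher  F_k <- alpha * g_k^2 + (1 - alpha) * F_k  and a
    path-integral score s_k accumulating the first-order loss decrease
    attributed to the step's parameter motion, -g_k * (theta_after -
    theta_before), clipped at >= 0.  Total importance Omega = F + s.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("rw alpha must lie in [0, 1]")
    if state is None:
        state = {"fisher": {}, "score": {}}
    for k, g in gradients.items():
        g2 = np.square(g)
        prev = state["fisher"].get(k, np.zeros_like(g))
        state["fisher"][k] = alpha * g2 + (1.0 - alpha) * prev
        motion = params_after[k] - params_before[k]
        contrib = np.clip(-g * motion, 0.0, None)
        state["score"][k] = state["score"].get(k, np.zeros_like(g)) + contrib
    return state


def rw_importance(state: dict) -> dict[str, np.ndarray]:
    return {k: state["fisher"][k] + state["score"].get(k, 0.0) for k in state["fisher"]}


# ---------------------------------------------------------------------------
# the training loop
# ---------------------------------------------------------------------------

def _pool(task: TaskDataset, buffer: MemoryBuffer | None):
    """Training pool: current train split plus buffer, all z-scored; every
    case has equal sampling weight."""
    entries = [(cid, zscore(img), mask.astype(np.int64))
               for cid, img, mask in task.train_cases()]
    if buffer is not None:
        entries += [(cid, zscore(img), mask.astype(np.int64))
                    for _, cid, img, mask in buffer.entries]
    return entries


def _batch(pool, idx):
    x = np.stack([pool[i][1] for i in idx])[:, None]
    y = np.stack([pool[i][2] for i in idx])
    return x, y


def _sgd(model: SegModel, grads: dict[str, np.ndarray], lr: float) -> None:
    for name, p in model.trainable().items():
        if name in grads:
            p -= lr * grads[name]


def _validation_dice(model: SegModel, tasks) -> dict[str, float]:
    """Mean foreground Dice of the current model on every task's validation
    (held-out) cases; per-task heads are used where they exist."""
    out = {}
    for t in tasks:
        try:
            head_task = t.task_id if (model.head_mode == "multi" and t.task_id in model.heads) else None
        except KeyError:  # pragma: no cover
            head_task = None
        scores = []
        for _, img, mask in t.test_cases():
            pred = evaluation.predict_for(model, img, head_task)
            scores.append(evaluation.mean_foreground_dice(pred, mask, model.arch.n_classes))
        out[t.task_id] = float(np.mean(scores)) if scores else float("nan")
    return out


def _quadratic_penalty_names(model: SegModel) -> bool:
    """Quadratic penalties anchor the shared parameters: body+head in
    single-head mode, body only in multi-head mode (per-task heads have no
    cross-task anchor)."""
    return model.head_mode == "single"


def _anchored(model: SegModel) -> dict[str, np.ndarray]:
    if _quadratic_penalty_names(model):
        return model.all_named()
    return dict(model.body)


def train_stage(model: SegModel, task: TaskDataset, config: TrainConfig,
                state: MethodState, stage_index: int,
                val_tasks: list[TaskDataset] | None = None):
    """Train one stage in place; returns the trajectory fragment (one record
    per epoch per validation task)."""
    if val_tasks is None:
        val_tasks = [task]
    method = config.method
    params = config.method_params
    stage_seed = derive_seed("stage", config.seed, stage_index)
    rng = np.random.default_rng(stage_seed)

    if method == "lwf":
        if model.head_mode != "multi":
            raise ValueError("LwF requires head_mode='multi' (task-specific heads)")
        return _lwf_stage(model, task, config, state, stage_index, val_tasks, rng)

    buffer = state.buffer if method == "rehearsal" else None
    pool = _pool(task, buffer)
    n_classes = model.arch.n_classes
    lam = params.get("lam", 0.0)
    use_penalty = method in ("ewc", "rw") and lam > 0 and len(state.importance) > 0
    teacher = state.teacher.model if (method == "mib" and state.teacher is not None) else None
    head = model.heads[model.active_head]

    traj = []
    for epoch in range(config.epochs):
        for _ in range(config.steps_per_epoch):
            idx = rng.integers(0, len(pool), size=config.batch_size)
            x, y = _batch(pool, idx)
            logits, cache = forward_logits(model.body, head, x)
            loss, dlogits = loss_and_grad(logits, y, n_classes)
            if teacher is not None:
                t_logits, _ = forward_logits(teacher.body,
                                             teacher.heads[teacher.active_head], x)
                _, _, dkd = mib_losses(logits, y, t_logits, params["alpha"])
                dlogits = dlogits + params["kd_weight"] * dkd
            grads = backward(model.body, head, cache, dlogits)
            if method == "rw":
                before = {k: v.copy() for k, v in model.trainable().items()}
                _sgd(model, grads, config.learning_rate)
                if use_penalty:
                    apply_proximal_penalty(_anchored(model), state.importance,
                                           lam, config.learning_rate)
                state.rw_running = rw_update(state.rw_running, {
                    k: grads[k] for k in before if k in grads},
                    before, model.trainable(), params["alpha"])
            else:
                _sgd(model, grads, config.learning_rate)
                if use_penalty:
                    apply_proximal_penalty(_anchored(model), state.importance,
                                           lam, config.learning_rate)
        for tid, d in _validation_dice(model, val_tasks).items():
            traj.append({"stage": stage_index, "stage_task": task.task_id,
                         "epoch": epoch, "task": tid, "dice": d})
    return traj


def _lwf_stage(model, task, config, state, stage_index, val_tasks, rng):
    """Three-phase LwF stage: (1) record the previous model's outputs on the
    new task's train images once; (2) warm up the new head with the body and
    old heads frozen; (3) fine-tune body and all heads, old heads supervised
    by the recorded outputs through temperature-T distillation."""
    params = config.method_params
    T = params["temperature"]
    pool = _pool(task, None)
    n_classes = model.arch.n_classes
    old_heads = [tid for tid in model.heads if tid != model.active_head]

    recorded: dict[str, list[np.ndarray]] = {tid: [] for tid in old_heads}
    if old_heads and state.teacher is not None:
        teacher = state.teacher.model
        for _, ximg, _ in pool:
            feat_t, _ = forward_features(teacher.body, ximg[None, None])
            for tid in old_heads:
                t_logits, _ = head_logits(teacher.heads[tid], feat_t)
                recorded[tid].append(t_logits[0])

    n_warm = max(1, _round_half_away(params["warmup_fraction"] * config.epochs)) \
        if old_heads else 0
    head = model.heads[model.active_head]
    traj = []
    for epoch in range(config.epochs):
        warmup = epoch < n_warm
        for _ in range(config.steps_per_epoch):
            idx = rng.integers(0, len(pool), size=config.batch_size)
            x, y = _batch(pool, idx)
            feat, cache = forward_features(model.body, x)
            logits, hcols = head_logits(head, feat)
            cache["head_cols"] = hcols
            _, dlogits = loss_and_grad(logits, y, n_classes)
            extra_dfeat = None
            if not warmup and old_heads:
                extra_dfeat = np.zeros_like(feat)
                for tid in old_heads:
                    s_logits, s_cols = head_logits(model.heads[tid], feat)
                    t_logits = np.stack([recorded[tid][i] for i in idx])
                    _, dkd = lwf_distillation(t_logits, s_logits, T)
                    dfeat_o, dw, db = conv_backward(
                        dkd, s_cols, model.heads[tid][f"{HEAD_PREFIX}.w"], feat.shape)
                    model.heads[tid][f"{HEAD_PREFIX}.w"] -= config.learning_rate * dw
                    model.heads[tid][f"{HEAD_PREFIX}.b"] -= config.learning_rate * db
                    extra_dfeat += dfeat_o
            grads = backward(model.body, head, cache, dlogits,
                             extra_dfeat=None if warmup else extra_dfeat)
            if warmup and old_heads:
                grads = {k: g for k, g in grads.items() if k.startswith(HEAD_PREFIX)}
            _sgd(model, grads, config.learning_rate)
        for tid, d in _validation_dice(model, val_tasks).items():
            traj.append({"stage": stage_index, "stage_task": task.task_id,
                         "epoch": epoch, "task": tid, "dice": d})
    return traj


# ---------------------------------------------------------------------------
# sequence orchestration
# ---------------------------------------------------------------------------

def _normalised(omega: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Rescale importance weights to [0, 1] by their global maximum, so the
    penalty weight lambda is comparable across loss scales and parameter
    counts."""
    peak = max((float(v.max()) for v in omega.values()), default=0.0)
    if peak <= 0.0:
        return {k: v.astype(np.float32) for k, v in omega.items()}
    return {k: (v / peak).astype(np.float32) for k, v in omega.items()}


def _post_stage(model: SegModel, task: TaskDataset, config: TrainConfig,
                state: MethodState) -> None:
    method = config.method
    params = config.method_params
    if method == "ewc":
        fisher = compute_fisher(model, task, int(params["fisher_samples"]),
                                seed=config.seed)
        anchored = _anchored(model)
        state.importance.append(task.task_id, anchored,
                                _normalised({k: fisher[k] for k in anchored
                                             if k in fisher}))
    elif method == "rw" and state.rw_running is not None:
        omega = rw_importance(state.rw_running)
        anchored = _anchored(model)
        state.importance.append(task.task_id, anchored,
                                _normalised({k: omega[k] for k in anchored
                                             if k in omega}))
    if method in ("lwf", "mib"):
        state.teacher = TeacherSnapshot.of(model)
    state.previous_tasks.append(task)


def run_sequence(datasets: list[TaskDataset], config: TrainConfig,
                 model: SegModel | None = None):
    """Train sequentially over an ordered task list.

    Returns ``(model, trajectory, stage_evals)`` where ``stage_evals`` maps
    each completed stage to per-task, per-class test Dice of the model state
    at that point (the substrate of the performance matrix).
    """
    if not datasets:
        raise ValueError("empty task sequence")
    if model is None:
        model = build_model(datasets[0], seed=config.seed, head_mode=config.head_mode)
    model.provenance.update({"method": config.method, "seed": config.seed})
    state = MethodState()
    trajectory: list[dict] = []
    stage_evals: list[dict] = []
    for s, task in enumerate(datasets):
        if s > 0:
            add_head(model, task.task_id)
            if config.freeze_body_after_first:
                freeze_body(model)
            if config.method == "rehearsal":
                state.buffer = rehearsal_sample(
                    state.previous_tasks, config.method_params["fraction"],
                    seed=derive_seed("reh", config.seed, s))
        trajectory += train_stage(model, task, config, state, s, val_tasks=datasets)
        _post_stage(model, task, config, state)
        stage_evals.append({
            "stage": s, "stage_task": task.task_id,
            "dice": {t.task_id: evaluation.eval_task(model, t) for t in datasets},
        })
    return model, trajectory, stage_evals


def train_independent(task: TaskDataset, config: TrainConfig) -> SegModel:
    """Reference model trained solely on one task with the same architecture
    and budget as the continual model (the FWT baseline)."""
    cfg = TrainConfig(epochs=config.epochs, steps_per_epoch=config.steps_per_epoch,
                      batch_size=config.batch_size, learning_rate=config.learning_rate,
                      seed=config.seed, method="sequential",
                      head_mode="single")
    model = build_model(task, seed=cfg.seed, head_mode="single")
    train_stage(model, task, cfg, MethodState(), 0, val_tasks=[task])
    return model
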