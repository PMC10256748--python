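"""Continual-learning evaluation: Dice, backward/forward transfer, inter-task
matrices and multi-task validation trajectories.

Conventions, fixed and documented because they change downstream numbers:

* Dice of two empty voxel sets is 1.0 (perfect agreement on absence); empty
  prediction against nonempty truth (or vice versa) is 0.0.
* Relative BWT/FWT are percentages of the right-hand reference value, with a
  denominator guard of 1e-3 Dice below which the relative form is undefined
  and reported as NaN.
* "Mean Dice" across classes is the unweighted mean over foreground classes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import SegModel, TrainConfig, predict
from .synthetic import TaskDataset

__all__ = [
    "dice", "mean_foreground_dice", "predict_for", "eval_task",
    "PerfMatrix", "backward_transfer", "forward_transfer",
    "inter_task_matrix", "evaluate_final",
    "trajectory_to_jsonl", "trajectory_from_jsonl", "trajectory_frame",
]

#: guard below which relative transfer metrics are undefined
RELATIVE_EPS = 1e-3


def dice(pred: np.ndarray, truth: np.ndarray, cls: int) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|) of class-``cls`` voxel sets."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    a = pred == cls
    b = truth == cls
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def mean_foreground_dice(pred: np.ndarray, truth: np.ndarray, n_classes: int) -> float:
    return float(np.mean([dice(pred, truth, c) for c in range(1, n_classes)]))


def predict_for(model: SegModel, image: np.ndarray, task_id: str | None) -> np.ndarray:
    return predict(model, image, task_id)


def _head_for(model: SegModel, task_id: str) -> str | None:
    if model.head_mode == "multi" and task_id in model.heads:
        return task_id
    return None


def eval_task(model: SegModel, task: TaskDataset) -> dict[int, dict[str, float]]:
    """Per-class test Dice of the model on one task: mean/std over cases."""
    head_task = _head_for(model, task.task_id)
    per_class: dict[int, list[float]] = {c: [] for c in range(1, model.arch.n_classes)}
    for _, img, mask in task.test_cases():
        pred = predict(model, img, head_task)
        for c in per_class:
            per_class[c].append(dice(pred, mask, c))
    return {c: {"mean": float(np.mean(v)), "std": float(np.std(v)), "n": len(v)}
            for c, v in per_class.items()}


# ---------------------------------------------------------------------------
# performance matrix
# ---------------------------------------------------------------------------

@dataclass
class PerfMatrix:
    """Dice of the model state after each stage, evaluated on every task,
    plus the per-task independently-trained reference row."""

    stage_order: list[str] = field(default_factory=list)  # stage s -> task trained at s
    entries: dict[tuple[int, str, int], float] = field(default_factory=dict)
    independent: dict[tuple[str, int], float] = field(default_factory=dict)

    def set(self, stage: int, task: str, cls: int, value: float) -> None:
        if not (0.0 <= value <= 1.0):
            raise ValueError("Dice entries must lie in [0, 1]")
        self.entries[(int(stage), task, int(cls))] = float(value)

    def set_independent(self, task: str, cls: int, value: float) -> None:
        self.independent[(task, int(cls))] = float(value)

    def get(self, stage: int, task: str, cls: int) -> float:
        key = (int(stage), task, int(cls))
        if key not in self.entries:
            raise KeyError(f"missing performance entry {key}")
        return self.entries[key]

    def classes(self) -> list[int]:
        return sorted({c for _, _, c in self.entries})

    @property
    def n_stages(self) -> int:
        return len(self.stage_order)

    def stage_of(self, task: str) -> int:
        return self.stage_order.index(task)

    def at_training(self, task: str, cls: int) -> float:
        """F_[..., i](T_i): performance right after the task's own stage."""
        return self.get(self.stage_of(task), task, cls)

    def final(self, task: str, cls: int) -> float:
        """F_[..., i, ...](T_i): performance of the last model state."""
        return self.get(self.n_stages - 1, task, cls)

    def mean_over_classes(self, getter, task: str) -> float:
        return float(np.mean([getter(task, c) for c in self.classes()]))

    @classmethod
    def from_stage_evals(cls, stage_evals, independent: dict | None = None) -> "PerfMatrix":
        pm = cls(stage_order=[ev["stage_task"] for ev in stage_evals])
        for ev in stage_evals:
            for task_id, per_class in ev["dice"].items():
                for c, stats in per_class.items():
                    pm.set(ev["stage"], task_id, c, stats["mean"])
        if independent:
            for task_id, per_class in independent.items():
                for c, stats in per_class.items():
                    pm.set_independent(task_id, c, stats["mean"])
        return pm

    def to_frame(self) -> pd.DataFrame:
        rows = [{"stage": s, "stage_task": self.stage_order[s] if s < len(self.stage_order) else "",
                 "task": t, "class": c, "dice": v}
                for (s, t, c), v in sorted(self.entries.items())]
        rows += [{"stage": -1, "stage_task": "independent", "task": t, "class": c, "dice": v}
                 for (t, c), v in sorted(self.independent.items())]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PerfMatrix":
        df = pd.read_csv(path)
        pm = cls()
        stages = df[df["stage"] >= 0].drop_duplicates("stage").sort_values("stage")
        pm.stage_order = stages["stage_task"].tolist()
        for _, row in df.iterrows():
            if row["stage"] < 0:
                pm.set_independent(row["task"], int(row["class"]), row["dice"])
            else:
                pm.set(int(row["stage"]), row["task"], int(row["class"]), row["dice"])
        return pm


def _transfer(after: float, reference: float, relative: bool) -> float:
    delta = after - reference
    if not relative:
        return delta
    if abs(reference) < RELATIVE_EPS:
        return float("nan")
    return 100.0 * delta / reference


def backward_transfer(perf: PerfMatrix, task: str, cls: int | None = None,
                      relative: bool = False) -> float:
    """BWT = F_[..., i, ...](T_i) - F_[..., i](T_i).

    Negative means forgetting; positive means backward transfer.  With
    ``cls=None`` the unweighted mean over foreground classes is used.
    ``relative`` reports the percentage change w.r.t. the at-training value
    (NaN when the reference is below the guard).
    """
    if cls is None:
        final = perf.mean_over_classes(perf.final, task)
        at = perf.mean_over_classes(perf.at_training, task)
    else:
        final = perf.final(task, cls)
        at = perf.at_training(task, cls)
    return _transfer(final, at, relative)


def forward_transfer(perf: PerfMatrix, task: str, cls: int | None = None,
                     relative: bool = False) -> float:
    """FWT = F_[..., i](T_i) - F_i(T_i).

    Compares the continual model right after the task's stage against an
    independent model trained only on that task; negative means plasticity
    loss."""
    def indep(t: str, c: int) -> float:
        key = (t, int(c))
        if key not in perf.independent:
            raise KeyError(f"missing independent reference for {key}")
        return perf.independent[key]

    if cls is None:
        at = perf.mean_over_classes(perf.at_training, task)
        ref = perf.mean_over_classes(indep, task)
    else:
        at = perf.at_training(task, cls)
        ref = indep(task, cls)
    return _transfer(at, ref, relative)


# ---------------------------------------------------------------------------
# inter-task matrix and final evaluation
# ---------------------------------------------------------------------------

def inter_task_matrix(tasks: list[TaskDataset], config: TrainConfig,
                      return_models: bool = False):
    """Cross-evaluation grid of independent per-task models.

    Trains one model per task (fixed seeds) and evaluates each on every
    task's test split.  Returns a DataFrame of mean foreground Dice with
    model-task rows and eval-task columns; the diagonal is in-distribution
    performance.
    """
    if len(tasks) < 1:
        raise ValueError("need at least one task")
    from .trainers import train_independent

    models = {t.task_id: train_independent(t, config) for t in tasks}
    grid = {}
    for ti in tasks:
        row = {}
        for tj in tasks:
            stats = eval_task(models[ti.task_id], tj)
            row[tj.task_id] = float(np.mean([s["mean"] for s in stats.values()]))
        grid[ti.task_id] = row
    df = pd.DataFrame(grid).T  # rows: trained-on, cols: evaluated-on
    df.index.name = "trained_on"
    df.columns.name = "evaluated_on"
    return (df, models) if return_models else df


def evaluate_final(model: SegModel, tasks: list[TaskDataset]) -> pd.DataFrame:
    """Per-task, per-class test Dice (mean ± std over cases) of the final
    model state, with the matching head selected per task in multi-head
    mode."""
    for t in tasks:
        if model.head_mode == "multi" and t.task_id not in model.heads:
            raise KeyError(f"no head for task {t.task_id!r} in multi-head mode")
    rows = []
    for t in tasks:
        for c, stats in eval_task(model, t).items():
            rows.append({"task": t.task_id, "class": c,
                         "dice_mean": stats["mean"], "dice_std": stats["std"],
                         "n_cases": stats["n"]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def trajectory_frame(records: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(records)


def trajectory_to_jsonl(records: list[dict], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec) + "\n")


def trajectory_from_jsonl(path) -> list[dict]:
    return [json.loads(line) for line in Path(path).read_text().splitlines() if line]
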