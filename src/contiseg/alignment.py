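"""Label-characteristic alignment across heterogeneous task label schemes.

Segmentation corpora for the same anatomy rarely agree on label structure:
one site annotates the whole organ as label 1, another splits it into two
sub-regions (1, 2), a third adds an irrelevant neighbouring structure.
Continual training requires a single consistent scheme, so every task is
remapped once, at preprocessing time, through an explicit user-supplied
mapping — alignment is a semantic act and is never inferred from label
statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .synthetic import TaskDataset

__all__ = ["LabelMapping", "AlignmentError", "AlignmentReport",
           "align_mask", "align_dataset", "validate_alignment"]


class AlignmentError(ValueError):
    """Raised when a mask contains a nonzero label with no mapping entry."""


@dataclass(frozen=True)
class LabelMapping:
    """Raw-label -> target-label map for one task; target 0 is background.

    Background (raw 0) maps to 0 implicitly and need not be listed.
    """

    entries: Mapping[int, int]
    name: str = ""

    def __post_init__(self):
        ent = {int(k): int(v) for k, v in self.entries.items()}
        if any(k < 0 or v < 0 for k, v in ent.items()):
            raise ValueError("labels must be nonnegative")
        if ent.get(0, 0) != 0:
            raise ValueError("background (0) must map to 0")
        ent.setdefault(0, 0)
        object.__setattr__(self, "entries", ent)

    @classmethod
    def identity(cls, labels: Sequence[int], name: str = "identity") -> "LabelMapping":
        return cls({int(l): int(l) for l in labels}, name=name)

    @classmethod
    def from_json(cls, path) -> "LabelMapping":
        data = json.loads(Path(path).read_text())
        return cls({int(k): int(v) for k, v in data["map"].items()},
                   name=str(data.get("task_id", "")))

    def to_json(self, path) -> None:
        payload = {"task_id": self.name,
                   "map": {str(k): v for k, v in sorted(self.entries.items()) if k != 0}}
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    def targets(self) -> set[int]:
        return set(self.entries.values()) | {0}

    def compose(self, after: "LabelMapping") -> "LabelMapping":
        """Mapping equivalent to applying ``self`` then ``after``."""
        return LabelMapping(
            {k: after.entries.get(v, 0) if v == 0 or v in after.entries else _missing(v)
             for k, v in self.entries.items()},
            name=f"{self.name}∘{after.name}",
        )


def _missing(label: int):
    raise AlignmentError(f"composition target label {label} has no entry in outer mapping")


def align_mask(mask: np.ndarray, mapping: LabelMapping, case_id: str = "?") -> np.ndarray:
    """Remap a mask voxel-wise; errors on any unmapped nonzero label."""
    mask = np.asarray(mask)
    present = np.unique(mask)
    unmapped = [int(l) for l in present if l != 0 and int(l) not in mapping.entries]
    if unmapped:
        raise AlignmentError(
            f"case {case_id!r}: labels {unmapped} have no entry in mapping {mapping.name!r}"
        )
    lut_size = int(present.max()) + 1 if present.size else 1
    lut = np.zeros(lut_size, dtype=mask.dtype)
    for raw, tgt in mapping.entries.items():
        if raw < lut_size:
            lut[raw] = tgt
    return lut[mask]


def align_dataset(dataset: TaskDataset, mapping: LabelMapping) -> TaskDataset:
    """Return a copy of the dataset with every mask remapped (split kept)."""
    cases = [(cid, img, align_mask(m, mapping, case_id=cid)) for cid, img, m in dataset.cases]
    new_scheme = tuple(sorted(t for t in mapping.targets() if t != 0))
    spec = replace(dataset.spec, label_scheme=new_scheme if new_scheme else (1,))
    return replace(dataset, spec=spec, cases=cases)


@dataclass
class AlignmentReport:
    """Outcome of validating a sequence's alignment; failures are carried,
    not raised."""

    unified_labels: tuple[int, ...]
    per_task_labels: dict[str, tuple[int, ...]]
    per_task_voxel_counts: dict[str, dict[int, int]]  # post-alignment, per class
    failures: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.failures


def validate_alignment(datasets: Sequence[TaskDataset],
                       mappings: Sequence[LabelMapping]) -> AlignmentReport:
    """Check that the per-task mappings yield one consistent label scheme.

    Reports the unified target label set, the per-task voxel counts after
    remapping, and any task whose post-alignment labels differ from the
    unified set or whose masks contain unmapped labels.
    """
    if len(datasets) != len(mappings):
        raise ValueError("need exactly one mapping per task")
    failures: list[str] = []
    per_task_labels: dict[str, tuple[int, ...]] = {}
    per_task_counts: dict[str, dict[int, int]] = {}
    target_sets: list[set[int]] = []

    for ds, mapping in zip(datasets, mappings):
        tid = ds.task_id
        counts: dict[int, int] = {}
        observed: set[int] = set()
        ok = True
        for cid, _, mask in ds.cases:
            try:
                aligned = align_mask(mask, mapping, case_id=cid)
            except AlignmentError as exc:
                failures.append(f"task {tid}: {exc}")
                ok = False
                break
            vals, n = np.unique(aligned, return_counts=True)
            for v, c in zip(vals.tolist(), n.tolist()):
                counts[int(v)] = counts.get(int(v), 0) + int(c)
            observed |= set(int(v) for v in vals)
        if not ok:
            continue
        per_task_labels[tid] = tuple(sorted(observed))
        per_task_counts[tid] = counts
        target_sets.append(mapping.targets())

    unified: set[int] = set().union(*target_sets) if target_sets else {0}
    contiguous = sorted(unified) == list(range(len(unified)))
    if not contiguous:
        failures.append(f"target labels {sorted(unified)} are not contiguous 0..K")
    for tid, tset in zip(per_task_labels, target_sets):
        if tset != unified:
            failures.append(
                f"task {tid}: target set {sorted(tset)} != unified {sorted(unified)}"
            )
    return AlignmentReport(
        unified_labels=tuple(sorted(unified)),
        per_task_labels=per_task_labels,
        per_task_voxel_counts=per_task_counts,
        failures=failures,
    )
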