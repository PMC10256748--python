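"""Task persistence: NIfTI volumes plus a per-task JSON manifest.

A task directory holds one image and one mask file per case and a
``manifest.json`` recording the task id, label semantics, case list and the
persistent train/test split.  The manifest is the unit every other module
consumes, so real volumetric datasets laid out the same way plug in
identically to generated ones.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .synthetic import TaskDataset, TaskSpec

__all__ = ["write_task", "read_task", "MANIFEST_NAME"]

MANIFEST_NAME = "manifest.json"


def write_task(dataset: TaskDataset, directory) -> Path:
    """Write a task as NIfTI pairs + manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    case_ids = []
    for cid, image, mask in dataset.cases:
        img3 = np.asarray(image, dtype=np.float32)
        msk3 = np.asarray(mask, dtype=np.int16)
        if img3.ndim == 2:  # NIfTI stores volumes; promote planes to depth 1
            img3 = img3[..., None]
            msk3 = msk3[..., None]
        nib.save(nib.Nifti1Image(img3, np.eye(4)), directory / f"{cid}_image.nii.gz")
        nib.save(nib.Nifti1Image(msk3, np.eye(4)), directory / f"{cid}_mask.nii.gz")
        case_ids.append(cid)
    spec = dataset.spec
    manifest = {
        "task_id": spec.task_id,
        "image_shape": list(spec.image_shape),
        "label_scheme": list(spec.label_scheme),
        "label_semantics": {str(l): f"label_{l}" for l in spec.label_scheme},
        "cases": case_ids,
        "split": {"train": list(dataset.train_idx), "test": list(dataset.test_idx)},
        "generator": {
            "n_cases": spec.n_cases,
            "intensity_fg": list(spec.intensity_fg),
            "intensity_bg": list(spec.intensity_bg),
            "noise_sigma": spec.noise_sigma,
            "shape_family": spec.shape_family,
            "roi_fraction": spec.roi_fraction,
        },
    }
    path = directory / MANIFEST_NAME
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path


def read_task(directory) -> TaskDataset:
    """Load a task directory written by :func:`write_task` (or an external
    dataset following the same manifest layout)."""
    directory = Path(directory)
    manifest = json.loads((directory / MANIFEST_NAME).read_text())
    shape = tuple(manifest["image_shape"])
    cases = []
    for cid in manifest["cases"]:
        image = np.asarray(nib.load(directory / f"{cid}_image.nii.gz").dataobj,
                           dtype=np.float32)
        mask = np.asarray(nib.load(directory / f"{cid}_mask.nii.gz").dataobj,
                          dtype=np.int16)
        if len(shape) == 2:
            image = image[..., 0]
            mask = mask[..., 0]
        cases.append((cid, image, mask))
    gen = manifest.get("generator", {})
    spec = TaskSpec(
        task_id=manifest["task_id"],
        n_cases=len(cases),
        image_shape=shape,
        intensity_fg=tuple(gen.get("intensity_fg", (0.75, 0.03))),
        intensity_bg=tuple(gen.get("intensity_bg", (0.25, 0.03))),
        noise_sigma=gen.get("noise_sigma", 0.0),
        shape_family=gen.get("shape_family", "ellipsoid"),
        label_scheme=tuple(manifest["label_scheme"]),
        roi_fraction=gen.get("roi_fraction", 0.1),
    )
    return TaskDataset(spec=spec, cases=cases,
                       train_idx=tuple(manifest["split"]["train"]),
                       test_idx=tuple(manifest["split"]["test"]))
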