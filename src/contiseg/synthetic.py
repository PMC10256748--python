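"""Seeded generation of domain-shifted segmentation task sequences.

Each *task* plays the role of one acquisition site in a continual-learning
study: all tasks share anatomy (parametric foreground shapes) but differ in
intensity statistics, noise level and — optionally — in their raw label
scheme, so that the label-alignment preprocessing step is exercised.

The intensity model is deliberately minimal: piecewise-constant class means
(with per-case jitter), a smooth multiplicative bias field, and additive
Gaussian noise.  This emulates inter-scanner shift in contrast and gain, not
MRI physics.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "GenerationError",
    "TaskSpec",
    "TaskDataset",
    "generate_task",
    "generate_sequence",
    "make_split",
    "derive_seed",
    "high_shift_pair",
    "no_shift_pair",
    "shift_ladder",
    "heterogeneous_triplet",
]

SHAPE_FAMILIES = ("ellipsoid", "bilobed", "ring")

#: default fraction of cases held out for testing, fixed across experiments
DEFAULT_TEST_FRACTION = 0.2


class GenerationError(ValueError):
    """Raised when a task spec cannot be realised (e.g. ROI does not fit)."""


def derive_seed(*parts) -> int:
    """Deterministic sub-seed from arbitrary parts via SHA-256 (< 2**31).

    Sub-seeds are tied to stable identifiers (task ids, stage indices), so
    permuting a task list permutes the outputs without changing per-task
    content.
    """
    digest = hashlib.sha256(":".join(str(p) for p in parts).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class TaskSpec:
    """Declarative description of one synthetic task (acquisition site).

    Parameters
    ----------
    task_id:
        Short label, unique within a sequence.
    n_cases:
        Number of cases (images); must be >= 2 so both split sides exist.
    image_shape:
        Spatial shape, 2-D or 3-D.
    intensity_fg, intensity_bg:
        (mean, std) of the per-case foreground / background class means,
        arbitrary units.
    noise_sigma:
        Additive voxel-noise scale, >= 0.
    shape_family:
        ``ellipsoid`` | ``bilobed`` (two overlapping lobes, merge-able into
        one structure) | ``ring`` (annulus with a distinct interior
        structure when a second label is declared).
    label_scheme:
        Raw nonzero labels present in generated masks; 0 is background.
    roi_fraction:
        Target foreground voxel fraction, in (0, 0.5).
    """

    task_id: str
    n_cases: int = 30
    image_shape: tuple[int, ...] = (64, 64)
    intensity_fg: tuple[float, float] = (0.75, 0.03)
    intensity_bg: tuple[float, float] = (0.25, 0.03)
    noise_sigma: float = 0.08
    shape_family: str = "ellipsoid"
    label_scheme: tuple[int, ...] = (1,)
    roi_fraction: float = 0.12
    bias_field_strength: float = 0.08

    def __post_init__(self):
        if self.n_cases < 2:
            raise ValueError("n_cases must be >= 2")
        if len(self.image_shape) not in (2, 3) or any(s <= 0 for s in self.image_shape):
            raise ValueError("image_shape must be 2 or 3 positive integers")
        if not (0.0 < self.roi_fraction < 0.5):
            raise ValueError("roi_fraction must lie strictly in (0, 0.5)")
        if self.shape_family not in SHAPE_FAMILIES:
            raise ValueError(f"unknown shape_family {self.shape_family!r}")
        labels = tuple(int(l) for l in self.label_scheme)
        if len(set(labels)) != len(labels) or any(l <= 0 for l in labels):
            raise ValueError("label_scheme must be distinct positive integers (0 is background)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        object.__setattr__(self, "image_shape", tuple(int(s) for s in self.image_shape))
        object.__setattr__(self, "label_scheme", labels)

    @property
    def ndim(self) -> int:
        return len(self.image_shape)


@dataclass
class TaskDataset:
    """One task's realised cases plus its persistent train/test split."""

    spec: TaskSpec
    cases: list[tuple[str, np.ndarray, np.ndarray]]  # (case_id, image, mask)
    train_idx: tuple[int, ...] = ()
    test_idx: tuple[int, ...] = ()

    @property
    def task_id(self) -> str:
        return self.spec.task_id

    @property
    def n_cases(self) -> int:
        return len(self.cases)

    def train_cases(self):
        return [self.cases[i] for i in self.train_idx]

    def test_cases(self):
        return [self.cases[i] for i in self.test_idx]

    def labels_present(self) -> set[int]:
        out: set[int] = set()
        for _, _, mask in self.cases:
            out |= set(np.unique(mask).tolist())
        return out


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _rotation_matrix(ndim: int, rng: np.random.Generator) -> np.ndarray:
    if ndim == 2:
        a = rng.uniform(0, np.pi)
        c, s = np.cos(a), np.sin(a)
        return np.array([[c, -s], [s, c]])
    # random 3-D rotation via QR of a Gaussian matrix
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    return q * np.sign(np.diag(r))


def _ellipsoid_mask(shape, center, axes, rot) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    pts = np.stack([g - c for g, c in zip(grids, center)], axis=-1)
    local = pts @ rot  # rotate into ellipsoid frame
    q = sum((local[..., i] / axes[i]) ** 2 for i in range(len(shape)))
    return q <= 1.0


def _axes_for_volume(volume: float, ndim: int, aspect: float) -> np.ndarray:
    """Semi-axes of an ellipse/ellipsoid of given volume and aspect ratio."""
    if ndim == 2:
        # pi * a * b = volume, a / b = aspect
        b = np.sqrt(volume / (np.pi * aspect))
        return np.array([aspect * b, b])
    # (4/3) pi a b c = volume with a = aspect * b, c = b
    b = (volume / ((4.0 / 3.0) * np.pi * aspect)) ** (1.0 / 3.0)
    return np.array([aspect * b, b, b])


def _place_center(shape, bound: float, rng: np.random.Generator) -> np.ndarray:
    margin = bound + 1.0
    if any(s - 2 * margin <= 0 for s in shape):
        raise GenerationError(
            f"ROI of radius {bound:.1f} cannot fit inside image of shape {tuple(shape)}"
        )
    return np.array([rng.uniform(margin, s - margin) for s in shape])


def _render_mask(spec: TaskSpec, rng: np.random.Generator) -> np.ndarray:
    shape = spec.image_shape
    ndim = spec.ndim
    total = spec.roi_fraction * float(np.prod(shape))
    labels = spec.label_scheme
    mask = np.zeros(shape, dtype=np.int16)

    if spec.shape_family == "ellipsoid":
        aspect = rng.uniform(1.0, 1.6)
        axes = _axes_for_volume(total, ndim, aspect)
        center = _place_center(shape, axes.max(), rng)
        rot = _rotation_matrix(ndim, rng)
        mask[_ellipsoid_mask(shape, center, axes, rot)] = labels[0]

    elif spec.shape_family == "bilobed":
        # two overlapping lobes; with two declared labels each lobe keeps its
        # own sub-label (head/body style), otherwise they form one structure
        aspect = rng.uniform(1.0, 1.4)
        lobe_vol = 0.58 * total
        axes = _axes_for_volume(lobe_vol, ndim, aspect)
        sep = 0.9 * axes.max()
        center = _place_center(shape, axes.max() + sep / 2.0, rng)
        direction = rng.standard_normal(ndim)
        direction /= np.linalg.norm(direction)
        rot = _rotation_matrix(ndim, rng)
        m1 = _ellipsoid_mask(shape, center - direction * sep / 2.0, axes, rot)
        m2 = _ellipsoid_mask(shape, center + direction * sep / 2.0, axes, rot)
        l1 = labels[0]
        l2 = labels[1] if len(labels) > 1 else labels[0]
        mask[m2] = l2
        mask[m1] = l1  # overlap resolved toward the first lobe

    elif spec.shape_family == "ring":
        # annulus (the ROI); the interior is a distinct structure when a
        # second raw label is declared, e.g. a cavity to be dropped later
        kappa = 0.6
        outer_vol = total / (1.0 - kappa**ndim)
        aspect = rng.uniform(1.0, 1.3)
        axes = _axes_for_volume(outer_vol, ndim, aspect)
        center = _place_center(shape, axes.max(), rng)
        rot = _rotation_matrix(ndim, rng)
        outer = _ellipsoid_mask(shape, center, axes, rot)
        inner = _ellipsoid_mask(shape, center, axes * kappa, rot)
        mask[outer & ~inner] = labels[0]
        if len(labels) > 1:
            mask[inner] = labels[1]

    if not (mask > 0).any():
        raise GenerationError(f"generated mask for task {spec.task_id!r} has no foreground")
    return mask


def _render_image(spec: TaskSpec, mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    fg_mean = rng.normal(*spec.intensity_fg)
    bg_mean = rng.normal(*spec.intensity_bg)
    image = np.full(spec.image_shape, bg_mean, dtype=np.float32)
    # secondary structures take intermediate intensity so they are visually
    # distinct from the primary ROI
    for idx, label in enumerate(spec.label_scheme):
        mean = fg_mean + idx * 0.45 * (bg_mean - fg_mean)
        image[mask == label] = mean
    if spec.bias_field_strength > 0:
        bias = gaussian_filter(
            rng.standard_normal(spec.image_shape), sigma=max(spec.image_shape) / 4.0
        )
        sd = bias.std()
        if sd > 0:
            bias = bias / sd
        image = image * (1.0 + spec.bias_field_strength * bias).astype(np.float32)
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, spec.image_shape).astype(np.float32)
    return image.astype(np.float32)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def generate_task(spec: TaskSpec, seed: int) -> TaskDataset:
    """Generate one task deterministically from ``(spec, seed)``.

    Cases are drawn independently; a 20% test split (round half away from
    zero) is attached and persists with the dataset.
    """
    rng = np.random.default_rng(derive_seed("task", spec.task_id, seed))
    cases = []
    for i in range(spec.n_cases):
        mask = _render_mask(spec, rng)
        image = _render_image(spec, mask, rng)
        cases.append((f"{spec.task_id}_{i:03d}", image, mask))
    ds = TaskDataset(spec=spec, cases=cases)
    return make_split(ds, DEFAULT_TEST_FRACTION,
                      seed=derive_seed("split", spec.task_id, seed), clamp=True)


def generate_sequence(specs: Sequence[TaskSpec], seed: int) -> list[TaskDataset]:
    """Generate an ordered task sequence; per-task seeds are tied to task ids
    so reordering the specs permutes (but does not alter) the datasets."""
    ids = [s.task_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate task_id in sequence: {ids}")
    return [generate_task(s, derive_seed("seq", seed, s.task_id)) for s in specs]


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def make_split(dataset: TaskDataset, test_fraction: float, seed: int,
               clamp: bool = False) -> TaskDataset:
    """Attach a deterministic train/test split; |test| = round(f * n).

    With ``clamp`` the test side is clamped to [1, n-1] instead of erroring,
    so tiny datasets always keep one case on each side."""
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must be in (0, 1)")
    n = dataset.n_cases
    n_test = _round_half_away(n * test_fraction)
    if clamp:
        n_test = min(max(n_test, 1), n - 1)
    if n_test == 0 or n_test == n:
        raise ValueError(
            f"split of {n} cases at fraction {test_fraction} leaves one side empty"
        )
    perm = np.random.default_rng(seed).permutation(n)
    test = tuple(sorted(int(i) for i in perm[:n_test]))
    train = tuple(sorted(int(i) for i in perm[n_test:]))
    return replace(dataset, train_idx=train, test_idx=test)


# ---------------------------------------------------------------------------
# benchmark presets
# ---------------------------------------------------------------------------
# The high-shift pair swaps foreground/background intensity means between
# sites (a contrast inversion — the shift survives per-case z-scoring), which
# reliably induces catastrophic forgetting in a plain sequential run.

def high_shift_pair(n_cases: int = 30, image_shape=(64, 64)) -> list[TaskSpec]:
    """Two sites with swapped fg/bg intensity means: the standard forgetting
    benchmark."""
    a = TaskSpec(task_id="siteA", n_cases=n_cases, image_shape=image_shape,
                 intensity_fg=(0.75, 0.03), intensity_bg=(0.25, 0.03))
    b = replace(a, task_id="siteB", intensity_fg=(0.25, 0.03), intensity_bg=(0.75, 0.03))
    return [a, b]


def no_shift_pair(n_cases: int = 30, image_shape=(64, 64)) -> list[TaskSpec]:
    """Two sites with identical generating distributions (control pair)."""
    a = TaskSpec(task_id="site1", n_cases=n_cases, image_shape=image_shape)
    b = replace(a, task_id="site2")
    return [a, b]


def shift_ladder(gaps: Sequence[float], n_cases: int = 30, image_shape=(64, 64)) -> list[list[TaskSpec]]:
    """Pairs of specs whose fg/bg mean gap shrinks toward inversion.

    ``gap`` is the second site's foreground-minus-background mean difference;
    the first site is fixed at +0.5.  Decreasing (more negative) gaps give
    increasing domain shift.
    """
    pairs = []
    for g, gap in enumerate(gaps):
        a = TaskSpec(task_id=f"ref{g}", n_cases=n_cases, image_shape=image_shape,
                     intensity_fg=(0.75, 0.03), intensity_bg=(0.25, 0.03))
        mid = 0.5
        b = replace(a, task_id=f"shifted{g}",
                    intensity_fg=(mid + gap / 2.0, 0.03),
                    intensity_bg=(mid - gap / 2.0, 0.03))
        pairs.append([a, b])
    return pairs


def heterogeneous_triplet(n_cases: int = 30, image_shape=(64, 64)) -> list[TaskSpec]:
    """Three sites sharing anatomy but with heterogeneous raw label schemes.

    * ``siteP``: one ROI label {1} (already aligned).
    * ``siteQ``: bilobed ROI annotated as two sub-labels {1, 2} that must be
      merged into one structure.
    * ``siteR``: ring ROI {1} plus an irrelevant interior structure {2} that
      must be mapped to background.
    """
    p = TaskSpec(task_id="siteP", n_cases=n_cases, image_shape=image_shape)
    q = TaskSpec(task_id="siteQ", n_cases=n_cases, image_shape=image_shape,
                 shape_family="bilobed", label_scheme=(1, 2),
                 intensity_fg=(0.65, 0.03), intensity_bg=(0.3, 0.03))
    r = TaskSpec(task_id="siteR", n_cases=n_cases, image_shape=image_shape,
                 shape_family="ring", label_scheme=(1, 2),
                 intensity_fg=(0.8, 0.03), intensity_bg=(0.2, 0.03),
                 roi_fraction=0.14)
    return [p, q, r]
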