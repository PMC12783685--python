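"""Self-supervised training objectives as desk-scale, framework-free math.

The pre-training scheme pairs a DINO-style teacher/student cross-entropy with
a Barlow Twins redundancy-reduction term at a 1:1 ratio.  Two twists make it
batch-aware for multi-replica live imaging:

* *cross-batch centering* — the teacher keeps a separate EMA center vector
  per experimental batch (replica) and subtracts the center of whichever
  batch fed the teacher branch, so batch-specific logit offsets cannot leak
  into the targets;
* *cross-batch crop sampling* — the two global crops of a view pair come
  from two different replicas of the same (compound, dose, timepoint), with
  the focal plane of every crop drawn uniformly from the z-stack
  (plane-agnostic augmentation, replacing artificial Gaussian blur).

Everything here is pure NumPy on small arrays: the loss/augmentation
contract, consumable by any training harness, with no optimizer or backbone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import log_softmax, softmax

__all__ = [
    "CenterBank",
    "CropSpec",
    "Crop",
    "LossWeights",
    "dino_cross_batch_loss",
    "update_centers",
    "barlow_twins_loss",
    "combined_loss",
    "sample_cross_batch_crops",
]


@dataclass
class LossWeights:
    """Loss mixing weights and softmax temperatures."""

    dino_weight: float = 1.0
    barlow_weight: float = 1.0
    barlow_offdiag_lambda: float = 0.5
    student_temp: float = 0.1
    teacher_temp: float = 0.04

    def __post_init__(self):
        if self.dino_weight < 0 or self.barlow_weight < 0:
            raise ValueError("loss weights must be non-negative")
        if self.student_temp <= 0 or self.teacher_temp <= 0:
            raise ValueError("temperatures must be positive")


@dataclass
class CenterBank:
    """Per-batch EMA center vectors for teacher centering."""

    centers: dict[str, np.ndarray]
    momentum: float = 0.9

    def __post_init__(self):
        if not 0 <= self.momentum <= 1:
            raise ValueError("momentum must lie in [0, 1]")
        dims = {np.asarray(v).shape for v in self.centers.values()}
        if len(dims) > 1:
            raise ValueError("all centers must share one dimension")
        for b, v in self.centers.items():
            if not np.isfinite(v).all():
                raise ValueError(f"center for batch {b!r} is not finite")


def dino_cross_batch_loss(
    student_logits: np.ndarray,
    teacher_logits: np.ndarray,
    batch_ids,
    bank: CenterBank,
    weights: LossWeights,
) -> float:
    """Mean teacher->student cross-entropy with per-batch teacher centering.

    Row ``i`` gets target ``t_i = softmax((teacher_i - center[batch_i]) / tau_t)``
    (teacher is gradient-stopped by construction here) and contributes
    ``-sum t_i log softmax(student_i / tau_s)``.
    """
    student = np.asarray(student_logits, dtype=float)
    teacher = np.asarray(teacher_logits, dtype=float)
    if student.shape != teacher.shape:
        raise ValueError("student and teacher logits must share a shape")
    batch_ids = list(batch_ids)
    if len(batch_ids) != len(student):
        raise ValueError("one batch id per row required")
    unknown = [b for b in batch_ids if b not in bank.centers]
    if unknown:
        raise KeyError(f"batch id(s) {sorted(set(unknown))} missing from the center bank")
    centers = np.stack([bank.centers[b] for b in batch_ids])
    targets = softmax((teacher - centers) / weights.teacher_temp, axis=1)
    log_student = log_softmax(student / weights.student_temp, axis=1)
    return float(-(targets * log_student).sum(axis=1).mean())


def update_centers(bank: CenterBank, batch_id: str, teacher_logits: np.ndarray) -> CenterBank:
    """EMA update of one batch's center: ``m*c + (1-m)*mean(teacher rows)``.

    Returns a new bank; all other batches are untouched.  Empty input is a
    warned no-op.
    """
    rows = np.atleast_2d(np.asarray(teacher_logits, dtype=float))
    if rows.size == 0:
        warnings.warn(f"no teacher rows for batch {batch_id!r}; center unchanged", stacklevel=2)
        return CenterBank(dict(bank.centers), bank.momentum)
    if batch_id not in bank.centers:
        raise KeyError(f"unknown batch id {batch_id!r}")
    m = bank.momentum
    centers = {b: np.array(v, dtype=float) for b, v in bank.centers.items()}
    centers[batch_id] = m * centers[batch_id] + (1 - m) * rows.mean(axis=0)
    return CenterBank(centers, m)


def barlow_twins_loss(zA: np.ndarray, zB: np.ndarray, lam: float = 0.5) -> float:
    """Barlow Twins redundancy-reduction loss.

    Columns of both views are standardized over the batch (zero-SD columns
    fall back to SD + 1e-12 so degenerate toy batches stay finite), the
    cross-correlation ``C = zA'^T zB' / N`` is formed, and the loss is
    ``sum_i (1 - C_ii)^2 + lam * sum_{i != j} C_ij^2``.
    """
    zA = np.asarray(zA, dtype=float)
    zB = np.asarray(zB, dtype=float)
    if zA.shape != zB.shape or zA.ndim != 2:
        raise ValueError("views must be two equal-shape 2-d arrays")
    N = zA.shape[0]
    if N < 2:
        raise ValueError("Barlow Twins needs a batch of at least 2")

    def _standardize(z):
        sd = z.std(axis=0)
        return (z - z.mean(axis=0)) / (sd + 1e-12)

    C = _standardize(zA).T @ _standardize(zB) / N
    on_diag = ((1.0 - np.diag(C)) ** 2).sum()
    off_diag = (C**2).sum() - (np.diag(C) ** 2).sum()
    return float(on_diag + lam * off_diag)


def combined_loss(dino: float, barlow: float, weights: LossWeights | None = None) -> float:
    """Total objective: weighted sum, 1:1 by default."""
    w = weights or LossWeights()
    if not (np.isfinite(dino) and np.isfinite(barlow)):
        raise ValueError("loss terms must be finite")
    return float(w.dino_weight * dino + w.barlow_weight * barlow)


@dataclass
class CropSpec:
    """Multi-crop geometry: 2 global + 3 local crops per global source."""

    n_global: int = 2
    locals_per_global: int = 3
    n_planes: int = 3
    global_scale: tuple[float, float] = (0.4, 1.0)
    local_scale: tuple[float, float] = (0.05, 0.4)

    def __post_init__(self):
        if self.n_global < 2:
            raise ValueError("cross-batch sampling needs >= 2 global crops")
        if self.n_planes < 1:
            raise ValueError("need at least one focal plane")


@dataclass
class Crop:
    """One sampled crop with its provenance annotations."""

    kind: str  # "global" | "local"
    source_replica: str
    plane: int
    scale: float
    box: tuple[int, int, int, int]  # (y0, x0, height, width)
    patch: np.ndarray


def _sample_crop(stack, replica, kind, scale_range, spec, rng) -> Crop:
    n_planes, H, W = stack.shape
    plane = int(rng.integers(spec.n_planes))
    scale = float(rng.uniform(*scale_range))
    h = max(1, int(round(np.sqrt(scale) * H)))
    w = max(1, int(round(np.sqrt(scale) * W)))
    y0 = int(rng.integers(H - h + 1))
    x0 = int(rng.integers(W - w + 1))
    return Crop(kind, replica, plane, scale, (y0, x0, h, w), stack[plane, y0 : y0 + h, x0 : x0 + w])


def sample_cross_batch_crops(
    zstacks: dict[str, np.ndarray],
    spec: CropSpec | None = None,
    rng: np.random.Generator | None = None,
) -> list[Crop]:
    """Sample the cross-batch multi-crop set for one (compound, dose, timepoint).

    ``zstacks`` maps replica id -> (n_planes, H, W) image stack.  The two
    global crops come from two *distinct* replicas; each global source image
    then yields ``locals_per_global`` local crops; every crop's plane is
    drawn uniformly.  Returns 2 global + 6 local crops (default spec).
    """
    spec = spec or CropSpec()
    rng = rng or np.random.default_rng()
    if len(zstacks) < 2:
        raise ValueError("cross-batch sampling requires >= 2 replicas")
    for rep, stack in zstacks.items():
        stack = np.asarray(stack)
        if stack.ndim != 3 or stack.shape[0] < spec.n_planes:
            raise ValueError(f"replica {rep!r}: expected (n_planes, H, W) stack")
    replicas = sorted(zstacks)
    chosen = [replicas[i] for i in rng.choice(len(replicas), size=2, replace=False)]
    crops: list[Crop] = []
    for rep in chosen:
        stack = np.asarray(zstacks[rep])
        crops.append(_sample_crop(stack, rep, "global", spec.global_scale, spec, rng))
    for rep in chosen:
        stack = np.asarray(zstacks[rep])
        for _ in range(spec.locals_per_global):
            crops.append(_sample_crop(stack, rep, "local", spec.local_scale, spec, rng))
    return crops
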