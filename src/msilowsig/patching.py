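"""Patch extraction and [0,1] normalization of cubes and annotations.

The autoencoder consumes overlapping p x p patches of the intensity cube
(step 2 for training; step 1 when building random-forest inputs).  Each data
patch is paired with the mean of the corresponding p x p annotation pixels,
which serves as the continuous hypoxia regression target.  Patches lying
entirely in background are discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .preproc import IntensityCube

log = logging.getLogger(__name__)


@dataclass
class AnnotationImage:
    """Co-registered annotation in [0,1]; 0 = none, 1 = maximum found."""

    sample_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("annotation must be 2-D")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("annotation values must lie in [0, 1]")


@dataclass
class PatchSet:
    """Extracted patches with their annotation targets and provenance.

    ``patches``: N x p x p x P, ``targets``: N in [0,1],
    ``coords``: N x 2 (top-left row, col), ``sample_ids``: N labels,
    ``annotation_patches``: N x p x p pixel-level annotation values (kept for
    the semi-supervised loss, which gates individual pixels).
    """

    patches: np.ndarray
    targets: np.ndarray
    coords: np.ndarray
    sample_ids: np.ndarray
    annotation_patches: np.ndarray
    patch_size: int
    step: int

    def __len__(self) -> int:
        return len(self.patches)

    def subset(self, idx: np.ndarray) -> "PatchSet":
        return PatchSet(
            patches=self.patches[idx],
            targets=self.targets[idx],
            coords=self.coords[idx],
            sample_ids=self.sample_ids[idx],
            annotation_patches=self.annotation_patches[idx],
            patch_size=self.patch_size,
            step=self.step,
        )


@dataclass
class MinMaxScaler:
    """Per-channel min/max bounds frozen on the training samples."""

    mins: np.ndarray
    maxs: np.ndarray

    def transform(self, cube: IntensityCube) -> IntensityCube:
        out = cube.copy()
        span = self.maxs - self.mins
        safe = np.where(span > 0, span, 1.0)
        scaled = (out.intensities - self.mins) / safe
        scaled = np.where(span[None, None, :] > 0, scaled, 0.0)
        out.intensities = np.clip(scaled, 0.0, 1.0)
        out.intensities[out.background_mask] = 0.0
        return out


def minmax_normalize(
    cubes: list[IntensityCube],
    train_ids: list[str] | None = None,
) -> tuple[list[IntensityCube], MinMaxScaler]:
    """Scale each channel to [0,1] using bounds from the training samples.

    Bounds are computed jointly over the tissue pixels of the training
    samples only and then frozen; validation samples are transformed with the
    same bounds and clipped into [0,1], so no information leaks from them.
    Constant channels map to 0.
    """
    if not cubes:
        raise ValueError("no cubes given")
    if train_ids is None:
        train = cubes
    else:
        train = [c for c in cubes if c.sample_id in set(train_ids)]
        if not train:
            raise ValueError("train_ids match no cube")
    pooled = np.concatenate([c.intensities[c.tissue_mask] for c in train])
    scaler = MinMaxScaler(mins=pooled.min(axis=0), maxs=pooled.max(axis=0))
    return [scaler.transform(c) for c in cubes], scaler


def downsample_annotation(
    image: np.ndarray, factor: int, sample_id: str = ""
) -> AnnotationImage:
    """Mean-pool a high-resolution annotation down to the MSI raster.

    Dimensions not divisible by ``factor`` are padded with background (0).
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    img = np.asarray(image, dtype=float)
    if factor == 1:
        return AnnotationImage(sample_id, img)
    h, w = img.shape
    ph = (-h) % factor
    pw = (-w) % factor
    if ph or pw:
        img = np.pad(img, ((0, ph), (0, pw)))
    h, w = img.shape
    pooled = img.reshape(h // factor, factor, w // factor, factor).mean(axis=(1, 3))
    return AnnotationImage(sample_id, pooled)


def patch_grid(height: int, width: int, patch_size: int, step: int) -> np.ndarray:
    """Top-left coordinates of the row-major sliding-window grid."""
    rows = np.arange(0, height - patch_size + 1, step)
    cols = np.arange(0, width - patch_size + 1, step)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return np.stack([rr.ravel(), cc.ravel()], axis=1)


def extract_patches(
    cube: IntensityCube,
    annotation: AnnotationImage,
    patch_size: int = 3,
    step: int = 2,
) -> PatchSet:
    """Cut a cube into overlapping patches, discarding all-background ones.

    The target of a patch is the mean of its p x p annotation pixels.
    """
    h, w, p = cube.shape
    if patch_size > min(h, w):
        raise ValueError("patch_size exceeds image dimensions")
    if annotation.values.shape != (h, w):
        raise ValueError("annotation shape must match cube")
    coords = patch_grid(h, w, patch_size, step)
    patches, targets, kept, ann_patches = [], [], [], []
    for r, c in coords:
        bg = cube.background_mask[r : r + patch_size, c : c + patch_size]
        if bg.all():
            continue
        patches.append(cube.intensities[r : r + patch_size, c : c + patch_size])
        ann = annotation.values[r : r + patch_size, c : c + patch_size]
        ann_patches.append(ann)
        targets.append(ann.mean())
        kept.append((r, c))
    n = len(patches)
    return PatchSet(
        patches=np.asarray(patches).reshape(n, patch_size, patch_size, p),
        targets=np.asarray(targets, dtype=float),
        coords=np.asarray(kept, dtype=int).reshape(n, 2),
        sample_ids=np.asarray([cube.sample_id] * n),
        annotation_patches=np.asarray(ann_patches).reshape(n, patch_size, patch_size),
        patch_size=patch_size,
        step=step,
    )


def concat_patchsets(sets: list[PatchSet]) -> PatchSet:
    if not sets:
        raise ValueError("no patch sets")
    if len({s.patch_size for s in sets}) != 1 or len({s.step for s in sets}) != 1:
        raise ValueError("patch sets differ in geometry")
    return PatchSet(
        patches=np.concatenate([s.patches for s in sets]),
        targets=np.concatenate([s.targets for s in sets]),
        coords=np.concatenate([s.coords for s in sets]),
        sample_ids=np.concatenate([s.sample_ids for s in sets]),
        annotation_patches=np.concatenate([s.annotation_patches for s in sets]),
        patch_size=sets[0].patch_size,
        step=sets[0].step,
    )


def balance_patches(patchset: PatchSet, seed: int = 0) -> PatchSet:
    """Downsample non-hypoxic patches to the hypoxic count.

    A patch counts as hypoxic when its annotation target exceeds 0; the
    regression target itself stays continuous.  No upsampling is performed
    when hypoxic patches are the majority.
    """
    hypoxic = np.flatnonzero(patchset.targets > 0)
    normal = np.flatnonzero(patchset.targets <= 0)
    if hypoxic.size == 0:
        raise ValueError(
            "no hypoxic patches: the sample carries too few annotated spots "
            "and should be excluded from the regression task"
        )
    rng = np.random.default_rng(seed)
    if normal.size > hypoxic.size:
        normal = rng.choice(normal, size=hypoxic.size, replace=False)
    idx = np.sort(np.concatenate([hypoxic, normal]))
    return patchset.subset(idx)


def patch_mean(patch: np.ndarray) -> np.ndarray:
    """Mean over a patch's pixels, one value per channel."""
    patch = np.asarray(patch, dtype=float)
    if patch.size == 0:
        raise ValueError("empty patch")
    if patch.ndim == 2:  # single-channel p x p
        return np.asarray([patch.mean()])
    return patch.reshape(-1, patch.shape[-1]).mean(axis=0)
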