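"""Volume I/O, intensity normalization, and resampling.

Volumes are carried as plain numpy grids in voxel index space together with
their voxel spacing (mm) and, when read from disk, the NIfTI affine.  The
segmentation pipeline itself operates purely on voxel indices; affine and
orientation metadata are passed through untouched so outputs land in the same
physical frame as their inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

#: Canonical tissue legend. 0 is background (non-brain).
TISSUE_LEGEND: dict[int, str] = {
    1: "white_matter",
    2: "gray_matter",
    3: "cerebellar_cortex",
    4: "basal_ganglia",
    5: "csf_ventricles",
}

N_TISSUES = 5


@dataclass
class ScalarVolume:
    """A 3D real-valued image with voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("scalar volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelVolume:
    """A 3D integer tissue-label grid with values in 0..5."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None
    legend: dict[int, str] = field(default_factory=lambda: dict(TISSUE_LEGEND))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D label volume, got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            rounded = np.rint(self.data)
            if not np.allclose(self.data, rounded, atol=1e-6):
                raise ValueError("label volume holds non-integral values")
            self.data = rounded.astype(np.int16)
        bad = np.setdiff1d(np.unique(self.data), np.arange(N_TISSUES + 1))
        if bad.size:
            raise ValueError(f"label values outside 0..{N_TISSUES}: {bad.tolist()}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class TemplatePair:
    """A co-registered (image, label) pair of identical dimensions."""

    image: ScalarVolume
    label: LabelVolume

    def __post_init__(self) -> None:
        if self.image.shape != self.label.shape:
            raise ValueError(
                f"image/label dimension mismatch: {self.image.shape} vs {self.label.shape}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.image.shape


def _load_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, ...], np.ndarray]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing, img.affine


def read_scalar(path: str | Path) -> ScalarVolume:
    data, spacing, affine = _load_nifti(path)
    return ScalarVolume(data.astype(np.float64), spacing, affine)


def read_label(path: str | Path) -> LabelVolume:
    data, spacing, affine = _load_nifti(path)
    return LabelVolume(data, spacing, affine)


def read_pair(image_path: str | Path, label_path: str | Path) -> TemplatePair:
    """Read a co-registered image+label pair, validating dims and label range."""
    return TemplatePair(read_scalar(image_path), read_label(label_path))


def write_volume(vol: ScalarVolume | LabelVolume, path: str | Path) -> None:
    """Write a volume to NIfTI, carrying spacing/affine provenance through."""
    affine = vol.affine
    if affine is None:
        affine = np.diag(list(vol.spacing) + [1.0])
    data = vol.data
    if isinstance(vol, LabelVolume):
        data = data.astype(np.int16)
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def normalize_max(volume: ScalarVolume) -> ScalarVolume:
    """Rescale intensities so the maximum equals one.

    An all-zero volume is returned unchanged; this is the only preprocessing
    applied before augmentation and training.
    """
    peak = float(volume.data.max(initial=0.0))
    if peak == 0.0:
        return replace(volume, data=volume.data.copy())
    out = volume.data / peak
    # guard against round-off leaving max slightly off 1
    out[np.unravel_index(np.argmax(out), out.shape)] = 1.0
    return replace(volume, data=out)


def resample_to(
    volume: ScalarVolume | LabelVolume,
    target_spacing: tuple[float, float, float],
) -> ScalarVolume | LabelVolume:
    """Resample a volume to a target voxel spacing.

    Scalar images use cubic-spline interpolation; label volumes use
    nearest-neighbor so no fractional label values are invented.
    """
    target = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target):
        raise ValueError(f"nonpositive target spacing: {target}")
    if tuple(volume.spacing) == target:
        return replace(volume, data=volume.data.copy())
    zoom = [src / dst for src, dst in zip(volume.spacing, target)]
    if isinstance(volume, LabelVolume):
        data = ndimage.zoom(volume.data, zoom, order=0, mode="nearest")
        return LabelVolume(data, target, volume.affine, dict(volume.legend))
    data = ndimage.zoom(volume.data, zoom, order=3, mode="nearest")
    return ScalarVolume(data, target, volume.affine)
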