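"""Post-processing: raw network output -> skull-strip, label, tissue maps.

The raw 5-channel field is clamped to [0, 1] to give tissue probability maps.
A brain mask is the largest 6-connected component of (channel sum > 0.5);
the mask zeroes the input image (skull-stripping) and the probability maps,
and the voxel-wise label is the argmax tissue inside the mask.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .volume_io import N_TISSUES

#: faces-only adjacency used for the largest-component search
SIX_CONNECTIVITY = ndimage.generate_binary_structure(3, 1)


def clip_probs(raw: np.ndarray) -> np.ndarray:
    """Clamp the raw 5-channel output elementwise to [0, 1]."""
    raw = np.asarray(raw)
    if raw.ndim != 4 or raw.shape[0] != N_TISSUES:
        raise ValueError(f"expected ({N_TISSUES}, D, H, W) channels, got {raw.shape}")
    return np.clip(raw, 0.0, 1.0)


def brain_mask(probs: np.ndarray) -> np.ndarray:
    """Largest 6-connected component of (sum of tissue probabilities > 0.5).

    Returns a boolean volume.  If no voxel clears the threshold an all-false
    mask is returned with a warning.  Ties between equally large components go
    to the first in scanning order.
    """
    binary = probs.sum(axis=0) > 0.5
    if not binary.any():
        warnings.warn("brain mask is empty: no voxel's probability sum exceeds 0.5")
        return binary
    labeled, n = ndimage.label(binary, structure=SIX_CONNECTIVITY)
    if n == 1:
        return binary
    sizes = np.bincount(labeled.ravel())
    sizes[0] = 0
    return labeled == int(np.argmax(sizes))


def skull_strip(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero the image outside the brain mask."""
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise ValueError(f"image/mask dimension mismatch: {image.shape} vs {mask.shape}")
    return image * mask


def argmax_label(probs: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Voxel-wise tissue label: argmax channel (1..5) inside the mask, 0 outside.

    Ties break to the lowest tissue index.
    """
    lab = (np.argmax(probs, axis=0) + 1).astype(np.int16)
    lab[~np.asarray(mask, dtype=bool)] = 0
    return lab


def masked_tissue_maps(probs: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero each probability channel outside the mask."""
    return probs * np.asarray(mask, dtype=bool)


def postprocess(raw: np.ndarray, image: np.ndarray | None = None) -> dict:
    """Full chain on a raw network output.

    Returns a dict with ``probs`` (masked tissue probability maps), ``mask``,
    ``label``, and — when the input image is given — ``stripped``.
    """
    probs = clip_probs(raw)
    mask = brain_mask(probs)
    out = {
        "mask": mask,
        "label": argmax_label(probs, mask),
        "probs": masked_tissue_maps(probs, mask),
    }
    if image is not None:
        out["stripped"] = skull_strip(image, mask)
    return out
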