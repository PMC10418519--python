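"""Synthetic brain-like phantoms: templates and "unseen subject" variants.

The phantom replaces a curated brain template so the whole pipeline can be
exercised without downloads.  It is deliberately not anatomically realistic:
it only reproduces the statistical structure the method relies on — nested,
contiguous tissue compartments (all five classes present), tissue-specific
mean intensities, smooth partial-volume-like boundaries, and a zero
background that dominates the volume.

:func:`make_subject` manufactures an unseen evaluation scan from a template:
a smooth random deformation plus a low-frequency multiplicative intensity
bias emulate anatomical and acquisition variability, and an *independent*
boundary jitter applied to the label alone emulates the disagreement between
labeling sources that inflates evaluation error above true test error.  The
deformation family (Gaussian-filtered displacement noise) is disjoint from
the augmentation family, so generalization measured against subjects is not
circular.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume_io import LabelVolume, ScalarVolume, TemplatePair, normalize_max

DEFAULT_INTENSITY = {1: 0.90, 2: 0.60, 3: 0.65, 4: 0.75, 5: 0.30}


@dataclass
class PhantomSpec:
    dims: tuple[int, int, int] = (48, 48, 48)
    seed: int = 0
    intensity: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_INTENSITY))
    smoothness: float = 1.0  # PSF-like blur, voxels
    texture: float = 0.05  # amplitude of smooth intra-tissue variation

    def __post_init__(self) -> None:
        if isinstance(self.dims, int):
            self.dims = (self.dims,) * 3
        self.dims = tuple(int(d) for d in self.dims)
        if min(self.dims) < 24:
            raise ValueError("phantom needs dims >= 24 to fit all compartments")


def _ellipsoid(shape, center, semi_axes) -> np.ndarray:
    grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
    acc = 0.0
    for g, c, a in zip(grids, center, semi_axes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def make_template(spec: PhantomSpec) -> TemplatePair:
    """Build a nested-ellipsoid template pair with all five tissue classes.

    Painted inside-out on a zero background: gray-matter shell (2), white
    matter (1), basal-ganglia blobs (4), ventricular core (5), and a separate
    cerebellar lobe (3) below/behind the cerebrum.
    """
    dims = np.array(spec.dims, dtype=float)
    w = dims[0]
    c = (dims - 1.0) / 2.0
    cerebrum_c = c + np.array([0.0, 0.0, 0.04 * w])
    lab = np.zeros(spec.dims, dtype=np.int16)

    lab[_ellipsoid(spec.dims, cerebrum_c, (0.36 * w, 0.33 * w, 0.28 * w))] = 2
    lab[_ellipsoid(spec.dims, cerebrum_c, (0.28 * w, 0.25 * w, 0.20 * w))] = 1
    for side in (-1.0, 1.0):
        bg_c = cerebrum_c + np.array([side * 0.12 * w, 0.0, -0.02 * w])
        lab[_ellipsoid(spec.dims, bg_c, (0.075 * w, 0.085 * w, 0.075 * w))] = 4
    lab[_ellipsoid(spec.dims, cerebrum_c, (0.055 * w, 0.14 * w, 0.075 * w))] = 5
    cereb_c = c + np.array([0.0, -0.26 * w, -0.22 * w])
    lab[_ellipsoid(spec.dims, cereb_c, (0.16 * w, 0.11 * w, 0.09 * w))] = 3

    present = set(np.unique(lab).tolist())
    if present != {0, 1, 2, 3, 4, 5}:
        raise ValueError(f"phantom geometry degenerate, classes present: {present}")
    # compartments must stay strictly inside the volume (zero-border background)
    border = np.concatenate([lab[0].ravel(), lab[-1].ravel(), lab[:, 0].ravel(),
                             lab[:, -1].ravel(), lab[:, :, 0].ravel(),
                             lab[:, :, -1].ravel()])
    if border.any():
        raise ValueError("phantom compartments overflow the volume")

    img = np.zeros(spec.dims, dtype=float)
    for k, mean in spec.intensity.items():
        img[lab == k] = mean
    if spec.smoothness > 0:
        img = ndimage.gaussian_filter(img, spec.smoothness)
    if spec.texture > 0:
        rng = np.random.default_rng(spec.seed)
        ripple = ndimage.gaussian_filter(rng.normal(size=spec.dims), 3.0)
        ripple /= max(np.abs(ripple).max(), 1e-12)
        img = img * (1.0 + spec.texture * ripple)
    img = np.maximum(img, 0.0)
    image = normalize_max(ScalarVolume(img))
    return TemplatePair(image, LabelVolume(lab))


def _smooth_field(shape, rng: np.random.Generator, sigma: float,
                  amplitude: float, n_components: int = 1) -> np.ndarray:
    """Gaussian-filtered noise scaled so its per-component std is `amplitude`."""
    out = np.empty((n_components,) + tuple(shape))
    for i in range(n_components):
        f = ndimage.gaussian_filter(rng.normal(size=shape), sigma)
        std = f.std()
        out[i] = f * (amplitude / std) if std > 0 else 0.0
    return out


def make_subject(
    template: TemplatePair,
    seed: int = 0,
    deform_scale: float = 1.5,
    bias_scale: float = 0.2,
    label_jitter: float = 0.4,
) -> TemplatePair:
    """Derive an "unseen subject" scan+label from a template.

    deform_scale: std of the smooth displacement field (voxels), applied to
    image and label alike (anatomy).  bias_scale: relative std of the smooth
    multiplicative intensity bias (acquisition).  label_jitter: std of an
    additional displacement (voxels) applied to the label only, emulating an
    independent labeling source.  All zero -> returns an identical copy.
    """
    rng = np.random.default_rng(seed)
    shape = template.shape
    img = template.image.data.astype(float)
    lab = template.label.data

    # draw all fields up front so the stream layout is scale-independent
    warp = _smooth_field(shape, rng, sigma=6.0, amplitude=1.0, n_components=3)
    bias = _smooth_field(shape, rng, sigma=10.0, amplitude=1.0)[0]
    jitter = _smooth_field(shape, rng, sigma=3.0, amplitude=1.0, n_components=3)

    grid = np.indices(shape, dtype=float)
    if deform_scale > 0:
        coords = grid + deform_scale * warp
        img = ndimage.map_coordinates(img, coords.reshape(3, -1), order=3,
                                      mode="constant", cval=0.0).reshape(shape)
        img = np.maximum(img, 0.0)
        lab = ndimage.map_coordinates(lab, coords.reshape(3, -1), order=0,
                                      mode="constant", cval=0).reshape(shape)
    if bias_scale > 0:
        img = img * np.maximum(1.0 + bias_scale * bias, 0.0)
    if label_jitter > 0:
        coords = grid + label_jitter * jitter
        lab = ndimage.map_coordinates(lab, coords.reshape(3, -1), order=0,
                                      mode="constant", cval=0).reshape(shape)

    image = normalize_max(ScalarVolume(img, template.image.spacing,
                                       template.image.affine))
    label = LabelVolume(lab.astype(np.int16), template.label.spacing,
                        template.label.affine, dict(template.label.legend))
    return TemplatePair(image, label)
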