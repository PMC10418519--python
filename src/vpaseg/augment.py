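"""Visual-perception augmentation: manufacturing training data from one template.

The operator family mimics the robustness of human vision to degraded viewing
conditions: resolution loss and noise (image reduction), occlusion (spherical
crop-out), illumination changes (ambient / diffuse / specular light), bounded
viewpoint changes (rigid motion plus camera transforms: scale, aspect ratio,
perspective, pincushion lens distortion), and figure-ground variation
(synthetic background textures).  Rotation and translation are deliberately
*bounded* — unlimited rotations and flips degrade recognition of oriented
anatomy — and all geometric transforms are applied by backward warping so the
image can be resampled with cubic splines.

One call to :func:`augment_once` composes the steps in pipeline order
(reduction -> lighting -> rigid/camera warp -> background textures -> final
rescale to max 1) and yields a new image+label pair.  Photometric and texture
steps never touch the label; only the crop-out and the spatial warp transform
it, and then with the identical geometry as the image.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import LabelVolume, ScalarVolume, TemplatePair

# --------------------------------------------------------------------------- #
# randomness
# --------------------------------------------------------------------------- #


class RandomStream:
    """Seeded random source; the only randomness entry point of the package.

    ``child(*keys)`` derives an independent stream by extending the seed key,
    so e.g. epoch ``k`` of a run is reproducible in isolation.  Identical seed
    keys give bit-identical draw sequences.
    """

    def __init__(self, seed: int | tuple[int, ...]) -> None:
        if isinstance(seed, (int, np.integer)):
            seed = (int(seed),)
        self.seed: tuple[int, ...] = tuple(int(s) for s in seed)
        self.gen = np.random.default_rng(self.seed)

    def child(self, *keys: int) -> "RandomStream":
        return RandomStream(self.seed + tuple(int(k) for k in keys))

    # thin delegation so callers never touch .gen directly
    def random(self, size=None):
        return self.gen.random(size)

    def uniform(self, low=0.0, high=1.0, size=None):
        return self.gen.uniform(low, high, size)

    def normal(self, loc=0.0, scale=1.0, size=None):
        return self.gen.normal(loc, scale, size)

    def integers(self, low, high=None, size=None):
        return self.gen.integers(low, high, size)

    def permutation(self, x):
        return self.gen.permutation(x)


# --------------------------------------------------------------------------- #
# configuration
# --------------------------------------------------------------------------- #


@dataclass
class AugmentConfig:
    """All tunable augmentation parameters (see docs/methods.md for units)."""

    # image reduction
    p_subsample_per_dim: float = 0.5
    noise_high: float = 0.2
    p_noise: float = 0.5
    # spherical crop-out (off by default; used for lesion-robust training)
    crop_enabled: bool = False
    p_crop: float = 0.5
    crop_radius_range: tuple[float, float] = (0.1, 0.2)  # fraction of width
    crop_fill_range: tuple[float, float] = (0.0, 2.0)
    # lighting
    ambient_range: tuple[float, float] = (0.0, 2.0)
    diffuse_gain: float = 0.2
    p_each_light: float = 0.5
    ambient_enabled: bool = True
    diffuse_enabled: bool = True
    specular_enabled: bool = True
    literal_lighting: bool = False  # raw gain multiply instead of 1+g modulation
    # rigid motion and camera transform
    rotation_max: float = 0.2  # radians
    translation_max: float = 0.2  # fraction of dim size
    scale_range: tuple[float, float] = (0.8, 1.25)
    aspect_range: tuple[float, float] = (1.0, 1.25)
    perspective_range: tuple[float, float] = (-0.5, 0.5)  # divided by dim size
    distortion_max: float = 0.1  # fraction, scaled by half max width
    # background textures
    p_each_texture: float = 0.5
    stamp_repeats: int = 5
    stamp_scale_range: tuple[float, float] = (0.8, 1.25)
    perlin_levels: int = 4  # banding quantization of the Perlin field
    perlin_res: int = 4  # lattice periods across the volume

    def __post_init__(self) -> None:
        for name in ("p_subsample_per_dim", "p_noise", "p_crop", "p_each_light",
                     "p_each_texture"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} not a probability")
        for name in ("crop_radius_range", "crop_fill_range", "ambient_range",
                     "scale_range", "aspect_range", "perspective_range",
                     "stamp_scale_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}=({lo},{hi}) not ordered")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AugmentConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in d:
                v = d[f.name]
                kwargs[f.name] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)


def identity_config() -> AugmentConfig:
    """A config whose every operator degenerates to the identity."""
    return AugmentConfig(
        p_subsample_per_dim=0.0, p_noise=0.0, noise_high=0.0,
        crop_enabled=False, p_each_light=0.0,
        rotation_max=0.0, translation_max=0.0,
        scale_range=(1.0, 1.0), aspect_range=(1.0, 1.0),
        perspective_range=(0.0, 0.0), distortion_max=0.0,
        p_each_texture=0.0,
    )


# --------------------------------------------------------------------------- #
# image reduction
# --------------------------------------------------------------------------- #


def _resize_linear(data: np.ndarray, axis: int, new_size: int) -> np.ndarray:
    """Linear resize along one axis (endpoints map to endpoints)."""
    n = data.shape[axis]
    if new_size == n:
        return data.copy()
    coords = np.linspace(0.0, n - 1.0, new_size)
    lo = np.floor(coords).astype(np.intp)
    hi = np.minimum(lo + 1, n - 1)
    frac = coords - lo
    a = np.take(data, lo, axis=axis)
    b = np.take(data, hi, axis=axis)
    shape = [1] * data.ndim
    shape[axis] = new_size
    frac = frac.reshape(shape)
    return a * (1.0 - frac) + b * frac


def subsample_blur(image: np.ndarray, rng: RandomStream, cfg: AugmentConfig,
                   trace: dict | None = None) -> np.ndarray:
    """Halve each axis independently with probability p, then linearly upsample back.

    The down/up round trip smooths out high-frequency detail, emulating a
    lower-resolution acquisition.  Axes of size < 2 are skipped.
    """
    out = image
    for axis in range(3):
        if image.shape[axis] < 2:
            continue
        fired = rng.random() < cfg.p_subsample_per_dim
        if trace is not None:
            trace[f"subsample_{'xyz'[axis]}"] = fired
        if fired:
            half = max(1, image.shape[axis] // 2)
            out = _resize_linear(out, axis, half)
            out = _resize_linear(out, axis, image.shape[axis])
    return out if out is not image else image.copy()


def add_uniform_noise(image: np.ndarray, rng: RandomStream, cfg: AugmentConfig) -> np.ndarray:
    """Add independent per-voxel noise drawn from U(0, noise_high)."""
    if cfg.noise_high == 0.0:
        return image.copy()
    return image + rng.uniform(0.0, cfg.noise_high, image.shape)


def crop_sphere(pair: TemplatePair, rng: RandomStream, cfg: AugmentConfig) -> TemplatePair:
    """Remove a spherical region: constant fill in the image, background in the label.

    Radius ~ U(crop_radius_range) x image width; center uniform over the
    volume; fill ~ U(crop_fill_range).  This is the one photometric-group step
    that *does* modify the label (the removed tissue is gone).
    """
    if not cfg.crop_enabled:
        return TemplatePair(
            ScalarVolume(pair.image.data.copy(), pair.image.spacing, pair.image.affine),
            LabelVolume(pair.label.data.copy(), pair.label.spacing, pair.label.affine,
                        dict(pair.label.legend)),
        )
    dims = np.array(pair.shape, dtype=float)
    width = dims[0]
    radius = rng.uniform(*cfg.crop_radius_range) * width
    center = np.array([rng.uniform(0.0, d - 1.0) for d in dims])
    fill = rng.uniform(*cfg.crop_fill_range)
    grids = np.ogrid[: pair.shape[0], : pair.shape[1], : pair.shape[2]]
    dist2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    mask = dist2 <= radius**2
    img = pair.image.data.copy()
    lab = pair.label.data.copy()
    img[mask] = fill
    lab[mask] = 0
    return TemplatePair(
        ScalarVolume(img, pair.image.spacing, pair.image.affine),
        LabelVolume(lab, pair.label.spacing, pair.label.affine, dict(pair.label.legend)),
    )


# --------------------------------------------------------------------------- #
# lighting
# --------------------------------------------------------------------------- #


def _center(shape) -> np.ndarray:
    return (np.asarray(shape, dtype=float) - 1.0) / 2.0


def _coord_grids(shape):
    return np.ogrid[: shape[0], : shape[1], : shape[2]]


def ambient_light(image: np.ndarray, a: float) -> np.ndarray:
    """Uniform illumination: add the constant a to every voxel."""
    return image + a


def diffuse_light(image: np.ndarray, direction: np.ndarray, gain: float,
                  literal: bool = False) -> np.ndarray:
    """Directional shading from a light-direction unit vector.

    The gain field is g(x) = gain * <n, (x - c)/W> with W the image width.
    Default is multiplicative modulation I*(1+g); ``literal`` multiplies by g
    alone.
    """
    shape = image.shape
    c = _center(shape)
    w = float(shape[0])
    gx, gy, gz = _coord_grids(shape)
    g = gain * (direction[0] * (gx - c[0]) + direction[1] * (gy - c[1])
                + direction[2] * (gz - c[2])) / w
    return image * g if literal else image * (1.0 + g)


def specular_light(image: np.ndarray, center: np.ndarray,
                   literal: bool = False) -> np.ndarray:
    """Highlight falloff by distance to a specular center q: g(x) = |x - q|/W."""
    shape = image.shape
    w = float(shape[0])
    gx, gy, gz = _coord_grids(shape)
    dist = np.sqrt((gx - center[0]) ** 2 + (gy - center[1]) ** 2
                   + (gz - center[2]) ** 2) / w
    return image * dist if literal else image * (1.0 + dist)


def apply_lighting(image: np.ndarray, rng: RandomStream, cfg: AugmentConfig,
                   trace: dict | None = None) -> np.ndarray:
    """Apply ambient, diffuse, and specular light, each gated independently."""
    out = image.copy()
    gates = {}
    gates["ambient"] = cfg.ambient_enabled and rng.random() < cfg.p_each_light
    if gates["ambient"]:
        out = ambient_light(out, rng.uniform(*cfg.ambient_range))
    gates["diffuse"] = cfg.diffuse_enabled and rng.random() < cfg.p_each_light
    if gates["diffuse"]:
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        out = diffuse_light(out, v, cfg.diffuse_gain, cfg.literal_lighting)
    gates["specular"] = cfg.specular_enabled and rng.random() < cfg.p_each_light
    if gates["specular"]:
        q = np.array([rng.uniform(0.0, d - 1.0) for d in image.shape])
        out = specular_light(out, q, cfg.literal_lighting)
    if trace is not None:
        trace.update(gates)
    return out


# --------------------------------------------------------------------------- #
# rigid motion and camera transform
# --------------------------------------------------------------------------- #


@dataclass
class SpatialTransform:
    """Backward-warp parameters mapping destination voxel u to source coordinate v.

    Applied in order: pincushion lens distortion (magnitude m, in units of the
    half max width h), perspective scaling about the center (vector p, units
    1/voxel), then the linear part v = R(u - c) + c + t with R combining
    rotation, isotropic scale, and a single-axis aspect stretch.
    """

    R: np.ndarray
    t: np.ndarray
    p: np.ndarray
    m: float
    c: np.ndarray
    h: float  # half of the maximum image width (distortion length unit)

    @classmethod
    def identity(cls, dims) -> "SpatialTransform":
        dims = np.asarray(dims, dtype=float)
        return cls(R=np.eye(3), t=np.zeros(3), p=np.zeros(3), m=0.0,
                   c=(dims - 1.0) / 2.0, h=float(dims.max()) / 2.0)


def _rotation_matrix(angles: np.ndarray) -> np.ndarray:
    ax, ay, az = angles
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def sample_transform_params(rng: RandomStream, cfg: AugmentConfig, dims) -> dict:
    """Draw the raw bounded transform parameters (before composition).

    Rotation angles ~ U(0, rotation_max) per axis, isotropic scale ~
    U(scale_range), aspect stretch ~ U(aspect_range) on one random axis,
    translation fractions ~ U(0, translation_max) per axis, perspective
    constants ~ U(perspective_range) per axis (later divided by the dims),
    and a lens-distortion fraction ~ U(0, distortion_max).
    """
    return {
        "angles": rng.uniform(0.0, cfg.rotation_max, 3),
        "scale": float(rng.uniform(*cfg.scale_range)),
        "aspect": float(rng.uniform(*cfg.aspect_range)),
        "aspect_axis": int(rng.integers(3)),
        "translation_frac": rng.uniform(0.0, cfg.translation_max, 3),
        "perspective": rng.uniform(*cfg.perspective_range, 3),
        "distortion_frac": float(rng.uniform(0.0, cfg.distortion_max)),
        "dims": np.asarray(dims, dtype=float),
    }


def transform_from_params(params: dict) -> SpatialTransform:
    """Compose a SpatialTransform from raw sampled parameters."""
    dims = params["dims"]
    s = np.full(3, params["scale"])
    s[params["aspect_axis"]] *= params["aspect"]
    R = _rotation_matrix(params["angles"]) @ np.diag(s)
    t = params["translation_frac"] * dims
    p = params["perspective"] / dims
    h = float(dims.max()) / 2.0
    m = h * params["distortion_frac"]
    return SpatialTransform(R=R, t=t, p=p, m=float(m), c=(dims - 1.0) / 2.0, h=h)


def sample_transform(rng: RandomStream, cfg: AugmentConfig, dims) -> SpatialTransform:
    """Draw one bounded rigid-motion + camera transform (about the image center)."""
    return transform_from_params(sample_transform_params(rng, cfg, dims))


def map_coordinate(T: SpatialTransform, u: np.ndarray) -> np.ndarray:
    """Map destination coordinates u (3,) or (3, N) to source coordinates.

    Pure function of (T, u): lens distortion u + m*nu*|nu|^2 with
    nu = (c - u)/h, then perspective scaling about c, then the linear part.
    """
    u = np.asarray(u, dtype=float)
    single = u.ndim == 1
    pts = u.reshape(3, -1) if not single else u.reshape(3, 1)
    c = T.c.reshape(3, 1)
    # pincushion lens distortion, Taylor form: displacement ~ r^3 toward/away center
    nu = (c - pts) / T.h
    pts = pts + T.m * nu * np.sum(nu * nu, axis=0, keepdims=True)
    # perspective: scale the centered coordinate by (1 + p.(u - c))
    d = pts - c
    factor = 1.0 + np.sum(T.p.reshape(3, 1) * d, axis=0, keepdims=True)
    pts = c + d * factor
    # rotation/scale/aspect about the center, then translation
    v = T.R @ (pts - c) + c + T.t.reshape(3, 1)
    return v[:, 0] if single else v.reshape(u.shape)


def warp_pair(pair: TemplatePair, T: SpatialTransform) -> TemplatePair:
    """Backward-warp image (cubic spline) and label (nearest) with one transform.

    Samples falling outside the source volume fill with 0 (background).
    """
    shape = pair.shape
    grid = np.indices(shape, dtype=float).reshape(3, -1)
    src = map_coordinate(T, grid)
    img = ndimage.map_coordinates(pair.image.data, src, order=3, mode="constant",
                                  cval=0.0).reshape(shape)
    lab = ndimage.map_coordinates(pair.label.data, src, order=0, mode="constant",
                                  cval=0).reshape(shape)
    return TemplatePair(
        ScalarVolume(img, pair.image.spacing, pair.image.affine),
        LabelVolume(lab.astype(pair.label.data.dtype), pair.label.spacing,
                    pair.label.affine, dict(pair.label.legend)),
    )


# --------------------------------------------------------------------------- #
# background textures
# --------------------------------------------------------------------------- #


def blend(s, b):
    """Composite new intensity b onto existing s: s + b*f(s), f(s)=max(1-s, 0.1).

    The headroom factor f keeps repeated compositing from blowing up bright
    regions while still letting dark background accumulate texture.
    """
    s = np.asarray(s, dtype=float)
    b = np.asarray(b, dtype=float)
    f = np.where(1.0 - s < 0.1, 0.1, 1.0 - s)
    out = s + b * f
    return float(out) if out.ndim == 0 else out


def stamp_texture(pair: TemplatePair, rng: RandomStream, cfg: AugmentConfig,
                  trace: dict | None = None) -> TemplatePair:
    """Populate the background by repeatedly stamping copies of itself.

    Each of ``stamp_repeats`` passes draws the background image (foreground
    excluded) rotated by unrestricted angles, scaled by U(stamp_scale_range),
    and translated up to half the image width, then composites it onto the
    background with :func:`blend`.  Foreground voxels are bit-unchanged.
    """
    lab = pair.label.data
    bg_mask = lab == 0
    img = pair.image.data.copy()
    if not bg_mask.any():
        return TemplatePair(
            ScalarVolume(img, pair.image.spacing, pair.image.affine),
            LabelVolume(lab.copy(), pair.label.spacing, pair.label.affine,
                        dict(pair.label.legend)),
        )
    shape = img.shape
    c = _center(shape)
    width = float(shape[0])
    bg_img = np.where(bg_mask, img, 0.0)
    passes = 0
    for _ in range(cfg.stamp_repeats):
        passes += 1
        angles = rng.uniform(0.0, 2.0 * np.pi, 3)
        scale = rng.uniform(*cfg.stamp_scale_range)
        t = rng.uniform(-0.5, 0.5, 3) * width
        A = _rotation_matrix(angles) * scale
        # backward map for "draw A(x-c)+c+t": source = A^-1 (dest - c - t) + c
        Ainv = np.linalg.inv(A)
        offset = c - Ainv @ (c + t)
        stamped = ndimage.affine_transform(bg_img, Ainv, offset=offset, order=1,
                                           mode="constant", cval=0.0)
        img[bg_mask] = blend(img[bg_mask], stamped[bg_mask])
    if trace is not None:
        trace["stamp_passes"] = passes
    return TemplatePair(
        ScalarVolume(img, pair.image.spacing, pair.image.affine),
        LabelVolume(lab.copy(), pair.label.spacing, pair.label.affine,
                    dict(pair.label.legend)),
    )


def perlin_field(shape, rng: RandomStream, res: int = 4) -> np.ndarray:
    """Classic 3D gradient (Perlin) noise over ``res`` lattice periods, in [0, 1].

    Lattice gradients are random unit vectors addressed through a shuffled
    permutation table; interpolation uses the quintic fade, so the field and
    its first two derivatives are continuous across cell borders.
    """
    perm = rng.permutation(256).astype(np.intp)
    perm = np.concatenate([perm, perm])
    grads = rng.normal(size=(256, 3))
    grads /= np.linalg.norm(grads, axis=1, keepdims=True)

    coords = [np.arange(n, dtype=float) * res / n for n in shape]
    x, y, z = np.meshgrid(*coords, indexing="ij")
    xi, yi, zi = (np.floor(a).astype(np.intp) for a in (x, y, z))
    xf, yf, zf = x - xi, y - yi, z - zi

    def fade(t):
        return t * t * t * (t * (t * 6 - 15) + 10)

    u, v, w = fade(xf), fade(yf), fade(zf)

    def grad_dot(ix, iy, iz, dx, dy, dz):
        h = perm[perm[perm[ix % 256] + iy % 256] + iz % 256]
        g = grads[h]
        return g[..., 0] * dx + g[..., 1] * dy + g[..., 2] * dz

    n000 = grad_dot(xi, yi, zi, xf, yf, zf)
    n100 = grad_dot(xi + 1, yi, zi, xf - 1, yf, zf)
    n010 = grad_dot(xi, yi + 1, zi, xf, yf - 1, zf)
    n110 = grad_dot(xi + 1, yi + 1, zi, xf - 1, yf - 1, zf)
    n001 = grad_dot(xi, yi, zi + 1, xf, yf, zf - 1)
    n101 = grad_dot(xi + 1, yi, zi + 1, xf - 1, yf, zf - 1)
    n011 = grad_dot(xi, yi + 1, zi + 1, xf, yf - 1, zf - 1)
    n111 = grad_dot(xi + 1, yi + 1, zi + 1, xf - 1, yf - 1, zf - 1)

    nx00 = n000 + u * (n100 - n000)
    nx10 = n010 + u * (n110 - n010)
    nx01 = n001 + u * (n101 - n001)
    nx11 = n011 + u * (n111 - n011)
    nxy0 = nx00 + v * (nx10 - nx00)
    nxy1 = nx01 + v * (nx11 - nx01)
    out = nxy0 + w * (nxy1 - nxy0)
    return np.clip((out + 1.0) / 2.0, 0.0, 1.0)


def perlin_texture(pair: TemplatePair, rng: RandomStream, cfg: AugmentConfig) -> TemplatePair:
    """Composite a floor-banded 3D Perlin field onto the background."""
    lab = pair.label.data
    bg_mask = lab == 0
    img = pair.image.data.copy()
    if bg_mask.any():
        noise = perlin_field(img.shape, rng, cfg.perlin_res)
        banded = np.floor(noise * cfg.perlin_levels) / cfg.perlin_levels
        img[bg_mask] = blend(img[bg_mask], banded[bg_mask])
    return TemplatePair(
        ScalarVolume(img, pair.image.spacing, pair.image.affine),
        LabelVolume(lab.copy(), pair.label.spacing, pair.label.affine,
                    dict(pair.label.legend)),
    )


# --------------------------------------------------------------------------- #
# composition
# --------------------------------------------------------------------------- #


def augment_once(template: TemplatePair, rng: RandomStream,
                 cfg: AugmentConfig | None = None,
                 trace: dict | None = None) -> TemplatePair:
    """Draw one augmented training pair from the template.

    Pipeline order: subsample blur -> uniform noise (gated) -> spherical crop
    (gated, if enabled) -> lighting -> rigid/camera backward warp ->
    background textures (each gated) -> rescale so max intensity is 1.
    When ``trace`` is a dict it is filled with which gated steps fired.
    """
    if cfg is None:
        cfg = AugmentConfig()
    img = template.image.data.astype(float)
    lab = template.label.data.copy()

    img = subsample_blur(img, rng, cfg, trace)
    noise_fired = rng.random() < cfg.p_noise
    if trace is not None:
        trace["noise"] = noise_fired
    if noise_fired:
        img = add_uniform_noise(img, rng, cfg)
    pair = TemplatePair(
        ScalarVolume(img, template.image.spacing, template.image.affine),
        LabelVolume(lab, template.label.spacing, template.label.affine,
                    dict(template.label.legend)),
    )
    if cfg.crop_enabled:
        crop_fired = rng.random() < cfg.p_crop
        if trace is not None:
            trace["crop"] = crop_fired
        if crop_fired:
            pair = crop_sphere(pair, rng, cfg)

    lit = apply_lighting(pair.image.data, rng, cfg, trace)
    pair = TemplatePair(
        ScalarVolume(lit, pair.image.spacing, pair.image.affine), pair.label)

    T = sample_transform(rng, cfg, pair.shape)
    pair = warp_pair(pair, T)

    stamp_fired = rng.random() < cfg.p_each_texture
    if trace is not None:
        trace["stamp"] = stamp_fired
    if stamp_fired:
        pair = stamp_texture(pair, rng, cfg, trace)
    perlin_fired = rng.random() < cfg.p_each_texture
    if trace is not None:
        trace["perlin"] = perlin_fired
    if perlin_fired:
        pair = perlin_texture(pair, rng, cfg)

    # cubic-spline resampling can overshoot below zero; clamp, then rescale
    # so the augmented image again spans [0, 1] with max exactly 1
    img = np.maximum(pair.image.data, 0.0)
    peak = float(img.max(initial=0.0))
    if peak > 0:
        img = img / peak
    return TemplatePair(
        ScalarVolume(img, pair.image.spacing, pair.image.affine), pair.label)
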