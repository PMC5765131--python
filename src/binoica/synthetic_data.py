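"""Synthetic verged-stereo generator and low-level test fixtures.

Produces left/right luminance rasters with ground-truth horizontal and
vertical disparity fields for a symmetrically converged viewer, plus
single Gabor patches and sparse-source matrices used to exercise the
downstream fitting and ICA stages.

Conventions: azimuth is positive rightward, elevation positive upward,
origin at fixation (the image centre).  Horizontal disparity is positive
for features farther than fixation (uncrossed); vertical disparity is
positive for features that project higher in the left image.
"""
from __future__ import annotations

import dataclasses
import math
from typing import Optional

import numpy as np
from scipy.ndimage import map_coordinates

ARCMIN_PER_RAD = 60.0 * 180.0 / math.pi  # 3437.7467...


@dataclasses.dataclass(frozen=True)
class ViewingGeometry:
    """Symmetric binocular viewing geometry."""

    interocular_mm: float = 65.0
    fixation_mm: float = 1000.0
    field_half_width_arcmin: float = 600.0
    pixel_pitch_arcmin: float = 1.0

    def __post_init__(self):
        for name in ("interocular_mm", "fixation_mm",
                     "field_half_width_arcmin", "pixel_pitch_arcmin"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def raster_size(self) -> int:
        """Side length (pixels) of a raster covering the field, odd so the
        fixation falls on a pixel centre."""
        n = int(round(2.0 * self.field_half_width_arcmin / self.pixel_pitch_arcmin))
        return n + 1 if n % 2 == 0 else n


@dataclasses.dataclass
class BinocularImagePair:
    """Left/right luminance rasters with angular calibration.

    ``fixation`` is the (row, col) of the fixation point in pixel
    coordinates (sub-pixel allowed).
    """

    left: np.ndarray
    right: np.ndarray
    pixel_pitch_arcmin: float
    fixation: tuple[float, float]

    def __post_init__(self):
        if self.left.shape != self.right.shape:
            raise ValueError("left/right rasters must share shape")

    @property
    def shape(self):
        return self.left.shape


@dataclasses.dataclass
class DisparityField:
    """Ground-truth disparity maps in arcmin, same raster as the texture."""

    horizontal: np.ndarray
    vertical: np.ndarray

    def __post_init__(self):
        if self.horizontal.shape != self.vertical.shape:
            raise ValueError("disparity maps must share shape")


@dataclasses.dataclass
class SceneSpec:
    """Scene description for the stereo renderer.

    Either an explicit ``depth_map`` (mm, matching the raster) or the
    parametric ground plane (viewer ``eye_height_mm`` above a floor through
    the fixation point) is used.  ``texture_alpha`` is the exponent of the
    1/f^alpha texture spectrum; ``vertical_gain`` scales the quadrant
    vertical-disparity pattern; ``texture_cutoff`` optionally band-limits
    the texture (cycles/px).
    """

    depth_map: Optional[np.ndarray] = None
    eye_height_mm: float = 1600.0
    texture_alpha: float = 1.0
    vertical_gain: float = 0.0
    texture_cutoff: Optional[float] = None
    rng_seed: int = 0

    def __post_init__(self):
        if self.depth_map is not None and np.any(np.asarray(self.depth_map) <= 0):
            raise ValueError("depth_map must be strictly positive")
        if self.texture_alpha < 0:
            raise ValueError("texture_alpha must be >= 0")


def depth_to_horizontal_disparity(depth_mm, geometry: ViewingGeometry):
    """Horizontal disparity (arcmin) of a point at depth ``depth_mm``.

    Small-angle vergence model ``d = I * (1/D - 1/Z)``: zero at fixation,
    positive (uncrossed) beyond it, negative (crossed) nearer.
    """
    depth = np.asarray(depth_mm, dtype=float)
    if np.any(depth <= 0):
        raise ValueError("depth must be strictly positive")
    d_rad = geometry.interocular_mm * (1.0 / geometry.fixation_mm - 1.0 / depth)
    out = d_rad * ARCMIN_PER_RAD
    return float(out) if np.isscalar(depth_mm) else out


def vertical_disparity_field(azimuth, elevation, gain: float):
    """Quadrant vertical-disparity pattern ``v = -gain * azimuth * elevation``.

    Positive in the top-left and bottom-right quadrants, negative in the
    other two, zero on both meridians, growing away from them.
    """
    az = np.asarray(azimuth, dtype=float)
    el = np.asarray(elevation, dtype=float)
    out = -gain * az * el
    return float(out) if np.isscalar(azimuth) and np.isscalar(elevation) else out


def ground_plane_depth(elevation_arcmin, geometry: ViewingGeometry,
                       eye_height_mm: float, max_depth_mm: float = 1e6):
    """Depth along lines of sight for a viewer fixating a ground plane.

    The eye sits ``eye_height_mm`` above a floor containing the fixation
    point at distance ``fixation_mm``.  Rays above the horizon never meet
    the floor and are capped at ``max_depth_mm``.
    """
    if eye_height_mm <= 0 or eye_height_mm > geometry.fixation_mm:
        raise ValueError("eye height must be in (0, fixation distance]")
    el = np.asarray(elevation_arcmin, dtype=float) / ARCMIN_PER_RAD
    declination = math.asin(eye_height_mm / geometry.fixation_mm)
    below = declination - el  # angle below horizontal of each ray
    with np.errstate(divide="ignore", invalid="ignore"):
        depth = eye_height_mm / np.sin(below)
    depth = np.where((below <= 0) | (depth > max_depth_mm), max_depth_mm, depth)
    return depth


def gaussian_texture(shape, alpha: float, rng: np.random.Generator,
                     cutoff: Optional[float] = None) -> np.ndarray:
    """Zero-mean, unit-variance periodic Gaussian field with a 1/f^alpha
    spectrum (random phases).  Useful for warp/interpolation checks; note a
    Gaussian field carries no higher-order structure, so it is *not* a
    useful input for ICA."""
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    radius = np.hypot(fy, fx)
    amp = np.zeros(shape)
    nonzero = radius > 0
    amp[nonzero] = radius[nonzero] ** (-alpha)
    if cutoff is not None:
        amp[radius > cutoff] = 0.0
    phase = rng.uniform(0.0, 2.0 * math.pi, size=shape)
    tex = np.real(np.fft.ifft2(amp * np.exp(1j * phase)))
    tex -= tex.mean()
    sd = tex.std()
    if sd > 0:
        tex /= sd
    return tex


def _periodic_gabor_kernel(n: int, f: float, sigma: float, theta: float):
    """Gabor kernel wrapped onto a periodic n x n raster, centred at (0, 0)."""
    x = (np.arange(n) + n // 2) % n - n // 2
    X, Y = np.meshgrid(x, x)
    y = -Y  # rows grow downward
    z = X * math.cos(theta) - y * math.sin(theta)
    return np.exp(-(X ** 2 + y ** 2) / (2.0 * sigma ** 2)) \
        * np.cos(2.0 * math.pi * f * z)


def uniform_disparity_depth(d_arcmin: float, geometry: ViewingGeometry,
                            shape) -> np.ndarray:
    """Constant depth map whose horizontal disparity equals ``d_arcmin``.

    Inverts the vergence model ``d = I * (1/D - 1/Z)``; raises if the
    requested disparity would need a non-positive depth.
    """
    inv = (1.0 / geometry.fixation_mm
           - d_arcmin / (geometry.interocular_mm * ARCMIN_PER_RAD))
    if inv <= 0:
        raise ValueError("requested disparity exceeds the far-field limit")
    return np.full(shape, 1.0 / inv)


def synth_texture(shape, alpha: float, rng: np.random.Generator,
                  cutoff: Optional[float] = None,
                  n_orientations: int = 8,
                  base_frequency: float = 0.15,
                  n_octaves: int = 3,
                  base_density: float = 1e-4) -> np.ndarray:
    """Sparse-element texture with a natural 1/f^alpha-like spectrum.

    The field is a sum of sparsely placed, oriented Gabor elements over
    octave-spaced scales; per-octave amplitudes follow the 1/f^alpha
    envelope.  Unlike a random-phase Gaussian field this carries the
    heavy-tailed, oriented higher-order structure ICA needs to recover
    localized oriented components.  Zero-mean, unit variance, periodic.
    """
    if shape[0] != shape[1]:
        raise ValueError("texture raster must be square")
    n = shape[0]
    tex = np.zeros(shape)
    for j in range(n_octaves):
        f_j = base_frequency / (2.0 ** j)
        if cutoff is not None and f_j > cutoff:
            continue
        sigma_j = 0.375 / f_j
        density_j = base_density * f_j / (base_frequency / 2.0 ** (n_octaves - 1))
        # amplitude weight giving ~1/f^alpha radially averaged power
        weight_j = (f_j / base_frequency) ** (1.5 - alpha)
        for i in range(n_orientations):
            theta = math.pi * i / n_orientations \
                + rng.uniform(0.0, math.pi / n_orientations)
            coeffs = rng.laplace(size=shape) * (rng.random(shape) < density_j)
            kernel = _periodic_gabor_kernel(n, f_j, sigma_j, theta)
            tex += weight_j * np.real(
                np.fft.ifft2(np.fft.fft2(coeffs) * np.fft.fft2(kernel))
            )
    tex -= tex.mean()
    sd = tex.std()
    if sd > 0:
        tex /= sd
    return tex


def angular_grids(shape, pixel_pitch: float, fixation: tuple[float, float]):
    """(azimuth, elevation) arcmin grids for a raster."""
    rows = np.arange(shape[0], dtype=float)[:, None]
    cols = np.arange(shape[1], dtype=float)[None, :]
    az = (cols - fixation[1]) * pixel_pitch
    el = (fixation[0] - rows) * pixel_pitch
    return np.broadcast_to(az, shape), np.broadcast_to(el, shape)


def render_stereo_pair(
    scene: SceneSpec,
    geometry: ViewingGeometry,
    shape: Optional[tuple[int, int]] = None,
    max_warp_arcmin: float = 60.0,
) -> tuple[BinocularImagePair, DisparityField]:
    """Render a verged stereo pair plus its ground-truth disparity fields.

    A periodic 1/f^alpha texture is warped half into each eye: the left
    image samples the texture at ``(az + d/2, el - v/2)`` and the right at
    ``(az - d/2, el + v/2)``, so a feature with v > 0 sits higher in the
    left image.  Deterministic given ``scene.rng_seed``.
    """
    if shape is None:
        n = geometry.raster_size
        shape = (n, n)
    fixation = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    pitch = geometry.pixel_pitch_arcmin
    az, el = angular_grids(shape, pitch, fixation)

    if scene.depth_map is not None:
        depth = np.asarray(scene.depth_map, dtype=float)
        if depth.shape != shape:
            raise ValueError("depth_map shape must match raster shape")
    else:
        depth = ground_plane_depth(el, geometry, scene.eye_height_mm)

    horiz = depth_to_horizontal_disparity(depth, geometry)
    vert = vertical_disparity_field(az, el, scene.vertical_gain)
    max_shift = max(np.abs(horiz).max(), np.abs(vert).max()) / 2.0
    if max_shift > max_warp_arcmin:
        raise ValueError(
            f"disparity warp {max_shift:.1f} arcmin exceeds budget "
            f"{max_warp_arcmin} arcmin"
        )

    rng = np.random.default_rng(scene.rng_seed)
    texture = synth_texture(shape, scene.texture_alpha, rng,
                            cutoff=scene.texture_cutoff)

    rows = np.arange(shape[0], dtype=float)[:, None] + np.zeros(shape)
    cols = np.arange(shape[1], dtype=float)[None, :] + np.zeros(shape)
    dr = vert / (2.0 * pitch)
    dc = horiz / (2.0 * pitch)
    # texture is periodic, so wrap-around sampling is seamless
    left = map_coordinates(texture, [rows + dr, cols + dc],
                           order=1, mode="grid-wrap")
    right = map_coordinates(texture, [rows - dr, cols - dc],
                            order=1, mode="grid-wrap")
    pair = BinocularImagePair(left=left, right=right,
                              pixel_pitch_arcmin=pitch, fixation=fixation)
    return pair, DisparityField(horizontal=horiz, vertical=vert)


def make_gabor_patch(params, size: int, noise_sd: float = 0.0,
                     rng_seed: int = 0) -> np.ndarray:
    """Evaluate a Gabor on the standard patch grid, plus optional white noise."""
    from .gabor import eval_gabor, patch_grid

    if size < 4:
        raise ValueError("size must be >= 4")
    if params.f >= 0.5:
        raise ValueError("frequency must be below Nyquist (0.5 cycles/sample)")
    x, y = patch_grid(size)
    patch = eval_gabor(params, x, y)
    if noise_sd > 0:
        patch = patch + np.random.default_rng(rng_seed).normal(
            0.0, noise_sd, size=patch.shape
        )
    return patch


def make_sparse_source_patches(
    n_sources: int,
    n_samples: int,
    mixing_seed: int = 0,
    source_seed: int = 1,
    identity_mixing: bool = False,
    max_condition: float = 1e6,
) -> tuple[np.ndarray, np.ndarray]:
    """Heavy-tailed independent sources through a random full-rank mixing.

    Returns ``(data, mixing)`` where ``data = mixing @ sources`` has shape
    ``(n_sources, n_samples)`` (one mixture per row) and sources are unit
    Laplace draws.  Ill-conditioned mixing draws are redrawn.
    """
    if n_samples <= n_sources:
        raise ValueError("need n_samples > n_sources")
    src_rng = np.random.default_rng(source_seed)
    sources = src_rng.laplace(0.0, 1.0, size=(n_sources, n_samples))
    if identity_mixing:
        mixing = np.eye(n_sources)
    else:
        mix_rng = np.random.default_rng(mixing_seed)
        while True:
            mixing = mix_rng.normal(size=(n_sources, n_sources))
            if np.linalg.cond(mixing) < max_condition:
                break
    return mixing @ sources, mixing
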