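"""Region partitioning, resolution rescaling and binocular patch cutting.

The visual field is split into three half-open eccentricity bands
(centre [0, 150), mid [150, 300), outer [300, 600) arcmin from fixation)
optionally crossed with the four quadrants through the fixation point.
Region membership is always decided in the original angular coordinates,
so it is invariant to the sample resolution.
"""
from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
from skimage.transform import resize

from .synthetic_data import BinocularImagePair

ECCENTRICITY_BANDS: dict[str, tuple[float, float]] = {
    "centre": (0.0, 150.0),
    "mid": (150.0, 300.0),
    "outer": (300.0, 600.0),
}
QUADRANTS = ("top_left", "top_right", "bottom_left", "bottom_right")


@dataclasses.dataclass(frozen=True)
class RegionSpec:
    """One of the 12 eccentricity x quadrant regions (or a full annulus).

    ``quadrant`` is ``"all"`` for the annulus, one of :data:`QUADRANTS`,
    or ``None`` for a point lying exactly on a quadrant boundary.
    """

    band: str
    quadrant: Optional[str] = "all"

    def __post_init__(self):
        if self.band not in ECCENTRICITY_BANDS:
            raise ValueError(f"unknown eccentricity band {self.band!r}")
        if self.quadrant is not None and self.quadrant != "all" \
                and self.quadrant not in QUADRANTS:
            raise ValueError(f"unknown quadrant {self.quadrant!r}")


@dataclasses.dataclass(frozen=True)
class PatchGeometry:
    """Square per-eye patch joined into one rectangular binocular sample."""

    width: int
    height: int
    sample_resolution: float  # arcmin/sample

    def __post_init__(self):
        if self.width != self.height:
            raise ValueError("per-eye patches must be square")
        if self.width < 4:
            raise ValueError("patch side must be >= 4 samples")
        if not (1.0 <= self.sample_resolution <= 10.0):
            raise ValueError("sample_resolution must lie in [1, 10] arcmin/sample")

    @property
    def binocular_dim(self) -> int:
        return 2 * self.width * self.height


@dataclasses.dataclass
class PatchSet:
    """Vectorized binocular patches plus their provenance.

    ``data`` rows are ``[left, right]`` concatenations; ``positions`` holds
    the (row, col) of each patch's top-left corner in the sampled raster.
    """

    data: np.ndarray
    geometry: PatchGeometry
    region: RegionSpec
    positions: np.ndarray
    seed: Optional[int] = None

    @property
    def n_patches(self) -> int:
        return self.data.shape[0]


def region_of(azimuth: float, elevation: float) -> Optional[RegionSpec]:
    """Map an angular position (arcmin from fixation) to its region.

    Returns ``None`` beyond 600 arcmin.  Points on a quadrant boundary
    (azimuth == 0 or elevation == 0) get ``quadrant=None``; they belong to
    the annulus but to no single quadrant.
    """
    radius = float(np.hypot(azimuth, elevation))
    band = None
    for name, (lo, hi) in ECCENTRICITY_BANDS.items():
        if lo <= radius < hi:
            band = name
            break
    if band is None:
        return None
    if azimuth == 0 or elevation == 0:
        quadrant = None
    elif elevation > 0:
        quadrant = "top_left" if azimuth < 0 else "top_right"
    else:
        quadrant = "bottom_left" if azimuth < 0 else "bottom_right"
    return RegionSpec(band=band, quadrant=quadrant)


def in_region(azimuth, elevation, region: RegionSpec) -> np.ndarray:
    """Vectorized membership test against a target region."""
    az = np.asarray(azimuth, dtype=float)
    el = np.asarray(elevation, dtype=float)
    radius = np.hypot(az, el)
    lo, hi = ECCENTRICITY_BANDS[region.band]
    mask = (radius >= lo) & (radius < hi)
    if region.quadrant and region.quadrant != "all":
        left = az < 0
        top = el > 0
        quadmask = {
            "top_left": left & top,
            "top_right": ~left & (az > 0) & top,
            "bottom_left": left & (el < 0),
            "bottom_right": (az > 0) & (el < 0),
        }[region.quadrant]
        mask &= quadmask
    return mask


def resample_image(image: np.ndarray, from_res: float, to_res: float) -> np.ndarray:
    """Bicubic rescale from ``from_res`` to a coarser ``to_res`` (arcmin/sample).

    Output size is ``round(n * from_res / to_res)`` per axis; upsampling
    requests are rejected.
    """
    if to_res < from_res:
        raise ValueError("upsampling not supported (to_res must be >= from_res)")
    if to_res == from_res:
        return np.array(image, copy=True)
    factor = from_res / to_res
    out_shape = tuple(max(1, int(round(s * factor))) for s in image.shape)
    return resize(image, out_shape, order=3, mode="reflect",
                  anti_aliasing=True, preserve_range=True)


def resample_pair(pair: BinocularImagePair, to_res: float) -> BinocularImagePair:
    """Rescale both eyes to a target sample resolution, tracking fixation."""
    from_res = pair.pixel_pitch_arcmin
    left = resample_image(pair.left, from_res, to_res)
    right = resample_image(pair.right, from_res, to_res)
    # skimage's resize maps new coord j to old (j + .5) / scale - .5
    def _map(coord, old_n, new_n):
        return (coord + 0.5) * new_n / old_n - 0.5

    fixation = (
        _map(pair.fixation[0], pair.left.shape[0], left.shape[0]),
        _map(pair.fixation[1], pair.left.shape[1], left.shape[1]),
    )
    return BinocularImagePair(left=left, right=right,
                              pixel_pitch_arcmin=to_res, fixation=fixation)


def admissible_positions(pair: BinocularImagePair, region: RegionSpec,
                         geometry: PatchGeometry) -> np.ndarray:
    """(row, col) top-left corners whose patch centre lies in the region
    and whose patch fits inside the raster."""
    if abs(pair.pixel_pitch_arcmin - geometry.sample_resolution) > 1e-9:
        raise ValueError("pair must be resampled to geometry.sample_resolution")
    h, w = pair.shape
    ph, pw = geometry.height, geometry.width
    if h < ph or w < pw:
        return np.empty((0, 2), dtype=int)
    r0 = np.arange(h - ph + 1, dtype=float)
    c0 = np.arange(w - pw + 1, dtype=float)
    centre_rows = r0 + (ph - 1) / 2.0
    centre_cols = c0 + (pw - 1) / 2.0
    res = geometry.sample_resolution
    az = (centre_cols[None, :] - pair.fixation[1]) * res
    el = (pair.fixation[0] - centre_rows[:, None]) * res
    mask = in_region(np.broadcast_to(az, (len(r0), len(c0))),
                     np.broadcast_to(el, (len(r0), len(c0))), region)
    rows, cols = np.nonzero(mask)
    return np.column_stack([rows, cols]).astype(int)


def sample_patches(
    pair: BinocularImagePair,
    region: RegionSpec,
    geometry: PatchGeometry,
    n_patches: int,
    rng_seed: int = 0,
) -> PatchSet:
    """Cut ``n_patches`` co-located left/right patches from one region.

    Positions are drawn uniformly (with replacement) among grid positions
    whose patch centre lies in the region; both eyes are cut at identical
    image coordinates, so disparity lives in the data, not the sampling.
    Rows are raw, un-normalized ``[left, right]`` concatenations.
    """
    candidates = admissible_positions(pair, region, geometry)
    if n_patches == 0:
        return PatchSet(
            data=np.empty((0, geometry.binocular_dim)),
            geometry=geometry, region=region,
            positions=np.empty((0, 2), dtype=int), seed=rng_seed,
        )
    if len(candidates) == 0:
        raise ValueError(
            f"region {region} is empty at {geometry.sample_resolution} "
            "arcmin/sample with this patch size"
        )
    rng = np.random.default_rng(rng_seed)
    picks = candidates[rng.integers(0, len(candidates), size=n_patches)]
    ph, pw = geometry.height, geometry.width
    data = np.empty((n_patches, geometry.binocular_dim))
    half = ph * pw
    for i, (r, c) in enumerate(picks):
        data[i, :half] = pair.left[r:r + ph, c:c + pw].ravel()
        data[i, half:] = pair.right[r:r + ph, c:c + pw].ravel()
    return PatchSet(data=data, geometry=geometry, region=region,
                    positions=picks, seed=rng_seed)
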