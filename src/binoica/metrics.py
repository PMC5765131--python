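"""Per-component binocular measures and distribution statistics.

Sign conventions: horizontal position disparity is positive for
uncrossed/far tuning (right-eye envelope shifted rightward of the left);
vertical position disparity is positive when the receptive field sits
higher in the left eye.  Phase disparity lives in [0, pi] (pi =
anti-correlated), orientation disparity in [0, 90] degrees.
"""
from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np

from .gabor import GaborParams


@dataclasses.dataclass
class DisparityMeasures:
    dx: float  # arcmin, positive = uncrossed/far
    dy: float  # arcmin, positive = higher in left eye
    dphi: float  # radians in [0, pi]
    dtheta: float  # degrees in [0, 90]
    freq: float  # cycles/sample (mean of the two eyes)
    freq_arcmin: float  # cycles/arcmin


def position_disparity(gl: GaborParams, gr: GaborParams,
                       res: float) -> tuple[float, float]:
    """Envelope-centre separation in arcmin: ``dx`` along azimuth
    (rightward positive), ``dy`` along elevation (upward positive, sign
    chosen so positive means higher in the left image)."""
    dx = (gr.centre_x - gl.centre_x) * res
    dy = (gl.centre_y - gr.centre_y) * res
    return float(dx), float(dy)


def phase_disparity(gl: GaborParams, gr: GaborParams) -> float:
    """Absolute centre-relative carrier phase difference in [0, pi].

    If the two carrier orientations differ by more than 90 degrees the
    right eye is re-expressed via the (theta + pi, -phi) equivalence first
    so the comparison is between aligned carriers.
    """
    phi_r = gr.phi
    delta_theta = gr.theta - gl.theta
    if abs(delta_theta) > math.pi / 2.0:
        phi_r = -phi_r
    d = (phi_r - gl.phi + math.pi) % (2.0 * math.pi) - math.pi
    return abs(d)


def orientation_disparity(gl: GaborParams, gr: GaborParams) -> float:
    """Absolute circular carrier-orientation difference, degrees in [0, 90]."""
    d = abs(gl.theta - gr.theta)
    return math.degrees(min(d, math.pi - d))


def component_measures(component, res: float) -> DisparityMeasures:
    """Bundle all disparity measures for a component with valid fits."""
    gl, gr = component.gabor_left, component.gabor_right
    if gl is None or gr is None:
        raise ValueError("component lacks valid Gabor fits in both eyes")
    dx, dy = position_disparity(gl, gr, res)
    freq = 0.5 * (gl.f + gr.f)
    return DisparityMeasures(
        dx=dx, dy=dy,
        dphi=phase_disparity(gl, gr),
        dtheta=orientation_disparity(gl, gr),
        freq=freq, freq_arcmin=freq / res,
    )


def asymmetry(hist: np.ndarray) -> float:
    """Mirror asymmetry of a normalized histogram over [0, pi].

    Half the summed absolute difference between the histogram and its
    mirror about pi/2: 0 for a symmetric distribution, 1 when all mass
    lies on one side.  Requires an even bin count; unnormalized input is
    normalized with a warning.
    """
    p = np.asarray(hist, dtype=float)
    if p.ndim != 1 or p.size % 2:
        raise ValueError("histogram must be 1-D with an even bin count")
    if np.any(p < 0):
        raise ValueError("histogram bins must be non-negative")
    total = p.sum()
    if not math.isclose(total, 1.0, abs_tol=1e-8):
        if total <= 0:
            raise ValueError("histogram has no mass")
        warnings.warn("unnormalized histogram; normalizing internally")
        p = p / total
    return float(np.abs(p - p[::-1]).sum() / 2.0)


def mad(values) -> float:
    """Median of absolute deviations from the median (no consistency factor)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("mad of empty input")
    return float(np.median(np.abs(v - np.median(v))))


def classify_binocularity(ratio: float, threshold: float = 0.25) -> str:
    """``"binocular"`` iff ratio >= threshold (boundary inclusive)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    if not 0.0 <= ratio <= 1.0:
        raise ValueError("ratio must lie in [0, 1]")
    return "binocular" if ratio >= threshold else "monocular"
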