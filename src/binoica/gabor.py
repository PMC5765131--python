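"""Parametric 2-D Gabor model: evaluation, canonicalization and fitting.

The model is a Gaussian envelope (width ``sigma_w``, height ``sigma_h``,
orientation ``psi``) multiplying a 1-D cosine carrier (frequency ``f`` in
cycles/sample, phase ``phi``, orientation ``theta``).  Both the envelope
coordinates and the carrier coordinate are measured from the envelope
centre, so ``phi`` is a centre-relative phase.

Patch coordinates follow the package convention: ``x`` increases with
column (rightward), ``y`` decreases with row (upward), and the origin sits
on the pixel at index ``(n // 2, n // 2)``.
"""
from __future__ import annotations

import dataclasses
import math
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

TWO_PI = 2.0 * math.pi


class GaborFitError(RuntimeError):
    """Raised when a patch does not admit an acceptable Gabor fit."""

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}: {detail}" if detail else reason)


@dataclasses.dataclass
class GaborParams:
    """Parameters of the 2-D Gabor surface.

    Canonical ranges: ``theta`` and ``psi`` in [0, pi), ``phi`` in [0, 2*pi),
    ``f`` in (0, 0.5], ``sigma_w``/``sigma_h`` > 0, ``amplitude`` >= 0.
    ``fit_error`` is the normalized residual of a fit, in [0, 1], or None
    for parameters that were not produced by fitting.
    """

    theta: float
    f: float
    phi: float
    sigma_w: float
    sigma_h: float
    psi: float
    centre_x: float = 0.0
    centre_y: float = 0.0
    amplitude: float = 1.0
    fit_error: Optional[float] = None


def patch_grid(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(x, y)`` coordinate arrays for an ``n`` x ``n`` patch.

    ``x[i, j] = j - n // 2`` and ``y[i, j] = n // 2 - i`` so that the origin
    lies on an actual pixel and ``y`` points upward.
    """
    cols = np.arange(n, dtype=float) - n // 2
    rows = float(n // 2) - np.arange(n, dtype=float)
    x, y = np.meshgrid(cols, rows)
    return x, y


def eval_gabor(params: GaborParams, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Evaluate the Gabor surface at coordinates ``(x, y)``."""
    u = np.asarray(x, dtype=float) - params.centre_x
    v = np.asarray(y, dtype=float) - params.centre_y
    cw, sw = math.cos(params.psi), math.sin(params.psi)
    xr = u * cw - v * sw
    yr = u * sw + v * cw
    z = u * math.cos(params.theta) - v * math.sin(params.theta)
    envelope = np.exp(
        -(xr ** 2) / (2.0 * params.sigma_w ** 2)
        - (yr ** 2) / (2.0 * params.sigma_h ** 2)
    )
    return params.amplitude * envelope * np.cos(TWO_PI * params.f * z + params.phi)


def canonicalize(params: GaborParams) -> GaborParams:
    """Map parameters onto the canonical ranges without changing the surface.

    Equivalences used: ``f -> -f`` with ``phi -> -phi``; ``A -> -A`` with
    ``phi -> phi + pi``; ``theta -> theta - pi`` with ``phi -> -phi``;
    ``psi`` is pi-periodic.
    """
    theta, f, phi = params.theta, params.f, params.phi
    amplitude = params.amplitude
    if f < 0:
        f = -f
        phi = -phi
    if amplitude < 0:
        amplitude = -amplitude
        phi += math.pi
    k = math.floor(theta / math.pi)
    theta -= k * math.pi
    if k % 2:
        phi = -phi
    psi = params.psi % math.pi
    phi %= TWO_PI
    return dataclasses.replace(
        params, theta=theta, f=f, phi=phi, psi=psi, amplitude=amplitude
    )


def _initial_guess(patch: np.ndarray, x: np.ndarray, y: np.ndarray):
    """Deterministic initialization: dominant Fourier peak for the carrier,
    intensity moments for the envelope."""
    n = patch.shape[0]
    spectrum = np.abs(np.fft.fft2(patch))
    spectrum[0, 0] = 0.0  # ignore DC
    kr, kc = np.unravel_index(int(np.argmax(spectrum)), spectrum.shape)
    freqs = np.fft.fftfreq(n)
    fx, fy = freqs[kc], -freqs[kr]
    f0 = float(np.clip(math.hypot(fx, fy), 1.0 / n, 0.45))
    theta0 = math.atan2(-fy, fx)

    w = patch ** 2
    tot = w.sum()
    cx0 = float((w * x).sum() / tot)
    cy0 = float((w * y).sum() / tot)
    dx, dy = x - cx0, y - cy0
    m = np.array(
        [
            [(w * dx * dx).sum(), (w * dx * dy).sum()],
            [(w * dx * dy).sum(), (w * dy * dy).sum()],
        ]
    ) / tot
    evals, evecs = np.linalg.eigh(m)
    # major axis -> sigma_w; the sigma_w axis points along (cos psi, -sin psi)
    major = evecs[:, 1]
    psi0 = -math.atan2(major[1], major[0])
    sw0 = float(np.clip(math.sqrt(2.0 * max(evals[1], 1e-6)), 0.8, n / 2))
    sh0 = float(np.clip(math.sqrt(2.0 * max(evals[0], 1e-6)), 0.8, n / 2))
    return theta0, f0, cx0, cy0, sw0, sh0, psi0


def _linear_amp_phase(patch, x, y, theta, f, cx, cy, sw, sh, psi):
    """Given the nonlinear parameters, solve amplitude and phase linearly.

    ``A cos(2 pi f z + phi) = a cos(2 pi f z) + b sin(2 pi f z)`` with
    ``a = A cos phi`` and ``b = -A sin phi``.
    """
    base = GaborParams(theta, f, 0.0, sw, sh, psi, cx, cy, 1.0)
    g_cos = eval_gabor(base, x, y).ravel()
    base_s = dataclasses.replace(base, phi=-math.pi / 2.0)
    g_sin = eval_gabor(base_s, x, y).ravel()
    design = np.column_stack([g_cos, g_sin])
    coef, *_ = np.linalg.lstsq(design, patch.ravel(), rcond=None)
    a, b = coef
    amp = math.hypot(a, b)
    phi = math.atan2(-b, a)
    return amp, phi


def fit_gabor(
    patch: np.ndarray,
    *,
    max_residual: float = 0.5,
    sigma_min: float = 0.5,
    sigma_max: Optional[float] = None,
    centre_max_factor: float = 1.5,
    phase_starts: int = 8,
    n_refine: int = 3,
    max_nfev: int = 400,
) -> GaborParams:
    """Fit the Gabor model to a square patch by nonlinear least squares.

    Initialization is deterministic (Fourier peak + envelope moments) with a
    grid of phase starts; the best few starts are refined.  Raises
    :class:`GaborFitError` with reason ``"degenerate"`` (flat/zero patch),
    ``"no-fit"`` (optimizer failure), ``"poor-fit"`` (residual above
    ``max_residual``) or ``"out-of-box"`` (parameters outside the admissible
    box).
    """
    patch = np.asarray(patch, dtype=float)
    if patch.ndim != 2 or patch.shape[0] != patch.shape[1]:
        raise ValueError("patch must be square 2-D")
    n = patch.shape[0]
    if n < 8:
        raise ValueError("patch side must be >= 8")
    norm = float(np.linalg.norm(patch))
    if norm == 0.0 or np.ptp(patch) == 0.0:
        raise GaborFitError("degenerate", "flat patch")

    x, y = patch_grid(n)
    theta0, f0, cx0, cy0, sw0, sh0, psi0 = _initial_guess(patch, x, y)
    if sigma_max is None:
        sigma_max = float(n)

    amp_cap = 10.0 * float(np.abs(patch).max()) + 1e-12
    lower = [-TWO_PI, 1e-3, -TWO_PI, 0.3, 0.3, -TWO_PI, -float(n), -float(n), 0.0]
    upper = [TWO_PI, 0.5, TWO_PI, 2.0 * n, 2.0 * n, TWO_PI, float(n), float(n), amp_cap]

    target = patch.ravel()

    def residuals(p):
        gp = GaborParams(p[0], p[1], p[2], p[3], p[4], p[5], p[6], p[7], p[8])
        return eval_gabor(gp, x, y).ravel() - target

    # candidate starts: linear amplitude/phase at theta0 and theta0 + 90deg,
    # plus a coarse phase grid (robust when the Fourier peak is ambiguous)
    starts = []
    for theta_c in (theta0, theta0 + math.pi / 2.0):
        amp, phi = _linear_amp_phase(
            patch, x, y, theta_c, f0, cx0, cy0, sw0, sh0, psi0
        )
        starts.append([theta_c, f0, phi, sw0, sh0, psi0, cx0, cy0, amp])
    amp0 = float(np.abs(patch).max())
    for k in range(phase_starts):
        phi = TWO_PI * k / phase_starts
        starts.append([theta0, f0, phi, sw0, sh0, psi0, cx0, cy0, amp0])

    def clip_start(p):
        return [float(np.clip(v, lo + 1e-9, hi - 1e-9))
                for v, lo, hi in zip(p, lower, upper)]

    starts = [clip_start(p) for p in starts]
    starts.sort(key=lambda p: float(np.sum(residuals(p) ** 2)))

    best = None
    for p0 in starts[:n_refine]:
        try:
            sol = least_squares(
                residuals, p0, bounds=(lower, upper), method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=max_nfev,
            )
        except Exception:  # pragma: no cover - optimizer blow-up
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise GaborFitError("no-fit", "optimizer divergence")

    p = best.x
    params = canonicalize(
        GaborParams(p[0], p[1], p[2], p[3], p[4], p[5], p[6], p[7], p[8])
    )
    fit_error = min(1.0, math.sqrt(2.0 * best.cost) / norm)
    params = dataclasses.replace(params, fit_error=fit_error)

    if fit_error > max_residual:
        raise GaborFitError("poor-fit", f"residual {fit_error:.3f} > {max_residual}")
    half = n / 2.0
    if not (sigma_min <= params.sigma_w <= sigma_max
            and sigma_min <= params.sigma_h <= sigma_max):
        raise GaborFitError("out-of-box", "envelope size outside admissible box")
    if (abs(params.centre_x) > centre_max_factor * half
            or abs(params.centre_y) > centre_max_factor * half):
        raise GaborFitError("out-of-box", "envelope centre outside admissible box")
    return params


def fit_component(component, *, ratio_threshold: float = 0.25, **fit_kwargs):
    """Fit Gabors to both eye halves of a binocular component.

    Returns a copy of the component with ``gabor_left``/``gabor_right``
    filled in where fitting succeeded, ``valid`` set iff both fits
    succeeded and the binocular ratio clears ``ratio_threshold``, and a
    ``rejection`` reason otherwise.  Fit failures are recorded, not raised.
    """
    gl = gr = None
    reasons = []
    try:
        gl = fit_gabor(component.left_weights, **fit_kwargs)
    except GaborFitError as err:
        reasons.append(f"left:{err.reason}")
    try:
        gr = fit_gabor(component.right_weights, **fit_kwargs)
    except GaborFitError as err:
        reasons.append(f"right:{err.reason}")
    if component.binocular_ratio < ratio_threshold:
        reasons.append("monocular")
    valid = gl is not None and gr is not None and not reasons
    return dataclasses.replace(
        component,
        gabor_left=gl,
        gabor_right=gr,
        valid=valid,
        rejection=";".join(reasons) if reasons else None,
    )
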