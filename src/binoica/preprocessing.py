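"""Patch normalization and truncated PCA whitening.

Each binocular patch is centred and normalized per eye, the two eyes are
concatenated and the concatenation renormalized to unit length.  The
resulting patch sets are whitened with PCA truncated to K components,
discarding the lowest-variance (high spatial frequency) axes.
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Union

import numpy as np

from .sampling import PatchSet

logger = logging.getLogger(__name__)


class DegeneratePatchError(ValueError):
    """A flat (constant) eye patch cannot be contrast-normalized."""


@dataclasses.dataclass
class WhiteningModel:
    """Truncated PCA whitening transform.

    ``axes`` holds the leading K orthonormal principal axes as columns;
    ``stds`` the corresponding per-axis standard deviations.
    """

    mean: np.ndarray
    axes: np.ndarray  # (D, K)
    stds: np.ndarray  # (K,)
    K: int
    variance_fraction: float

    def __post_init__(self):
        if np.any(self.stds <= 0):
            raise ValueError("retained axis deviations must be strictly positive")
        if self.axes.shape[1] != self.K:
            raise ValueError("axes/K mismatch")


def normalize_binocular_patch(
    raw_left: np.ndarray,
    raw_right: np.ndarray,
    denominator: str = "centred",
) -> np.ndarray:
    """Centre and normalize one binocular patch.

    Per eye the mean is removed and the patch divided by its magnitude;
    by default the magnitude of the *centred* patch (each eye exactly
    unit-norm before concatenation), ``denominator="raw"`` preserves the
    literal un-centred reading.  The concatenation is then renormalized to
    unit length.
    """
    out = _normalize_rows(
        np.concatenate([np.ravel(raw_left), np.ravel(raw_right)])[None, :],
        denominator=denominator,
    )
    if out.shape[0] == 0:
        raise DegeneratePatchError("constant patch in one eye")
    return out[0]


def _normalize_rows(data: np.ndarray, denominator: str = "centred"):
    """Vectorized Eq.-style normalization; returns only non-degenerate rows
    plus a keep-mask when requested via the two-value return."""
    if denominator not in ("centred", "raw"):
        raise ValueError("denominator must be 'centred' or 'raw'")
    half = data.shape[1] // 2
    left = data[:, :half]
    right = data[:, half:]
    keep = (np.ptp(left, axis=1) > 0) & (np.ptp(right, axis=1) > 0)
    left = left[keep]
    right = right[keep]
    parts = []
    for eye in (left, right):
        centred = eye - eye.mean(axis=1, keepdims=True)
        if denominator == "centred":
            mag = np.linalg.norm(centred, axis=1, keepdims=True)
        else:
            mag = np.linalg.norm(eye, axis=1, keepdims=True)
        mag[mag == 0] = 1.0
        parts.append(centred / mag)
    joined = np.concatenate(parts, axis=1)
    joined /= np.linalg.norm(joined, axis=1, keepdims=True)
    return joined


def normalize_patchset(patches: PatchSet, denominator: str = "centred") -> PatchSet:
    """Normalize every patch; degenerate (flat-eye) patches are dropped."""
    data = _normalize_rows(patches.data, denominator=denominator)
    n_dropped = patches.n_patches - data.shape[0]
    if n_dropped:
        logger.warning("dropped %d degenerate patches", n_dropped)
    half = patches.data.shape[1] // 2
    keep = (np.ptp(patches.data[:, :half], axis=1) > 0) \
        & (np.ptp(patches.data[:, half:], axis=1) > 0)
    return PatchSet(data=data, geometry=patches.geometry, region=patches.region,
                    positions=patches.positions[keep], seed=patches.seed)


def fit_whitening(patches: Union[PatchSet, np.ndarray], K: int) -> WhiteningModel:
    """Fit truncated PCA whitening retaining the K highest-variance axes.

    The forward transform maps the training data to K dimensions with
    identity covariance.  Raises if the achievable rank is below K.
    """
    data = patches.data if isinstance(patches, PatchSet) else np.asarray(patches)
    n, dim = data.shape
    if n <= K:
        raise ValueError("need more patches than retained components")
    if K > dim:
        raise ValueError("K cannot exceed the data dimension")
    mean = data.mean(axis=0)
    centred = data - mean
    cov = centred.T @ centred / n
    evals, evecs = np.linalg.eigh(cov)
    evals = evals[::-1]
    evecs = evecs[:, ::-1]
    tol = max(dim, n) * np.finfo(float).eps * max(evals[0], 0.0)
    rank = int(np.sum(evals > tol))
    if rank < K:
        raise ValueError(f"data rank {rank} is below requested K={K}")
    total = float(np.sum(np.clip(evals, 0.0, None)))
    retained = float(np.sum(evals[:K]))
    return WhiteningModel(
        mean=mean,
        axes=evecs[:, :K],
        stds=np.sqrt(evals[:K]),
        K=K,
        variance_fraction=retained / total if total > 0 else 1.0,
    )


def whiten(model: WhiteningModel, patches: Union[PatchSet, np.ndarray]) -> np.ndarray:
    """Forward transform to the K-dimensional whitened space."""
    data = patches.data if isinstance(patches, PatchSet) else np.asarray(patches)
    if data.shape[-1] != model.mean.shape[0]:
        raise ValueError("dimension mismatch")
    return (data - model.mean) @ model.axes / model.stds


def unwhiten_filter(model: WhiteningModel, filter_white: np.ndarray) -> np.ndarray:
    """Compose a whitened-space filter with the whitening transform.

    The returned pixel-space vector ``f`` satisfies
    ``f @ (x - mean) == w @ whiten(x)`` for any raw patch ``x``.
    """
    w = np.asarray(filter_white, dtype=float)
    if w.shape[-1] != model.K:
        raise ValueError("dimension mismatch")
    return model.axes @ (w / model.stds)


def whiten_filter(model: WhiteningModel, filter_pixel: np.ndarray) -> np.ndarray:
    """Inverse of :func:`unwhiten_filter` on the retained subspace."""
    f = np.asarray(filter_pixel, dtype=float)
    if f.shape[-1] != model.mean.shape[0]:
        raise ValueError("dimension mismatch")
    return (model.axes.T @ f) * model.stds
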