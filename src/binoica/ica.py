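"""Independent component estimation on whitened binocular patch sets.

The fixed-point (log-cosh) algorithm is run in the whitened space; the
analysis objects are the *filters* — unmixing rows composed with the
whitening transform back to pixel space — split into left/right halves.
Component order and sign are canonicalized so runs are reproducible.
"""
from __future__ import annotations

import dataclasses
import warnings
from typing import Optional

import numpy as np
from scipy import stats
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .preprocessing import WhiteningModel, unwhiten_filter
from .sampling import PatchGeometry


@dataclasses.dataclass
class ICAModel:
    """Unmixing matrix in whitened space plus convergence metadata."""

    unmixing: np.ndarray  # (K, K), unit-norm rows
    K: int
    seed: Optional[int]
    n_iter: int
    converged: bool
    identifiable: bool
    kurtosis: np.ndarray


@dataclasses.dataclass
class BinocularComponent:
    """One pixel-space filter split into its per-eye halves."""

    index: int
    left_weights: np.ndarray
    right_weights: np.ndarray
    left_energy: float
    right_energy: float
    binocular_ratio: float
    gabor_left: object = None
    gabor_right: object = None
    valid: Optional[bool] = None
    rejection: Optional[str] = None


def fit_ica(
    whitened_data: np.ndarray,
    rng_seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 1000,
) -> ICAModel:
    """Estimate independent components of whitened data (rows = samples).

    Non-convergence yields a flagged (not raised) partial model; data with
    no appreciably non-Gaussian direction is flagged non-identifiable.
    Components are ordered by descending response kurtosis and signed so
    the response skew is non-negative (falling back to making the largest
    unmixing weight positive).
    """
    X = np.asarray(whitened_data, dtype=float)
    n, K = X.shape
    if n <= K:
        raise ValueError("need more samples than components")
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        ica = FastICA(
            n_components=K, algorithm="parallel", whiten=False,
            fun="logcosh", tol=tol, max_iter=max_iter,
            random_state=int(rng_seed) % (2 ** 32),
        )
        ica.fit(X)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False
    W = np.array(ica.components_)
    W /= np.linalg.norm(W, axis=1, keepdims=True)

    responses = X @ W.T
    kurt = stats.kurtosis(responses, axis=0, fisher=True)
    order = np.argsort(-kurt)
    W = W[order]
    kurt = kurt[order]
    responses = responses[:, order]

    skew = stats.skew(responses, axis=0)
    for i in range(K):
        if abs(skew[i]) > 1e-8:
            sign = np.sign(skew[i])
        else:
            sign = np.sign(W[i, np.argmax(np.abs(W[i]))])
        if sign < 0:
            W[i] *= -1.0

    # well below the excess kurtosis of any usefully sparse source (e.g.
    # Laplace: 3), but above what FastICA can squeeze out of finite
    # Gaussian samples by rotation
    identifiable = bool(np.any(np.abs(kurt) > 0.5))
    return ICAModel(
        unmixing=W, K=K, seed=rng_seed, n_iter=int(ica.n_iter_),
        converged=converged, identifiable=identifiable, kurtosis=kurt,
    )


def pixel_filters(model: ICAModel, whitening: WhiteningModel) -> np.ndarray:
    """All K filters mapped to pixel space, one per row."""
    return np.stack([unwhiten_filter(whitening, w) for w in model.unmixing])


def split_component(
    model: ICAModel,
    whitening: WhiteningModel,
    geometry: PatchGeometry,
    index: int,
) -> BinocularComponent:
    """Split one pixel-space filter into left/right halves with energies.

    Energies and the binocular ratio (min/max of the two energies) come
    from the filter weights themselves, never from any fitted Gabor.
    """
    if not 0 <= index < model.K:
        raise IndexError("component index out of range")
    filt = unwhiten_filter(whitening, model.unmixing[index])
    half = geometry.width * geometry.height
    left = filt[:half].reshape(geometry.height, geometry.width)
    right = filt[half:].reshape(geometry.height, geometry.width)
    e_l = float(np.sum(left ** 2))
    e_r = float(np.sum(right ** 2))
    top = max(e_l, e_r)
    ratio = (min(e_l, e_r) / top) if top > 0 else 0.0
    return BinocularComponent(
        index=index, left_weights=left, right_weights=right,
        left_energy=e_l, right_energy=e_r, binocular_ratio=ratio,
    )


def split_all(model: ICAModel, whitening: WhiteningModel,
              geometry: PatchGeometry) -> list[BinocularComponent]:
    return [split_component(model, whitening, geometry, i)
            for i in range(model.K)]


def amari_index(estimated_unmixing: np.ndarray, true_mixing: np.ndarray) -> float:
    """Permutation/scale-invariant distance between an estimated unmixing
    and the true mixing; 0 means perfect source recovery, bounded by 1."""
    P = np.abs(np.asarray(estimated_unmixing) @ np.asarray(true_mixing))
    K = P.shape[0]
    rows = (P.sum(axis=1) / P.max(axis=1) - 1.0).sum()
    cols = (P.sum(axis=0) / P.max(axis=0) - 1.0).sum()
    return float((rows + cols) / (2.0 * K * (K - 1)))
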