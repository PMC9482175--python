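"""Brightfield stain unmixing via a non-negative group-sparsity model.

A brightfield pixel follows the Beer-Lambert law: the transmitted RGB
intensity is ``I_c = I0 * 10**(-OD_c)`` where the optical density is a
non-negative mixture of per-stain absorbance vectors,
``OD = sum_s a_s * d_s``.  With four stains (haematoxylin plus three
chromogens) and three colour channels the mixture is underdetermined, so
concentrations are recovered per pixel as

    min_{a >= 0}  1/2 ||od - D a||^2  +  lam * sum_g ||a_g||

with one stain per group, which reduces the group penalty to a
non-negative lasso over the four concentrations.  The problem is convex
and is solved by cyclic coordinate descent, vectorised across pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ConfigurationError, UnmixConfig


class IllConditionedBasisError(ValueError):
    """Raised when stain vectors are duplicated or numerically dependent."""


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise IllConditionedBasisError("zero stain vector")
    return v / n


# Absorbance (optical-density) vectors in RGB space, unit Euclidean norm.
# Haematoxylin and DAB are the standard published brightfield vectors;
# fast red and PermaGreen were measured from rendered reference chromogen
# patches of the synthetic generator.  All are configuration inputs, not
# fixed constants of the method.
DEFAULT_STAIN_VECTORS = {
    "haematoxylin": (0.650, 0.704, 0.286),
    "dab": (0.268, 0.570, 0.776),
    "fast_red": (0.214, 0.851, 0.478),
    "perma_green": (0.620, 0.180, 0.764),
}


@dataclass
class StainBasis:
    """Dictionary of per-stain RGB optical-density vectors.

    The group structure is implicit: exactly one dictionary atom per stain,
    so group index s selects concentration channel s.
    """

    stains: tuple = ("haematoxylin", "dab", "fast_red", "perma_green")
    vectors: dict = field(default_factory=lambda: dict(DEFAULT_STAIN_VECTORS))

    def __post_init__(self) -> None:
        self.vectors = {k: _unit(v) for k, v in self.vectors.items()}
        for s in self.stains:
            if s not in self.vectors:
                raise ConfigurationError(f"no vector for stain {s!r}")
            if np.any(self.vectors[s] < 0):
                raise ConfigurationError(f"stain vector {s!r} has negative components")

    @property
    def matrix(self) -> np.ndarray:
        """3 x n_stains dictionary matrix D with unit-norm columns."""
        D = np.column_stack([self.vectors[s] for s in self.stains])
        # duplicate / numerically dependent columns make per-pixel recovery
        # meaningless even under non-negativity
        gram = D.T @ D
        off = gram - np.eye(D.shape[1])
        if np.any(np.abs(off) > 1.0 - 1e-6):
            raise IllConditionedBasisError("duplicate or near-parallel stain vectors")
        return D


def rgb_to_od(rgb: np.ndarray, background_intensity: float = 255.0) -> np.ndarray:
    """Convert transmitted RGB intensities to decadic optical densities.

    Zero intensities are clamped to one count before the logarithm, so the
    result is finite;  OD = log10(I0 / I) >= 0 for I <= I0.
    """
    if background_intensity <= 0:
        raise ConfigurationError("background intensity must be positive")
    I = np.asarray(rgb, dtype=float)
    I = np.clip(I, 1.0, background_intensity)
    return np.log10(background_intensity / I)


def group_sparse_unmix(
    od: np.ndarray,
    basis: StainBasis,
    config: UnmixConfig | None = None,
) -> tuple[np.ndarray, float]:
    """Solve the per-pixel non-negative sparse unmixing problem.

    Parameters
    ----------
    od
        ``(..., 3)`` optical-density raster (or a flat ``(n, 3)`` pixel list).
    basis
        Stain dictionary.
    config
        Solver settings; ``config.lam`` is the sparsity weight.

    Returns
    -------
    concentrations, residual
        ``(..., n_stains)`` non-negative concentrations and the root mean
        squared reconstruction residual over foreground pixels.
    """
    config = config or UnmixConfig()
    config.validate()
    D = basis.matrix  # 3 x S
    S = D.shape[1]

    od = np.asarray(od, dtype=float)
    if not np.all(np.isfinite(od)):
        raise ValueError("optical densities must be finite")
    shape = od.shape[:-1]
    X = od.reshape(-1, 3)
    A = np.zeros((X.shape[0], S))

    fg = X.sum(axis=1) >= config.od_floor
    if fg.any():
        A[fg] = _coordinate_descent(X[fg], D, config.lam, config.tol, config.max_iter)

    resid = X - A @ D.T
    rms = float(np.sqrt(np.mean(resid[fg] ** 2))) if fg.any() else 0.0
    return A.reshape(shape + (S,)), rms


def _coordinate_descent(
    X: np.ndarray, D: np.ndarray, lam: float, tol: float, max_iter: int
) -> np.ndarray:
    """Cyclic coordinate descent on 1/2||x - Da||^2 + lam*sum(a), a >= 0.

    With unit-norm dictionary columns the per-coordinate minimiser is the
    soft-thresholded residual correlation clipped at zero.  All pixels are
    updated simultaneously; iteration stops when the largest coefficient
    change over a full sweep falls below ``tol``.
    """
    G = D.T @ D  # S x S, unit diagonal
    C = X @ D  # n x S
    A = np.zeros_like(C)
    S = D.shape[1]
    for _ in range(max_iter):
        delta = 0.0
        for s in range(S):
            # gradient w.r.t. a_s excluding its own quadratic term
            a_new = C[:, s] - A @ G[:, s] + A[:, s] - lam
            np.maximum(a_new, 0.0, out=a_new)
            delta = max(delta, float(np.max(np.abs(a_new - A[:, s]), initial=0.0)))
            A[:, s] = a_new
        if delta < tol:
            break
    return A


def unmix_core(
    rgb: np.ndarray,
    basis: StainBasis | None = None,
    config: UnmixConfig | None = None,
) -> tuple[np.ndarray, float]:
    """Convert a brightfield RGB core image to stain-concentration channels.

    Composition of :func:`rgb_to_od` and :func:`group_sparse_unmix`; output
    channels follow ``basis.stains`` order (haematoxylin first).
    """
    basis = basis or StainBasis()
    config = config or UnmixConfig()
    od = rgb_to_od(rgb, config.background_intensity)
    return group_sparse_unmix(od, basis, config)
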