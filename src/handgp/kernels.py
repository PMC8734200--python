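"""Squared-exponential and logarithmic squared-exponential kernels.

The logarithmic kernel is the SE kernel composed with the warp
u = log(1 + x/l).  The warp is defined at dose 0 (unlike a plain log-dose
transform), behaves like x/l for x << l (so the kernel then coincides with
the linear SE kernel) and like log(x/l) for x >> l, capturing the usual
log-dose dependence of cellular responses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Hyperparameters", "k_se", "k_log", "k_log2d", "gram_matrix", "cross_matrix"]

# relative jitter added to Gram diagonals before factorization; duplicate
# dose pairs (replicates) make K exactly singular without it
JITTER = 1e-8


@dataclass(frozen=True)
class Hyperparameters:
    """GP hyperparameters: noise variance, signal variance and length scales.

    ``l1``/``l2`` are in the dose units of the two drugs; their ratio is the
    potency ratio at which the drugs substitute for each other.  ``sigma2``
    is the observational noise variance on the response scale.
    """

    sigma2: float
    sigma_f2: float
    l1: float
    l2: float

    def __post_init__(self) -> None:
        if not (self.sigma_f2 > 0 and self.l1 > 0 and self.l2 > 0):
            raise ValueError("sigma_f2, l1 and l2 must be strictly positive")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be non-negative")

    @property
    def potency_ratio(self) -> float:
        return self.l1 / self.l2

    def to_array(self) -> np.ndarray:
        return np.array([self.sigma2, self.sigma_f2, self.l1, self.l2])

    @classmethod
    def from_array(cls, a) -> "Hyperparameters":
        return cls(float(a[0]), float(a[1]), float(a[2]), float(a[3]))


def k_se(x, x2, sigma_f2: float, l: float):
    """Squared-exponential covariance sigma_f2 * exp(-(x-x')^2 / (2 l^2))."""
    if l <= 0:
        raise ValueError("length scale must be positive")
    x = np.asarray(x, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    return sigma_f2 * np.exp(-0.5 * ((x - x2) / l) ** 2)


def _warp(x, l: float):
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise ValueError("doses must be non-negative")
    return np.log1p(x / l)


def k_log(x, x2, sigma_f2: float, l: float):
    """Logarithmic SE covariance: SE applied to log(1 + x/l)."""
    if l <= 0:
        raise ValueError("length scale must be positive")
    u, u2 = _warp(x, l), _warp(x2, l)
    return sigma_f2 * np.exp(-0.5 * (u - u2) ** 2)


def k_log2d(p, q, theta: Hyperparameters):
    """Product of two logarithmic kernels with one shared amplitude.

    ``p`` and ``q`` are dose pairs (x1, x2); broadcasting over arrays of
    pairs is supported on the last axis.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    du1 = _warp(p[..., 0], theta.l1) - _warp(q[..., 0], theta.l1)
    du2 = _warp(p[..., 1], theta.l2) - _warp(q[..., 1], theta.l2)
    return theta.sigma_f2 * np.exp(-0.5 * (du1**2 + du2**2))


def _pair_sqdist(points_a: np.ndarray, points_b: np.ndarray, theta: Hyperparameters) -> np.ndarray:
    u1a = _warp(points_a[:, 0], theta.l1)
    u2a = _warp(points_a[:, 1], theta.l2)
    u1b = _warp(points_b[:, 0], theta.l1)
    u2b = _warp(points_b[:, 1], theta.l2)
    return (u1a[:, None] - u1b[None, :]) ** 2 + (u2a[:, None] - u2b[None, :]) ** 2


def gram_matrix(points, theta: Hyperparameters, jitter: float = JITTER) -> np.ndarray:
    """n x n kernel matrix of the 2-D logarithmic kernel, with diagonal jitter.

    The jitter is relative (``jitter * sigma_f2``) so that replicated dose
    pairs still give a factorizable matrix.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if not np.isfinite(pts).all():
        raise ValueError("non-finite dose values")
    K = theta.sigma_f2 * np.exp(-0.5 * _pair_sqdist(pts, pts, theta))
    if jitter:
        K[np.diag_indices_from(K)] += jitter * theta.sigma_f2
    return K


def cross_matrix(points_a, points_b, theta: Hyperparameters) -> np.ndarray:
    """Cross-covariance matrix k(a_i, b_j), shape (len(a), len(b))."""
    a = np.atleast_2d(np.asarray(points_a, dtype=float))
    b = np.atleast_2d(np.asarray(points_b, dtype=float))
    return theta.sigma_f2 * np.exp(-0.5 * _pair_sqdist(a, b, theta))
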