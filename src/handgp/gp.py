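"""Exact GP regression on dose-response surfaces.

Zero-mean GP with the 2-D logarithmic SE kernel (optionally the linear SE
kernel for comparison), exact Cholesky-based inference.  All target designs
have at most a few hundred wells, so no approximations are needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .data import DoseResponseData, PredictionGrid
from .kernels import Hyperparameters, cross_matrix, gram_matrix, k_se

__all__ = [
    "PosteriorSurface",
    "SliceCurve",
    "log_marginal_likelihood",
    "posterior_predict",
    "slice_surface",
    "mse",
]

Z95 = 1.959963984540054  # two-sided 95% Gaussian multiplier


@dataclass(frozen=True)
class SliceCurve:
    position: np.ndarray  # dose along the slice (drug-1 dose for diagonal/ray)
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    kind: str = ""


@dataclass(frozen=True)
class PosteriorSurface:
    """Posterior predictive surface of the latent response f on a grid."""

    grid: PredictionGrid
    mean: np.ndarray  # shape grid.shape
    variance: np.ndarray  # latent variance (noise-free f*)
    theta: Hyperparameters

    def __post_init__(self) -> None:
        if self.mean.shape != self.grid.shape or self.variance.shape != self.grid.shape:
            raise ValueError("mean/variance shape must match the grid")

    @property
    def ci95(self) -> tuple[np.ndarray, np.ndarray]:
        half = Z95 * np.sqrt(self.variance)
        return self.mean - half, self.mean + half

    def predictive_variance(self, observation_noise: bool = False) -> np.ndarray:
        if observation_noise:
            return self.variance + self.theta.sigma2
        return self.variance

    def value_at(self, dose1: float, dose2: float) -> float:
        i = int(np.argmin(np.abs(self.grid.axis1 - dose1)))
        j = int(np.argmin(np.abs(self.grid.axis2 - dose2)))
        return float(self.mean[i, j])


def _se_gram(X: np.ndarray, theta: Hyperparameters, jitter: float = 1e-8) -> np.ndarray:
    K = k_se(X[:, 0][:, None], X[:, 0][None, :], 1.0, theta.l1) * k_se(
        X[:, 1][:, None], X[:, 1][None, :], theta.sigma_f2, theta.l2
    )
    K[np.diag_indices_from(K)] += jitter * theta.sigma_f2
    return K


def _se_cross(A: np.ndarray, B: np.ndarray, theta: Hyperparameters) -> np.ndarray:
    return k_se(A[:, 0][:, None], B[:, 0][None, :], 1.0, theta.l1) * k_se(
        A[:, 1][:, None], B[:, 1][None, :], theta.sigma_f2, theta.l2
    )


def _factor(data: DoseResponseData, theta: Hyperparameters, kernel: str):
    X = data.X
    if kernel == "log":
        K = gram_matrix(X, theta)
    elif kernel == "se":
        K = _se_gram(X, theta)
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    A = K + theta.sigma2 * np.eye(X.shape[0])
    try:
        cho = cho_factor(A, lower=True)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("covariance not positive definite") from exc
    return cho


def log_marginal_likelihood(
    data: DoseResponseData, theta: Hyperparameters, kernel: str = "log"
) -> float:
    """log N(y | 0, K + sigma^2 I) for the zero-mean GP."""
    y = data.y
    cho = _factor(data, theta, kernel)
    alpha = cho_solve(cho, y)
    logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
    return float(-0.5 * y @ alpha - 0.5 * logdet - 0.5 * y.size * np.log(2.0 * np.pi))


def posterior_predict(
    data: DoseResponseData,
    theta: Hyperparameters,
    grid: PredictionGrid,
    kernel: str = "log",
) -> PosteriorSurface:
    """Exact posterior mean and latent variance on every grid node."""
    X = data.X
    y = data.y
    nodes = grid.nodes()
    cho = _factor(data, theta, kernel)
    alpha = cho_solve(cho, y)
    if kernel == "log":
        Ks = cross_matrix(nodes, X, theta)
    else:
        Ks = _se_cross(nodes, X, theta)
    mean = Ks @ alpha
    V = cho_solve(cho, Ks.T)
    var = theta.sigma_f2 - np.einsum("ij,ji->i", Ks, V)
    var = np.maximum(var, 0.0)
    shape = grid.shape
    return PosteriorSurface(grid, mean.reshape(shape), var.reshape(shape), theta)


def posterior_predict_points(
    data: DoseResponseData,
    theta: Hyperparameters,
    points,
    kernel: str = "log",
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and latent variance at arbitrary dose pairs."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    cho = _factor(data, theta, kernel)
    alpha = cho_solve(cho, data.y)
    Ks = cross_matrix(pts, data.X, theta) if kernel == "log" else _se_cross(pts, data.X, theta)
    mean = Ks @ alpha
    V = cho_solve(cho, Ks.T)
    var = np.maximum(theta.sigma_f2 - np.einsum("ij,ji->i", Ks, V), 0.0)
    return mean, var


def slice_surface(surface: PosteriorSurface, which: str) -> SliceCurve:
    """Extract a 1-D slice: monotherapy edges, the diagonal, or a dose ray.

    The diagonal pairs the i-th grid dose of each axis, which for matched
    designs follows the design's diagonal ray.  ``which='ray:r'`` follows the
    fixed-ratio line dose2 = r * dose1 by nearest-node lookup on axis 2.
    """
    lo, hi = surface.ci95
    if which == "drug1-mono":
        return SliceCurve(surface.grid.axis1, surface.mean[:, 0], lo[:, 0], hi[:, 0], which)
    if which == "drug2-mono":
        return SliceCurve(surface.grid.axis2, surface.mean[0, :], lo[0, :], hi[0, :], which)
    if which == "diagonal":
        n = min(surface.grid.shape)
        idx = np.arange(n)
        return SliceCurve(
            surface.grid.axis1[idx], surface.mean[idx, idx], lo[idx, idx], hi[idx, idx], which
        )
    if which.startswith("ray:"):
        r = float(which.split(":", 1)[1])
        j = np.array(
            [np.argmin(np.abs(surface.grid.axis2 - r * x)) for x in surface.grid.axis1]
        )
        i = np.arange(surface.grid.axis1.size)
        return SliceCurve(surface.grid.axis1, surface.mean[i, j], lo[i, j], hi[i, j], which)
    raise ValueError(f"unknown slice kind {which!r}")


def mse(
    data: DoseResponseData,
    surface: PosteriorSurface,
    which: str = "all",
) -> float:
    """Mean squared error of the surface mean at the observed design points.

    ``which`` selects 'all' points, or only the 'drug1-mono' / 'drug2-mono'
    axis (points where the other drug's dose is 0, including (0, 0)).
    """
    if which == "all":
        mask = np.ones(data.n_points, dtype=bool)
    elif which == "drug1-mono":
        mask = data.dose2 == 0
    elif which == "drug2-mono":
        mask = data.dose1 == 0
    else:
        raise ValueError(f"unknown selection {which!r}")
    if not mask.any():
        raise ValueError("empty selection")
    pred = np.array(
        [surface.value_at(x1, x2) for x1, x2 in zip(data.dose1[mask], data.dose2[mask])]
    )
    return float(np.mean((data.response[mask] - pred) ** 2))
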