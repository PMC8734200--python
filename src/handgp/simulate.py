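"""Synthetic checkerboard data with known ground truth.

Surfaces follow the interaction-isobole family: two shared-asymptote Hill
monotherapies combined through

    d1/D1(E) + d2/D2(E) + alpha * d1*d2 / (D1(E)*D2(E)) = 1,

where D_i(E) is the inverse Hill dose reaching effect E and alpha is the
synergy coefficient (0 = exact Loewe additivity, > 0 synergy, < 0
antagonism).  The default design mirrors the classic 6x6 benchmark
checkerboard with doses [0, 2, 5, 10, 20, 50] x [0, 0.2, 0.5, 1, 2, 5],
percent-scale inhibitory responses and mild synergy (alpha = 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .baselines import HillParams, hill_curve
from .data import Direction, DoseResponseData, ResponseScale
from .kernels import Hyperparameters, gram_matrix

__all__ = ["GeneratorSpec", "loewe_surface", "generate", "gp_sample",
           "GRECO_DESIGN_1", "GRECO_DESIGN_2"]

GRECO_DESIGN_1 = (0.0, 2.0, 5.0, 10.0, 20.0, 50.0)
GRECO_DESIGN_2 = (0.0, 0.2, 0.5, 1.0, 2.0, 5.0)

_BISECT_TOL = 1e-10


@dataclass(frozen=True)
class GeneratorSpec:
    """Ground-truth surface + noise specification.

    The two Hill curves must share E0 and Emax; a Loewe surface is only
    well defined when both drugs can reach every effect level between the
    shared asymptotes.
    """

    hill1: HillParams = HillParams(E0=100.0, Emax=0.0, h=1.2, C=10.0)
    hill2: HillParams = HillParams(E0=100.0, Emax=0.0, h=1.2, C=1.0)
    interaction_alpha: float = 0.5
    design1: tuple = GRECO_DESIGN_1
    design2: tuple = GRECO_DESIGN_2
    # default percent-scale noise level consistent with the Gamma(2, 1)
    # noise-variance prior used for this data class (variance ~ 2)
    noise_sd: float = 1.5
    seed: int = 0
    response_scale: ResponseScale = ResponseScale.PERCENT
    direction: Direction = Direction.INHIBITORY

    def __post_init__(self) -> None:
        if not np.isclose(self.hill1.E0, self.hill2.E0) or not np.isclose(
            self.hill1.Emax, self.hill2.Emax
        ):
            raise ValueError("the two Hill curves must share E0 and Emax")
        if 0.0 not in self.design1 or 0.0 not in self.design2:
            raise ValueError("designs must include dose 0 on both axes")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _inverse_hill(p: HillParams, effect: float) -> float:
    # dose producing `effect`; effect strictly between Emax and E0
    return p.C * ((p.E0 - effect) / (effect - p.Emax)) ** (1.0 / p.h)


def loewe_surface(spec: GeneratorSpec, d1, d2) -> np.ndarray:
    """Noise-free interaction-isobole response at dose pairs (vectorized).

    Solved for E by bisection between the shared asymptotes; the
    monotherapy margins reduce exactly to the Hill curves.
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    d1b, d2b = np.broadcast_arrays(d1, d2)
    out = np.empty(d1b.shape)
    it = np.nditer([d1b, d2b], flags=["multi_index"])
    for a, b in it:
        out[it.multi_index] = _loewe_point(spec, float(a), float(b))
    return out


def _loewe_point(spec: GeneratorSpec, d1: float, d2: float) -> float:
    p1, p2 = spec.hill1, spec.hill2
    if d1 == 0 and d2 == 0:
        return p1.E0
    if d2 == 0:
        return float(hill_curve(p1, d1))
    if d1 == 0:
        return float(hill_curve(p2, d2))
    alpha = spec.interaction_alpha
    e0, emax = p1.E0, p1.Emax

    def g(effect: float) -> float:
        D1 = _inverse_hill(p1, effect)
        D2 = _inverse_hill(p2, effect)
        return d1 / D1 + d2 / D2 + alpha * d1 * d2 / (D1 * D2) - 1.0

    # D_i(E) -> 0 at the no-effect end (E0) so g -> +inf there, and
    # D_i(E) -> inf at the full-effect end (Emax) so g -> -1 there:
    # bracket the root between the asymptotes.
    span = abs(e0 - emax)
    a = emax + np.sign(e0 - emax) * 1e-12 * span  # full-effect end, g < 0
    b = e0 - np.sign(e0 - emax) * 1e-12 * span  # no-effect end, g > 0
    if g(a) >= 0:  # doses beyond the bracketed range: clamp to full effect
        return a
    for _ in range(200):
        mid = 0.5 * (a + b)
        if abs(b - a) < _BISECT_TOL:
            break
        if g(mid) > 0:
            b = mid
        else:
            a = mid
    return 0.5 * (a + b)


def generate(spec: GeneratorSpec) -> tuple[DoseResponseData, np.ndarray]:
    """Noisy checkerboard data plus the noise-free truth matrix.

    Returns ``(data, truth)`` with ``truth`` shaped (len(design1),
    len(design2)); responses are truth + iid N(0, noise_sd^2), seeded.
    """
    g1, g2 = np.meshgrid(spec.design1, spec.design2, indexing="ij")
    truth = loewe_surface(spec, g1, g2)
    rng = np.random.default_rng(spec.seed)
    noisy = truth + rng.normal(scale=spec.noise_sd, size=truth.shape)
    data = DoseResponseData(
        g1.ravel(),
        g2.ravel(),
        noisy.ravel(),
        response_scale=spec.response_scale,
        direction=spec.direction,
    )
    return data, truth


def gp_sample(
    theta: Hyperparameters,
    design1,
    design2,
    seed: int = 0,
    mean: float = 0.0,
) -> DoseResponseData:
    """One draw from the zero-mean GP (plus observation noise) on a design.

    Used for hyperparameter-recovery simulations; ``mean`` shifts the draw
    to a convenient response level without changing the covariance.
    """
    g1, g2 = np.meshgrid(np.asarray(design1, float), np.asarray(design2, float),
                         indexing="ij")
    pts = np.column_stack([g1.ravel(), g2.ravel()])
    K = gram_matrix(pts, theta) + theta.sigma2 * np.eye(pts.shape[0])
    rng = np.random.default_rng(seed)
    y = mean + rng.multivariate_normal(np.zeros(pts.shape[0]), K, method="cholesky")
    return DoseResponseData(pts[:, 0], pts[:, 1], y,
                            response_scale=ResponseScale.FRACTION)
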