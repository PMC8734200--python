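"""Parametric baselines: Hill monotherapy fits and the MuSyC surface model.

The MuSyC model is the two-dimensional generalization of the Hill equation
built on a four-state mass-action scheme (unaffected U, affected by drug 1
A1, by drug 2 A2, by both A12).  Its 12 parameters comprise the four state
effects E0..E3, the monotherapy Hill shapes (h1, C1, h2, C2) and five
synergy parameters: beta (efficacy, derived from the E's), alpha12/alpha21
(potency) and gamma12/gamma21 (cooperativity).  The non-interacting null
instance fixes alpha12 = alpha21 = gamma12 = gamma21 = 1 and beta = 0.
Steady-state occupancies are obtained by solving the 4-state balance
equations directly, which reduces exactly to Hill curves on the
monotherapy edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .data import DoseResponseData, PredictionGrid
from .synergy import volume_under_surface

__all__ = [
    "HillParams",
    "MuSyCParams",
    "hill_curve",
    "fit_hill",
    "bootstrap_ci",
    "musyc_response",
    "fit_musyc",
    "musyc_effect_surface",
    "HillCurveModel",
    "MuSyCRegressor",
]


@dataclass(frozen=True)
class HillParams:
    """4-parameter Hill curve E(d) = Emax + (E0 - Emax) / (1 + (d/C)^h)."""

    E0: float
    Emax: float
    h: float
    C: float
    ci95: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.h <= 0 or self.C <= 0:
            raise ValueError("h and C must be positive")

    def to_array(self) -> np.ndarray:
        return np.array([self.E0, self.Emax, self.h, self.C])


@dataclass(frozen=True)
class MuSyCParams:
    E0: float
    E1: float
    E2: float
    E3: float
    h1: float
    h2: float
    C1: float
    C2: float
    alpha12: float = 1.0
    alpha21: float = 1.0
    gamma12: float = 1.0
    gamma21: float = 1.0
    ci95: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.h1, self.h2, self.C1, self.C2, self.gamma12, self.gamma21) <= 0:
            raise ValueError("h, C and gamma parameters must be positive")
        if min(self.alpha12, self.alpha21) < 0:
            raise ValueError("alpha parameters must be non-negative")

    @property
    def beta(self) -> float:
        """Synergistic efficacy, derived from the state effects.

        For inhibitory data beta > 0 means the combination reaches a
        stronger maximal effect (lower E3) than the strongest single drug.
        """
        e_best = min(self.E1, self.E2)
        denom = self.E0 - e_best
        if denom == 0:
            return 0.0
        return (e_best - self.E3) / denom

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.E0, self.E1, self.E2, self.E3, self.h1, self.h2, self.C1,
             self.C2, self.alpha12, self.alpha21, self.gamma12, self.gamma21]
        )


def hill_curve(params: HillParams, dose) -> np.ndarray:
    dose = np.asarray(dose, dtype=float)
    if (dose < 0).any():
        raise ValueError("doses must be non-negative")
    with np.errstate(divide="ignore"):
        ratio = np.where(dose > 0, (dose / params.C) ** params.h, 0.0)
    return params.Emax + (params.E0 - params.Emax) / (1.0 + ratio)


def _hill_bounds(doses: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    top = 1.1 * float(np.max(y))
    pos = doses[doses > 0]
    return (
        np.array([0.0, 0.0, 0.1, float(pos.min()) / 10.0]),
        np.array([top, top, 10.0, 10.0 * float(doses.max())]),
    )


def fit_hill(
    doses,
    responses,
    bounds: tuple | None = None,
    starts=None,
) -> HillParams:
    """Bounded least-squares Hill fit with a deterministic multi-start grid.

    ``starts`` overrides the default start grid with explicit (E0, Emax, h,
    C) vectors -- bootstrap refits restart from the point estimate.
    """
    d = np.asarray(doses, dtype=float).ravel()
    y = np.asarray(responses, dtype=float).ravel()
    if np.unique(d).size < 4 or (d == 0).sum() == 0:
        raise ValueError("need at least 4 distinct doses including 0")
    lo, hi = bounds if bounds is not None else _hill_bounds(d, y)

    def residual(p):
        return hill_curve(HillParams(p[0], p[1], max(p[2], 1e-12), max(p[3], 1e-300)), d) - y

    if starts is None:
        pos = np.sort(d[d > 0])
        c_starts = [float(np.median(pos)), float(pos[0]), float(pos[-1])]
        starts = []
        for h0 in (0.5, 1.0, 2.0):
            for c0 in c_starts:
                starts.append(
                    np.clip(np.array([float(y.max()), float(y.min()), h0, c0]), lo, hi)
                )
    else:
        starts = [np.clip(np.asarray(s, dtype=float), lo, hi) for s in starts]
    best = None
    for p0 in starts:
        try:
            res = least_squares(residual, p0, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        if best is None or res.cost < best.cost - 1e-12:
            best = res
    if best is None:
        raise RuntimeError("Hill fit failed on all starts")
    p = best.x
    return HillParams(float(p[0]), float(p[1]), float(p[2]), float(p[3]))


def musyc_response(params: MuSyCParams, d1, d2) -> np.ndarray:
    """MuSyC steady-state response at dose pairs (vectorized).

    Solves the four-state balance equations with unit basal rates; the
    monotherapy edges reduce exactly to Hill curves (E0, E1, h1, C1) and
    (E0, E2, h2, C2), and (0, 0) gives E0.
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    d1b, d2b = np.broadcast_arrays(d1, d2)
    shape = d1b.shape
    d1f = d1b.ravel()
    d2f = d2b.ravel()
    if (d1f < 0).any() or (d2f < 0).any():
        raise ValueError("doses must be non-negative")
    p = params
    f1 = d1f**p.h1
    f2 = d2f**p.h2
    b1 = p.C1**p.h1
    b2 = p.C2**p.h2
    f12 = (p.alpha12 * d2f) ** (p.gamma12 * p.h2)
    f21 = (p.alpha21 * d1f) ** (p.gamma21 * p.h1)
    b12 = b2**p.gamma12
    b21 = b1**p.gamma21

    m = d1f.size
    M = np.zeros((m, 4, 4))
    M[:, 0, 0] = -(f1 + f2)
    M[:, 0, 1] = b1
    M[:, 0, 2] = b2
    M[:, 1, 0] = f1
    M[:, 1, 1] = -(b1 + f12)
    M[:, 1, 3] = b12
    M[:, 2, 0] = f2
    M[:, 2, 2] = -(b2 + f21)
    M[:, 2, 3] = b21
    # replace the redundant balance row with the normalization sum(P) = 1
    M[:, 3, :] = 1.0
    rhs = np.zeros((m, 4))
    rhs[:, 3] = 1.0
    # scale rows for conditioning at extreme doses
    norm = np.maximum(np.abs(M).max(axis=2, keepdims=True), 1e-300)
    P = np.linalg.solve(M / norm, (rhs / norm[:, :, 0])[..., None])[..., 0]
    E = P @ np.array([p.E0, p.E1, p.E2, p.E3])
    return E.reshape(shape)


_LOG_IDX = slice(4, 12)  # h1, h2, C1, C2, alpha12, alpha21, gamma12, gamma21


def _pack(params: MuSyCParams) -> np.ndarray:
    v = params.to_array()
    v[_LOG_IDX] = np.log(np.maximum(v[_LOG_IDX], 1e-12))
    return v


def _unpack(v: np.ndarray) -> MuSyCParams:
    w = v.copy()
    w[_LOG_IDX] = np.exp(w[_LOG_IDX])
    return MuSyCParams(*w)


def fit_musyc(
    data: DoseResponseData,
    e_bounds: tuple[float, float] | None = None,
    constrained: bool = False,
) -> MuSyCParams:
    """Bounded least-squares MuSyC fit (12 parameters, or 7 when constrained).

    ``constrained=True`` fits the non-interacting null instance:
    alpha12 = alpha21 = gamma12 = gamma21 = 1 and beta = 0 (so
    E3 = min(E1, E2)).  State effects E1, E2, E3 are kept inside
    ``e_bounds`` (defaults to [0, 100] or [0, 1] by response scale).
    """
    if e_bounds is None:
        e_bounds = (0.0, 100.0) if data.response_scale.value == "percent" else (0.0, 1.0)
    e_lo, e_hi = e_bounds
    y = data.y
    d1, d2 = data.dose1, data.dose2

    m1_d, m1_y = data.monotherapy(1)
    m2_d, m2_y = data.monotherapy(2)
    try:
        h1_init = fit_hill(m1_d, m1_y)
        h2_init = fit_hill(m2_d, m2_y)
    except (ValueError, RuntimeError):
        pos1 = np.median(d1[d1 > 0])
        pos2 = np.median(d2[d2 > 0])
        h1_init = HillParams(float(y.max()), float(y.min()), 1.0, float(pos1))
        h2_init = HillParams(float(y.max()), float(y.min()), 1.0, float(pos2))

    e0_init = float(np.clip(0.5 * (h1_init.E0 + h2_init.E0), e_lo, 1.1 * max(y.max(), e_hi)))
    e1_init = float(np.clip(h1_init.Emax, e_lo, e_hi))
    e2_init = float(np.clip(h2_init.Emax, e_lo, e_hi))

    if constrained:
        def build(v):
            e3 = min(v[1], v[2])
            return MuSyCParams(v[0], v[1], v[2], e3,
                               np.exp(v[3]), np.exp(v[4]), np.exp(v[5]), np.exp(v[6]))

        x0 = np.array([e0_init, e1_init, e2_init,
                       np.log(h1_init.h), np.log(h2_init.h),
                       np.log(h1_init.C), np.log(h2_init.C)])
        lo = np.array([e_lo, e_lo, e_lo, np.log(0.1), np.log(0.1),
                       np.log(h1_init.C) - 7, np.log(h2_init.C) - 7])
        hi = np.array([1.1 * max(float(y.max()), e_hi), e_hi, e_hi,
                       np.log(10.0), np.log(10.0),
                       np.log(h1_init.C) + 7, np.log(h2_init.C) + 7])
    else:
        def build(v):
            return _unpack(v)

        e3_init = float(np.clip(min(e1_init, e2_init), e_lo, e_hi))
        x0 = _pack(MuSyCParams(e0_init, e1_init, e2_init, e3_init,
                               h1_init.h, h2_init.h, h1_init.C, h2_init.C))
        lo = np.concatenate([
            [e_lo, e_lo, e_lo, e_lo],
            [np.log(0.1), np.log(0.1), np.log(h1_init.C) - 7, np.log(h2_init.C) - 7],
            [np.log(1e-6), np.log(1e-6), np.log(1e-2), np.log(1e-2)],
        ])
        hi = np.concatenate([
            [1.1 * max(float(y.max()), e_hi), e_hi, e_hi, e_hi],
            [np.log(10.0), np.log(10.0), np.log(h1_init.C) + 7, np.log(h2_init.C) + 7],
            [np.log(1e6), np.log(1e6), np.log(1e2), np.log(1e2)],
        ])
    x0 = np.clip(x0, lo, hi)

    def residual(v):
        try:
            return musyc_response(build(v), d1, d2) - y
        except (ValueError, np.linalg.LinAlgError):
            return np.full(y.size, 1e6)

    starts = [x0]
    shift = np.zeros(x0.size)
    if not constrained:
        shift[8:10] = np.log(3.0)  # nudge the potency-synergy starts
        starts.append(np.clip(x0 + shift, lo, hi))
        starts.append(np.clip(x0 - shift, lo, hi))
    best = None
    for s in starts:
        try:
            res = least_squares(residual, s, bounds=(lo, hi), method="trf",
                                max_nfev=2000)
        except Exception:
            continue
        if best is None or res.cost < best.cost - 1e-12:
            best = res
    if best is None:
        raise RuntimeError("MuSyC fit failed on all starts")
    return build(best.x)


def bootstrap_ci(
    fit_fn,
    predict_fn,
    fitted,
    data_x,
    data_y,
    B: int = 1000,
    seed: int = 0,
    level: float = 0.95,
):
    """Parametric bootstrap percentile intervals for any fitted model.

    Responses are resampled as fitted prediction + Gaussian noise with the
    residual standard deviation, the model is refit ``B`` times, and
    per-parameter percentile intervals are returned together with the
    fraction of failed refits.
    """
    y = np.asarray(data_y, dtype=float)
    pred = predict_fn(fitted, data_x)
    resid_sd = float(np.std(y - pred, ddof=1))
    rng = np.random.default_rng(seed)
    draws = []
    failures = 0
    for _ in range(B):
        y_star = pred + rng.normal(scale=resid_sd, size=y.size) if resid_sd > 0 else pred
        try:
            refit = fit_fn(data_x, y_star)
        except Exception:
            failures += 1
            continue
        draws.append(refit.to_array())
    if not draws:
        raise RuntimeError("all bootstrap refits failed")
    draws = np.asarray(draws)
    q = 0.5 * (1 - level)
    lo = np.quantile(draws, q, axis=0)
    hi = np.quantile(draws, 1 - q, axis=0)
    return np.column_stack([lo, hi]), failures / B


def musyc_effect_surface(
    full: MuSyCParams,
    null: MuSyCParams,
    grid: PredictionGrid,
    direction: str = "inhibitory",
) -> tuple[np.ndarray, float]:
    """Effect grid (constrained null - full, positive = synergy for
    inhibitory data) and its volume difference."""
    g1, g2 = np.meshgrid(grid.axis1, grid.axis2, indexing="ij")
    full_surf = musyc_response(full, g1, g2)
    null_surf = musyc_response(null, g1, g2)
    if str(direction) in ("inhibitory", "Direction.INHIBITORY"):
        effect = null_surf - full_surf
    else:
        effect = full_surf - null_surf
    return effect, volume_under_surface(grid, effect)


class HillCurveModel(BaseEstimator, RegressorMixin):
    """Scikit-learn style wrapper around the bounded Hill fit.

    Parameters
    ----------
    bounds : optional (lower, upper) arrays for (E0, Emax, h, C).
    """

    def __init__(self, bounds=None):
        self.bounds = bounds

    def fit(self, X, y):
        d = np.asarray(X, dtype=float).ravel()
        self.params_ = fit_hill(d, y, bounds=self.bounds)
        return self

    def predict(self, X):
        d = np.asarray(X, dtype=float).ravel()
        return hill_curve(self.params_, d)

    def bootstrap_ci_(self, X, y, B: int = 1000, seed: int = 0):
        d = np.asarray(X, dtype=float).ravel()
        ci, fail_rate = bootstrap_ci(
            lambda dx, yy: fit_hill(dx, yy, bounds=self.bounds),
            lambda p, dx: hill_curve(p, dx),
            self.params_, d, y, B=B, seed=seed,
        )
        names = ("E0", "Emax", "h", "C")
        self.params_ = replace(
            self.params_,
            ci95={n: (float(ci[k, 0]), float(ci[k, 1])) for k, n in enumerate(names)},
        )
        self.bootstrap_failure_rate_ = fail_rate
        return self.params_.ci95


class MuSyCRegressor(BaseEstimator, RegressorMixin):
    """Scikit-learn style MuSyC surface regressor.

    ``X`` is an (n, 2) array of dose pairs.  ``constrained=True`` fits the
    non-interacting null instance (alpha = gamma = 1, beta = 0).
    """

    def __init__(self, constrained=False, e_bounds=None, response_scale="percent"):
        self.constrained = constrained
        self.e_bounds = e_bounds
        self.response_scale = response_scale

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        data = DoseResponseData(
            X[:, 0], X[:, 1], y, response_scale=self.response_scale
        )
        self.params_ = fit_musyc(data, e_bounds=self.e_bounds, constrained=self.constrained)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return musyc_response(self.params_, X[:, 0], X[:, 1])
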