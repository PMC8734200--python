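"""Effect surfaces, per-dose synergy calls and the volume-difference score.

The effect surface is the signed difference between the Hand null reference
and the GP-fitted response (null - fit for inhibitory data), so positive
values mean more inhibition than expected under no interaction, i.e.
synergy.  The summary score is the difference of the volumes under the two
surfaces, computed by Delaunay triangulation of the dose grid in linear
dose units.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay

from .data import Direction, DoseResponseData, PredictionGrid, ResponseScale
from .gp import Z95, PosteriorSurface
from .hand import HandNullSurface

__all__ = [
    "SynergyResult",
    "effect_surface",
    "volume_under_surface",
    "volume_difference",
    "fractional_effect_curve",
    "score_surfaces",
]


@dataclass(frozen=True)
class SynergyResult:
    """Per-node effect surface with CIs, volumes, and per-design-dose calls."""

    grid: PredictionGrid
    effect: np.ndarray
    effect_lower: np.ndarray
    effect_upper: np.ndarray
    volume_fitted: float
    volume_null: float
    volume_difference: float
    volume_difference_ci: tuple[float, float]
    calls: pd.DataFrame | None = None
    residuals: pd.DataFrame | None = None

    def call_at(self, dose1: float, dose2: float) -> str:
        i = int(np.argmin(np.abs(self.grid.axis1 - dose1)))
        j = int(np.argmin(np.abs(self.grid.axis2 - dose2)))
        return _call(self.effect_lower[i, j], self.effect_upper[i, j])

    @property
    def overall_call(self) -> str:
        lo, hi = self.volume_difference_ci
        return _call(lo, hi)


def _call(lower: float, upper: float) -> str:
    if lower > 0:
        return "synergy"
    if upper < 0:
        return "antagonism"
    return "additive"


@lru_cache(maxsize=32)
def _triangulation(axis1_bytes: bytes, axis2_bytes: bytes, n1: int, n2: int):
    axis1 = np.frombuffer(axis1_bytes).reshape(n1)
    axis2 = np.frombuffer(axis2_bytes).reshape(n2)
    g1, g2 = np.meshgrid(axis1, axis2, indexing="ij")
    pts = np.column_stack([g1.ravel(), g2.ravel()])
    tri = Delaunay(pts)
    simplices = tri.simplices
    a = pts[simplices[:, 0]]
    b = pts[simplices[:, 1]]
    c = pts[simplices[:, 2]]
    areas = 0.5 * np.abs(
        (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
        - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1])
    )
    return simplices, areas


def volume_under_surface(grid: PredictionGrid, values: np.ndarray) -> float:
    """Volume under a gridded surface via Delaunay triangulation.

    Each triangle contributes area x mean of its three vertex values, which
    integrates piecewise-planar surfaces exactly.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise ValueError("values shape must match the grid")
    simplices, areas = _triangulation(
        grid.axis1.tobytes(), grid.axis2.tobytes(), grid.axis1.size, grid.axis2.size
    )
    v = values.ravel()
    return float(np.sum(areas * v[simplices].mean(axis=1)))


def effect_surface(
    fitted: PosteriorSurface,
    null: HandNullSurface,
    direction: Direction = Direction.INHIBITORY,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Signed effect surface and its 95% CI (positive = synergy).

    The CI uses the fitted surface's predictive variance only; the null is
    treated as fixed because it is built from the same posterior's
    monotherapy slices (avoiding double-counting keeps the effect CIs tight).
    """
    if fitted.grid.shape != null.grid.shape or not np.allclose(
        fitted.grid.axis1, null.grid.axis1
    ):
        raise ValueError("fitted and null surfaces are on different grids")
    if Direction(direction) == Direction.INHIBITORY:
        effect = null.values - fitted.mean
    else:
        effect = fitted.mean - null.values
    half = Z95 * np.sqrt(fitted.variance)
    return effect, effect - half, effect + half


def volume_difference(
    fitted: PosteriorSurface,
    null: HandNullSurface,
    direction: Direction = Direction.INHIBITORY,
) -> float:
    """Volume(null) - volume(fit) for inhibitory data (positive = synergy)."""
    effect, _, _ = effect_surface(fitted, null, direction)
    return volume_under_surface(fitted.grid, effect)


def score_surfaces(
    fitted: PosteriorSurface,
    null: HandNullSurface,
    data: DoseResponseData | None = None,
) -> SynergyResult:
    """Assemble the full synergy result from fitted and null surfaces."""
    direction = data.direction if data is not None else Direction.INHIBITORY
    effect, lower, upper = effect_surface(fitted, null, direction)
    grid = fitted.grid
    v_fit = volume_under_surface(grid, fitted.mean)
    v_null = volume_under_surface(grid, null.values)
    vd = volume_under_surface(grid, effect)
    vd_ci = (
        volume_under_surface(grid, lower),
        volume_under_surface(grid, upper),
    )

    calls = None
    residuals = None
    if data is not None:
        rows = []
        for d1 in data.unique_doses(1):
            for d2 in data.unique_doses(2):
                i = int(np.argmin(np.abs(grid.axis1 - d1)))
                j = int(np.argmin(np.abs(grid.axis2 - d2)))
                rows.append(
                    {
                        "dose1": d1,
                        "dose2": d2,
                        "effect": effect[i, j],
                        "lower": lower[i, j],
                        "upper": upper[i, j],
                        "call": _call(lower[i, j], upper[i, j]),
                    }
                )
        calls = pd.DataFrame(rows)
        pred = np.array(
            [fitted.value_at(x1, x2) for x1, x2 in zip(data.dose1, data.dose2)]
        )
        residuals = pd.DataFrame(
            {
                "dose1": data.dose1,
                "dose2": data.dose2,
                "observed": data.response,
                "fitted": pred,
                "residual": data.response - pred,
            }
        )
    return SynergyResult(
        grid=grid,
        effect=effect,
        effect_lower=lower,
        effect_upper=upper,
        volume_fitted=v_fit,
        volume_null=v_null,
        volume_difference=vd,
        volume_difference_ci=vd_ci,
        calls=calls,
        residuals=residuals,
    )


def fractional_effect_curve(
    null_diag,
    fitted_diag,
    response_scale: ResponseScale = ResponseScale.PERCENT,
    direction: Direction = Direction.INHIBITORY,
) -> tuple[np.ndarray, np.ndarray, list]:
    """Effect difference along the diagonal against fitted fractional effect.

    The x-axis is the fractional effect implied by the null diagonal
    (0 = no effect at dose 0, 1 = the largest effect the null reaches along
    the diagonal); the y-axis is the signed difference between null and
    fitted diagonals (positive = synergy for inhibitory data).  Restricted
    to the monotone segment of the null diagonal.
    """
    null_mean = np.asarray(null_diag, dtype=float)
    fit_mean = np.asarray(fitted_diag, dtype=float)
    if null_mean.shape != fit_mean.shape:
        raise ValueError("diagonal curves must have the same length")
    warnings_list: list[str] = []
    diffs = np.diff(null_mean)
    sign = np.sign(diffs[np.nonzero(diffs)[0][0]]) if (diffs != 0).any() else 0.0
    end = null_mean.size - 1
    for k, d in enumerate(diffs):
        if np.sign(d) != sign:
            end = k
            warnings_list.append("non-monotone null diagonal; restricted to monotone segment")
            break
    sl = slice(0, end + 1)
    null_seg = null_mean[sl]
    span = abs(null_seg[-1] - null_seg[0])
    if span == 0:
        frac = np.zeros(null_seg.shape)
    else:
        frac = np.abs(null_seg - null_seg[0]) / span
    if Direction(direction) == Direction.INHIBITORY:
        diff = null_seg - fit_mean[sl]
    else:
        diff = fit_mean[sl] - null_seg
    if ResponseScale(response_scale) == ResponseScale.PERCENT:
        diff = diff / 100.0
    return frac, diff, warnings_list
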