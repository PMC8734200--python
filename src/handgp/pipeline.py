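"""End-to-end Hand-GP synergy estimator.

``HandGPSynergy`` runs the whole pipeline on one checkerboard: Gamma priors
from the data, hyperparameter inference (fast MAP mode or full HMC), exact
GP posterior surface on a dense log-warped grid, Hand null construction
from the fitted monotherapy slices, and the volume-difference synergy
score.  It follows the scikit-learn estimator protocol so it composes with
pipelines and model selection; the fitted state lives in trailing-underscore
attributes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .data import Direction, DoseResponseData, ResponseScale, make_grid
from .gp import posterior_predict, posterior_predict_points, slice_surface
from .hand import MonotherapyCurve, hand_null_surface
from .inference import HmcSettings, build_priors, fit_map, run_hmc
from .synergy import fractional_effect_curve, score_surfaces

__all__ = ["HandGPSynergy"]


def _as_data(X, y, response_scale, direction) -> DoseResponseData:
    if isinstance(X, DoseResponseData):
        return X
    if isinstance(X, pd.DataFrame) and {"dose1", "dose2", "response"} <= set(X.columns):
        return DoseResponseData(
            X["dose1"].to_numpy(float),
            X["dose2"].to_numpy(float),
            X["response"].to_numpy(float),
            response_scale=response_scale,
            direction=direction,
        )
    X = np.asarray(X, dtype=float)
    if y is None:
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError("without y, X must be (n, 3): dose1, dose2, response")
        d1, d2, resp = X[:, 0], X[:, 1], X[:, 2]
    else:
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be an (n, 2) array of dose pairs")
        d1, d2, resp = X[:, 0], X[:, 1], np.asarray(y, dtype=float)
    return DoseResponseData(
        d1, d2, resp, response_scale=response_scale, direction=direction
    )


class HandGPSynergy(BaseEstimator, RegressorMixin):
    """GP dose-response surface + Hand null reference + volume synergy score.

    Parameters
    ----------
    mode : {'map', 'hmc'}
        'map' maximizes the log posterior (fast, deterministic); 'hmc'
        samples the hyperparameter posterior and plugs in the posterior
        mean for the surface.
    n_grid : prediction-grid nodes per axis (log1p-warped spacing, design
        doses snapped on).
    prior_c : constant scaling the length-scale prior mean relative to the
        maximal dose, or 'auto' (min/max monotherapy effect ratio, so
        strongly responding data get genuinely log-scaled length scales).
    hmc : HmcSettings for 'hmc' mode (defaults to the standard settings).
    kernel : {'log', 'se'} -- logarithmic or plain squared-exponential.
    response_scale, direction : used when X is a bare array.

    Attributes
    ----------
    data_, priors_, theta_, posterior_ (hmc mode), grid_, surface_, null_,
    result_, volume_difference_.
    """

    def __init__(
        self,
        mode: str = "map",
        n_grid: int = 101,
        prior_c="auto",
        hmc: HmcSettings | None = None,
        kernel: str = "log",
        response_scale=ResponseScale.PERCENT,
        direction=Direction.INHIBITORY,
        seed: int = 0,
    ):
        self.mode = mode
        self.n_grid = n_grid
        self.prior_c = prior_c
        self.hmc = hmc
        self.kernel = kernel
        self.response_scale = response_scale
        self.direction = direction
        self.seed = seed

    def fit(self, X, y=None):
        data = _as_data(X, y, self.response_scale, self.direction)
        self.data_ = data
        # the auto c-rule shrinks the length scales to make the *warp*
        # logarithmic; a plain SE kernel has no warp and its natural prior
        # scale is the dose range itself
        c = self.prior_c
        if c == "auto" and self.kernel == "se":
            c = 1.0
        self.priors_ = build_priors(data, c=c)
        if self.mode == "map":
            self.theta_ = fit_map(data, self.priors_)
            self.posterior_ = None
        elif self.mode == "hmc":
            settings = self.hmc if self.hmc is not None else HmcSettings(seed=self.seed)
            self.posterior_ = run_hmc(data, self.priors_, settings)
            self.theta_ = self.posterior_.posterior_mean
        else:
            raise ValueError(f"unknown mode {self.mode!r}")
        spacing = "natural-log1p" if self.kernel == "log" else "linear"
        self.grid_ = make_grid(
            data,
            n_per_axis=self.n_grid,
            lengthscales=(self.theta_.l1, self.theta_.l2),
            spacing=spacing,
        )
        self.surface_ = posterior_predict(data, self.theta_, self.grid_, kernel=self.kernel)
        self.monotherapy_curves_ = (
            self._mono_curve(1), self._mono_curve(2)
        )
        f1, f2 = self.monotherapy_curves_
        self.null_ = hand_null_surface(f1, f2, self.grid_)
        self.result_ = score_surfaces(self.surface_, self.null_, data)
        self.volume_difference_ = self.result_.volume_difference
        return self

    def _mono_curve(self, axis: int) -> MonotherapyCurve:
        """Monotherapy slice extended past the design range for Hand steps.

        At the high-dose corner the Hand construction walks to combined
        equivalent doses beyond the design's maximum; the GP predicts there
        (decaying toward the zero prior mean, i.e. full effect for
        inhibitory data), so the curve is tabulated out to twice the warped
        dose range.  Grid nodes keep the exact on-design slice values.
        """
        ax = self.grid_.axis1 if axis == 1 else self.grid_.axis2
        mean = self.surface_.mean[:, 0] if axis == 1 else self.surface_.mean[0, :]
        l = self.theta_.l1 if axis == 1 else self.theta_.l2
        u_max = np.log1p(ax[-1] / l)
        n_ext = max(ax.size // 2, 8)
        ext = l * np.expm1(np.linspace(u_max, 2.0 * u_max, n_ext + 1)[1:])
        pts = np.zeros((n_ext, 2))
        pts[:, axis - 1] = ext
        ext_mean, _ = posterior_predict_points(
            self.data_, self.theta_, pts, kernel=self.kernel
        )
        return MonotherapyCurve(np.r_[ax, ext], np.r_[mean, ext_mean])

    def predict(self, X):
        """GP posterior mean response at (n, 2) dose pairs."""
        X = np.asarray(X, dtype=float)
        mean, _ = posterior_predict_points(self.data_, self.theta_, X, kernel=self.kernel)
        return mean

    def slice(self, which: str):
        return slice_surface(self.surface_, which)

    def fractional_effect(self):
        """Diagonal effect difference vs fitted fractional effect."""
        n = min(self.grid_.shape)
        idx = np.arange(n)
        return fractional_effect_curve(
            self.null_.values[idx, idx],
            self.surface_.mean[idx, idx],
            response_scale=self.data_.response_scale,
            direction=self.data_.direction,
        )

    def summary(self) -> dict:
        r = self.result_
        out = {
            "theta": {
                "sigma2": self.theta_.sigma2,
                "sigma_f2": self.theta_.sigma_f2,
                "l1": self.theta_.l1,
                "l2": self.theta_.l2,
            },
            "volume_fitted": r.volume_fitted,
            "volume_null": r.volume_null,
            "volume_difference": r.volume_difference,
            "volume_difference_ci": list(r.volume_difference_ci),
            "overall_call": r.overall_call,
        }
        if self.posterior_ is not None:
            out["posterior"] = self.posterior_.summary()
            out["hmc"] = {
                "acceptance_rate": self.posterior_.acceptance_rate,
                "step_size": self.posterior_.step_size_used,
                "divergence_rate": self.posterior_.divergence_rate,
                "rhat": [float(r) for r in self.posterior_.rhat],
            }
        return out
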