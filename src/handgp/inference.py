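"""Bayesian hyperparameter inference: moment-matched Gamma priors, HMC
sampling with grid-based step-size selection, HPD summaries, and a fast
deterministic MAP mode.

The four hyperparameters (noise variance sigma^2, signal variance sigma_f^2,
length scales l1, l2) are sampled on the log scale with the Gamma priors
transformed accordingly.  Step size is picked from a fixed log-spaced grid:
a short pilot chain is run at each candidate, largest first, and the largest
step size whose pilot acceptance reaches the target is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from ._hmc import lp_and_grad, lp_and_grad_grid, run_chain
from .data import DoseResponseData, ResponseScale
from .kernels import JITTER, Hyperparameters

__all__ = [
    "PriorSpec",
    "HmcSettings",
    "HyperparameterPosterior",
    "build_priors",
    "run_hmc",
    "hpd_interval",
    "fit_map",
    "split_rhat",
]

PARAM_NAMES = ("sigma2", "sigma_f2", "l1", "l2")

DEFAULT_STEP_GRID = (0.01, 0.02, 0.03, 0.05, 0.08, 0.1, 0.2, 0.3, 0.6, 1.00)


@dataclass(frozen=True)
class PriorSpec:
    """Independent Gamma(shape, rate) priors, ordered (sigma2, sigma_f, l1, l2).

    The amplitude prior targets the GP standard deviation sigma_f (the
    effect-scale hyperparameter), the noise prior targets the noise
    *variance* sigma^2.
    """

    alpha: np.ndarray
    beta: np.ndarray
    c: float = 1.0

    def __post_init__(self) -> None:
        a = np.asarray(self.alpha, dtype=float)
        b = np.asarray(self.beta, dtype=float)
        if a.shape != (4,) or b.shape != (4,):
            raise ValueError("alpha and beta must have 4 entries")
        if (a <= 0).any() or (b <= 0).any():
            raise ValueError("Gamma shape and rate must be positive")
        object.__setattr__(self, "alpha", a)
        object.__setattr__(self, "beta", b)

    @property
    def mean(self) -> np.ndarray:
        return self.alpha / self.beta

    @property
    def variance(self) -> np.ndarray:
        return self.alpha / self.beta**2


@dataclass(frozen=True)
class HmcSettings:
    burn_in: int = 1000
    n_samples: int = 100_000
    target_accept: float = 0.75
    leapfrog_steps: int = 5
    step_size_grid: tuple = DEFAULT_STEP_GRID
    step_size: float | None = None  # fixed step size skips the pilot search
    thin: int = 1
    pilot_iterations: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.target_accept < 1:
            raise ValueError("target_accept must be in (0, 1)")
        g = tuple(float(s) for s in self.step_size_grid)
        if any(s <= 0 for s in g) or any(b <= a for a, b in zip(g, g[1:])):
            raise ValueError("step_size_grid must be strictly increasing and positive")
        object.__setattr__(self, "step_size_grid", g)


@dataclass
class HyperparameterPosterior:
    samples: np.ndarray  # (n_kept, 4) in theta space
    acceptance_rate: float
    step_size_used: float
    divergence_rate: float
    warnings: list = field(default_factory=list)

    @property
    def posterior_mean(self) -> Hyperparameters:
        return Hyperparameters.from_array(self.samples.mean(axis=0))

    @property
    def hpd95(self) -> np.ndarray:
        return np.array([hpd_interval(self.samples[:, k]) for k in range(4)])

    @property
    def rhat(self) -> np.ndarray:
        return np.array([split_rhat(self.samples[:, k]) for k in range(4)])

    def summary(self) -> dict:
        mean = self.posterior_mean.to_array()
        hpd = self.hpd95
        return {
            name: {"mean": float(mean[k]), "hpd95": [float(hpd[k, 0]), float(hpd[k, 1])]}
            for k, name in enumerate(PARAM_NAMES)
        }


def _moment_match(mean: float, variance: float) -> tuple[float, float]:
    beta = mean / variance
    return mean * beta, beta


def build_priors(data: DoseResponseData, c: float | str = 1.0) -> PriorSpec:
    """Moment-matched Gamma priors from the design and the observed effects.

    Length scale l_i: mean c * Dmax_i, variance 0.1 * (c * Dmax_i / 2).
    GP amplitude sigma_f: mean Emax_obs / 2, variance 0.1 * (Emax_obs / 2),
    with Emax_obs the maximum effect reached (observed response range) --
    so the GP can swing across about half the effect range a priori.  Noise
    variance: Gamma(2, 1) on percent-scale data, Gamma(0.14, 1.14) otherwise.

    ``c='auto'`` sets c to the ratio between the minimal and maximal effect
    reached on the monotherapy data: when the response barely moves, c is
    near 1 and the prior favours length scales near the dose range (an
    almost linear warp / very smooth surface); when the response swings
    strongly, c shrinks the length scales so the warp -- and hence the
    kernel -- becomes genuinely logarithmic over the design.
    """
    if c == "auto":
        mono = np.concatenate(
            [data.monotherapy(1)[1], data.monotherapy(2)[1]]
        )
        lo = np.abs(mono).min()
        hi = np.abs(mono).max()
        c_val = float(np.clip(lo / hi, 1e-3, 1.0)) if hi > 0 else 1.0
    else:
        c_val = float(c)
    if c_val <= 0:
        raise ValueError("c must be positive")

    emax_obs = data.effect_range()
    if emax_obs <= 0:
        raise ValueError("responses are constant; effect scale undefined")

    alphas = np.empty(4)
    betas = np.empty(4)
    if data.response_scale == ResponseScale.PERCENT:
        alphas[0], betas[0] = 2.0, 1.0
    else:
        alphas[0], betas[0] = 0.14, 1.14
    alphas[1], betas[1] = _moment_match(emax_obs / 2.0, 0.1 * (emax_obs / 2.0))
    for axis in (1, 2):
        dmax = data.max_dose(axis)
        if dmax <= 0:
            raise ValueError("zero dose range")
        m = c_val * dmax
        alphas[1 + axis], betas[1 + axis] = _moment_match(m, 0.1 * (m / 2.0))
    return PriorSpec(alphas, betas, c=c_val)


def hpd_interval(samples, level: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``level`` posterior mass (sorted window)."""
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if n == 0:
        raise ValueError("empty samples")
    m = max(int(np.ceil(level * n)), 1)
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m:] - x[: n - m]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m])


def split_rhat(samples) -> float:
    """Split-R-hat of a single chain (two half-chains)."""
    x = np.asarray(samples, dtype=float).ravel()
    n = x.size // 2
    if n < 2:
        return np.nan
    halves = np.stack([x[:n], x[n : 2 * n]])
    within = halves.var(axis=1, ddof=1).mean()
    between = n * halves.mean(axis=1).var(ddof=1)
    if within == 0:
        return 1.0
    var_plus = (n - 1) / n * within + between / n
    return float(np.sqrt(var_plus / within))


def _chain_inputs(data: DoseResponseData, priors: PriorSpec):
    """Inputs for the jitted chain; detects complete-grid designs.

    A complete checkerboard without replicates admits the Kronecker fast
    path; anything else (missing wells, replicates) uses the dense path.
    """
    ux1, id1 = np.unique(data.dose1, return_inverse=True)
    ux2, id2 = np.unique(data.dose2, return_inverse=True)
    id1 = id1.astype(np.int64)
    id2 = id2.astype(np.int64)
    n, m1, m2 = data.n_points, ux1.size, ux2.size
    grid_mode = False
    Y = np.zeros((1, 1))
    if n == m1 * m2:
        flat = id1 * m2 + id2
        if np.unique(flat).size == n:
            Y = np.empty((m1, m2))
            Y[id1, id2] = data.y
            grid_mode = True
    return (
        np.ascontiguousarray(ux1),
        np.ascontiguousarray(ux2),
        np.ascontiguousarray(id1),
        np.ascontiguousarray(id2),
        np.ascontiguousarray(data.y),
        np.ascontiguousarray(Y),
        grid_mode,
        np.ascontiguousarray(priors.alpha),
        np.ascontiguousarray(priors.beta),
    )


def _start_phi(priors: PriorSpec) -> np.ndarray:
    return np.log(priors.mean)


def _phi_to_theta(phi: np.ndarray) -> np.ndarray:
    """phi = (log s2, log sf, log l1, log l2) -> (s2, sf^2, l1, l2)."""
    phi = np.atleast_2d(phi)
    theta = np.exp(phi)
    theta[:, 1] = theta[:, 1] ** 2
    return theta


def run_hmc(
    data: DoseResponseData,
    priors: PriorSpec,
    settings: HmcSettings = HmcSettings(),
) -> HyperparameterPosterior:
    """Sample the hyperparameter posterior with leapfrog HMC.

    Randomness is fully determined by ``settings.seed``.  When no candidate
    step size reaches the target acceptance in the pilot runs, the smallest
    grid value is used and a warning is recorded in the result.
    """
    ux1, ux2, id1, id2, y, Y, grid_mode, pa, pb = _chain_inputs(data, priors)
    phi0 = _start_phi(priors)
    warnings_list: list[str] = []
    rng = np.random.SeedSequence(settings.seed)
    pilot_seed, main_seed = (int(s) for s in rng.generate_state(2) % (2**31 - 1))

    if settings.step_size is not None:
        eps = float(settings.step_size)
    else:
        eps = None
        for cand in sorted(settings.step_size_grid, reverse=True):
            _, acc, _ = run_chain(
                phi0, cand, settings.leapfrog_steps, 0, settings.pilot_iterations, 1,
                ux1, ux2, id1, id2, y, Y, grid_mode, pa, pb, JITTER, pilot_seed,
            )
            if acc >= settings.target_accept:
                eps = cand
                break
        if eps is None:
            eps = settings.step_size_grid[0]
            warnings_list.append(
                "no step size reached the target acceptance; using the smallest"
            )

    samples_phi, acc, div = run_chain(
        phi0, eps, settings.leapfrog_steps, settings.burn_in, settings.n_samples,
        settings.thin, ux1, ux2, id1, id2, y, Y, grid_mode, pa, pb, JITTER, main_seed,
    )
    if div > 0.05:
        warnings_list.append(f"divergent trajectories: {div:.1%}")
    return HyperparameterPosterior(
        samples=_phi_to_theta(samples_phi),
        acceptance_rate=float(acc),
        step_size_used=float(eps),
        divergence_rate=float(div),
        warnings=warnings_list,
    )


def fit_map(
    data: DoseResponseData,
    priors: PriorSpec,
    n_starts: int = 4,
) -> Hyperparameters:
    """Posterior mode by multi-start L-BFGS-B in log-space; deterministic."""
    ux1, ux2, id1, id2, y, Y, grid_mode, pa, pb = _chain_inputs(data, priors)

    def objective(phi):
        if grid_mode:
            lp, grad = lp_and_grad_grid(phi, ux1, ux2, Y, pa, pb, JITTER)
        else:
            lp, grad = lp_and_grad(phi, ux1, ux2, id1, id2, y, pa, pb, JITTER)
        if not np.isfinite(lp):
            return 1e12, np.zeros(4)
        return -lp, -grad

    base = _start_phi(priors)
    offsets = [np.zeros(4)]
    rng = np.random.default_rng(0)
    for _ in range(n_starts - 1):
        offsets.append(rng.normal(scale=1.0, size=4))
    best = None
    for off in offsets:
        res = minimize(objective, base + off, jac=True, method="L-BFGS-B")
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError("MAP optimization failed on all starts")
    return Hyperparameters.from_array(_phi_to_theta(best.x)[0])
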