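"""Hand-principle null reference surface.

The Hand model is the infinitesimal version of Loewe additivity: the two
doses are split into small partitions that are applied alternately, each
step moving along the corresponding monotherapy curve from the current
effect level.  In the limit of many partitions the construction satisfies
the sham-combination principle, commutativity and associativity.  Here the
monotherapy curves are dense grid slices of the fitted GP surface, inverted
numerically by monotone linear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import PredictionGrid

__all__ = [
    "MonotherapyCurve",
    "HandNullSurface",
    "invert_curve",
    "choose_partitions",
    "hand_construct",
    "hand_null_surface",
]

SHARED_START_TOL = 0.01  # fraction of effect range


@dataclass(frozen=True)
class MonotherapyCurve:
    """Dense monotherapy curve with the invertible branch used by Hand steps.

    GP posterior mean slices are often mildly non-monotone (wiggles near
    dose 0, upturns at the top of the dose range), so the inversion table is
    the sequence of *record extrema* of the curve in its dominant direction:
    the strictly monotone envelope through the running minima (inhibitory)
    or maxima (stimulatory).  Bumps are bridged by interpolation between
    records; effects or doses beyond the last record clamp there and are
    flagged.  ``monotone_segment`` reports the index range from dose 0 to
    the last record.
    """

    doses: np.ndarray
    effects: np.ndarray
    monotone_segment: tuple[int, int] = field(init=False)

    def __post_init__(self) -> None:
        d = np.asarray(self.doses, dtype=float).ravel()
        e = np.asarray(self.effects, dtype=float).ravel()
        if d.size != e.size or d.size < 2:
            raise ValueError("doses and effects must be equal-length, size >= 2")
        if not (np.diff(d) > 0).all():
            raise ValueError("doses must be strictly increasing")
        if not np.isfinite(e).all():
            raise ValueError("non-finite effects")
        object.__setattr__(self, "doses", d)
        object.__setattr__(self, "effects", e)

        dev = e - e[0]
        decreasing = -dev.min() >= dev.max()
        s = e if decreasing else -e
        keep = [0]
        for i in range(1, s.size):
            if s[i] < s[keep[-1]]:
                keep.append(i)
        if len(keep) < 2:
            raise ValueError(
                "non-invertible monotherapy: no monotone segment from dose 0"
            )
        idx = np.asarray(keep)
        object.__setattr__(self, "_inv_doses", d[idx])
        object.__setattr__(self, "_inv_effects", e[idx])
        object.__setattr__(self, "_decreasing", decreasing)
        object.__setattr__(self, "monotone_segment", (0, int(idx[-1])))

    @property
    def start_effect(self) -> float:
        return float(self.effects[0])

    def __call__(self, dose) -> np.ndarray:
        """Forward evaluation f(dose) by linear interpolation (clamped)."""
        return np.interp(dose, self.doses, self.effects)

    def inverse(self, effect) -> tuple[np.ndarray, np.ndarray]:
        """Inverse dose f^-1(effect) on the monotone envelope.

        Returns (dose, clamped-flag); effects outside the envelope's range
        are clamped to its nearest endpoint.
        """
        d, e = self._inv_doses, self._inv_effects
        effect = np.asarray(effect, dtype=float)
        if self._decreasing:  # flip for np.interp's increasing-xp contract
            d, e = d[::-1], e[::-1]
        clamped = (effect < e[0]) | (effect > e[-1])
        return np.interp(effect, e, d), clamped

    def advance(self, effect, delta) -> tuple[np.ndarray, np.ndarray]:
        """One Hand step: effect -> f(f^-1(effect) + delta).

        Both inversion and forward evaluation stay on the monotone envelope;
        doses walking past its end clamp there (flagged), so the
        construction never wanders onto a non-invertible branch.
        """
        dose, cl = self.inverse(effect)
        dose = dose + delta
        over = dose > self._inv_doses[-1]
        return np.interp(dose, self._inv_doses, self._inv_effects), cl | over


@dataclass(frozen=True)
class HandNullSurface:
    """Hand null reference on a prediction grid, with construction flags."""

    grid: PredictionGrid
    values: np.ndarray
    clamped: np.ndarray  # nodes where an inversion was clamped
    warnings: tuple = ()

    def __post_init__(self) -> None:
        if self.values.shape != self.grid.shape:
            raise ValueError("values shape must match the grid")


def invert_curve(curve: MonotherapyCurve, effect: float) -> float:
    """Numerical inverse dose for one effect level (clamped to the segment)."""
    dose, _ = curve.inverse(effect)
    return float(dose)


def choose_partitions(grid: PredictionGrid, x1: float, x2: float) -> tuple[int, int]:
    """Partition counts: grid points in (0, nearest grid node to x_i].

    Because design doses are snapped onto the grid, the nearest node of a
    design dose is exact and N_i is simply its axis index.  Ties between two
    neighbouring nodes break toward the lower index.
    """
    counts = []
    for axis, x in ((grid.axis1, x1), (grid.axis2, x2)):
        if x == 0:
            counts.append(0)
            continue
        dist = np.abs(axis - x)
        counts.append(int(np.argmin(dist)))  # argmin takes the first (lower) tie
    return counts[0], counts[1]


def _start_effect(f1: MonotherapyCurve, f2: MonotherapyCurve) -> tuple[float, bool]:
    e_all = np.concatenate([f1.effects, f2.effects])
    rng = max(float(e_all.max() - e_all.min()), 1e-12)
    mismatch = abs(f1.start_effect - f2.start_effect) > SHARED_START_TOL * rng
    return 0.5 * (f1.start_effect + f2.start_effect), mismatch


def hand_construct(
    f1: MonotherapyCurve,
    f2: MonotherapyCurve,
    x1: float,
    x2: float,
    N1: int,
    N2: int,
) -> float:
    """Hand effect at one dose pair by alternating partition steps.

    Runs N = max(N1, N2) rounds; each round applies a drug-1 step of size
    x1/N then a drug-2 step of size x2/N, every step mapping
    E -> f_i(f_i^-1(E) + step).  The result is the average of the
    drug-1-first and drug-2-first passes: alternation alone carries an
    O(1/N) ordering bias, and symmetrizing both makes the construction
    exactly commutative under drug swap and cancels the leading error term.
    """
    e0, _ = _start_effect(f1, f2)
    N = max(int(N1), int(N2))
    if N == 0 or (x1 == 0 and x2 == 0):
        return e0
    forward = _alternate(f1, f2, x1 / N, x2 / N, N, e0)
    backward = _alternate(f2, f1, x2 / N, x1 / N, N, e0)
    return 0.5 * (forward + backward)


def _alternate(fa: MonotherapyCurve, fb: MonotherapyCurve,
               da: float, db: float, N: int, e0: float) -> float:
    E = e0
    for _ in range(N):
        if da > 0:
            E = float(fa.advance(E, da)[0])
        if db > 0:
            E = float(fb.advance(E, db)[0])
    return E


def hand_null_surface(
    f1: MonotherapyCurve,
    f2: MonotherapyCurve,
    grid: PredictionGrid,
) -> HandNullSurface:
    """Hand null at every grid node (vectorized over nodes).

    Node (i, j) uses partition counts (i, j) -- the number of grid points
    between 0 and its doses -- and N = max(i, j) alternating rounds, exactly
    as the per-node construction; all nodes still in progress at round r are
    stepped together.
    """
    warnings_list = []
    e0, mismatch = _start_effect(f1, f2)
    if mismatch:
        warnings_list.append("monotherapy curves disagree at dose 0; using the average")

    n1, n2 = grid.shape
    ii, jj = np.meshgrid(np.arange(n1), np.arange(n2), indexing="ij")
    N = np.maximum(ii, jj).ravel()
    x1 = grid.axis1[ii.ravel()]
    x2 = grid.axis2[jj.ravel()]
    with np.errstate(invalid="ignore", divide="ignore"):
        step1 = np.where(N > 0, x1 / np.maximum(N, 1), 0.0)
        step2 = np.where(N > 0, x2 / np.maximum(N, 1), 0.0)

    clamped = np.zeros(x1.shape, dtype=bool)
    n_rounds = int(N.max())

    def sweep(fa, fb, stepa, stepb):
        E = np.full(x1.shape, e0)
        for r in range(1, n_rounds + 1):
            active = (N >= r) & (stepa > 0)
            if active.any():
                E[active], cl = fa.advance(E[active], stepa[active])
                clamped[active] |= cl
            active = (N >= r) & (stepb > 0)
            if active.any():
                E[active], cl = fb.advance(E[active], stepb[active])
                clamped[active] |= cl
        return E

    E = 0.5 * (sweep(f1, f2, step1, step2) + sweep(f2, f1, step2, step1))
    return HandNullSurface(
        grid,
        E.reshape(n1, n2),
        clamped.reshape(n1, n2),
        tuple(warnings_list),
    )
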