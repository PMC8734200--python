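"""Reading, validation and grid conventions for two-drug checkerboard data.

Dose-response matrices arrive either in *long* form (``dose1,dose2,response``
CSV, one row per well) or in *wide* form (a matrix whose first row and first
column hold the doses of drug 2 and drug 1 respectively).  Responses stay on
their native scale -- percent (0-100) or fraction (0-1) -- because the
Gamma priors used for inference are moment-matched to the observed effect
scale.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "ResponseScale",
    "Direction",
    "DoseResponseData",
    "PredictionGrid",
    "read_dose_response",
    "write_dose_response",
    "make_grid",
]


class ResponseScale(str, enum.Enum):
    PERCENT = "percent"
    FRACTION = "fraction"


class Direction(str, enum.Enum):
    INHIBITORY = "inhibitory"
    STIMULATORY = "stimulatory"


@dataclass(frozen=True)
class DoseResponseData:
    """Observed (dose1, dose2, response) triples for one drug pair.

    Replicate wells are kept as separate points.  Validation requires
    monotherapy rows for both drugs (some point with ``dose1 == 0`` and some
    with ``dose2 == 0``) because the Hand null reference is built from the
    monotherapy slices.
    """

    dose1: np.ndarray
    dose2: np.ndarray
    response: np.ndarray
    drug1_name: str = "drug1"
    drug2_name: str = "drug2"
    dose_unit: str = ""
    response_scale: ResponseScale = ResponseScale.PERCENT
    direction: Direction = Direction.INHIBITORY

    def __post_init__(self) -> None:
        d1 = np.asarray(self.dose1, dtype=float).ravel()
        d2 = np.asarray(self.dose2, dtype=float).ravel()
        y = np.asarray(self.response, dtype=float).ravel()
        if not (d1.size == d2.size == y.size):
            raise ValueError("dose1, dose2 and response must have equal length")
        if d1.size == 0:
            raise ValueError("empty data set")
        if not (np.isfinite(d1).all() and np.isfinite(d2).all() and np.isfinite(y).all()):
            raise ValueError("non-finite dose or response values")
        if (d1 < 0).any() or (d2 < 0).any():
            raise ValueError("negative dose")
        if not (d1 == 0).any() or not (d2 == 0).any():
            raise ValueError("no monotherapy data")
        object.__setattr__(self, "dose1", d1)
        object.__setattr__(self, "dose2", d2)
        object.__setattr__(self, "response", y)
        if not isinstance(self.response_scale, ResponseScale):
            object.__setattr__(self, "response_scale", ResponseScale(self.response_scale))
        if not isinstance(self.direction, Direction):
            object.__setattr__(self, "direction", Direction(self.direction))

    @property
    def n_points(self) -> int:
        return int(self.dose1.size)

    @property
    def X(self) -> np.ndarray:
        """Design matrix of dose pairs, shape (n, 2)."""
        return np.column_stack([self.dose1, self.dose2])

    @property
    def y(self) -> np.ndarray:
        return self.response

    def unique_doses(self, axis: int) -> np.ndarray:
        d = self.dose1 if axis == 1 else self.dose2
        return np.unique(d)

    def max_dose(self, axis: int) -> float:
        return float(self.unique_doses(axis)[-1])

    def monotherapy(self, axis: int) -> tuple[np.ndarray, np.ndarray]:
        """Doses and responses where the *other* drug is at dose 0."""
        other = self.dose2 if axis == 1 else self.dose1
        mask = other == 0
        d = (self.dose1 if axis == 1 else self.dose2)[mask]
        order = np.argsort(d, kind="stable")
        return d[order], self.response[mask][order]

    def effect_range(self) -> float:
        return float(self.response.max() - self.response.min())

    def swap_drugs(self) -> "DoseResponseData":
        return replace(
            self,
            dose1=self.dose2,
            dose2=self.dose1,
            drug1_name=self.drug2_name,
            drug2_name=self.drug1_name,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"dose1": self.dose1, "dose2": self.dose2, "response": self.response}
        )


@dataclass(frozen=True)
class PredictionGrid:
    """Dense prediction grid; both axes start at 0 and include the design doses.

    ``spacing='natural-log1p'`` places the nodes uniformly in
    u = log(1 + x/l), the same warped coordinate the logarithmic kernel
    operates in, so the Hand inversion sees roughly uniform resolution in
    effect space.
    """

    axis1: np.ndarray
    axis2: np.ndarray
    spacing: str = "natural-log1p"

    def __post_init__(self) -> None:
        for name in ("axis1", "axis2"):
            a = np.asarray(getattr(self, name), dtype=float).ravel()
            if a.size < 2:
                raise ValueError("grid axis needs at least 2 points")
            if a[0] != 0:
                raise ValueError("grid axis must start at 0")
            if not (np.diff(a) > 0).all():
                raise ValueError("grid axis must be strictly increasing")
            object.__setattr__(self, name, a)

    @property
    def shape(self) -> tuple[int, int]:
        return self.axis1.size, self.axis2.size

    def nodes(self) -> np.ndarray:
        """All (x1, x2) pairs, shape (n1*n2, 2), axis-2 fastest."""
        g1, g2 = np.meshgrid(self.axis1, self.axis2, indexing="ij")
        return np.column_stack([g1.ravel(), g2.ravel()])


def _log1p_axis(max_dose: float, n: int, lengthscale: float) -> np.ndarray:
    u_max = np.log1p(max_dose / lengthscale)
    u = np.linspace(0.0, u_max, n)
    x = lengthscale * np.expm1(u)
    x[0], x[-1] = 0.0, max_dose
    return x


def _snap(axis: np.ndarray, design: np.ndarray) -> np.ndarray:
    axis = axis.copy()
    for d in design:
        axis[np.argmin(np.abs(axis - d))] = d
    axis = np.unique(axis)
    return axis


def make_grid(
    data: DoseResponseData,
    n_per_axis: int = 101,
    lengthscales: tuple[float, float] | None = None,
    spacing: str = "natural-log1p",
) -> PredictionGrid:
    """Build the prediction grid spanning [0, max dose] on each axis.

    Every distinct design dose is snapped onto the grid (the nearest grid
    node is replaced by the exact design dose) so that observed points always
    have an exact prediction node and Hand partition counts are well defined.
    """
    if n_per_axis < 2:
        raise ValueError("n_per_axis must be >= 2")
    axes = []
    for axis_no in (1, 2):
        design = data.unique_doses(axis_no)
        if n_per_axis < design.size:
            raise ValueError("n_per_axis smaller than the number of design doses")
        dmax = float(design[-1])
        if dmax <= 0:
            raise ValueError("zero dose range")
        if spacing == "natural-log1p":
            l = 1.0 if lengthscales is None else float(lengthscales[axis_no - 1])
            ax = _log1p_axis(dmax, n_per_axis, l)
        elif spacing == "linear":
            ax = np.linspace(0.0, dmax, n_per_axis)
        else:
            raise ValueError(f"unknown spacing {spacing!r}")
        axes.append(_snap(ax, design))
    return PredictionGrid(axes[0], axes[1], spacing=spacing)


def _read_long(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    required = {"dose1", "dose2", "response"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"long CSV missing columns: {sorted(missing)}")
    for col in ("dose1", "dose2", "response"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.nonzero(vals.isna().to_numpy() & df[col].notna().to_numpy())[0]
        if bad.size or vals.isna().any():
            row = int(bad[0]) if bad.size else int(np.nonzero(vals.isna().to_numpy())[0][0])
            raise ValueError(f"non-numeric or missing value in column {col!r}, row {row}")
        df[col] = vals
    return (
        df["dose1"].to_numpy(float),
        df["dose2"].to_numpy(float),
        df["response"].to_numpy(float),
    )


def _read_wide(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    # rows = drug-1 doses (first column), columns = drug-2 doses (header row)
    arr = df.to_numpy()
    try:
        col_doses = np.asarray(df.columns[1:], dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError("wide CSV header must hold drug-2 doses") from exc
    try:
        row_doses = np.asarray(arr[:, 0], dtype=float)
        body = np.asarray(arr[:, 1:], dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError("non-numeric cell in wide matrix") from exc
    d1, d2 = np.meshgrid(row_doses, col_doses, indexing="ij")
    return d1.ravel(), d2.ravel(), body.ravel()


def read_dose_response(
    path,
    dialect: str = "long",
    response_scale: ResponseScale | str = ResponseScale.PERCENT,
    direction: Direction | str = Direction.INHIBITORY,
    drug1_name: str = "drug1",
    drug2_name: str = "drug2",
    dose_unit: str = "",
) -> DoseResponseData:
    """Read a checkerboard dose-response CSV.

    ``dialect='long'`` expects columns ``dose1,dose2,response`` (replicates
    allowed, one row each).  ``dialect='wide'`` expects a matrix whose header
    row holds the drug-2 doses and whose first column holds the drug-1 doses.
    """
    if dialect == "long":
        df = pd.read_csv(path)
        d1, d2, y = _read_long(df)
    elif dialect == "wide":
        df = pd.read_csv(path)
        d1, d2, y = _read_wide(df)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return DoseResponseData(
        d1,
        d2,
        y,
        drug1_name=drug1_name,
        drug2_name=drug2_name,
        dose_unit=dose_unit,
        response_scale=ResponseScale(response_scale),
        direction=Direction(direction),
    )


def write_dose_response(data: DoseResponseData, path) -> None:
    """Write long-format CSV (``dose1,dose2,response``)."""
    data.to_frame().to_csv(path, index=False)
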