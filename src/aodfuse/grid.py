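"""Regular lat/lon analysis grid and daily gridded AOD fields.

The analysis grid is a rectangular lat/lon domain divided into square
cells of ``cell_size`` degrees.  Cells are half-open intervals
``[edge, edge + cell_size)`` in both axes, so every point inside the
domain belongs to exactly one cell and points on the maximum boundary
fall outside.  Row 0 is the southernmost row (smallest latitude),
column 0 the westernmost column.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GridSpec",
    "DailyGridField",
    "BEIJING_GRID",
    "MISSING",
    "RETRIEVED",
    "FILLED",
    "FLAG_NAMES",
    "FLAG_CODES",
]

# source_flag codes for DailyGridField
MISSING: int = 0
RETRIEVED: int = 1
FILLED: int = 2
FLAG_NAMES = {MISSING: "missing", RETRIEVED: "retrieved", FILLED: "filled"}
FLAG_CODES = {v: k for k, v in FLAG_NAMES.items()}

#: tolerance on (extent / cell_size) being integral
_INTEGRAL_TOL = 1e-6


@dataclass(frozen=True)
class GridSpec:
    """Rectangular lat/lon domain with a fixed cell size in degrees."""

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    cell_size: float

    def __post_init__(self) -> None:
        if not (self.lon_max > self.lon_min and self.lat_max > self.lat_min):
            raise ValueError("grid extent must be positive in both axes")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        for lo, hi, axis in (
            (self.lon_min, self.lon_max, "lon"),
            (self.lat_min, self.lat_max, "lat"),
        ):
            n = (hi - lo) / self.cell_size
            if abs(n - round(n)) > _INTEGRAL_TOL * max(1.0, n):
                raise ValueError(
                    f"{axis} extent {hi - lo} is not an integral number of "
                    f"cells of size {self.cell_size}"
                )

    @property
    def n_rows(self) -> int:
        return round((self.lat_max - self.lat_min) / self.cell_size)

    @property
    def n_cols(self) -> int:
        return round((self.lon_max - self.lon_min) / self.cell_size)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def contains(self, lat: float, lon: float) -> bool:
        """Half-open membership: max-edge points are outside."""
        return (
            self.lat_min <= lat < self.lat_max
            and self.lon_min <= lon < self.lon_max
        )

    def cell_of(self, lat: float, lon: float) -> tuple[int, int] | None:
        """(row, col) of the cell containing the point, or None if outside."""
        if not (math.isfinite(lat) and math.isfinite(lon)):
            raise ValueError("lat/lon must be finite")
        if not self.contains(lat, lon):
            return None
        row = int((lat - self.lat_min) / self.cell_size)
        col = int((lon - self.lon_min) / self.cell_size)
        # guard against float round-off at interior edges
        row = min(row, self.n_rows - 1)
        col = min(col, self.n_cols - 1)
        return row, col

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lat, lon) of the center of cell (row, col)."""
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise IndexError(f"cell ({row}, {col}) outside grid {self.shape}")
        lat = self.lat_min + (row + 0.5) * self.cell_size
        lon = self.lon_min + (col + 0.5) * self.cell_size
        return lat, lon

    def to_dict(self) -> dict:
        return {
            "lon_min": self.lon_min,
            "lon_max": self.lon_max,
            "lat_min": self.lat_min,
            "lat_max": self.lat_max,
            "cell_size": self.cell_size,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(**{k: float(d[k]) for k in
                      ("lon_min", "lon_max", "lat_min", "lat_max", "cell_size")})


#: the 0.1-degree Beijing-area analysis grid (115.2-117.6 E, 39.4-41.2 N)
BEIJING_GRID = GridSpec(115.2, 117.6, 39.4, 41.2, 0.1)


@dataclass
class DailyGridField:
    """One day's gridded AOD with an explicit missingness mask.

    ``values`` is a (n_rows, n_cols) float array with NaN marking missing
    cells; ``flags`` is an int8 array of the same shape taking the codes
    MISSING / RETRIEVED / FILLED.  A value is present iff its flag is not
    MISSING, and all present values are non-negative.
    """

    date: object  # datetime.date or any hashable day label
    values: np.ndarray
    flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.flags is None:
            self.flags = np.where(np.isnan(self.values), MISSING, RETRIEVED).astype(np.int8)
        else:
            self.flags = np.asarray(self.flags, dtype=np.int8)
        if self.values.shape != self.flags.shape or self.values.ndim != 2:
            raise ValueError("values and flags must be 2-D arrays of equal shape")
        self.validate()

    def validate(self) -> None:
        present = self.flags != MISSING
        if np.any(np.isnan(self.values[present])):
            raise ValueError("non-missing flag over NaN value")
        if np.any(~np.isnan(self.values[~present])):
            raise ValueError("missing flag over finite value")
        if np.any(self.values[present] < 0):
            raise ValueError("present AOD values must be non-negative")

    @property
    def present(self) -> np.ndarray:
        """Boolean mask of cells with a value (retrieved or filled)."""
        return self.flags != MISSING

    @property
    def retrieved(self) -> np.ndarray:
        return self.flags == RETRIEVED

    @property
    def filled(self) -> np.ndarray:
        return self.flags == FILLED

    def copy(self) -> "DailyGridField":
        return DailyGridField(self.date, self.values.copy(), self.flags.copy())

    @classmethod
    def all_missing(cls, date, shape: tuple[int, int]) -> "DailyGridField":
        return cls(date, np.full(shape, np.nan),
                   np.full(shape, MISSING, dtype=np.int8))
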