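"""Core containers shared across the package.

Mid-infrared spectra are stored on a common wavenumber grid in the
conventional descending orientation (high wavenumber first, 4000 -> 650
cm^-1), matching how IR spectra are plotted.  Compositions are plain
pandas DataFrames (percent w/w per constituent), and band-assignment
tables are DataFrames with one row per literature band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: The four wood constituents quantified by wet chemistry and modelled here.
CONSTITUENTS: tuple[str, ...] = ("extractives", "lignin", "cellulose", "hemicellulose")

#: Mid-IR acquisition range (cm^-1) used throughout as the valid band window.
GRID_HIGH_DEFAULT = 4000.0
GRID_LOW_DEFAULT = 650.0
GRID_STEP_DEFAULT = 2.0


class WoodFTIRError(Exception):
    """Base class for package errors."""


class ConfigError(WoodFTIRError, ValueError):
    """Invalid configuration (ranges, seeds, component counts...)."""


class FormatError(WoodFTIRError, ValueError):
    """Malformed input file or container."""


class GridMismatchError(WoodFTIRError, ValueError):
    """Spectra supplied on a grid a model was not fitted on."""


@dataclass(frozen=True)
class WavenumberGrid:
    """A uniform, strictly descending wavenumber axis in cm^-1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 1:
            raise FormatError("wavenumber grid needs at least one point")
        d = np.diff(v)
        if d.size:
            if not np.all(d < 0):
                raise FormatError("wavenumber grid must be strictly descending")
            if not np.allclose(d, d[0], rtol=1e-6, atol=1e-9):
                bad = int(np.argmax(~np.isclose(d, d[0], rtol=1e-6, atol=1e-9))) + 1
                raise FormatError(f"non-uniform grid spacing at row {bad} (value {v[bad]})")
        object.__setattr__(self, "values", v)

    @classmethod
    def default(
        cls,
        high: float = GRID_HIGH_DEFAULT,
        low: float = GRID_LOW_DEFAULT,
        step: float = GRID_STEP_DEFAULT,
    ) -> "WavenumberGrid":
        """The default acquisition grid: 4000 -> 650 cm^-1 in 2 cm^-1 steps."""
        n = int(round((high - low) / step)) + 1
        return cls(high - step * np.arange(n))

    @property
    def spacing(self) -> float:
        """Positive grid step in cm^-1."""
        if len(self.values) < 2:
            raise FormatError("spacing undefined for a single-point grid")
        return float(self.values[0] - self.values[1])

    def __len__(self) -> int:
        return self.values.size

    def window_mask(self, low: float, high: float) -> np.ndarray:
        """Boolean mask of points v with low <= v <= high (closed interval)."""
        if low >= high:
            raise ConfigError(f"window low ({low}) must be below high ({high})")
        return (self.values >= low) & (self.values <= high)


@dataclass
class SpectraSet:
    """Absorbance matrix (samples x grid points) on a shared grid."""

    grid: WavenumberGrid
    absorbance: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        a = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        if a.shape[1] != len(self.grid):
            raise FormatError(
                f"absorbance has {a.shape[1]} columns but the grid has {len(self.grid)} points"
            )
        if not np.all(np.isfinite(a)):
            raise FormatError("absorbance contains missing or non-finite values")
        ids = [str(s) for s in self.sample_ids]
        if len(ids) != a.shape[0]:
            raise FormatError(
                f"{len(ids)} sample ids for {a.shape[0]} spectra"
            )
        if len(set(ids)) != len(ids):
            raise FormatError("duplicated sample id")
        self.absorbance = a
        self.sample_ids = ids

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    def subset(self, indices: Sequence[int]) -> "SpectraSet":
        idx = list(indices)
        return SpectraSet(
            self.grid,
            self.absorbance[idx, :],
            [self.sample_ids[i] for i in idx],
        )


def validate_composition(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a composition table (index: sample id, columns: constituents).

    Values are percent w/w; every value must lie in [0, 100] and the
    constituent names must come from the fixed vocabulary.
    """
    unknown = [c for c in table.columns if c not in CONSTITUENTS]
    if unknown:
        raise FormatError(
            f"unknown constituent(s) {unknown}; expected names from {list(CONSTITUENTS)}"
        )
    if table.index.has_duplicates:
        raise FormatError("duplicated sample id in composition table")
    vals = table.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise FormatError("composition table contains missing values")
    bad = np.where((vals < 0) | (vals > 100))
    if bad[0].size:
        rid = table.index[bad[0][0]]
        raise FormatError(f"composition out of [0, 100] for sample {rid!r}")
    return table


def validate_band_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a band-assignment table (constituent, center_cm1, ...)."""
    required = {"constituent", "center_cm1"}
    missing = required - set(table.columns)
    if missing:
        raise FormatError(f"band table missing column(s) {sorted(missing)}")
    unknown = sorted(set(table["constituent"]) - set(CONSTITUENTS))
    if unknown:
        raise FormatError(
            f"unknown constituent(s) {unknown}; expected names from {list(CONSTITUENTS)}"
        )
    centers = table["center_cm1"].to_numpy(dtype=float)
    out = (centers < GRID_LOW_DEFAULT) | (centers > GRID_HIGH_DEFAULT)
    if out.any():
        bad = centers[out][0]
        raise FormatError(
            f"band center {bad} cm^-1 outside [{GRID_LOW_DEFAULT}, {GRID_HIGH_DEFAULT}]"
        )
    if "width_cm1" in table.columns and (table["width_cm1"].to_numpy(dtype=float) <= 0).any():
        raise FormatError("band width must be positive")
    if "amplitude" in table.columns and (table["amplitude"].to_numpy(dtype=float) < 0).any():
        raise FormatError("band amplitude must be non-negative")
    return table
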