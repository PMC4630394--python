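"""Spectral pretreatment: window selection, first derivative, centering.

The two pretreatments used for calibration are a per-constituent
wavenumber window and a Savitzky-Golay first derivative, which removes
additive baseline offsets (and attenuates slow drift) before modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .core import ConfigError, SpectraSet

__all__ = [
    "PreprocessSpec",
    "select_window",
    "first_derivative",
    "mean_center",
    "CenteringRecord",
    "apply_preprocess",
    "DEFAULT_WINDOWS",
]

#: Default per-constituent modelling windows (low, high) in cm^-1.
DEFAULT_WINDOWS: dict[str, tuple[float, float]] = {
    "extractives": (1250.0, 1750.0),
    "lignin": (800.0, 1800.0),
    "cellulose": (1000.0, 1500.0),
    "hemicellulose": (800.0, 1750.0),
}


@dataclass(frozen=True)
class PreprocessSpec:
    """Pretreatment recipe: mode (raw | first_derivative), SG settings, window.

    ``window_first`` controls whether the wavenumber window is cut before
    the derivative is taken (default) or after; the difference is only at
    the window edges.
    """

    mode: str = "raw"
    sg_window: int = 9
    sg_polyorder: int = 2
    window: tuple[float, float] | None = None
    window_first: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("raw", "first_derivative"):
            raise ConfigError(f"unknown preprocessing mode {self.mode!r}")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ConfigError(
                f"sg_window must be odd and > sg_polyorder, got "
                f"({self.sg_window}, {self.sg_polyorder})"
            )
        if self.window is not None and self.window[0] >= self.window[1]:
            raise ConfigError(f"window low must be below high, got {self.window}")


def select_window(spectra: SpectraSet, low: float, high: float) -> SpectraSet:
    """Keep exactly the grid points v with low <= v <= high (closed interval)."""
    mask = spectra.grid.window_mask(low, high)
    if not mask.any():
        raise ConfigError(
            f"window [{low}, {high}] does not overlap the grid "
            f"[{spectra.grid.values[-1]}, {spectra.grid.values[0]}]"
        )
    from .core import WavenumberGrid

    return SpectraSet(
        WavenumberGrid(spectra.grid.values[mask]),
        spectra.absorbance[:, mask],
        spectra.sample_ids,
    )


def first_derivative(
    spectra: SpectraSet, sg_window: int = 9, sg_polyorder: int = 2
) -> SpectraSet:
    """Savitzky-Golay first derivative of absorbance w.r.t. wavenumber.

    The derivative is taken with respect to *increasing* wavenumber
    regardless of the descending storage order; output is on the same
    grid (polynomial-fit edge handling, so edge points are approximate).
    """
    if sg_window > len(spectra.grid):
        raise ConfigError(
            f"sg_window ({sg_window}) exceeds grid length ({len(spectra.grid)})"
        )
    if sg_window % 2 == 0 or sg_window <= sg_polyorder:
        raise ConfigError("sg_window must be odd and > sg_polyorder")
    # compute on the ascending-ordered axis, then restore descending order
    asc = spectra.absorbance[:, ::-1]
    d = savgol_filter(
        asc, sg_window, sg_polyorder, deriv=1, delta=spectra.grid.spacing, axis=1
    )
    return SpectraSet(spectra.grid, d[:, ::-1], spectra.sample_ids)


@dataclass(frozen=True)
class CenteringRecord:
    """Stored column means; lets predictions and inverse transforms reuse them."""

    mean: np.ndarray = field(repr=False)

    def apply(self, data: np.ndarray) -> np.ndarray:
        return np.asarray(data, dtype=float) - self.mean

    def restore(self, centered: np.ndarray) -> np.ndarray:
        return np.asarray(centered, dtype=float) + self.mean


def mean_center(
    train: np.ndarray, apply_to: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None, CenteringRecord]:
    """Subtract training column means from train (and optionally apply_to)."""
    train = np.asarray(train, dtype=float)
    if train.size == 0:
        raise ConfigError("cannot center an empty training set")
    mean = train.mean(axis=0)
    record = CenteringRecord(mean)
    return record.apply(train), (None if apply_to is None else record.apply(apply_to)), record


def apply_preprocess(spectra: SpectraSet, spec: PreprocessSpec) -> SpectraSet:
    """Apply a full PreprocessSpec (window and/or derivative) to a SpectraSet."""
    out = spectra
    steps = ["window", "derivative"] if spec.window_first else ["derivative", "window"]
    for step in steps:
        if step == "window" and spec.window is not None:
            out = select_window(out, *spec.window)
        elif step == "derivative" and spec.mode == "first_derivative":
            out = first_derivative(out, spec.sg_window, spec.sg_polyorder)
    return out
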