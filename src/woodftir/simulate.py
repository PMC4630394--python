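"""Synthetic FT-IR dataset generator with known ground-truth band structure.

Real mid-IR spectra of milled hardwood are, to first order, composition-
weighted superpositions of vibrational bands of the cell-wall polymers
(cellulose, hemicellulose, lignin) and of the extractives, riding on a
slowly varying baseline with instrument noise.  The generator emulates a
small hardwood calibration set (default 37 samples) in exactly those
terms:

    A(v) = baseline(v) + sum_c (pct_c / 100) * sum_{bands of c}
               amplitude * exp(-(v - center)^2 / (2 sigma^2)) + noise(v)

Band centers come from the shipped literature assignment table, so every
downstream stage (calibration, loading-peak extraction, residual
statistics) can be tested against a known ground truth.  The generator is
deliberately idealised: it makes no attempt at ATR optics, band-shape
asymmetry, or real hardwood variability.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .core import (
    CONSTITUENTS,
    ConfigError,
    SpectraSet,
    WavenumberGrid,
    validate_band_table,
)

__all__ = [
    "BandSpec",
    "GeneratorConfig",
    "default_band_table",
    "sample_compositions",
    "render_spectrum",
    "generate_dataset",
    "DEFAULT_COMPOSITION_RANGES",
]

#: Default Gaussian sigma (cm^-1) for synthetic bands.
DEFAULT_BAND_WIDTH = 12.0

#: Plausible hardwood composition ranges, percent w/w (generator defaults,
#: not literature claims): the remainder to 100% is ash and unresolved mass.
DEFAULT_COMPOSITION_RANGES: dict[str, tuple[float, float]] = {
    "extractives": (1.0, 8.0),
    "lignin": (18.0, 30.0),
    "cellulose": (38.0, 52.0),
    "hemicellulose": (18.0, 32.0),
}


@dataclass(frozen=True)
class BandSpec:
    """One synthetic Gaussian band belonging to a constituent.

    amplitude is in absorbance units per unit mass fraction, i.e. a pure
    (100%) constituent contributes `amplitude` at the band center.
    """

    constituent: str
    center: float
    width: float = DEFAULT_BAND_WIDTH
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ConfigError(f"band width must be > 0, got {self.width}")
        if self.amplitude < 0:
            raise ConfigError(f"band amplitude must be >= 0, got {self.amplitude}")


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything needed to draw one reproducible synthetic dataset.

    Parameters
    ----------
    n_samples:
        Number of samples (>= 8); the default mirrors a 37-sample
        hardwood calibration study.
    seed:
        Master seed; all randomness (compositions, baselines, noise)
        derives from it through independent substreams.
    composition_ranges:
        Per-constituent (min%, max%) uniform sampling ranges.
    baseline:
        (intercept_max, slope_max).  Each sample gets an additive linear
        baseline  b0 + b1 * (v - grid_low)  with  b0 ~ U(0, intercept_max)
        and  b1 ~ U(-slope_max, +slope_max)  (absorbance per cm^-1),
        emulating the drift that first-derivative pretreatment removes.
    noise_sd:
        Standard deviation of iid Gaussian absorbance noise.
    bands:
        Band table; None means the shipped literature table with default
        width and amplitude.
    """

    n_samples: int = 37
    seed: int = 0
    composition_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITION_RANGES)
    )
    baseline: tuple[float, float] = (0.05, 2e-5)
    noise_sd: float = 0.005
    bands: tuple[BandSpec, ...] | None = None
    grid_high: float = 4000.0
    grid_low: float = 650.0
    grid_step: float = 2.0
    max_attempts: int = 1000

    def __post_init__(self) -> None:
        if self.n_samples < 8:
            raise ConfigError(f"n_samples must be >= 8, got {self.n_samples}")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        for name, (lo, hi) in self.composition_ranges.items():
            if name not in CONSTITUENTS:
                raise ConfigError(
                    f"unknown constituent {name!r}; expected names from {list(CONSTITUENTS)}"
                )
            if not (0 <= lo <= hi <= 100):
                raise ConfigError(f"bad range for {name}: ({lo}, {hi})")
            if lo > hi:
                raise ConfigError(f"range min > max for {name}")

    def grid(self) -> WavenumberGrid:
        return WavenumberGrid.default(self.grid_high, self.grid_low, self.grid_step)

    def band_specs(self) -> tuple[BandSpec, ...]:
        if self.bands is not None:
            return self.bands
        return _bands_from_table(default_band_table())

    def with_(self, **kwargs) -> "GeneratorConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def default_band_table() -> pd.DataFrame:
    """The shipped literature band-assignment table.

    Columns: constituent, center_cm1, functional_group, literature_ref.
    Centers are the mid-IR assignments commonly used for extractives,
    lignin, cellulose and hemicellulose; overlapping assignments (e.g.
    the 1510 cm^-1 aromatic band claimed by both extractives and lignin)
    are kept, as they are genuinely shared in wood spectra.  Assignments
    quoted in the literature as a range (e.g. 1047-1004 cm^-1) are stored
    as two rows, one per endpoint.
    """
    path = importlib.resources.files("woodftir.data") / "band_assignments.tsv"
    with importlib.resources.as_file(path) as p:
        table = pd.read_csv(p, sep="\t")
    return validate_band_table(table)


def _bands_from_table(table: pd.DataFrame) -> tuple[BandSpec, ...]:
    widths = table["width_cm1"] if "width_cm1" in table.columns else None
    amps = table["amplitude"] if "amplitude" in table.columns else None
    specs = []
    for i, row in table.reset_index(drop=True).iterrows():
        specs.append(
            BandSpec(
                constituent=row["constituent"],
                center=float(row["center_cm1"]),
                width=float(widths.iloc[i]) if widths is not None else DEFAULT_BAND_WIDTH,
                amplitude=float(amps.iloc[i]) if amps is not None else 1.0,
            )
        )
    return tuple(specs)


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    """Independent named RNG streams derived from one master seed.

    Fixed stage indices keep each stream stable when stages are added.
    """
    return {
        name: np.random.default_rng(np.random.SeedSequence([seed, idx]))
        for idx, name in enumerate(["compositions", "baseline", "noise"])
    }


def sample_compositions(config: GeneratorConfig) -> pd.DataFrame:
    """Draw a composition table (percent w/w) from the configured ranges.

    Each constituent is uniform on its range; rows whose constituent sum
    exceeds 100% are rejected and redrawn (bounded attempts).  The result
    is deterministic for a fixed seed.
    """
    rng = _substreams(config.seed)["compositions"]
    return _sample_compositions_rng(config, rng)


def _sample_compositions_rng(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    names = [c for c in CONSTITUENTS if c in config.composition_ranges]
    los = np.array([config.composition_ranges[c][0] for c in names])
    his = np.array([config.composition_ranges[c][1] for c in names])
    rows = []
    for _ in range(config.n_samples):
        for _attempt in range(config.max_attempts):
            draw = los + (his - los) * rng.random(len(names))
            if draw.sum() <= 100.0:
                rows.append(draw)
                break
        else:
            raise ConfigError(
                f"could not draw a composition with sum <= 100% in "
                f"{config.max_attempts} attempts; ranges {dict(config.composition_ranges)}"
            )
    ids = [f"S{i + 1:02d}" for i in range(config.n_samples)]
    return pd.DataFrame(rows, index=pd.Index(ids, name="sample_id"), columns=names)


def constituent_signatures(
    config: GeneratorConfig, grid: WavenumberGrid | None = None
) -> pd.DataFrame:
    """Pure-constituent spectra (absorbance at 100%), one column per constituent."""
    grid = grid or config.grid()
    v = grid.values
    sig = {c: np.zeros(len(grid)) for c in CONSTITUENTS}
    for band in config.band_specs():
        sig[band.constituent] += band.amplitude * np.exp(
            -((v - band.center) ** 2) / (2.0 * band.width**2)
        )
    return pd.DataFrame(sig, index=v)


def render_spectrum(
    composition: Mapping[str, float],
    config: GeneratorConfig,
    grid: WavenumberGrid | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one absorbance vector for a single composition row.

    ``composition`` maps constituent name -> percent w/w; every named
    constituent must appear in the band table.  ``rng`` drives the
    baseline and noise draws (defaults to streams derived from
    config.seed).
    """
    grid = grid or config.grid()
    known = {b.constituent for b in config.band_specs()}
    for name in composition:
        if name not in known:
            raise ConfigError(f"composition names unknown constituent {name!r}")
    if rng is None:
        streams = _substreams(config.seed)
        base_rng = streams["baseline"]
        noise_rng = streams["noise"]
    else:
        base_rng = noise_rng = rng
    sig = constituent_signatures(config, grid)
    fracs = np.array([composition.get(c, 0.0) / 100.0 for c in sig.columns])
    signal = sig.to_numpy() @ fracs
    b0 = base_rng.uniform(0.0, config.baseline[0])
    b1 = base_rng.uniform(-config.baseline[1], config.baseline[1])
    baseline = b0 + b1 * (grid.values - config.grid_low)
    noise = noise_rng.normal(0.0, config.noise_sd, size=len(grid)) if config.noise_sd > 0 else 0.0
    return signal + baseline + noise


def generate_dataset(
    config: GeneratorConfig,
) -> tuple[SpectraSet, pd.DataFrame, pd.DataFrame]:
    """Generate (spectra, compositions, band table) reproducibly from the seed.

    The returned band table is the ground truth used for rendering, which
    lets integrity-stage tests check that loading peaks recover the true
    band centers.
    """
    grid = config.grid()
    streams = _substreams(config.seed)
    comps = _sample_compositions_rng(config, streams["compositions"])
    sig = constituent_signatures(config, grid)
    frac = comps.reindex(columns=sig.columns, fill_value=0.0).to_numpy() / 100.0
    signal = frac @ sig.to_numpy().T

    n, p = config.n_samples, len(grid)
    b0 = streams["baseline"].uniform(0.0, config.baseline[0], size=n)
    b1 = streams["baseline"].uniform(-config.baseline[1], config.baseline[1], size=n)
    baseline = b0[:, None] + b1[:, None] * (grid.values - config.grid_low)[None, :]
    noise = (
        streams["noise"].normal(0.0, config.noise_sd, size=(n, p))
        if config.noise_sd > 0
        else np.zeros((n, p))
    )

    spectra = SpectraSet(grid, signal + baseline + noise, list(comps.index))
    bands = pd.DataFrame(
        [
            {
                "constituent": b.constituent,
                "center_cm1": b.center,
                "width_cm1": b.width,
                "amplitude": b.amplitude,
            }
            for b in config.band_specs()
        ]
    )
    # carry functional-group labels through when the default table is in use
    if config.bands is None:
        ref = default_band_table()
        bands = bands.merge(
            ref[["constituent", "center_cm1", "functional_group", "literature_ref"]],
            on=["constituent", "center_cm1"],
            how="left",
        )
    return spectra, comps, bands
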