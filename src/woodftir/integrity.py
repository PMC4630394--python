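"""Loading-peak integrity analysis: residuals against literature bands.

Latent-variable calibrations are routinely interpreted by reading peak
positions off the loading or regression-coefficient profile and matching
them to literature band assignments.  This module quantifies how precise
that interpretation is.  For each model, the local extrema W of the
coefficient profile are extracted and matched to the nearest literature
assignment BA_L of the modelled constituent, giving a signed residual

    R = W - BA_L            (cm^-1)

Residuals are pooled per algorithm and summarised (mean, sample variance,
SD, 95% t confidence interval).  Whether one algorithm locates peaks less
precisely than another is then a variance question,

    H0: sigma^2_PLS = sigma^2_PCR     vs.     Ha: sigma^2_PLS > sigma^2_PCR,

tested with the two-sample F ratio of residual variances; a two-sample
t-test on the mean residual checks for systematic location bias.  Twice
the residual SD gives the practical "+/- x cm^-1" interpretation band for
a model family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import find_peaks

from .core import ConfigError, WoodFTIRError

__all__ = [
    "Peak",
    "PeakSet",
    "ResidualRecord",
    "ResidualSummary",
    "VarianceTestResult",
    "extract_peaks",
    "match_bands",
    "pool_residuals",
    "summary_from_moments",
    "ci_halfwidth",
    "variance_f_test",
    "variance_f_test_from_summary",
    "mean_t_test",
    "residual_histogram",
]

DEFAULT_MIN_PROMINENCE = 0.10  # fraction of max |profile|
DEFAULT_MIN_SEPARATION = 16.0  # cm^-1
DEFAULT_MATCH_TOLERANCE = 50.0  # cm^-1


@dataclass(frozen=True)
class Peak:
    wavenumber: float  # cm^-1, sub-grid refined
    value: float  # signed profile value at the grid maximum
    prominence: float


@dataclass
class PeakSet:
    """Extracted loading peaks, sorted descending by wavenumber."""

    peaks: list[Peak]
    algorithm: str | None = None
    constituent: str | None = None
    mode: str | None = None

    def wavenumbers(self) -> np.ndarray:
        return np.array([p.wavenumber for p in self.peaks])

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass(frozen=True)
class ResidualRecord:
    """One matched (W, BA_L, R) triple; R = W - BA_L by construction."""

    W: float
    BA_L: float
    R: float
    constituent: str | None = None
    algorithm: str | None = None
    mode: str | None = None


@dataclass(frozen=True)
class ResidualSummary:
    """Pooled residual statistics in the usual summary-table layout."""

    n: int
    mean: float
    variance: float  # sample variance, n-1 denominator
    sd: float
    ci_low: float
    ci_high: float
    level: float = 0.95

    @property
    def ci_halfwidth(self) -> float:
        return (self.ci_high - self.ci_low) / 2.0

    @property
    def two_sd_band(self) -> float:
        """The +/- 2 SD practical interpretation band (cm^-1)."""
        return 2.0 * self.sd


def _parabolic_refine(values: np.ndarray, i: int) -> float:
    """Sub-grid offset (in index units, clamped to +/-0.5) of a local max."""
    if i == 0 or i == len(values) - 1:
        return 0.0
    denom = values[i - 1] - 2.0 * values[i] + values[i + 1]
    if denom == 0:
        return 0.0
    delta = 0.5 * (values[i - 1] - values[i + 1]) / denom
    return float(np.clip(delta, -0.5, 0.5))


def extract_peaks(
    profile: np.ndarray,
    wavenumbers: np.ndarray,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    min_separation: float = DEFAULT_MIN_SEPARATION,
    **tag,
) -> PeakSet:
    """Local extrema of a signed coefficient/loading profile.

    Peaks are found on |profile| so both positive and negative lobes
    count; a peak must have prominence of at least ``min_prominence``
    times max |profile| and be at least ``min_separation`` cm^-1 from a
    stronger peak.  Positions are refined by 3-point parabolic
    interpolation around the grid maximum.
    """
    profile = np.asarray(profile, dtype=float).ravel()
    wavenumbers = np.asarray(wavenumbers, dtype=float).ravel()
    if profile.size != wavenumbers.size:
        raise ConfigError("profile and wavenumber axis differ in length")
    if profile.size < 3:
        raise ConfigError("profile needs at least 3 points")
    mag = np.abs(profile)
    top = mag.max()
    if top == 0:
        return PeakSet([], **tag)
    step = abs(wavenumbers[0] - wavenumbers[1])
    distance = max(1, int(np.ceil(min_separation / step)))
    idx, props = find_peaks(mag, prominence=min_prominence * top, distance=distance)
    peaks = []
    for n, i in enumerate(idx):
        delta = _parabolic_refine(mag, int(i))
        w = wavenumbers[i] + delta * (
            wavenumbers[min(i + 1, len(wavenumbers) - 1)] - wavenumbers[i]
        )
        peaks.append(
            Peak(
                wavenumber=float(w),
                value=float(profile[i]),
                prominence=float(props["prominences"][n] / top),
            )
        )
    peaks.sort(key=lambda p: -p.wavenumber)
    return PeakSet(peaks, **tag)


def match_bands(
    peaks: PeakSet,
    bands: pd.DataFrame,
    constituent: str,
    tolerance: float = DEFAULT_MATCH_TOLERANCE,
) -> list[ResidualRecord]:
    """Greedily match extracted peaks to the constituent's assignments.

    Pairs are taken in order of ascending |W - BA_L| (ties broken toward
    the higher-wavenumber assignment); each peak and each assignment is
    used at most once, and pairs farther apart than ``tolerance`` cm^-1
    are discarded.
    """
    if tolerance <= 0:
        raise ConfigError("matching tolerance must be > 0")
    centers = bands.loc[bands["constituent"] == constituent, "center_cm1"].to_numpy(
        dtype=float
    )
    if centers.size == 0:
        raise ConfigError(f"band table has no assignments for {constituent!r}")
    W = peaks.wavenumbers()
    candidates = []
    for i, w in enumerate(W):
        for j, ba in enumerate(centers):
            r = w - ba
            if abs(r) <= tolerance:
                candidates.append((abs(r), -ba, i, j, r))
    candidates.sort()
    used_peak: set[int] = set()
    used_band: set[int] = set()
    records = []
    for _absr, _negba, i, j, r in candidates:
        if i in used_peak or j in used_band:
            continue
        used_peak.add(i)
        used_band.add(j)
        records.append(
            ResidualRecord(
                W=float(W[i]),
                BA_L=float(centers[j]),
                R=float(r),
                constituent=constituent,
                algorithm=peaks.algorithm,
                mode=peaks.mode,
            )
        )
    records.sort(key=lambda rec: -rec.W)
    return records


def _residual_values(records: Iterable[ResidualRecord] | Sequence[float]) -> np.ndarray:
    vals = [r.R if isinstance(r, ResidualRecord) else float(r) for r in records]
    return np.asarray(vals, dtype=float)


def ci_halfwidth(sd: float, n: int, level: float = 0.95) -> float:
    """Half-width of the t confidence interval for a mean: t * sd / sqrt(n)."""
    if n < 2:
        raise ConfigError("confidence interval needs n >= 2")
    if sd < 0:
        raise ConfigError("sd must be >= 0")
    tcrit = stats.t.ppf((1.0 + level) / 2.0, df=n - 1)
    return float(tcrit * sd / np.sqrt(n))


def summary_from_moments(mean: float, variance: float, n: int, level: float = 0.95) -> ResidualSummary:
    """Build a ResidualSummary from (mean, sample variance, n) alone."""
    if n < 2:
        raise ConfigError("summary needs n >= 2")
    sd = float(np.sqrt(variance))
    hw = ci_halfwidth(sd, n, level)
    return ResidualSummary(
        n=n, mean=float(mean), variance=float(variance), sd=sd,
        ci_low=float(mean) - hw, ci_high=float(mean) + hw, level=level,
    )


def pool_residuals(
    records: Iterable[ResidualRecord] | Sequence[float], level: float = 0.95
) -> ResidualSummary:
    """Pool residuals (across constituent models) into one summary."""
    vals = _residual_values(records)
    if vals.size < 2:
        raise ConfigError("pooling needs at least 2 residuals")
    return summary_from_moments(vals.mean(), vals.var(ddof=1), vals.size, level)


@dataclass(frozen=True)
class VarianceTestResult:
    """Two-sample F-test of Ha: sigma^2_PLS > sigma^2_PCR, both orientations.

    ``f_upper`` = var_PLS / var_PCR with its upper-tail p; ``f_lower`` is
    the reciprocal orientation (var_PCR / var_PLS) with the lower-tail p
    — the layout summary tables usually print.  The two p values are
    identical by symmetry of the test.
    """

    var_pls: float
    var_pcr: float
    n_pls: int
    n_pcr: int
    f_upper: float
    p_upper: float
    f_lower: float
    p_lower: float
    p_two_tailed: float
    crit_lower: float  # alpha=0.05 lower-tail critical value for f_lower
    crit_upper: float
    alpha: float = 0.05

    @property
    def df(self) -> tuple[int, int]:
        return (self.n_pls - 1, self.n_pcr - 1)

    @property
    def significant(self) -> bool:
        """Ha accepted at alpha (one-tailed)."""
        return self.p_upper < self.alpha


def variance_f_test_from_summary(
    var_pls: float, var_pcr: float, n_pls: int, n_pcr: int, alpha: float = 0.05
) -> VarianceTestResult:
    """F-test of residual variances from summary statistics alone."""
    if min(n_pls, n_pcr) < 2:
        raise ConfigError("F-test needs n >= 2 in both sets")
    if var_pls <= 0 or var_pcr <= 0:
        raise ConfigError("F-test undefined for zero variance")
    df_pls, df_pcr = int(n_pls) - 1, int(n_pcr) - 1
    f_upper = float(var_pls / var_pcr)
    p_upper = float(stats.f.sf(f_upper, df_pls, df_pcr))
    f_lower = float(var_pcr / var_pls)
    p_lower = float(stats.f.cdf(f_lower, df_pcr, df_pls))
    p_two = float(2.0 * min(p_upper, 1.0 - p_upper))
    return VarianceTestResult(
        var_pls=float(var_pls),
        var_pcr=float(var_pcr),
        n_pls=int(n_pls),
        n_pcr=int(n_pcr),
        f_upper=f_upper,
        p_upper=p_upper,
        f_lower=f_lower,
        p_lower=p_lower,
        p_two_tailed=p_two,
        crit_lower=float(stats.f.ppf(alpha, df_pcr, df_pls)),
        crit_upper=float(stats.f.isf(alpha, df_pls, df_pcr)),
        alpha=alpha,
    )


def variance_f_test(
    residuals_pls: Iterable[ResidualRecord] | Sequence[float],
    residuals_pcr: Iterable[ResidualRecord] | Sequence[float],
    alpha: float = 0.05,
) -> VarianceTestResult:
    """F-test of Ha: sigma^2_PLS > sigma^2_PCR on two residual sets."""
    a = _residual_values(residuals_pls)
    b = _residual_values(residuals_pcr)
    if min(a.size, b.size) < 2:
        raise ConfigError("F-test needs n >= 2 in both sets")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 or vb == 0:
        raise ConfigError("F-test undefined for zero variance")
    return variance_f_test_from_summary(va, vb, a.size, b.size, alpha)


def mean_t_test(
    residuals_pls: Iterable[ResidualRecord] | Sequence[float],
    residuals_pcr: Iterable[ResidualRecord] | Sequence[float],
    variant: str = "pooled",
) -> tuple[float, float, float]:
    """Two-sample t-test for a mean-location difference between models.

    Returns (t, df, two-tailed p).  ``variant`` is "pooled" (equal
    variances) or "welch".
    """
    a = _residual_values(residuals_pls)
    b = _residual_values(residuals_pcr)
    if min(a.size, b.size) < 2:
        raise ConfigError("t-test needs n >= 2 in both sets")
    if variant not in ("pooled", "welch"):
        raise ConfigError(f"unknown t-test variant {variant!r}")
    res = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return float(res.statistic), float(res.df), float(res.pvalue)


def residual_histogram(
    records: Iterable[ResidualRecord] | Sequence[float], bin_width: float = 5.0
) -> pd.DataFrame:
    """Frequency table of residuals in half-open bins (left, right].

    Bin edges sit at integer multiples of ``bin_width`` (so 0 is an
    edge); the returned table covers the contiguous range of occupied
    bins and its counts sum to n.
    """
    if bin_width <= 0:
        raise ConfigError("bin_width must be > 0")
    vals = _residual_values(records)
    if vals.size == 0:
        return pd.DataFrame(columns=["bin_left", "bin_right", "count"])
    # index i labels the bin ((i-1)w, i*w]
    idx = np.ceil(vals / bin_width).astype(int)
    lo, hi = idx.min(), idx.max()
    rows = []
    for i in range(lo, hi + 1):
        rows.append(
            {
                "bin_left": (i - 1) * bin_width,
                "bin_right": i * bin_width,
                "count": int(np.sum(idx == i)),
            }
        )
    return pd.DataFrame(rows)
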