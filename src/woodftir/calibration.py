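"""PCR and PLS1 calibration of constituent content from spectra.

Both regressions are latent-variable models fitted on mean-centered data:

* PCR — principal components of X from the SVD of the centered spectra,
  followed by least squares of y on the first k score columns;
* PLS1 — single-response partial least squares by NIPALS, deflating both
  X and y, with the regression vector assembled as b = W (P'W)^-1 q.

Diagnostics follow standard chemometric usage: r^2 (in percent, squared
Pearson correlation of fitted vs. reference on the calibration set),
RMSEC, RMSEP and RPD (validation SD / RMSEP; RPD > 4 is usually read as
quantitative-grade, 2-4 as screening-grade).  RMSEC and RMSEP use a 1/n
denominator (no degrees-of-freedom correction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import ConfigError, GridMismatchError, SpectraSet

__all__ = [
    "CalibrationModel",
    "Diagnostics",
    "SplitSpec",
    "fit_pcr",
    "fit_pls1",
    "predict",
    "split_samples",
    "cross_validate",
    "diagnostics",
    "coefficient_profile",
]


@dataclass
class CalibrationModel:
    """A fitted PCR or PLS1 model on mean-centered spectra.

    ``coef`` maps centered X to centered prediction; ``wavenumbers`` is
    the retained grid the model expects.  For PCR, ``loadings`` holds the
    principal-component loading vectors (columns); for PLS1 it holds the
    X-loadings P, with the weight vectors in ``weights``.
    """

    algorithm: str  # "pcr" | "pls1"
    n_components: int
    x_mean: np.ndarray = field(repr=False)
    y_mean: float = 0.0
    coef: np.ndarray = field(default=None, repr=False)
    wavenumbers: np.ndarray = field(default=None, repr=False)
    loadings: np.ndarray = field(default=None, repr=False)
    weights: np.ndarray | None = field(default=None, repr=False)
    scores: np.ndarray | None = field(default=None, repr=False)
    y_train: np.ndarray | None = field(default=None, repr=False)
    constituent: str | None = None
    preprocess: object | None = None


def _as_matrix(X) -> tuple[np.ndarray, np.ndarray | None]:
    """Accept a SpectraSet or plain matrix; return (matrix, wavenumbers)."""
    if isinstance(X, SpectraSet):
        return X.absorbance, X.grid.values
    return np.asarray(X, dtype=float), None


def _rank(s: np.ndarray, n: int, p: int) -> int:
    if s.size == 0 or s[0] == 0:
        return 0
    return int(np.sum(s > s[0] * max(n, p) * np.finfo(float).eps))


def fit_pcr(X, y, n_components: int, *, constituent: str | None = None) -> CalibrationModel:
    """Fit principal components regression with ``n_components`` components.

    X may be a SpectraSet or a samples-x-variables matrix; centering is
    performed internally and recorded on the model.
    """
    Xm, wn = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    x_mean = Xm.mean(axis=0)
    y_mean = float(y.mean())
    Xc, yc = Xm - x_mean, y - y_mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = _rank(s, *Xc.shape)
    if not 1 <= n_components <= rank:
        raise ConfigError(
            f"n_components={n_components} outside [1, rank={rank}] for PCR"
        )
    k = n_components
    # regression of centered y on scores T = U_k S_k
    gamma = (U[:, :k].T @ yc) / s[:k]
    coef = Vt[:k].T @ gamma
    return CalibrationModel(
        algorithm="pcr",
        n_components=k,
        x_mean=x_mean,
        y_mean=y_mean,
        coef=coef,
        wavenumbers=wn,
        loadings=Vt[:k].T,
        scores=U[:, :k] * s[:k],
        y_train=y.copy(),
        constituent=constituent,
    )


def _nipals_pls1(
    Xc: np.ndarray, yc: np.ndarray, k: int, tol: float = 1e-12, max_iter: int = 500
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[np.ndarray]]:
    """NIPALS PLS1 on centered data; returns (W, P, q, T, per-k coefficients).

    For a single response the weight vector w = X'y / ||X'y|| is exact in
    one step per component; the iteration cap exists only as a guard.
    """
    n, p = Xc.shape
    Xd, yd = Xc.copy(), yc.copy()
    W = np.zeros((p, k))
    P = np.zeros((p, k))
    q = np.zeros(k)
    T = np.zeros((n, k))
    coefs: list[np.ndarray] = []
    for a in range(k):
        w = Xd.T @ yd
        norm = np.linalg.norm(w)
        if norm <= tol:
            raise ConfigError(
                f"PLS1 deflation exhausted after {a} components (rank reached); "
                f"requested {k}"
            )
        w /= norm
        t = Xd @ w
        tt = float(t @ t)
        if tt <= tol:
            raise ConfigError(f"degenerate PLS1 score at component {a + 1}")
        pvec = Xd.T @ t / tt
        qa = float(yd @ t) / tt
        Xd -= np.outer(t, pvec)
        yd -= qa * t
        W[:, a], P[:, a], q[a], T[:, a] = w, pvec, qa, t
        Wk, Pk, qk = W[:, : a + 1], P[:, : a + 1], q[: a + 1]
        coefs.append(Wk @ np.linalg.solve(Pk.T @ Wk, qk))
    return W, P, q, T, coefs


def fit_pls1(X, y, n_components: int, *, constituent: str | None = None) -> CalibrationModel:
    """Fit single-response PLS by NIPALS with ``n_components`` latent variables."""
    Xm, wn = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    if np.allclose(y, y[0]):
        raise ConfigError("PLS1 requires a response with non-zero variance")
    x_mean = Xm.mean(axis=0)
    y_mean = float(y.mean())
    Xc, yc = Xm - x_mean, y - y_mean
    rank = _rank(np.linalg.svd(Xc, compute_uv=False), *Xc.shape)
    if not 1 <= n_components <= rank:
        raise ConfigError(
            f"n_components={n_components} outside [1, rank={rank}] for PLS1"
        )
    W, P, q, T, coefs = _nipals_pls1(Xc, yc, n_components)
    return CalibrationModel(
        algorithm="pls1",
        n_components=n_components,
        x_mean=x_mean,
        y_mean=y_mean,
        coef=coefs[-1],
        wavenumbers=wn,
        loadings=P,
        weights=W,
        scores=T,
        y_train=y.copy(),
        constituent=constituent,
    )


def predict(model: CalibrationModel, X) -> np.ndarray:
    """Predict constituent content for new spectra on the model's grid.

    The caller is responsible for applying the same pretreatment that was
    used at fit time; ``predict`` only centers, applies the coefficient
    vector and un-centers.
    """
    Xm, wn = _as_matrix(X)
    if wn is not None and model.wavenumbers is not None:
        if len(wn) != len(model.wavenumbers) or not np.allclose(wn, model.wavenumbers):
            raise GridMismatchError(
                f"spectra grid does not match the fitted window "
                f"[{model.wavenumbers[-1]:g}, {model.wavenumbers[0]:g}] "
                f"({len(model.wavenumbers)} points)"
            )
    if Xm.shape[-1] != model.coef.shape[0]:
        raise GridMismatchError(
            f"expected {model.coef.shape[0]} variables, got {Xm.shape[-1]}"
        )
    return (Xm - model.x_mean) @ model.coef + model.y_mean


@dataclass(frozen=True)
class SplitSpec:
    """Seeded calibration/validation split with a mean-balance check.

    A draw is accepted when, for every constituent, the validation mean
    lies within ``balance_check`` pooled standard deviations of the
    calibration mean (``inf`` accepts the first draw).
    """

    n_cal: int = 31
    n_val: int = 6
    seed: int = 0
    balance_check: float = 0.75
    max_attempts: int = 500


def split_samples(
    spectra: SpectraSet, compositions: pd.DataFrame, spec: SplitSpec
) -> tuple[tuple[SpectraSet, pd.DataFrame], tuple[SpectraSet, pd.DataFrame]]:
    """Split samples into calibration and validation sets per ``spec``."""
    n = spectra.n_samples
    if spec.n_cal + spec.n_val != n:
        raise ConfigError(
            f"split {spec.n_cal}+{spec.n_val} does not cover {n} samples"
        )
    comps = compositions.loc[spectra.sample_ids]
    sds = comps.std(axis=0, ddof=1).to_numpy()
    sds[sds == 0] = 1.0
    # stage tag 10 keeps the split stream independent of generator substreams
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 10]))
    best = None
    best_imbalance = np.inf
    for _ in range(spec.max_attempts):
        perm = rng.permutation(n)
        cal_idx, val_idx = perm[: spec.n_cal], perm[spec.n_cal :]
        delta = np.abs(
            comps.iloc[cal_idx].mean(axis=0).to_numpy()
            - comps.iloc[val_idx].mean(axis=0).to_numpy()
        )
        imbalance = float(np.max(delta / sds))
        if imbalance < best_imbalance:
            best, best_imbalance = (cal_idx, val_idx), imbalance
        if imbalance <= spec.balance_check:
            break
    else:
        raise ConfigError(
            f"no balanced split within {spec.max_attempts} attempts; best "
            f"imbalance {best_imbalance:.3f} SD > tolerance {spec.balance_check}"
        )
    cal_idx, val_idx = best
    cal_idx, val_idx = np.sort(cal_idx), np.sort(val_idx)
    return (
        (spectra.subset(cal_idx), comps.iloc[cal_idx]),
        (spectra.subset(val_idx), comps.iloc[val_idx]),
    )


def _coef_paths(Xc: np.ndarray, yc: np.ndarray, algorithm: str, k_max: int) -> list[np.ndarray]:
    """Coefficient vectors for k = 1..k_max in one pass (for cross-validation)."""
    if algorithm == "pcr":
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        rank = _rank(s, *Xc.shape)
        k_max = min(k_max, rank)
        gamma = (U[:, :k_max].T @ yc) / s[:k_max]
        return [Vt[: k + 1].T @ gamma[: k + 1] for k in range(k_max)]
    if algorithm == "pls1":
        rank = _rank(np.linalg.svd(Xc, compute_uv=False), *Xc.shape)
        *_, coefs = _nipals_pls1(Xc, yc, min(k_max, rank))
        return coefs
    raise ConfigError(f"unknown algorithm {algorithm!r}")


def cross_validate(
    X,
    y,
    algorithm: str,
    k_max: int = 10,
    folds: int | None = None,
    selection_margin: float = 0.05,
) -> tuple[pd.DataFrame, int]:
    """Cross-validated RMSECV per component count, plus the selected k.

    ``folds=None`` runs leave-one-out; otherwise contiguous k-fold.  The
    selected k is the smallest whose RMSECV is within ``selection_margin``
    (default 5%) of the global minimum — the usual parsimony rule.
    """
    Xm, _ = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    n = Xm.shape[0]
    if algorithm == "pls1" and np.allclose(y, y[0]):
        raise ConfigError("PLS1 requires a response with non-zero variance")
    n_folds = n if folds is None else int(folds)
    if not 2 <= n_folds <= n:
        raise ConfigError(f"folds must be in [2, {n}], got {n_folds}")
    fold_ids = np.arange(n) % n_folds

    feasible = k_max
    press = np.zeros(k_max)
    counts = np.zeros(k_max)
    for f in range(n_folds):
        test = fold_ids == f
        Xtr, ytr = Xm[~test], y[~test]
        x_mean, y_mean = Xtr.mean(axis=0), ytr.mean()
        coefs = _coef_paths(Xtr - x_mean, ytr - y_mean, algorithm, k_max)
        feasible = min(feasible, len(coefs))
        Xte_c = Xm[test] - x_mean
        for k, b in enumerate(coefs):
            pred = Xte_c @ b + y_mean
            press[k] += float(np.sum((pred - y[test]) ** 2))
            counts[k] += int(test.sum())
    if feasible < k_max:
        warnings.warn(
            f"k_max truncated from {k_max} to {feasible} by the rank of the "
            f"smallest training fold",
            stacklevel=2,
        )
    rmsecv = np.sqrt(press[:feasible] / counts[:feasible])
    table = pd.DataFrame({"k": np.arange(1, feasible + 1), "rmsecv": rmsecv})
    selected = int(np.argmax(rmsecv <= (1.0 + selection_margin) * rmsecv.min())) + 1
    return table, selected


@dataclass(frozen=True)
class Diagnostics:
    """Calibration/validation figures of merit.

    r2 is in percent; rpd is None (flagged undefined) when RMSEP is zero.
    """

    r2: float
    rmsec: float
    rmsep: float
    rpd: float | None
    n_cal: int
    n_val: int

    @property
    def rpd_defined(self) -> bool:
        return self.rpd is not None


def _rmse(pred: np.ndarray, ref: np.ndarray) -> float:
    return float(np.sqrt(np.mean((pred - ref) ** 2)))


def diagnostics(model: CalibrationModel, X_cal, y_cal, X_val, y_val) -> Diagnostics:
    """Compute r^2 (%), RMSEC, RMSEP and RPD for a fitted model."""
    y_cal = np.asarray(y_cal, dtype=float).ravel()
    y_val = np.asarray(y_val, dtype=float).ravel()
    if y_cal.size == 0 or y_val.size == 0:
        raise ConfigError("diagnostics needs non-empty calibration and validation sets")
    pred_cal = predict(model, X_cal)
    pred_val = predict(model, X_val)
    if np.std(pred_cal) == 0 or np.std(y_cal) == 0:
        r2 = 0.0
    else:
        r = stats.pearsonr(pred_cal, y_cal).statistic
        r2 = 100.0 * r * r
    # numerically-perfect fits can nudge the correlation past 1 in float
    r2 = min(r2, 100.0)
    rmsec = _rmse(pred_cal, y_cal)
    rmsep = _rmse(pred_val, y_val)
    rpd = None if rmsep == 0 else float(np.std(y_val, ddof=1) / rmsep)
    return Diagnostics(
        r2=r2, rmsec=rmsec, rmsep=rmsep, rpd=rpd, n_cal=y_cal.size, n_val=y_val.size
    )


def related_pc_index(model: CalibrationModel, y=None) -> int:
    """1-based index of the PC whose scores correlate most with y (PCR only)."""
    if model.algorithm != "pcr":
        raise ConfigError("related_pc_index applies to PCR models only")
    yv = model.y_train if y is None else np.asarray(y, dtype=float).ravel()
    if yv is None:
        raise ConfigError("no training response stored on the model")
    yc = yv - yv.mean()
    T = model.scores
    corr = np.abs(T.T @ yc) / (np.linalg.norm(T, axis=0) * np.linalg.norm(yc) + 1e-300)
    return int(np.argmax(corr)) + 1


def coefficient_profile(
    model: CalibrationModel,
    source: str | None = None,
    pc_index: int | None = None,
) -> np.ndarray:
    """The interpretation vector over retained wavenumbers.

    For PCR the default is the loading vector of the single PC most
    related to the response (scores most correlated with y), overridable
    via ``pc_index`` (1-based); for PLS1 the default (and only supported
    source) is the full regression coefficient vector.
    """
    if source is None:
        source = "single_pc_loading" if model.algorithm == "pcr" else "regression_coefficients"
    if source == "regression_coefficients":
        return model.coef.copy()
    if source == "single_pc_loading":
        if model.algorithm != "pcr":
            raise ConfigError(
                "single_pc_loading profiles are only defined for PCR models"
            )
        idx = related_pc_index(model) if pc_index is None else int(pc_index)
        if not 1 <= idx <= model.n_components:
            raise ConfigError(
                f"pc_index {idx} outside the {model.n_components} fitted components"
            )
        return model.loadings[:, idx - 1].copy()
    raise ConfigError(f"unknown profile source {source!r}")
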