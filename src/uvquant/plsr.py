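"""From-scratch PLS1 (NIPALS) with venetian-blinds cross-validation.

The model regresses a single analyte concentration on pre-processed,
mean-centered spectra. NIPALS extracts latent variables one at a time: the
weight vector w maximizes covariance between the spectra and the response,
scores t = Z w, x-loadings p and y-loading q are least-squares projections
on t, and both Z and y are deflated before the next component. The final
regression vector b = W (P'W)^-1 q maps a centered spectrum directly to a
(centered) predicted concentration; the stored calibration y-mean provides
the implicit intercept.

Cross-validation is venetian blinds over replicate groups: every technical
replicate of a (collection, fraction) pair stays in the same fold, folds are
assigned round-robin over the concentration-ordered groups, and both the
centering and the PLS fit are recomputed inside each fold so held-out
replicates never influence the model that predicts them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import PreprocessChain, run_chain
from .spectra_io import SpectraDataset

GroupKey = tuple


@dataclass
class PLSModel:
    """Fitted PLS1 model over the trimmed wavelength grid.

    W, P are (wavelengths x n_lv); q is (n_lv,); T (calibration scores) is
    (samples x n_lv); b is the per-wavelength regression vector.
    """

    n_lv: int
    W: np.ndarray
    P: np.ndarray
    q: np.ndarray
    T: np.ndarray
    b: np.ndarray
    y_mean: float
    analyte: str = ""
    chain: PreprocessChain | None = None
    grid_values: np.ndarray | None = None


@dataclass(frozen=True)
class CVPlan:
    """Partition of replicate groups into k venetian-blinds folds."""

    k: int
    folds: tuple[tuple[GroupKey, ...], ...]

    def __post_init__(self) -> None:
        all_groups = [g for fold in self.folds for g in fold]
        if len(set(all_groups)) != len(all_groups):
            raise ValueError("folds must be pairwise disjoint")


@dataclass
class RegressionMetrics:
    """Calibration / cross-validation / prediction errors (mg/L) and R^2.

    R^2 here is the squared Pearson correlation between measured and
    predicted concentrations (so it is affine-invariant and lies in [0, 1]).
    """

    rmsec: float | None = None
    rmsecv: float | None = None
    rmsep: float | None = None
    r2_cal: float | None = None
    r2_cv: float | None = None
    r2_pred: float | None = None


def _rmse(y_true: np.ndarray, y_hat: np.ndarray) -> float:
    return float(np.sqrt(np.mean((y_true - y_hat) ** 2)))


def _r2_pearson(y_true: np.ndarray, y_hat: np.ndarray) -> float:
    if np.std(y_true) == 0 or np.std(y_hat) == 0:
        return float("nan")
    return float(np.corrcoef(y_true, y_hat)[0, 1] ** 2)


def metrics(y_true, y_hat, context: str = "cal") -> RegressionMetrics:
    """RMSE and squared-Pearson R^2, placed in the fields named by ``context``
    (one of ``cal``, ``cv``, ``pred``)."""
    y_true = np.asarray(y_true, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y_true.shape != y_hat.shape:
        raise ValueError("y_true and y_hat must have equal length")
    if y_true.size < 2:
        raise ValueError("need at least 2 points")
    rmse = _rmse(y_true, y_hat)
    r2 = _r2_pearson(y_true, y_hat)
    out = RegressionMetrics()
    if context == "cal":
        out.rmsec, out.r2_cal = rmse, r2
    elif context == "cv":
        out.rmsecv, out.r2_cv = rmse, r2
    elif context == "pred":
        out.rmsep, out.r2_pred = rmse, r2
    else:
        raise ValueError(f"unknown context {context!r}")
    return out


def fit_pls1(
    Z: np.ndarray,
    y: np.ndarray,
    n_lv: int,
    analyte: str = "",
    chain: PreprocessChain | None = None,
    grid_values: np.ndarray | None = None,
) -> PLSModel:
    """NIPALS PLS1 on mean-centered spectra ``Z`` and concentrations ``y``.

    ``Z`` is assumed centered by the pre-processing chain; ``y`` is centered
    internally and its mean stored as the implicit intercept. Deterministic.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    y = np.asarray(y, dtype=float)
    n, p = Z.shape
    if y.shape != (n,):
        raise ValueError("y length must match the number of rows")
    if np.all(y == y[0]):
        raise ValueError("y is constant; PLS1 undefined")
    if not (1 <= n_lv <= min(n - 1, p)):
        raise ValueError(f"n_lv must be in [1, {min(n - 1, p)}], got {n_lv}")

    y_mean = float(y.mean())
    Xd = Z.copy()
    yd = y - y_mean
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    T = np.zeros((n, n_lv))
    for a in range(n_lv):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw == 0:
            raise ValueError(f"response deflated to zero covariance at LV {a + 1}")
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt == 0:
            raise ValueError(f"degenerate score vector at LV {a + 1}")
        pvec = Xd.T @ t / tt
        qa = float(yd @ t) / tt
        Xd -= np.outer(t, pvec)
        yd = yd - qa * t
        W[:, a], P[:, a], q[a], T[:, a] = w, pvec, qa, t

    b = W @ np.linalg.solve(P.T @ W, q)
    return PLSModel(
        n_lv=n_lv, W=W, P=P, q=q, T=T, b=b, y_mean=y_mean,
        analyte=analyte, chain=chain, grid_values=grid_values,
    )


def predict(model: PLSModel, rows: np.ndarray | SpectraDataset) -> np.ndarray:
    """Predicted concentrations (mg/L); negative predictions are not clipped.

    A :class:`~uvquant.spectra_io.SpectraDataset` is passed through the
    model's fitted chain first; a bare array is assumed already processed and
    centered, on the model's trimmed grid.
    """
    if isinstance(rows, SpectraDataset):
        if model.chain is None:
            raise ValueError("model carries no pre-processing chain")
        processed = run_chain(rows, model.chain)
        if model.grid_values is not None and not np.array_equal(processed.grid.values, model.grid_values):
            raise ValueError("wavelength grid mismatch between model and data")
        X = processed.absorbance
    else:
        X = np.atleast_2d(np.asarray(rows, dtype=float))
    if X.shape[1] != model.b.size:
        raise ValueError(f"rows have {X.shape[1]} wavelengths, model expects {model.b.size}")
    return X @ model.b + model.y_mean


def venetian_blinds(groups: list[GroupKey], k: int = 4) -> CVPlan:
    """Assign replicate groups to folds round-robin: sorted group i -> fold i mod k."""
    unique = sorted(set(groups))
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(unique):
        raise ValueError(f"k={k} exceeds the {len(unique)} replicate groups")
    folds: list[list[GroupKey]] = [[] for _ in range(k)]
    for i, g in enumerate(unique):
        folds[i % k].append(g)
    return CVPlan(k=k, folds=tuple(tuple(f) for f in folds))


def cross_validate(
    Z_rowwise: np.ndarray,
    y: np.ndarray,
    groups: list[GroupKey],
    n_lv: int,
    k: int = 4,
) -> tuple[RegressionMetrics, np.ndarray]:
    """Venetian-blinds CV with per-fold re-centering; returns metrics and
    pooled held-out predictions (aligned with the input rows).

    ``Z_rowwise`` must be processed through the per-row chain stages but NOT
    mean-centered: both the spectral centering and the PLS fit are redone on
    the retained folds only, so no information from a held-out replicate
    group reaches the model that predicts it.
    """
    Z_rowwise = np.atleast_2d(np.asarray(Z_rowwise, dtype=float))
    y = np.asarray(y, dtype=float)
    if len(groups) != Z_rowwise.shape[0] or y.shape[0] != Z_rowwise.shape[0]:
        raise ValueError("rows, y, and groups must align")
    plan = venetian_blinds(groups, k)
    y_pred = np.full_like(y, np.nan, dtype=float)
    for fold_idx, fold in enumerate(plan.folds):
        held = np.array([g in fold for g in groups])
        train = ~held
        y_train = y[train]
        if np.all(y_train == y_train[0]):
            raise ValueError(f"fold {fold_idx}: training response is constant")
        x_mean = Z_rowwise[train].mean(axis=0)
        model = fit_pls1(Z_rowwise[train] - x_mean, y_train, n_lv)
        y_pred[held] = predict(model, Z_rowwise[held] - x_mean)
    m = metrics(y, y_pred, context="cv")
    return m, y_pred


def regression_vector_report(model: PLSModel, wavelengths: np.ndarray | None = None) -> pd.DataFrame:
    """Per-wavelength regression coefficients with extrema annotations.

    Returns a DataFrame (``wavelength_nm``, ``coefficient``, ``sign``); the
    wavelengths of the most positive, most negative, and largest-magnitude
    coefficients are stored in ``df.attrs`` for plotting/inspection.
    """
    lam = model.grid_values if wavelengths is None else np.asarray(wavelengths, dtype=float)
    if lam is None:
        lam = np.arange(model.b.size, dtype=float)
    if lam.size != model.b.size:
        raise ValueError("wavelength axis does not match the regression vector")
    df = pd.DataFrame({"wavelength_nm": lam, "coefficient": model.b})
    df["sign"] = np.sign(df["coefficient"]).astype(int)
    df.attrs["max_positive_nm"] = float(lam[int(np.argmax(model.b))])
    df.attrs["max_negative_nm"] = float(lam[int(np.argmin(model.b))])
    df.attrs["max_abs_nm"] = float(lam[int(np.argmax(np.abs(model.b)))])
    return df
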