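"""Spectral pre-processing chain for multivariate calibration.

Fixed stage order: trim -> weighted-least-squares baseline removal ->
Savitzky-Golay smoothing -> standard normal variate (SNV) -> mean centering.
The first four stages are per-row (no information crosses samples); the
mean-centering stage is *fitted* on calibration rows only and the stored
calibration mean is subtracted from any later row, so validation data are
centered without leakage.

The baseline remover fits a low-order polynomial by iteratively reweighted
least squares with asymmetric weights: points at or below the current fit
keep weight 1, points above it (i.e. absorption peaks) are down-weighted to
0.01, so the converged polynomial hugs the lower envelope of the spectrum.
SNV standardizes each row to mean 0 / sample SD 1, which exactly cancels any
multiplicative path-length factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy.signal import savgol_filter

from .spectra_io import SampleMeta, SpectraDataset, WavelengthGrid

logger = logging.getLogger(__name__)

#: weight given to points above the current baseline fit
_ABOVE_WEIGHT = 0.01


def trim(ds: SpectraDataset, lo_nm: float, hi_nm: float) -> SpectraDataset:
    """Keep wavelengths lo <= lambda <= hi (inclusive); metadata untouched."""
    if lo_nm >= hi_nm:
        raise ValueError("trim range must satisfy lo < hi")
    mask = (ds.grid.values >= lo_nm) & (ds.grid.values <= hi_nm)
    if not mask.any():
        raise ValueError(
            f"trim range [{lo_nm}, {hi_nm}] nm does not overlap the grid "
            f"[{ds.grid.values[0]}, {ds.grid.values[-1]}] nm"
        )
    return SpectraDataset(WavelengthGrid(ds.grid.values[mask]), ds.absorbance[:, mask], ds.meta)


def baseline_wls(
    row: np.ndarray,
    grid: WavelengthGrid,
    poly_order: int = 2,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> np.ndarray:
    """Subtract an asymmetrically reweighted polynomial baseline from one row.

    Deterministic; if the reweighting has not stabilized after ``max_iter``
    iterations the last iterate is used and a warning is logged (never an
    exception).
    """
    row = np.asarray(row, dtype=float)
    lam = grid.values
    if len(lam) <= poly_order + 1:
        raise ValueError("grid length must exceed poly_order + 1")
    # scale abscissa for polynomial conditioning
    x = (lam - lam.mean()) / (lam.std() or 1.0)
    vander = np.vander(x, poly_order + 1)
    weights = np.ones_like(row)
    baseline = np.zeros_like(row)
    converged = False
    for _ in range(max_iter):
        wsqrt = np.sqrt(weights)
        coef, *_ = np.linalg.lstsq(vander * wsqrt[:, None], row * wsqrt, rcond=None)
        new_baseline = vander @ coef
        delta = np.linalg.norm(new_baseline - baseline) / max(np.linalg.norm(baseline), 1e-12)
        baseline = new_baseline
        if delta < tol:
            converged = True
            break
        weights = np.where(row <= baseline, 1.0, _ABOVE_WEIGHT)
    if not converged:
        logger.warning("baseline_wls: no convergence after %d iterations", max_iter)
    return row - baseline


def smooth(row: np.ndarray, window: int = 11, poly_order: int = 3) -> np.ndarray:
    """Savitzky-Golay smoothing; edges use a polynomial fit on the truncated window."""
    row = np.asarray(row, dtype=float)
    if window % 2 == 0 or window <= poly_order:
        raise ValueError("window must be odd and greater than poly_order")
    if window > row.size:
        raise ValueError("window exceeds row length")
    return savgol_filter(row, window_length=window, polyorder=poly_order, mode="interp")


def snv(row: np.ndarray) -> np.ndarray:
    """Standard normal variate: (row - mean) / sample SD (n-1 denominator)."""
    row = np.asarray(row, dtype=float)
    sd = row.std(ddof=1)
    if sd == 0:
        raise ValueError("SNV undefined for a constant row (SD = 0)")
    return (row - row.mean()) / sd


def fit_mean_center(rows: np.ndarray) -> np.ndarray:
    """Per-wavelength mean over calibration rows (the centering vector)."""
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    if rows.shape[0] < 1:
        raise ValueError("need at least one calibration row to fit the mean")
    return rows.mean(axis=0)


def apply_mean_center(rows: np.ndarray, fitted_mean: np.ndarray) -> np.ndarray:
    """Subtract the stored calibration mean from any rows (calibration or test)."""
    if fitted_mean is None:
        raise ValueError("mean-centering has not been fitted")
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    return rows - np.asarray(fitted_mean, dtype=float)[None, :]


@dataclass
class PreprocessChain:
    """Ordered, parameterized pre-processing pipeline.

    Any stage can be disabled by setting its field to ``None``/``False``;
    ``fitted_mean`` is set by :func:`fit_chain` and is required before the
    chain can be applied to data with ``mean_center`` enabled.
    """

    trim_range: tuple[float, float] | None = (190.0, 320.0)
    baseline: tuple[int, int, float] | None = (2, 100, 1e-6)  # (poly_order, max_iter, tol)
    smooth_params: tuple[int, int] | None = (11, 3)  # (window, poly_order)
    snv_enabled: bool = True
    mean_center: bool = True
    fitted_mean: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.trim_range is not None and self.trim_range[0] >= self.trim_range[1]:
            raise ValueError("trim range must satisfy lo < hi")
        if self.smooth_params is not None:
            window, order = self.smooth_params
            if window % 2 == 0 or window <= order:
                raise ValueError("smoothing window must be odd and greater than its poly order")

    @property
    def is_fitted(self) -> bool:
        return (not self.mean_center) or self.fitted_mean is not None

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "trim_range": list(self.trim_range) if self.trim_range else None,
            "baseline": list(self.baseline) if self.baseline else None,
            "smooth": list(self.smooth_params) if self.smooth_params else None,
            "snv": bool(self.snv_enabled),
            "mean_center": bool(self.mean_center),
            "fitted_mean": None if self.fitted_mean is None else [float(v) for v in self.fitted_mean],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessChain":
        return cls(
            trim_range=tuple(d["trim_range"]) if d.get("trim_range") else None,
            baseline=tuple(d["baseline"]) if d.get("baseline") else None,
            smooth_params=tuple(d["smooth"]) if d.get("smooth") else None,
            snv_enabled=bool(d.get("snv", True)),
            mean_center=bool(d.get("mean_center", True)),
            fitted_mean=None if d.get("fitted_mean") is None else np.asarray(d["fitted_mean"], dtype=float),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PreprocessChain":
        return cls.from_dict(yaml.safe_load(text))


def run_chain_rowwise(ds: SpectraDataset, chain: PreprocessChain) -> SpectraDataset:
    """Apply all per-row stages (trim, baseline, smoothing, SNV), no centering.

    This is the leakage-free portion of the chain; cross-validation re-fits
    only the centering inside each fold on top of this output.
    """
    out = ds
    if chain.trim_range is not None:
        out = trim(out, *chain.trim_range)
    rows = out.absorbance.copy()
    if chain.baseline is not None:
        order, max_iter, tol = chain.baseline
        rows = np.array([baseline_wls(r, out.grid, order, max_iter, tol) for r in rows]) if len(rows) else rows
    if chain.smooth_params is not None and len(rows):
        window, order = chain.smooth_params
        rows = np.array([smooth(r, window, order) for r in rows])
    if chain.snv_enabled and len(rows):
        rows = np.array([snv(r) for r in rows])
    return SpectraDataset(out.grid, rows, out.meta)


def fit_chain(calibration_ds: SpectraDataset, chain: PreprocessChain) -> SpectraDataset:
    """Fit the chain's centering on calibration data and return the processed set.

    ``chain.fitted_mean`` is set in place (per-wavelength mean of the
    row-wise-processed calibration rows); per-row stages involve no fitting.
    """
    rowwise = run_chain_rowwise(calibration_ds, chain)
    if chain.mean_center:
        chain.fitted_mean = fit_mean_center(rowwise.absorbance)
        return SpectraDataset(
            rowwise.grid, apply_mean_center(rowwise.absorbance, chain.fitted_mean), rowwise.meta
        )
    return rowwise


def run_chain(ds: SpectraDataset, chain: PreprocessChain) -> SpectraDataset:
    """Apply a (fitted) chain to any dataset; test rows are centered by the
    calibration mean learned in :func:`fit_chain`."""
    rowwise = run_chain_rowwise(ds, chain)
    if chain.mean_center:
        if chain.fitted_mean is None:
            raise ValueError("chain not fitted: call fit_chain on calibration data first")
        return SpectraDataset(
            rowwise.grid, apply_mean_center(rowwise.absorbance, chain.fitted_mean), rowwise.meta
        )
    return rowwise
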