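"""Clinical outputs and end-to-end pipeline orchestration.

The clinical layer turns predicted albumin and creatinine concentrations
into the urinary albumin/creatinine ratio (ACR, mg albumin per g
creatinine), an albuminuria category (normo < 30 mg/L, micro 30-300 mg/L
inclusive, macro > 300 mg/L, by albumin concentration alone), and
reliability flags when a concentration falls below its limit of detection —
a low-creatinine denominator in particular makes the ratio imprecise.

``run_pipeline`` drives the whole workflow from a single config: simulate
(or read) spectra, split collections into calibration and validation, fit
the pre-processing chain and one PLS1 model per analyte, cross-validate,
score the held-out collection, estimate LoB/LoD, and tabulate ACR for the
validation samples. Everything is reproducible from config + seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import synth
from .detection import DetectionLimits, detection_report
from .plsr import PLSModel, cross_validate, fit_pls1, metrics, predict
from .preprocess import PreprocessChain, fit_chain, run_chain, run_chain_rowwise
from .spectra_io import SpectraDataset, read_spectra, subset
from .synth import (
    BSA,
    CREATININE,
    NoiseModel,
    build_cospike_design,
    build_dilution_series,
    simulate_dataset,
)

logger = logging.getLogger(__name__)

ALBUMIN_MICRO_MG_L = 30.0
ALBUMIN_MACRO_MG_L = 300.0

#: latent-variable counts per design (chosen per-analyte for each experiment)
DEFAULT_LV = {
    "bsa": {BSA: 5},
    "creatinine": {CREATININE: 4},
    "cospike": {BSA: 6, CREATININE: 4},
}


@dataclass(frozen=True)
class ACRResult:
    """Albumin/creatinine ratio with category and reliability flags.

    ``acr`` is in mg albumin per g creatinine (albumin mg/L divided by
    creatinine g/L) and is ``None`` when creatinine <= 0.
    """

    albumin: float
    creatinine: float
    acr: float | None
    category: str
    flags: frozenset[str]


def classify_albuminuria(albumin_mg_L: float) -> str:
    """normo (< 30), micro (30-300 inclusive), or macro (> 300) by albumin mg/L."""
    if albumin_mg_L < 0:
        raise ValueError("albumin concentration must be >= 0")
    if albumin_mg_L < ALBUMIN_MICRO_MG_L:
        return "normo"
    if albumin_mg_L <= ALBUMIN_MACRO_MG_L:
        return "micro"
    return "macro"


def compute_acr(
    albumin_mg_L: float,
    creatinine_mg_L: float,
    limits: tuple[DetectionLimits | None, DetectionLimits | None] | None = None,
) -> ACRResult:
    """ACR in mg/g with below-LoD flags.

    ``limits`` is an optional (albumin, creatinine) pair of
    :class:`~uvquant.detection.DetectionLimits`; a concentration below its
    LoD raises the corresponding flag, and a creatinine below its LoD
    additionally flags the ratio as unreliable. A non-positive creatinine
    yields a flagged result with no ratio rather than an exception.
    """
    if albumin_mg_L < 0:
        raise ValueError("albumin concentration must be >= 0")
    flags: set[str] = set()
    alb_lim, cr_lim = limits if limits is not None else (None, None)
    if alb_lim is not None and albumin_mg_L < alb_lim.lod:
        flags.add("albumin_below_lod")
    if cr_lim is not None and creatinine_mg_L < cr_lim.lod:
        flags.add("creatinine_below_lod")
        flags.add("creatinine_unreliable")
    if creatinine_mg_L <= 0:
        flags.add("creatinine_unreliable")
        acr = None
    else:
        acr = albumin_mg_L / (creatinine_mg_L / 1000.0)
    return ACRResult(
        albumin=float(albumin_mg_L),
        creatinine=float(creatinine_mg_L),
        acr=acr,
        category=classify_albuminuria(albumin_mg_L),
        flags=frozenset(flags),
    )


@dataclass
class PipelineConfig:
    """Single source of truth for an end-to-end run.

    ``design`` selects the spiking experiment (``bsa``, ``creatinine``, or
    ``cospike``); ``data_csv`` substitutes a measured dataset (wide-layout
    CSV) for the simulator. Latent-variable counts default to the packaged
    per-design values.
    """

    design: str = "cospike"
    seed: int = 1
    additive_sd: float = 0.005
    pathlength_sd: float = 0.05
    baseline_drift: tuple[float, float] = (1e-4, 0.02)
    n_collections: int = 3
    n_calibration_collections: int = 2
    n_replicates: int = 3
    cv_folds: int = 4
    lv: dict[str, int] | None = None
    trim_range: tuple[float, float] = (190.0, 320.0)
    data_csv: str | None = None

    def __post_init__(self) -> None:
        if self.design not in DEFAULT_LV:
            raise ValueError(f"design must be one of {sorted(DEFAULT_LV)}, got {self.design!r}")
        if self.lv is None:
            self.lv = dict(DEFAULT_LV[self.design])

    def to_dict(self) -> dict:
        d = asdict(self)
        d["baseline_drift"] = list(self.baseline_drift)
        d["trim_range"] = list(self.trim_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "baseline_drift" in d:
            d["baseline_drift"] = tuple(d["baseline_drift"])
        if "trim_range" in d:
            d["trim_range"] = tuple(d["trim_range"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def build_design(name: str) -> synth.DesignTable:
    """The packaged spiking design for an experiment name."""
    if name == "bsa":
        return build_dilution_series(0.1, 200.0, analyte=BSA)
    if name == "creatinine":
        return build_dilution_series(0.4, 200.0, analyte=CREATININE)
    if name == "cospike":
        return build_cospike_design()
    raise ValueError(f"unknown design {name!r}")


def _load_dataset(config: PipelineConfig) -> SpectraDataset:
    if config.data_csv is not None:
        return read_spectra(config.data_csv, layout="wide")
    noise = NoiseModel(
        additive_sd=config.additive_sd,
        pathlength_sd=config.pathlength_sd,
        baseline_drift=config.baseline_drift,
        seed=config.seed,
    )
    return simulate_dataset(
        build_design(config.design),
        noise=noise,
        n_collections=config.n_collections,
        n_replicates=config.n_replicates,
        n_calibration_collections=config.n_calibration_collections,
    )


def fit_analyte(
    ds_cal: SpectraDataset, chain: PreprocessChain, analyte: str, n_lv: int
) -> PLSModel:
    """Fit one analyte's PLS1 model on chain-processed calibration spectra."""
    processed = run_chain(ds_cal, chain)
    model = fit_pls1(
        processed.absorbance,
        ds_cal.concentrations(analyte),
        n_lv,
        analyte=analyte,
        chain=chain,
        grid_values=processed.grid.values,
    )
    return model


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the full workflow and return (and optionally write) the results.

    Returns a JSON-serializable bundle with, per analyte: latent-variable
    count, RMSEC/RMSECV/RMSEP (mg/L), R^2 for calibration / CV / prediction,
    and the LoB/LoD record; plus an ACR table over the validation samples.
    When ``out_dir`` is given, ``results.json`` and a plain-text
    ``summary.txt`` are written there.
    """
    ds = _load_dataset(config)
    cal = subset(ds, lambda m: m.role == "calibration")
    val = subset(ds, lambda m: m.role == "validation")
    if cal.n_samples == 0:
        raise ValueError("split error: no calibration samples (role='calibration')")
    if val.n_samples == 0:
        raise ValueError("split error: no validation collection (role='validation')")
    logger.info("split: %d calibration rows, %d validation rows", cal.n_samples, val.n_samples)

    chain = PreprocessChain(trim_range=config.trim_range)
    fit_chain(cal, chain)
    cal_rowwise = run_chain_rowwise(cal, chain)

    results: dict = {
        "config": config.to_dict(),
        "n_calibration": cal.n_samples,
        "n_validation": val.n_samples,
        "analytes": {},
    }
    models: dict[str, PLSModel] = {}
    limits: dict[str, DetectionLimits] = {}
    for analyte, n_lv in sorted(config.lv.items()):
        logger.info("fitting %s with %d latent variables", analyte, n_lv)
        model = fit_analyte(cal, chain, analyte, n_lv)
        models[analyte] = model
        y_cal = cal.concentrations(analyte)
        m_cal = metrics(y_cal, predict(model, cal), context="cal")
        groups = [(m.urine_collection_id, m.fraction_index) for m in cal.meta]
        m_cv, _ = cross_validate(
            cal_rowwise.absorbance, y_cal, groups, n_lv, k=config.cv_folds
        )
        y_val = val.concentrations(analyte)
        m_pred = metrics(y_val, predict(model, val), context="pred")
        lim = detection_report(model, ds)
        limits[analyte] = lim
        results["analytes"][analyte] = {
            "n_lv": n_lv,
            "rmsec": m_cal.rmsec,
            "r2_cal": m_cal.r2_cal,
            "rmsecv": m_cv.rmsecv,
            "r2_cv": m_cv.r2_cv,
            "rmsep": m_pred.rmsep,
            "r2_pred": m_pred.r2_pred,
            "lob": lim.lob,
            "lod": lim.lod,
            "n_blank": lim.n_blank,
            "n_low": lim.n_low,
        }

    if BSA in models and CREATININE in models:
        alb_pred = predict(models[BSA], val)
        cr_pred = predict(models[CREATININE], val)
        table = []
        for m, a, c in zip(val.meta, alb_pred, cr_pred):
            res = compute_acr(max(float(a), 0.0), float(c), (limits[BSA], limits[CREATININE]))
            table.append(
                {
                    "sample_id": m.sample_id,
                    "albumin_pred_mg_L": res.albumin,
                    "creatinine_pred_mg_L": res.creatinine,
                    "acr_mg_g": res.acr,
                    "category": res.category,
                    "flags": sorted(res.flags),
                    "albumin_true_mg_L": m.conc.get(BSA, 0.0),
                    "creatinine_true_mg_L": m.conc.get(CREATININE, 0.0),
                }
            )
        results["acr_table"] = table

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "results.json", "w") as fh:
            json.dump(results, fh, indent=2, sort_keys=True)
        with open(out / "summary.txt", "w") as fh:
            fh.write(format_summary(results))
    return results


def format_summary(results: dict) -> str:
    """Human-readable one-screen summary of a pipeline results bundle."""
    lines = [
        f"design: {results['config']['design']}   seed: {results['config']['seed']}",
        f"calibration rows: {results['n_calibration']}   validation rows: {results['n_validation']}",
        "",
        f"{'analyte':<12}{'LV':>3}{'RMSEC':>9}{'RMSECV':>9}{'RMSEP':>9}"
        f"{'R2cal':>7}{'R2cv':>7}{'R2pred':>8}{'LoB':>8}{'LoD':>8}",
    ]
    for analyte, r in sorted(results["analytes"].items()):
        lines.append(
            f"{analyte:<12}{r['n_lv']:>3}{r['rmsec']:>9.2f}{r['rmsecv']:>9.2f}{r['rmsep']:>9.2f}"
            f"{r['r2_cal']:>7.3f}{r['r2_cv']:>7.3f}{r['r2_pred']:>8.3f}"
            f"{r['lob']:>8.2f}{r['lod']:>8.2f}"
        )
    lines.append("(concentrations and limits in mg/L; ACR table in results.json, mg/g)")
    return "\n".join(lines) + "\n"
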