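"""Limit of blank (LoB) and limit of detection (LoD) from model predictions.

Both limits follow the one-sided 95th-percentile convention (z = 1.645):

    LoB = mean(blank predictions) + 1.645 * SD(blank predictions)
    LoD = LoB + 1.645 * SD(low-concentration predictions)

"Blank" means the model's predicted concentrations for the unspiked (0 mg/L)
control fractions of urine — not the instrument's water reference — and the
"low concentration sample" is the lowest non-zero level of the spiking
design. Standard deviations use the n-1 (sample) denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .plsr import PLSModel, predict
from .spectra_io import SpectraDataset, subset

Z_95 = 1.645


@dataclass(frozen=True)
class DetectionLimits:
    """LoB/LoD record with provenance counts for one analyte."""

    analyte: str
    lob: float
    lod: float
    mean_blank: float
    sd_blank: float
    sd_low: float
    n_blank: int
    n_low: int
    z: float = Z_95

    def __post_init__(self) -> None:
        if self.sd_blank < 0 or self.sd_low < 0:
            raise ValueError("standard deviations must be >= 0")
        if abs(self.lob - (self.mean_blank + self.z * self.sd_blank)) > 1e-12 * max(1.0, abs(self.lob)):
            raise ValueError("lob must equal mean_blank + z * sd_blank")
        if self.lod < self.lob - 1e-12:
            raise ValueError("lod must be >= lob")


def limit_of_blank(blank_predictions) -> tuple[float, float, float]:
    """(LoB, mean, sample SD) of predicted concentrations on blank samples."""
    preds = np.asarray(blank_predictions, dtype=float)
    if preds.size < 2:
        raise ValueError("need at least 2 blank predictions")
    mean = float(preds.mean())
    sd = float(preds.std(ddof=1))
    return mean + Z_95 * sd, mean, sd


def limit_of_detection(lob: float, low_predictions) -> float:
    """LoB + 1.645 x sample SD of predictions at the lowest non-zero level."""
    preds = np.asarray(low_predictions, dtype=float)
    if preds.size < 2:
        raise ValueError("need at least 2 low-concentration predictions")
    return float(lob + Z_95 * preds.std(ddof=1))


def detection_report(model: PLSModel, ds: SpectraDataset) -> DetectionLimits:
    """Full LoB/LoD record for a model, from a dataset that contains both the
    blank control fractions and the lowest non-zero design level.

    Predictions are run through the model's fitted chain; the low group is
    every replicate at the minimum non-zero spiked concentration of the
    model's analyte.
    """
    analyte = model.analyte
    if not analyte:
        raise ValueError("model has no analyte name")
    blanks = subset(ds, lambda m: m.role == "blank")
    if blanks.n_samples < 2:
        raise ValueError("missing group: need >= 2 blank (0 mg/L control) samples")
    conc = ds.concentrations(analyte)
    nonzero = conc[conc > 0]
    if nonzero.size == 0:
        raise ValueError(f"missing group: no non-zero {analyte} fractions for the low level")
    low_level = float(nonzero.min())
    low = subset(ds, lambda m: m.conc.get(analyte, 0.0) == low_level)
    if low.n_samples < 2:
        raise ValueError(
            f"missing group: need >= 2 replicates at the lowest non-zero level ({low_level} mg/L)"
        )
    lob, mean_blank, sd_blank = limit_of_blank(predict(model, blanks))
    low_preds = predict(model, low)
    lod = limit_of_detection(lob, low_preds)
    return DetectionLimits(
        analyte=analyte,
        lob=lob,
        lod=lod,
        mean_blank=mean_blank,
        sd_blank=sd_blank,
        sd_low=float(np.asarray(low_preds).std(ddof=1)),
        n_blank=blanks.n_samples,
        n_low=low.n_samples,
    )
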