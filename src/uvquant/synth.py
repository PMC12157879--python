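"""Spiked-urine designs and Beer-Lambert simulation of NanoDrop-like spectra.

The spiking designs mirror the study's bench protocol: a stock of analyte
dissolved in urine (e.g. 0.1 g BSA in 200 mL -> 500 mg/L) is pipetted in
decreasing aliquots into 10 mL flasks and topped up with unspiked urine,
giving a dilution series plus an unspiked control; a co-spike design mixes
both analytes at fixed concentration pairs.

Spectra are simulated as additive Beer-Lambert mixtures of Gaussian
absorption bands (one ComponentSpectrum per analyte plus a urine
background), scaled by a per-replicate multiplicative path-length factor
(the NanoDrop auto-ranges its path length between measurements, which is
what SNV later removes), with a smooth linear baseline drift and additive
white noise. Every random draw comes from a stream keyed on
(seed, collection, fraction, replicate), so adding replicates or collections
never perturbs earlier draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra_io import SampleMeta, SpectraDataset, WavelengthGrid

BSA = "BSA"
CREATININE = "creatinine"

#: aliquot volumes (mL) pipetted from the stock into 10 mL flasks for the
#: single-analyte dilution series (fractions 1-12; fraction 13 is the control)
DILUTION_ALIQUOTS_ML = (10.0, 9.0, 8.0, 7.0, 6.0, 5.0, 4.0, 3.0, 2.0, 1.0, 0.5, 0.2)

#: co-spike concentration pairs (BSA mg/L, creatinine mg/L), fractions 1-15
COSPIKE_PAIRS = (
    (500.0, 2000.0),
    (450.0, 1800.0),
    (400.0, 1600.0),
    (350.0, 1050.0),
    (300.0, 900.0),
    (230.0, 1400.0),
    (250.0, 1300.0),
    (211.0, 1100.0),
    (150.0, 780.0),
    (180.0, 625.0),
    (138.0, 481.0),
    (90.0, 312.0),
    (50.0, 100.0),
    (100.0, 200.0),
    (25.0, 75.0),
)


def default_grid(lo: float = 190.0, hi: float = 350.0, step: float = 1.0) -> WavelengthGrid:
    """Simulation wavelength axis, 190-350 nm at 1 nm by default."""
    return WavelengthGrid(np.arange(lo, hi + step / 2, step))


@dataclass(frozen=True)
class DesignTable:
    """Spike concentrations per fraction, with stock provenance when known.

    For dilution series every row satisfies
    ``conc = stock_conc * aliquot / final_volume``; co-spike designs are
    specified directly as concentration pairs and carry no stock record.
    """

    rows: tuple[tuple[int, dict[str, float]], ...]
    stock: dict[str, tuple[float, float]] | None = None  # analyte -> (mass_g, volume_mL)
    aliquots_mL: tuple[float, ...] | None = None
    final_volume_mL: float | None = None

    def __post_init__(self) -> None:
        for _, conc in self.rows:
            for analyte, c in conc.items():
                if c < 0:
                    raise ValueError(f"negative concentration for {analyte!r}")
        if self.stock is not None and self.aliquots_mL is not None:
            for analyte, (mass_g, volume_mL) in self.stock.items():
                stock_conc = stock_concentration_mg_L(mass_g, volume_mL)
                for (_, conc), aliquot in zip(self.rows, self.aliquots_mL):
                    expected = stock_conc * aliquot / self.final_volume_mL
                    if abs(conc[analyte] - expected) > 1e-9 * max(expected, 1.0):
                        raise ValueError(
                            f"row concentration {conc[analyte]} inconsistent with "
                            f"stock dilution ({expected})"
                        )

    @property
    def analytes(self) -> list[str]:
        names: set[str] = set()
        for _, conc in self.rows:
            names.update(conc)
        return sorted(names)

    @property
    def n_fractions(self) -> int:
        return len(self.rows)

    def concentrations(self, analyte: str) -> np.ndarray:
        return np.array([conc.get(analyte, 0.0) for _, conc in self.rows])


def stock_concentration_mg_L(mass_g: float, volume_mL: float) -> float:
    """mg/L of analyte from mass weighed into a urine volume (0.1 g/200 mL -> 500)."""
    if mass_g <= 0 or volume_mL <= 0:
        raise ValueError("stock mass and volume must be positive")
    return mass_g * 1e6 / volume_mL


def build_dilution_series(
    stock_mass_g: float,
    stock_volume_mL: float,
    aliquots_mL: tuple[float, ...] | list[float] = DILUTION_ALIQUOTS_ML,
    final_volume_mL: float = 10.0,
    analyte: str = BSA,
) -> DesignTable:
    """Single-analyte dilution design: one row per aliquot plus a 0 mg/L control.

    Row concentration = stock concentration x aliquot / final volume; with the
    packaged default aliquots and the bench stocks (0.1 g BSA or 0.4 g
    creatinine in 200 mL) this reproduces the study's 13-fraction series.
    """
    if final_volume_mL <= 0:
        raise ValueError("final volume must be positive")
    stock_conc = stock_concentration_mg_L(stock_mass_g, stock_volume_mL)
    aliquots = tuple(float(a) for a in aliquots_mL)
    for a in aliquots:
        if a <= 0:
            raise ValueError("aliquot volumes must be positive")
        if a > final_volume_mL:
            raise ValueError(f"aliquot {a} mL exceeds the {final_volume_mL} mL flask volume")
    rows = [
        (i + 1, {analyte: stock_conc * a / final_volume_mL}) for i, a in enumerate(aliquots)
    ]
    rows.append((len(aliquots) + 1, {analyte: 0.0}))  # control fraction
    return DesignTable(
        rows=tuple(rows),
        stock={analyte: (float(stock_mass_g), float(stock_volume_mL))},
        aliquots_mL=aliquots,
        final_volume_mL=float(final_volume_mL),
    )


def build_cospike_design(
    pairs: tuple[tuple[float, float], ...] | list[tuple[float, float]] = COSPIKE_PAIRS,
) -> DesignTable:
    """Two-analyte co-spike design from (BSA, creatinine) mg/L pairs.

    The packaged default reproduces the study's 15 co-spiked fractions; a
    0:0 control row is always appended as the last fraction.
    """
    rows = []
    for i, (bsa, cr) in enumerate(pairs):
        if bsa < 0 or cr < 0:
            raise ValueError("co-spike concentrations must be >= 0")
        rows.append((i + 1, {BSA: float(bsa), CREATININE: float(cr)}))
    rows.append((len(rows) + 1, {BSA: 0.0, CREATININE: 0.0}))
    return DesignTable(rows=tuple(rows))


@dataclass(frozen=True)
class ComponentSpectrum:
    """Gaussian absorption bands of one mixture component.

    ``bands`` are (center nm, width nm, amplitude AU per mg/L); for the urine
    background the amplitude is interpreted at unit concentration, i.e.
    directly in AU.
    """

    name: str
    bands: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        for center, width, amp in self.bands:
            if width <= 0:
                raise ValueError(f"band width must be > 0 (got {width} at {center} nm)")
            if amp < 0:
                raise ValueError(f"band amplitude must be >= 0 (got {amp} at {center} nm)")


def component_absorbance(cs: ComponentSpectrum, grid: WavelengthGrid, conc_mg_L: float) -> np.ndarray:
    """Beer-Lambert absorbance row: conc x sum of Gaussian bands, linear in conc."""
    if conc_mg_L < 0:
        raise ValueError("concentration must be >= 0")
    lam = grid.values
    out = np.zeros_like(lam)
    for center, width, amp in cs.bands:
        out += amp * np.exp(-((lam - center) ** 2) / (2.0 * width**2))
    return conc_mg_L * out


def default_components() -> dict[str, ComponentSpectrum]:
    """Analyte band models at the observed peak positions.

    BSA: strong peptide-bond band at 217 nm with a tryptophan shoulder at
    229 nm and the aromatic 280 nm band. Creatinine: bands at 219, 229 and
    248.5 nm. Widths (4-8 nm) make the 229/249 nm features overlap.
    Amplitudes put the analyte contribution at roughly 0.4-0.5 AU at the top
    of each design range — well below the urine matrix absorbance, as in
    real far-UV urine spectra — so the whole spectrum tops out near 2 AU.
    """
    return {
        BSA: ComponentSpectrum(
            BSA,
            bands=(
                (217.0, 6.0, 1.0e-3),
                (229.0, 5.0, 4.0e-4),
                (280.0, 8.0, 2.5e-4),
            ),
        ),
        CREATININE: ComponentSpectrum(
            CREATININE,
            bands=(
                (219.0, 5.0, 2.0e-4),
                (229.0, 5.0, 1.5e-4),
                (248.5, 6.0, 1.8e-4),
            ),
        ),
    }


def default_urine_background() -> ComponentSpectrum:
    """Unspiked-urine absorbance: characteristic bands at 230 and 248 nm (AU).

    The matrix (urea, endogenous creatinine, uric acid, ...) dominates the
    far-UV absorbance of urine, so its bands are several times larger than
    any single spiked-analyte contribution.
    """
    return ComponentSpectrum(
        "urine_background",
        bands=(
            (230.0, 10.0, 1.2),
            (248.0, 8.0, 0.8),
        ),
    )


@dataclass(frozen=True)
class NoiseModel:
    """Instrumental noise parameters.

    * ``additive_sd`` — white detector noise, AU.
    * ``pathlength_sd`` — log-normal sigma of the per-replicate multiplicative
      path-length factor (the auto-ranging path length varies between drops).
    * ``baseline_drift`` — (max |slope| AU/nm, max |offset| AU) of a linear
      baseline drawn uniformly per replicate.
    """

    additive_sd: float = 0.005
    pathlength_sd: float = 0.05
    baseline_drift: tuple[float, float] = (1e-4, 0.02)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.additive_sd < 0 or self.pathlength_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.baseline_drift[0] < 0 or self.baseline_drift[1] < 0:
            raise ValueError("drift bounds must be >= 0")


def _replicate_rng(seed: int, collection: int, fraction: int, replicate: int) -> np.random.Generator:
    # independent stream per (collection, fraction, replicate); adding
    # replicates or collections never perturbs earlier draws
    return np.random.default_rng([seed, collection, fraction, replicate])


def _noisy_row(
    clean: np.ndarray, grid: WavelengthGrid, noise: NoiseModel, rng: np.random.Generator
) -> np.ndarray:
    pathfactor = float(np.exp(rng.normal(0.0, noise.pathlength_sd))) if noise.pathlength_sd > 0 else 1.0
    max_slope, max_offset = noise.baseline_drift
    slope = rng.uniform(-max_slope, max_slope) if max_slope > 0 else 0.0
    offset = rng.uniform(-max_offset, max_offset) if max_offset > 0 else 0.0
    drift = slope * (grid.values - grid.values[0]) + offset
    row = pathfactor * (clean + drift)
    if noise.additive_sd > 0:
        row = row + rng.normal(0.0, noise.additive_sd, size=len(grid))
    return row


def simulate_dataset(
    design: DesignTable,
    components: dict[str, ComponentSpectrum] | None = None,
    urine_background: ComponentSpectrum | None = None,
    noise: NoiseModel | None = None,
    n_collections: int = 3,
    n_replicates: int = 3,
    grid: WavelengthGrid | None = None,
    n_calibration_collections: int = 2,
) -> SpectraDataset:
    """Simulate spectra for every (collection, fraction, replicate) of a design.

    Each row is ``pathfactor * (background + sum_analytes conc * bands + drift)
    + additive noise``; with all noise terms zero the rows are exact
    Beer-Lambert sums. Metadata carry the true concentrations; the first
    ``n_calibration_collections`` urine collections are labeled calibration,
    the rest validation, and all-zero control fractions are labeled blank.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if n_collections < 1:
        raise ValueError("n_collections must be >= 1")
    components = default_components() if components is None else components
    urine_background = default_urine_background() if urine_background is None else urine_background
    noise = NoiseModel() if noise is None else noise
    grid = default_grid() if grid is None else grid

    missing = [a for a in design.analytes if a not in components]
    if missing:
        raise ValueError(f"design analytes without a component spectrum: {missing}")

    background = component_absorbance(urine_background, grid, 1.0)
    rows: list[np.ndarray] = []
    meta: list[SampleMeta] = []
    for ci in range(1, n_collections + 1):
        collection_id = f"day{ci}"
        base_role = "calibration" if ci <= n_calibration_collections else "validation"
        for fraction_index, conc in design.rows:
            clean = background.copy()
            for analyte, c in conc.items():
                clean += component_absorbance(components[analyte], grid, c)
            is_blank = all(c == 0 for c in conc.values())
            role = "blank" if is_blank else base_role
            for ri in range(1, n_replicates + 1):
                rng = _replicate_rng(noise.seed, ci, fraction_index, ri)
                rows.append(_noisy_row(clean, grid, noise, rng))
                meta.append(
                    SampleMeta(
                        sample_id=f"{collection_id}_f{fraction_index:02d}_r{ri}",
                        urine_collection_id=collection_id,
                        fraction_index=fraction_index,
                        replicate_index=ri,
                        conc=dict(conc),
                        role=role,
                    )
                )
    return SpectraDataset(grid, np.vstack(rows), meta)


def simulate_blanks(
    n: int,
    urine_background: ComponentSpectrum | None = None,
    noise: NoiseModel | None = None,
    seed: int | None = None,
    grid: WavelengthGrid | None = None,
    analytes: tuple[str, ...] = (BSA, CREATININE),
) -> SpectraDataset:
    """``n`` background-only spectra (role=blank, all concentrations 0).

    At least 2 are required — a single blank leaves the downstream blank SD
    undefined.
    """
    if n < 2:
        raise ValueError("need at least 2 blanks (SD undefined otherwise)")
    urine_background = default_urine_background() if urine_background is None else urine_background
    noise = NoiseModel() if noise is None else noise
    grid = default_grid() if grid is None else grid
    use_seed = noise.seed if seed is None else seed
    background = component_absorbance(urine_background, grid, 1.0)
    rows = []
    meta = []
    for i in range(1, n + 1):
        rng = _replicate_rng(use_seed, 0, 0, i)
        rows.append(_noisy_row(background, grid, noise, rng))
        meta.append(
            SampleMeta(
                sample_id=f"blank_{i:04d}",
                urine_collection_id="blank",
                fraction_index=0,
                replicate_index=i,
                conc={a: 0.0 for a in analytes},
                role="blank",
            )
        )
    return SpectraDataset(grid, np.vstack(rows), meta)
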