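"""Tabular I/O and validation for UV/Vis spectra datasets.

A dataset couples a wavelength grid (nm) with one absorbance row per sample
and per-sample metadata: which urine collection (day) the sample came from,
which fraction of the spiking design it is, its technical-replicate index,
the spiked concentrations (mg/L), and its modeling role (calibration,
validation, or blank).

Two plain-CSV exchange layouts are supported:

* ``wide``  — row 1 is ``wavelength_nm`` plus one column per sample; the
  metadata travel in ``#meta:``-prefixed header rows (one per field, plus one
  ``#meta:conc:<analyte>`` row per analyte); the numeric block follows, one
  row per wavelength.
* ``long``  — one record per (sample, wavelength) with metadata repeated on
  every record.

Floats are serialized with 17 significant digits so a write/read cycle is
lossless.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

VALID_ROLES = ("calibration", "validation", "blank")

_META_PREFIX = "#meta:"
_CONC_PREFIX = "conc:"
_FLOAT_FMT = "%.17g"


def _fmt(x: float) -> str:
    return _FLOAT_FMT % float(x)


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelength axis in nm."""

    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.size < 2:
            raise ValueError("wavelength grid needs at least 2 values")
        if not np.all(vals > 0):
            raise ValueError("wavelengths must be positive")
        if not np.all(np.diff(vals) > 0):
            raise ValueError("wavelengths must be strictly increasing")

    def __len__(self) -> int:
        return int(self.values.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(np.all(self.values == other.values))


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata.

    ``conc`` maps analyte name to spiked concentration in mg/L (0 allowed);
    the key (``urine_collection_id``, ``fraction_index``, ``replicate_index``)
    must be unique within a dataset.
    """

    sample_id: str
    urine_collection_id: str
    fraction_index: int
    replicate_index: int
    conc: dict[str, float] = field(default_factory=dict)
    role: str = "calibration"

    def __post_init__(self) -> None:
        if self.role not in VALID_ROLES:
            raise ValueError(f"role must be one of {VALID_ROLES}, got {self.role!r}")
        if self.replicate_index < 1:
            raise ValueError("replicate_index must be >= 1")
        for analyte, c in self.conc.items():
            if not np.isfinite(c) or c < 0:
                raise ValueError(f"concentration of {analyte!r} must be finite and >= 0")

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.urine_collection_id, self.fraction_index, self.replicate_index)


class SpectraDataset:
    """Wavelength grid + absorbance matrix + aligned sample metadata.

    ``absorbance`` has one row per sample (the calibration/test matrices of a
    multivariate calibration, samples x wavelengths) and must be finite.
    """

    def __init__(self, grid: WavelengthGrid, absorbance: np.ndarray, meta: Sequence[SampleMeta]):
        ab = np.atleast_2d(np.asarray(absorbance, dtype=float))
        if len(meta) == 0:
            ab = ab.reshape(0, len(grid))
        if ab.shape[0] != len(meta):
            raise ValueError(f"absorbance has {ab.shape[0]} rows but {len(meta)} metadata entries")
        if ab.shape[1] != len(grid):
            raise ValueError(f"absorbance rows have {ab.shape[1]} values but grid has {len(grid)}")
        if ab.size and not np.all(np.isfinite(ab)):
            raise ValueError("absorbance values must be finite")
        keys = [m.key for m in meta]
        if len(set(keys)) != len(keys):
            dupes = {k for k in keys if keys.count(k) > 1}
            raise ValueError(f"duplicate (collection, fraction, replicate) keys: {sorted(dupes)}")
        self.grid = grid
        self.absorbance = ab
        self.meta = list(meta)

    @property
    def n_samples(self) -> int:
        return len(self.meta)

    @property
    def analytes(self) -> list[str]:
        names: set[str] = set()
        for m in self.meta:
            names.update(m.conc)
        return sorted(names)

    def concentrations(self, analyte: str) -> np.ndarray:
        """Vector of spiked concentrations (mg/L) for one analyte, 0 if absent."""
        return np.array([m.conc.get(analyte, 0.0) for m in self.meta], dtype=float)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectraDataset):
            return NotImplemented
        return (
            self.grid == other.grid
            and self.absorbance.shape == other.absorbance.shape
            and bool(np.all(self.absorbance == other.absorbance))
            and self.meta == other.meta
        )

    def __repr__(self) -> str:
        return (
            f"SpectraDataset({self.n_samples} samples x {len(self.grid)} wavelengths, "
            f"analytes={self.analytes})"
        )


def subset(ds: SpectraDataset, predicate: Callable[[SampleMeta], bool]) -> SpectraDataset:
    """Rows whose metadata satisfy ``predicate``, in the original order.

    The grid is unchanged; an empty selection is allowed (0-sample dataset).
    """
    idx = [i for i, m in enumerate(ds.meta) if predicate(m)]
    return SpectraDataset(ds.grid, ds.absorbance[idx], [ds.meta[i] for i in idx])


# ---------------------------------------------------------------------------
# wide layout
# ---------------------------------------------------------------------------

def _write_wide(ds: SpectraDataset, fh: io.TextIOBase) -> None:
    w = csv.writer(fh, lineterminator="\n")
    ids = [m.sample_id for m in ds.meta]
    w.writerow(["wavelength_nm", *ids])
    w.writerow([f"{_META_PREFIX}sample_id", *ids])
    w.writerow([f"{_META_PREFIX}urine_collection_id", *[m.urine_collection_id for m in ds.meta]])
    w.writerow([f"{_META_PREFIX}fraction_index", *[str(m.fraction_index) for m in ds.meta]])
    w.writerow([f"{_META_PREFIX}replicate_index", *[str(m.replicate_index) for m in ds.meta]])
    w.writerow([f"{_META_PREFIX}role", *[m.role for m in ds.meta]])
    for analyte in ds.analytes:
        w.writerow(
            [f"{_META_PREFIX}{_CONC_PREFIX}{analyte}", *[_fmt(m.conc.get(analyte, 0.0)) for m in ds.meta]]
        )
    for j, lam in enumerate(ds.grid.values):
        w.writerow([_fmt(lam), *[_fmt(v) for v in ds.absorbance[:, j]]])


def _parse_float(token: str, what: str) -> float:
    try:
        return float(token)
    except ValueError as exc:
        raise ValueError(f"non-numeric {what}: {token!r}") from exc


def _read_wide(rows: list[list[str]]) -> SpectraDataset:
    if not rows:
        raise ValueError("empty spectra file")
    header = rows[0]
    if not header or header[0] != "wavelength_nm":
        raise ValueError("wide layout must start with a 'wavelength_nm' header row")
    n = len(header) - 1
    meta_rows: dict[str, list[str]] = {}
    data_start = 1
    for r in rows[1:]:
        if r and r[0].startswith(_META_PREFIX):
            if len(r) - 1 != n:
                raise ValueError(f"ragged metadata row {r[0]!r}: {len(r) - 1} values for {n} samples")
            meta_rows[r[0][len(_META_PREFIX):]] = r[1:]
            data_start += 1
        else:
            break
    required = ["sample_id", "urine_collection_id", "fraction_index", "replicate_index", "role"]
    missing = [k for k in required if k not in meta_rows]
    if missing:
        raise ValueError(f"missing metadata rows: {missing}")
    conc_keys = sorted(k for k in meta_rows if k.startswith(_CONC_PREFIX))

    meta: list[SampleMeta] = []
    for i in range(n):
        conc = {
            k[len(_CONC_PREFIX):]: _parse_float(meta_rows[k][i], f"concentration {k!r}")
            for k in conc_keys
        }
        meta.append(
            SampleMeta(
                sample_id=meta_rows["sample_id"][i],
                urine_collection_id=meta_rows["urine_collection_id"][i],
                fraction_index=int(meta_rows["fraction_index"][i]),
                replicate_index=int(meta_rows["replicate_index"][i]),
                conc=conc,
                role=meta_rows["role"][i],
            )
        )

    wavelengths: list[float] = []
    cols: list[list[float]] = []
    for r in rows[data_start:]:
        if not r or (len(r) == 1 and not r[0].strip()):
            continue
        if len(r) - 1 != n:
            raise ValueError(f"ragged data row at wavelength {r[0]!r}: {len(r) - 1} values for {n} samples")
        wavelengths.append(_parse_float(r[0], "wavelength"))
        cols.append([_parse_float(v, "absorbance") for v in r[1:]])
    grid_vals = np.array(wavelengths, dtype=float)
    ab = np.array(cols, dtype=float).reshape(len(wavelengths), n).T
    order = np.argsort(grid_vals, kind="stable")
    return SpectraDataset(WavelengthGrid(grid_vals[order]), ab[:, order], meta)


# ---------------------------------------------------------------------------
# long layout
# ---------------------------------------------------------------------------

def _write_long(ds: SpectraDataset, fh: io.TextIOBase) -> None:
    w = csv.writer(fh, lineterminator="\n")
    analytes = ds.analytes
    w.writerow(
        ["sample_id", "urine_collection_id", "fraction_index", "replicate_index", "role"]
        + [f"{_CONC_PREFIX}{a}" for a in analytes]
        + ["wavelength_nm", "absorbance"]
    )
    for i, m in enumerate(ds.meta):
        base = [m.sample_id, m.urine_collection_id, str(m.fraction_index), str(m.replicate_index), m.role]
        base += [_fmt(m.conc.get(a, 0.0)) for a in analytes]
        for j, lam in enumerate(ds.grid.values):
            w.writerow(base + [_fmt(lam), _fmt(ds.absorbance[i, j])])


def _read_long(rows: list[list[str]]) -> SpectraDataset:
    if not rows:
        raise ValueError("empty spectra file")
    header = rows[0]
    required = ["sample_id", "urine_collection_id", "fraction_index", "replicate_index", "role",
                "wavelength_nm", "absorbance"]
    missing = [c for c in required if c not in header]
    if missing:
        raise ValueError(f"missing columns in long layout: {missing}")
    col = {name: header.index(name) for name in header}
    conc_cols = [c for c in header if c.startswith(_CONC_PREFIX)]

    records: dict[str, dict] = {}
    order: list[str] = []
    for r in rows[1:]:
        if not r or (len(r) == 1 and not r[0].strip()):
            continue
        if len(r) != len(header):
            raise ValueError(f"ragged record: {len(r)} fields for {len(header)} columns")
        sid = r[col["sample_id"]]
        if sid not in records:
            order.append(sid)
            records[sid] = {
                "meta": SampleMeta(
                    sample_id=sid,
                    urine_collection_id=r[col["urine_collection_id"]],
                    fraction_index=int(r[col["fraction_index"]]),
                    replicate_index=int(r[col["replicate_index"]]),
                    conc={c[len(_CONC_PREFIX):]: _parse_float(r[col[c]], c) for c in conc_cols},
                    role=r[col["role"]],
                ),
                "points": {},
            }
        lam = _parse_float(r[col["wavelength_nm"]], "wavelength")
        records[sid]["points"][lam] = _parse_float(r[col["absorbance"]], "absorbance")

    if not order:
        raise ValueError("long layout with zero records has no wavelength grid")
    grids = [tuple(sorted(records[sid]["points"])) for sid in order]
    if len(set(grids)) != 1:
        raise ValueError("samples in long layout disagree on the wavelength grid")
    grid = WavelengthGrid(np.array(grids[0], dtype=float))
    ab = np.array([[records[sid]["points"][lam] for lam in grid.values] for sid in order])
    return SpectraDataset(grid, ab, [records[sid]["meta"] for sid in order])


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def write_spectra(ds: SpectraDataset, path: str | Path, layout: str = "wide") -> None:
    """Serialize a dataset to CSV; ``layout`` is ``wide`` (default) or ``long``."""
    if layout not in ("wide", "long"):
        raise ValueError(f"unknown layout {layout!r}")
    with open(path, "w", newline="") as fh:
        (_write_wide if layout == "wide" else _write_long)(ds, fh)


def read_spectra(path: str | Path, layout: str = "wide") -> SpectraDataset:
    """Parse and validate a CSV spectra file written by :func:`write_spectra`.

    Wavelength order is normalized to strictly increasing; duplicate sample
    keys, ragged rows, and non-numeric values are rejected.
    """
    if layout not in ("wide", "long"):
        raise ValueError(f"unknown layout {layout!r}")
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh)]
    return (_read_wide if layout == "wide" else _read_long)(rows)
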