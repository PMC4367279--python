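"""Readers and writers for the package's plain-text formats.

Conventions: comma-separated files for kinetic traces, 1D spectra and
dephasing curves; tab-separated files for shift tables and 2D peak lists.
'#'-prefixed comment lines are permitted everywhere and are used to carry a
provenance header (package version and random seed) on every file written.
"""
from __future__ import annotations

import io as _io
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import (
    DuplicateKeyError,
    EmptyTableError,
    FormatError,
    SizeError,
)
from .types import (
    MIN_FIT_POINTS,
    KNOWN_ATOMS,
    DephasingCurve,
    KineticTrace,
    Peak2D,
    PeakList2D,
    ShiftEntry,
    ShiftTable,
    Spectrum1D,
    canonical_atom,
)

logger = logging.getLogger("fibrilstack.io")

_FLOAT_FMT = "%.17g"


def _provenance(seed: int | None) -> str:
    lines = [f"# fibrilstack {__version__}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    return "\n".join(lines) + "\n"


def _read_table(path, sep: str, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=sep, comment="#", skip_blank_lines=True,
                         float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise EmptyTableError(f"{path} contains no data rows") from None
    except OSError as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    df.columns = [str(c).strip() for c in df.columns]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path} is missing required column {col!r}")
    return df


def _numeric(df: pd.DataFrame, cols: list[str], path) -> pd.DataFrame:
    """Coerce columns to float, dropping (and reporting) non-numeric rows."""
    coerced = df.copy()
    for col in cols:
        coerced[col] = pd.to_numeric(coerced[col], errors="coerce")
    bad = coerced[cols].isna().any(axis=1)
    if bad.any():
        rows = [int(i) for i in coerced.index[bad]]
        logger.warning("%s: dropped %d non-numeric row(s) at index %s", path, len(rows), rows)
    return coerced[~bad]


# ---------------------------------------------------------------------------
# kinetic traces (CSV)

def read_trace(path, time_col: str = "time", signal_col: str = "signal") -> KineticTrace:
    """Read a kinetic trace from a CSV file with a header row.

    Rows with non-numeric cells are rejected with their index reported via
    the package logger.  Fewer than 5 usable rows is a size error.
    """
    df = _read_table(path, ",", [time_col, signal_col])
    df = _numeric(df, [time_col, signal_col], path)
    if len(df) < MIN_FIT_POINTS:
        raise SizeError(
            f"{path} has {len(df)} usable rows; at least {MIN_FIT_POINTS} required"
        )
    return KineticTrace(df[time_col].to_numpy(), df[signal_col].to_numpy(),
                        label=str(Path(path).stem))


def write_trace(trace: KineticTrace, path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(seed))
        fh.write("time,signal\n")
        for t, y in zip(trace.time, trace.signal):
            fh.write(f"{t:.17g},{y:.17g}\n")


# ---------------------------------------------------------------------------
# 1D spectra (CSV)

def read_spectrum(path, kind: str = "emission",
                  wavelength_col: str = "wavelength",
                  intensity_col: str = "intensity") -> Spectrum1D:
    df = _read_table(path, ",", [wavelength_col, intensity_col])
    df = _numeric(df, [wavelength_col, intensity_col], path)
    if df.empty:
        raise EmptyTableError(f"{path} has no numeric rows")
    return Spectrum1D(df[wavelength_col].to_numpy(), df[intensity_col].to_numpy(), kind=kind)


def write_spectrum(spectrum: Spectrum1D, path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(seed))
        fh.write(f"# kind={spectrum.kind}\n")
        fh.write("wavelength,intensity\n")
        for w, y in zip(spectrum.wavelength, spectrum.intensity):
            fh.write(f"{w:.17g},{y:.17g}\n")


# ---------------------------------------------------------------------------
# dephasing curves (CSV)

def read_dephasing(path) -> DephasingCurve:
    df = _read_table(path, ",", ["time_ms", "s_ratio"])
    noise = 0.0
    with open(path) as fh:
        for line in fh:
            if line.startswith("# noise_sigma="):
                noise = float(line.split("=", 1)[1])
    df = _numeric(df, ["time_ms", "s_ratio"], path)
    if df.empty:
        raise EmptyTableError(f"{path} has no numeric rows")
    return DephasingCurve(df["time_ms"].to_numpy(), df["s_ratio"].to_numpy(), noise_sigma=noise)


def write_dephasing(curve: DephasingCurve, path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(seed))
        fh.write(f"# noise_sigma={curve.noise_sigma:.17g}\n")
        fh.write("time_ms,s_ratio\n")
        for t, s in zip(curve.time, curve.s_ratio):
            fh.write(f"{t:.17g},{s:.17g}\n")


# ---------------------------------------------------------------------------
# shift tables (TSV)

def read_shift_table(path) -> ShiftTable:
    """Read a per-residue ¹³C shift table from TSV.

    Expected columns: residue, number, atom, shift_ppm.  Rows whose atom
    name is outside the known carbon vocabulary are skipped with a logged
    warning and count; duplicate (number, atom) keys raise.
    """
    df = _read_table(path, "\t", ["residue", "number", "atom", "shift_ppm"])
    df = _numeric(df, ["number", "shift_ppm"], path)
    entries: list[ShiftEntry] = []
    skipped = 0
    for _, row in df.iterrows():
        atom = canonical_atom(str(row["atom"]))
        if atom not in KNOWN_ATOMS:
            skipped += 1
            logger.warning("%s: skipping unknown atom %r for residue %s%d",
                           path, str(row["atom"]), row["residue"], int(row["number"]))
            continue
        entries.append(ShiftEntry(str(row["residue"]).strip(), int(row["number"]),
                                  atom, float(row["shift_ppm"])))
    if skipped:
        logger.warning("%s: %d row(s) skipped for unknown atom names", path, skipped)
    if not entries:
        raise EmptyTableError(f"{path} yields an empty shift table")
    return ShiftTable(entries)


def write_shift_table(table: ShiftTable, path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(seed))
        fh.write("residue\tnumber\tatom\tshift_ppm\n")
        for e in table:
            fh.write(f"{e.residue}\t{e.number}\t{e.atom}\t{e.shift:.17g}\n")


# ---------------------------------------------------------------------------
# 2D peak lists (TSV)

def read_peaklist(path, window: tuple[float, float] | None = None) -> PeakList2D:
    """Read a 2D peak list.  Peaks outside a declared ppm window are kept
    but reported with a warning; negative intensities are a format error."""
    df = _read_table(path, "\t", ["ppm_direct", "ppm_indirect", "intensity"])
    df = _numeric(df, ["ppm_direct", "ppm_indirect", "intensity"], path)
    peaks = []
    for _, row in df.iterrows():
        if row["intensity"] < 0:
            raise FormatError(f"{path}: negative intensity {row['intensity']}")
        assignment = str(row["assignment"]) if "assignment" in df.columns and not pd.isna(row.get("assignment")) else ""
        p = Peak2D(float(row["ppm_direct"]), float(row["ppm_indirect"]),
                   float(row["intensity"]), assignment)
        if window is not None and not (
            window[0] <= p.ppm_direct <= window[1] and window[0] <= p.ppm_indirect <= window[1]
        ):
            warnings.warn(
                f"peak at ({p.ppm_direct}, {p.ppm_indirect}) outside declared "
                f"window {window}; kept", stacklevel=2)
        peaks.append(p)
    return PeakList2D(peaks, window=window)


def write_peaklist(peaklist: PeakList2D, path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(seed))
        if peaklist.window is not None:
            fh.write(f"# window={peaklist.window[0]:.17g},{peaklist.window[1]:.17g}\n")
        fh.write("ppm_direct\tppm_indirect\tintensity\tassignment\n")
        for p in peaklist:
            fh.write(f"{p.ppm_direct:.17g}\t{p.ppm_indirect:.17g}\t"
                     f"{p.intensity:.17g}\t{p.assignment}\n")
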