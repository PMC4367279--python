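"""Domain containers shared across the analysis stages.

All containers are lightweight frozen-ish dataclasses around numpy arrays
with eager validation: a constructed object always satisfies its invariants.
Axes are stored ascending; the NMR display convention (ppm decreasing to the
right) is a rendering concern only.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    DomainError,
    DuplicateKeyError,
    EmptyTableError,
    FormatError,
    SizeError,
)

#: Minimum number of points required before any curve fit is attempted.
MIN_FIT_POINTS = 5

#: Carbon atom names accepted in shift tables.  "C'" is the backbone
#: carbonyl (aliases "C" and "CO" are canonicalised on input).
KNOWN_ATOMS = frozenset({
    "C'", "CA", "CB",
    "CG", "CG1", "CG2",
    "CD", "CD1", "CD2",
    "CE", "CE1", "CE2", "CE3",
    "CZ", "CZ2", "CZ3",
    "CH2",
})

_ATOM_ALIASES = {"C": "C'", "CO": "C'"}


def canonical_atom(name: str) -> str:
    """Map atom-name aliases (C, CO) onto the canonical vocabulary."""
    name = name.strip().upper()
    return _ATOM_ALIASES.get(name, name)


def _as_1d(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise FormatError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise FormatError(f"{name} contains non-finite values")
    return arr


def _check_strictly_increasing(arr: np.ndarray, name: str) -> None:
    bad = np.nonzero(np.diff(arr) <= 0)[0]
    if bad.size:
        raise FormatError(
            f"{name} must be strictly increasing; first out-of-order row is "
            f"index {int(bad[0]) + 1} (value {arr[bad[0] + 1]!r})"
        )


@dataclass
class KineticTrace:
    """Time-stamped fluorescence signal from an aggregation assay.

    time is in hours, signal in relative fluorescence units (RFU).
    """

    time: np.ndarray
    signal: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.time = _as_1d(self.time, "time")
        self.signal = _as_1d(self.signal, "signal")
        if self.time.size != self.signal.size:
            raise FormatError(
                f"time and signal lengths differ ({self.time.size} vs {self.signal.size})"
            )
        _check_strictly_increasing(self.time, "time")

    def __len__(self) -> int:
        return int(self.time.size)

    def window(self, t_min: float | None = None, t_max: float | None = None) -> "KineticTrace":
        """Restrict the trace to a closed time window."""
        mask = np.ones(len(self), dtype=bool)
        if t_min is not None:
            mask &= self.time >= t_min
        if t_max is not None:
            mask &= self.time <= t_max
        if mask.sum() < MIN_FIT_POINTS:
            raise SizeError(
                f"window [{t_min}, {t_max}] keeps {int(mask.sum())} points; "
                f"at least {MIN_FIT_POINTS} required"
            )
        return KineticTrace(self.time[mask], self.signal[mask], self.label)


@dataclass
class Spectrum1D:
    """Sampled 1D spectrum on a strictly increasing wavelength grid (nm).

    kind is "emission" (tryptophan fluorescence, RFU) or "cd" (far-UV
    circular dichroism, mdeg or Δε — a documented linear scaling).
    """

    wavelength: np.ndarray
    intensity: np.ndarray
    kind: str = "emission"

    def __post_init__(self):
        self.wavelength = _as_1d(self.wavelength, "wavelength")
        self.intensity = _as_1d(self.intensity, "intensity")
        if self.wavelength.size != self.intensity.size:
            raise FormatError("wavelength and intensity lengths differ")
        _check_strictly_increasing(self.wavelength, "wavelength")
        if self.kind not in ("emission", "cd"):
            raise FormatError(f"kind must be 'emission' or 'cd', got {self.kind!r}")

    def __len__(self) -> int:
        return int(self.wavelength.size)


@dataclass(frozen=True)
class ShiftEntry:
    """One per-residue, per-atom ¹³C chemical shift in ppm."""

    residue: str
    number: int
    atom: str
    shift: float

    def __post_init__(self):
        object.__setattr__(self, "atom", canonical_atom(self.atom))
        if not (0.0 <= self.shift <= 220.0):
            raise DomainError(
                f"shift {self.shift} ppm for {self.residue}{self.number} {self.atom} "
                "outside the 0-220 ppm carbon range"
            )
        if self.number < 1:
            raise DomainError("residue numbering is 1-based")


@dataclass
class ShiftTable:
    """Collection of ¹³C shifts keyed uniquely by (residue number, atom)."""

    entries: list[ShiftEntry]

    def __post_init__(self):
        self.entries = list(self.entries)
        if not self.entries:
            raise EmptyTableError("shift table has no entries")
        seen: set[tuple[int, str]] = set()
        for e in self.entries:
            key = (e.number, e.atom)
            if key in seen:
                raise DuplicateKeyError(f"duplicate (residue, atom) key {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def get(self, number: int, atom: str) -> ShiftEntry | None:
        atom = canonical_atom(atom)
        for e in self.entries:
            if e.number == number and e.atom == atom:
                return e
        return None

    def in_window(self, lo: float, hi: float) -> list[ShiftEntry]:
        """Entries whose shift lies in the closed ppm interval [lo, hi]."""
        return [e for e in self.entries if lo <= e.shift <= hi]

    def residue_numbers(self) -> list[int]:
        return sorted({e.number for e in self.entries})


@dataclass(frozen=True)
class Peak2D:
    """A single 2D cross- or diagonal peak (ppm_direct, ppm_indirect)."""

    ppm_direct: float
    ppm_indirect: float
    intensity: float
    assignment: str = ""

    def __post_init__(self):
        if self.intensity < 0:
            raise FormatError(
                f"peak at ({self.ppm_direct}, {self.ppm_indirect}) has negative intensity"
            )


@dataclass
class PeakList2D:
    """Ordered list of 2D peaks, optionally carrying a declared ppm window."""

    peaks: list[Peak2D]
    window: tuple[float, float] | None = None

    def __post_init__(self):
        self.peaks = list(self.peaks)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)


@dataclass
class DephasingCurve:
    """REDOR S/S₀ dephasing ratios against dephasing time in ms.

    s_ratio is the dephased/full echo intensity ratio (the observable the
    experiment calls S_D); noise permits values slightly outside [0, 1].
    """

    time: np.ndarray
    s_ratio: np.ndarray
    noise_sigma: float = 0.0

    def __post_init__(self):
        self.time = _as_1d(self.time, "time")
        self.s_ratio = _as_1d(self.s_ratio, "s_ratio")
        if self.time.size != self.s_ratio.size:
            raise FormatError("time and s_ratio lengths differ")
        if np.any(self.time <= 0):
            raise DomainError("dephasing times must be positive")
        _check_strictly_increasing(self.time, "time")
        if np.any(self.s_ratio < -0.2) or np.any(self.s_ratio > 1.2):
            raise DomainError("s_ratio outside the plausible [-0.2, 1.2] band")
        if self.noise_sigma < 0:
            raise DomainError("noise_sigma must be non-negative")

    def __len__(self) -> int:
        return int(self.time.size)


@dataclass
class Spectrum2D:
    """Simulated 2D ¹³C–¹³C correlation spectrum on a ppm × ppm grid.

    intensity[i, j] is the magnitude at (ppm_indirect[i], ppm_direct[j]);
    both axes are stored ascending.
    """

    intensity: np.ndarray
    ppm_direct: np.ndarray
    ppm_indirect: np.ndarray
    linewidth: float
    window: tuple[float, float]

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.ppm_direct = _as_1d(self.ppm_direct, "ppm_direct")
        self.ppm_indirect = _as_1d(self.ppm_indirect, "ppm_indirect")
        if self.intensity.shape != (self.ppm_indirect.size, self.ppm_direct.size):
            raise FormatError(
                f"intensity shape {self.intensity.shape} does not match axes "
                f"({self.ppm_indirect.size}, {self.ppm_direct.size})"
            )
        if not np.all(np.isfinite(self.intensity)):
            raise FormatError("intensity matrix contains non-finite values")

    @property
    def grid_spacing(self) -> float:
        return float(self.ppm_direct[1] - self.ppm_direct[0])


@dataclass
class AnalysisConfig:
    """Shared numerical configuration; the seed is stamped into outputs."""

    spectral_window: tuple[float, float] = (0.0, 200.0)
    grid_points: int = 512
    linewidth: float = 0.8
    seed: int = 0
    peak_threshold: float = 0.05

    def __post_init__(self):
        lo, hi = self.spectral_window
        if not hi > lo:
            raise DomainError("spectral window must have positive extent")
        if self.grid_points <= 0 or self.linewidth <= 0:
            raise DomainError("grid_points and linewidth must be positive")
        if not (0 < self.peak_threshold < 1):
            raise DomainError("peak_threshold must lie in (0, 1)")
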