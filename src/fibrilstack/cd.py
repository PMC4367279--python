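"""Secondary-structure estimation from far-UV CD spectra.

A CD spectrum is modelled as a convex combination of per-class basis
spectra (helix, sheet, turn, coil).  Fractions are obtained by exact
constrained least squares on the probability simplex (f >= 0, sum f = 1),
solved by enumerating active sets — exact for the small class counts used
here.  Across several candidate basis sets the fit with the lowest
normalized spectral fit S.D. (RMS residual / RMS signal) is selected; fits
with S.D. above 0.07 are flagged as poor.

The packaged default basis is synthetic: analytic sums of Gaussian bands at
the conventional far-UV CD band positions (helix minima near 208/222 nm and
maximum near 192 nm; sheet minimum near 218 nm and maximum near 196 nm;
coil minimum near 198 nm; a weak broad turn band).  It is a transparent
stand-in for proprietary reference basis sets and is intended for forward
modelling and round-trip analysis, not for quantitating real spectra.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .errors import DomainError, GridError
from .types import Spectrum1D

#: Normalized spectral-fit S.D. above which a fit is flagged as poor.
POOR_FIT_SD = 0.07

CLASSES = ("helix", "sheet", "turn", "coil")


@dataclass
class BasisSet:
    """Named set of per-class CD basis spectra on a shared wavelength grid."""

    classes: tuple[str, ...]
    spectra: dict[str, Spectrum1D]
    name: str = "basis"

    def __post_init__(self):
        self.classes = tuple(self.classes)
        if len(self.classes) < 2:
            raise DomainError("a basis set needs at least 2 classes")
        grids = [self.spectra[c].wavelength for c in self.classes]
        for g in grids[1:]:
            if g.size != grids[0].size or not np.allclose(g, grids[0]):
                raise GridError("all basis spectra must share one wavelength grid")

    @property
    def wavelength(self) -> np.ndarray:
        return self.spectra[self.classes[0]].wavelength

    def matrix_on(self, grid: np.ndarray) -> np.ndarray:
        """Basis spectra linearly interpolated onto `grid`, as columns.

        Extrapolation is forbidden: `grid` must lie within the basis range.
        """
        w = self.wavelength
        if grid.min() < w.min() - 1e-9 or grid.max() > w.max() + 1e-9:
            raise GridError(
                f"spectrum grid [{grid.min():g}, {grid.max():g}] nm extends outside "
                f"the basis range [{w.min():g}, {w.max():g}] nm")
        return np.column_stack([
            np.interp(grid, w, self.spectra[c].intensity) for c in self.classes
        ])


@dataclass
class SSFractions:
    """Secondary-structure fractions with the fit's normalized S.D."""

    fractions: dict[str, float]
    fit_sd: float
    basis_name: str = ""
    poor_fit: bool = False
    tie: bool = False

    def __post_init__(self):
        vals = np.array(list(self.fractions.values()))
        if np.any(vals < -1e-12):
            raise DomainError("fractions must be non-negative")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise DomainError(f"fractions must sum to 1, got {vals.sum()!r}")
        if self.fit_sd < 0:
            raise DomainError("fit_sd must be non-negative")

    def as_array(self, classes) -> np.ndarray:
        return np.array([self.fractions.get(c, 0.0) for c in classes])


def _simplex_lstsq(B: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Exact min ||y - B f||² s.t. f >= 0, sum f = 1, by active-set enumeration."""
    k = B.shape[1]
    best_f, best_obj = None, np.inf
    for size in range(1, k + 1):
        for support in combinations(range(k), size):
            Bs = B[:, support]
            # KKT system for equality-constrained least squares on the support
            G = Bs.T @ Bs
            kkt = np.zeros((size + 1, size + 1))
            kkt[:size, :size] = 2.0 * G
            kkt[:size, size] = 1.0
            kkt[size, :size] = 1.0
            rhs = np.concatenate([2.0 * Bs.T @ y, [1.0]])
            try:
                sol = np.linalg.solve(kkt, rhs)
            except np.linalg.LinAlgError:
                sol, *_ = np.linalg.lstsq(kkt, rhs, rcond=None)
            f_s = sol[:size]
            if np.any(f_s < -1e-10):
                continue
            resid = y - Bs @ f_s
            obj = float(resid @ resid)
            if obj < best_obj - 1e-15:
                best_obj = obj
                f = np.zeros(k)
                f[list(support)] = np.clip(f_s, 0.0, None)
                best_f = f / f.sum()
    assert best_f is not None  # the full simplex always admits a feasible point
    return best_f


def unmix_cd(spectrum: Spectrum1D, basis: BasisSet) -> SSFractions:
    """Estimate secondary-structure fractions of a CD spectrum.

    Solves the simplex-constrained least-squares problem against the basis
    (interpolated onto the spectrum grid) and reports the normalized
    spectral fit S.D. = RMS(residual) / RMS(spectrum).
    """
    B = basis.matrix_on(spectrum.wavelength)
    y = spectrum.intensity
    f = _simplex_lstsq(B, y)
    resid = y - B @ f
    rms_y = float(np.sqrt(np.mean(y ** 2)))
    fit_sd = float(np.sqrt(np.mean(resid ** 2))) / rms_y if rms_y > 0 else 0.0
    return SSFractions(
        fractions={c: float(v) for c, v in zip(basis.classes, f)},
        fit_sd=fit_sd, basis_name=basis.name, poor_fit=fit_sd > POOR_FIT_SD)


def select_best_fit(candidates: list[SSFractions]) -> SSFractions:
    """Pick the candidate with the lowest normalized spectral fit S.D.

    Exact ties resolve to the first candidate in input order, with the tie
    noted on the result; the winner is flagged poor if its S.D. exceeds
    0.07.
    """
    if not candidates:
        raise DomainError("select_best_fit needs at least one candidate")
    best = min(candidates, key=lambda c: c.fit_sd)
    tie = sum(1 for c in candidates if c.fit_sd == best.fit_sd) > 1
    winner = next(c for c in candidates if c.fit_sd == best.fit_sd)
    return SSFractions(fractions=dict(winner.fractions), fit_sd=winner.fit_sd,
                       basis_name=winner.basis_name,
                       poor_fit=winner.fit_sd > POOR_FIT_SD, tie=tie)


def synth_cd(fractions: dict[str, float] | SSFractions, basis: BasisSet) -> Spectrum1D:
    """Forward model: the convex combination of basis spectra on the basis grid."""
    fr = fractions.fractions if isinstance(fractions, SSFractions) else dict(fractions)
    unknown = set(fr) - set(basis.classes)
    if unknown:
        raise DomainError(f"fractions over classes absent from basis: {sorted(unknown)}")
    w = basis.wavelength
    y = np.zeros_like(w)
    for c, f in fr.items():
        if f < 0:
            raise DomainError(f"negative fraction for class {c!r}")
        y = y + f * basis.spectra[c].intensity
    return Spectrum1D(w, y, kind="cd")


def _gauss(w, center, fwhm):
    return np.exp(-4.0 * np.log(2.0) * (w - center) ** 2 / fwhm ** 2)


def default_basis(wl_min: float = 190.0, wl_max: float = 260.0,
                  step: float = 0.5) -> BasisSet:
    """Synthetic 4-class far-UV CD basis built from Gaussian bands.

    Band positions follow textbook far-UV CD phenomenology; amplitudes are
    in arbitrary mdeg-like units.  Synthetic — see module docstring.
    """
    w = np.arange(wl_min, wl_max + step / 2, step)
    helix = 65.0 * _gauss(w, 192, 9) - 22.0 * _gauss(w, 208, 11) - 20.0 * _gauss(w, 222, 12)
    sheet = 32.0 * _gauss(w, 196, 9) - 14.0 * _gauss(w, 218, 11)
    coil = -20.0 * _gauss(w, 198, 10) + 2.0 * _gauss(w, 220, 25)
    turn = 8.0 * _gauss(w, 205, 14) - 3.0 * _gauss(w, 225, 18)
    spectra = {
        "helix": Spectrum1D(w, helix, kind="cd"),
        "sheet": Spectrum1D(w, sheet, kind="cd"),
        "turn": Spectrum1D(w, turn, kind="cd"),
        "coil": Spectrum1D(w, coil, kind="cd"),
    }
    return BasisSet(classes=CLASSES, spectra=spectra, name="default4")
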