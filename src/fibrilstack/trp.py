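"""Deconvolution of tryptophan emission spectra into Gaussian components.

Fibril assembly shifts tryptophan emission from a solvent-exposed component
(red, ~359 nm, 60 nm FWHM) toward a buried one (blue, ~327 nm, 40 nm FWHM).
Two fitting modes are provided:

* fixed-component fits, where centers and widths are held and only the
  component areas vary (non-negative linear least squares); and
* a free two-Gaussian fit with centers, widths and areas all refined.

Component fractions are area shares.  Gaussians are parameterized in
wavelength (nm), matching how emission data are usually presented, rather
than in wavenumber.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, nnls

from .errors import DomainError, FitFailureError, GridError
from .types import Spectrum1D

_LN2 = np.log(2.0)

#: Canonical medin components: (center nm, FWHM nm), red-most first.
DEFAULT_COMPONENTS = ((359.0, 60.0), (327.0, 40.0))


def gaussian_profile(wavelength, center: float, fwhm: float):
    """Unit-height Gaussian exp(-4 ln2 (λ-c)²/w²); FWHM parameterization."""
    if fwhm <= 0:
        raise DomainError(f"fwhm must be positive, got {fwhm}")
    lam = np.asarray(wavelength, dtype=float)
    return np.exp(-4.0 * _LN2 * (lam - center) ** 2 / fwhm ** 2)


def unit_height_area(fwhm: float) -> float:
    """Area under a unit-height Gaussian of the given FWHM: w·sqrt(π/(4 ln2))."""
    if fwhm <= 0:
        raise DomainError(f"fwhm must be positive, got {fwhm}")
    return fwhm * np.sqrt(np.pi / (4.0 * _LN2))


@dataclass(frozen=True)
class GaussianComponent:
    """One emission component; area is in instrument-unit·nm."""

    center: float
    fwhm: float
    area: float = 0.0

    def __post_init__(self):
        if self.fwhm <= 0:
            raise DomainError("fwhm must be positive")
        if self.area < 0:
            raise DomainError("area must be non-negative")

    def profile(self, wavelength) -> np.ndarray:
        """Component evaluated with its own area (not unit height)."""
        return self.area / unit_height_area(self.fwhm) * gaussian_profile(
            wavelength, self.center, self.fwhm)


@dataclass
class DeconvResult:
    components: list[GaussianComponent]
    fractions: list[float] | None
    residual_rms: float
    degenerate: bool = False

    def __post_init__(self):
        if self.residual_rms < 0:
            raise DomainError("residual_rms must be non-negative")
        if self.fractions is not None:
            f = np.asarray(self.fractions)
            if np.any(f < -1e-12) or abs(f.sum() - 1.0) > 1e-9:
                raise DomainError("fractions must lie on the simplex")


def _component_specs(components) -> list[tuple[float, float]]:
    out = []
    for comp in components:
        if isinstance(comp, GaussianComponent):
            out.append((comp.center, comp.fwhm))
        else:
            c, w = comp
            out.append((float(c), float(w)))
    return out


def fit_fixed_components(spectrum: Spectrum1D, components) -> DeconvResult:
    """Fit component areas with centers and widths held fixed.

    The areas are the only variables, obtained by non-negative linear least
    squares on unit-area profiles.  An all-zero spectrum returns a flagged
    degenerate result with no fractions.
    """
    specs = _component_specs(components)
    lam, y = spectrum.wavelength, spectrum.intensity
    dlam = np.min(np.diff(lam))
    for c, w in specs:
        if w / dlam < 2:
            raise GridError(
                f"fewer than 2 wavelength points per FWHM for component at {c} nm")
    # columns are unit-area profiles so coefficients are areas directly
    A = np.column_stack([
        gaussian_profile(lam, c, w) / unit_height_area(w) for c, w in specs])
    if np.allclose(y, 0.0):
        comps = [GaussianComponent(c, w, 0.0) for c, w in specs]
        return DeconvResult(comps, None, 0.0, degenerate=True)
    areas, _ = nnls(A, y)
    resid = y - A @ areas
    total = areas.sum()
    fractions = list(areas / total) if total > 0 else None
    comps = [GaussianComponent(c, w, float(a)) for (c, w), a in zip(specs, areas)]
    return DeconvResult(comps, fractions,
                        float(np.sqrt(np.mean(resid ** 2))),
                        degenerate=fractions is None)


def _two_gauss(lam, c1, w1, a1, c2, w2, a2):
    return (a1 / unit_height_area(w1) * np.exp(-4 * _LN2 * (lam - c1) ** 2 / w1 ** 2)
            + a2 / unit_height_area(w2) * np.exp(-4 * _LN2 * (lam - c2) ** 2 / w2 ** 2))


def _one_gauss(lam, c, w, a):
    return a / unit_height_area(w) * np.exp(-4 * _LN2 * (lam - c) ** 2 / w ** 2)


def fit_free_two_gaussian(spectrum: Spectrum1D, init=None) -> DeconvResult:
    """Two-Gaussian fit with centers, widths and areas all free.

    Components in the result are sorted by center descending (red-most,
    solvent-exposed component first).  A two-component model is only
    retained when it improves substantially on a single Gaussian —
    otherwise the problem is unidentifiable and the single-Gaussian
    solution is returned with a zero-area second component.
    Non-convergence and flat spectra raise FitFailureError.
    """
    lam, y = spectrum.wavelength, spectrum.intensity
    ymax = float(np.abs(y).max()) if y.size else 0.0
    if ymax == 0 or float(y.max() - y.min()) < 1e-12 * max(1.0, ymax):
        raise FitFailureError("flat spectrum: nothing to deconvolve")

    total_area = float(np.trapezoid(np.clip(y, 0, None), lam))
    power = float((y ** 2).sum())
    peak0 = float(lam[int(np.argmax(y))])

    # reference single-Gaussian fit for the identifiability check
    single = None
    single_rss = np.inf
    try:
        popt1, _ = curve_fit(_one_gauss, lam, y, p0=(peak0, 50.0, total_area),
                             bounds=([lam.min() - 50, 5.0, 0.0],
                                     [lam.max() + 50, 200.0, np.inf]),
                             maxfev=20000)
        single = tuple(float(v) for v in popt1)
        single_rss = float(((y - _one_gauss(lam, *popt1)) ** 2).sum())
    except (RuntimeError, ValueError):
        pass
    guesses = []
    if init is not None:
        specs = _component_specs(init)
        guesses.append((specs[0][0], specs[0][1], 0.5 * total_area,
                        specs[1][0], specs[1][1], 0.5 * total_area))
    peak = float(lam[int(np.argmax(y))])
    for offset in (-32.0, -25.0, -40.0, 25.0):
        guesses.append((peak, 50.0, 0.6 * total_area,
                        peak + offset, 40.0, 0.4 * total_area))

    lo = [lam.min() - 50, 5.0, 0.0, lam.min() - 50, 5.0, 0.0]
    hi = [lam.max() + 50, 200.0, np.inf, lam.max() + 50, 200.0, np.inf]
    best = None
    best_rss = np.inf
    last_exc = None
    for g in guesses:
        try:
            popt, _ = curve_fit(_two_gauss, lam, y, p0=np.clip(g, lo, hi),
                                bounds=(lo, hi), maxfev=20000)
        except (RuntimeError, ValueError) as exc:
            last_exc = exc
            continue
        rss = float(((y - _two_gauss(lam, *popt)) ** 2).sum())
        if rss < best_rss:
            best_rss, best = rss, popt
        if rss <= 1e-16 * max(1.0, float((y ** 2).sum())):
            break
    if best is None and single is None:
        raise FitFailureError(f"two-Gaussian fit did not converge: {last_exc}")

    # prefer the single-Gaussian solution when the second component buys no
    # real improvement (degenerate split of one band between two curves)
    use_single = single is not None and (
        best is None
        or single_rss <= 1e-10 * max(power, 1.0)
        or best_rss >= 0.99 * single_rss
    )
    if use_single:
        c, w, a = single
        best = (c, w, a, c - 30.0, w, 0.0)
        best_rss = single_rss

    c1, w1, a1, c2, w2, a2 = (float(v) for v in best)
    comps = [GaussianComponent(c1, w1, max(a1, 0.0)),
             GaussianComponent(c2, w2, max(a2, 0.0))]
    comps.sort(key=lambda comp: -comp.center)
    total = comps[0].area + comps[1].area
    fractions = [comps[0].area / total, comps[1].area / total] if total > 0 else None
    resid_rms = float(np.sqrt(best_rss / lam.size))
    return DeconvResult(comps, fractions, resid_rms, degenerate=fractions is None)


def timecourse_fractions(series, components=DEFAULT_COMPONENTS) -> pd.DataFrame:
    """Fixed-component fractions tabulated against time.

    `series` is an iterable of (time, Spectrum1D) sharing one wavelength
    grid; the result has one row per time point and one fraction column per
    component, named by its center.
    """
    specs = _component_specs(components)
    rows = []
    ref_grid = None
    for t, spec in series:
        if ref_grid is None:
            ref_grid = spec.wavelength
        elif spec.wavelength.size != ref_grid.size or not np.allclose(
                spec.wavelength, ref_grid):
            raise GridError(f"wavelength grid mismatch at time point {t}")
        res = fit_fixed_components(spec, specs)
        row = {"time": t}
        for (c, _), frac in zip(specs, res.fractions or [np.nan] * len(specs)):
            row[f"frac_{c:g}nm"] = frac
        rows.append(row)
    return pd.DataFrame(rows)
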