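"""Seeded synthetic-data generators for every analysis stage.

Each generator is a pure function of its parameters and seed and produces
data with the statistical structure the corresponding analysis assumes:
sigmoidal ThT traces with an optional early reversible transient, an
α→β CD transition time course, a two-component tryptophan emission time
course tied to the aggregation sigmoid, noisy REDOR dephasing curves for a
given distance, and shift tables for a hairpin segmentation of a sequence.
Noise is additive Gaussian throughout, with σ expressed in the signal's
own units.
"""
from __future__ import annotations

import warnings

import numpy as np

from .cd import BasisSet, default_basis, synth_cd
from .errors import DomainError
from .redor import simulate_fsr_curve
from .refshifts import class_means
from .darr import predict_shifts
from .tht import boltzmann
from .trp import DEFAULT_COMPONENTS, gaussian_profile, unit_height_area
from .types import DephasingCurve, KineticTrace, ShiftEntry, ShiftTable, Spectrum1D

_LN2 = np.log(2.0)


def _logistic(t, t_inflection, tau):
    return 1.0 / (1.0 + np.exp(-(np.asarray(t, float) - t_inflection) / tau))


def gen_tht(y0: float, a: float, t_inflection: float, tau: float,
            hump: tuple[float, float, float] | None = None,
            sigma: float = 0.0, grid=None, seed: int = 0,
            label: str = "synthetic") -> KineticTrace:
    """Synthetic ThT trace: Boltzmann sigmoid + optional Gaussian transient.

    `hump` is (center h, FWHM h, height RFU) modelling the early reversible
    fluorescence transient; a warning is issued when it encroaches on the
    inflection region (fit-window guidance).  `sigma` is the Gaussian noise
    s.d. in RFU.
    """
    if tau <= 0:
        raise DomainError("tau must be positive")
    if grid is None:
        grid = np.arange(0.0, 50.0 + 1e-9, 0.25)
    t = np.asarray(grid, dtype=float)
    y = boltzmann(t, y0, a, t_inflection, tau)
    if hump is not None:
        center, width, height = hump
        if width <= 0:
            raise DomainError("hump width must be positive")
        if abs(center - t_inflection) < width:
            warnings.warn(
                "transient hump overlaps the sigmoid inflection region; "
                "restrict the fit window to the main phase", stacklevel=2)
        y = y + height * np.exp(-4.0 * _LN2 * (t - center) ** 2 / width ** 2)
    if sigma < 0:
        raise DomainError("sigma must be non-negative")
    if sigma > 0:
        y = y + np.random.default_rng(seed).normal(0.0, sigma, size=t.size)
    return KineticTrace(t, y, label=label)


def gen_emission_series(times, total_intensity: float = 1000.0,
                        components=DEFAULT_COMPONENTS,
                        t_inflection: float = 35.0, tau: float = 2.0,
                        grid=None, sigma: float = 0.0, seed: int = 0):
    """Tryptophan emission time course tied to an aggregation sigmoid.

    At time t the spectrum is total·[(1−f(t))·G(red) + f(t)·G(blue)] with
    f the logistic fraction of the emergent blue-shifted component; both
    Gaussians carry unit area before scaling.  Returns a list of
    (time, Spectrum1D).  The grid must cover the 300–400 nm emission range.
    """
    if total_intensity <= 0:
        raise DomainError("total_intensity must be positive")
    if grid is None:
        grid = np.arange(300.0, 400.0 + 1e-9, 1.0)
    lam = np.asarray(grid, dtype=float)
    if lam.min() > 300.0 or lam.max() < 400.0:
        raise DomainError("wavelength grid must cover 300-400 nm")
    (c1, w1), (c2, w2) = components
    g1 = gaussian_profile(lam, c1, w1) / unit_height_area(w1)
    g2 = gaussian_profile(lam, c2, w2) / unit_height_area(w2)
    rng = np.random.default_rng(seed)
    out = []
    for t in times:
        f = float(_logistic(t, t_inflection, tau))
        y = total_intensity * ((1.0 - f) * g1 + f * g2)
        if sigma > 0:
            y = y + rng.normal(0.0, sigma, size=lam.size)
        out.append((float(t), Spectrum1D(lam, y, kind="emission")))
    return out


def gen_cd_series(times, basis: BasisSet | None = None,
                  end_fractions: dict[str, float] | None = None,
                  t_inflection: float = 20.0, tau: float = 2.0,
                  sigma: float = 0.0, seed: int = 0):
    """CD time course for an α→β structural transition.

    The helix fraction decays along a logistic g(t) while the end-point
    composition (default 65% sheet / 35% coil) grows in:
    f_helix = 1−g, f_class = end_fraction·g.  Returns (time, Spectrum1D)
    pairs on the basis grid with optional additive noise.
    """
    basis = basis or default_basis()
    end = dict(end_fractions or {"sheet": 0.65, "coil": 0.35})
    if abs(sum(end.values()) - 1.0) > 1e-9 or any(v < 0 for v in end.values()):
        raise DomainError("end_fractions must be a simplex vector")
    rng = np.random.default_rng(seed)
    out = []
    for t in times:
        g = float(_logistic(t, t_inflection, tau))
        fractions = {"helix": 1.0 - g}
        for cls, v in end.items():
            fractions[cls] = fractions.get(cls, 0.0) + v * g
        spec = synth_cd(fractions, basis)
        y = spec.intensity
        if sigma > 0:
            y = y + rng.normal(0.0, sigma, size=y.size)
        out.append((float(t), Spectrum1D(spec.wavelength, y, kind="cd")))
    return out


def gen_dephasing(distance: float, correction_f: float, times,
                  sigma: float = 0.0, seed: int = 0) -> DephasingCurve:
    """Noisy REDOR dephasing curve for a given ¹³C–¹⁵N distance (Å).

    Gaussian noise of s.d. `sigma` is added to the noiseless S/S₀ model and
    recorded on the curve as noise_sigma; values are clipped to the
    physically plausible [−0.2, 1.2] band.
    """
    times = np.asarray(times, dtype=float)
    if np.any(times <= 0):
        raise DomainError("dephasing times must be positive")
    if sigma < 0:
        raise DomainError("sigma must be non-negative")
    curve = simulate_fsr_curve(distance, times, correction_f)
    s = curve.s_ratio
    if sigma > 0:
        s = s + np.random.default_rng(seed).normal(0.0, sigma, size=s.size)
        s = np.clip(s, -0.2, 1.2)
    return DephasingCurve(times, s, noise_sigma=sigma)


def gen_hairpin_shift_table(sequence, segmentation, means=None,
                            jitter_sigma: float = 0.0, seed: int = 0) -> ShiftTable:
    """Shift table for a hairpin segmentation of a sequence.

    `segmentation` is a list of (class, start, end) spans with 1-based
    inclusive bounds that must tile the sequence exactly — e.g. a
    disordered N-terminal span, a β-sheet span, a turn, and a second
    β-sheet span.  Turn residues take coil shift values.  Per-atom Gaussian
    jitter of s.d. `jitter_sigma` ppm emulates structural heterogeneity.
    """
    seq = list(sequence)
    covered = []
    classes: list[str] = []
    for ss, start, end in segmentation:
        if ss == "turn":
            ss = "coil"
        if ss not in ("helix", "sheet", "coil"):
            raise DomainError(f"unknown segment class {ss!r}")
        covered.extend(range(start, end + 1))
        classes.extend([ss] * (end - start + 1))
    if covered != list(range(1, len(seq) + 1)):
        raise DomainError(
            "segmentation must tile residues 1..N exactly "
            f"(got positions {covered[:3]}...{covered[-3:] if covered else []} "
            f"for N={len(seq)})")
    table = predict_shifts(seq, classes, means=means or class_means())
    if jitter_sigma < 0:
        raise DomainError("jitter_sigma must be non-negative")
    if jitter_sigma == 0:
        return table
    rng = np.random.default_rng(seed)
    jittered = [ShiftEntry(e.residue, e.number, e.atom,
                           float(e.shift + rng.normal(0.0, jitter_sigma)))
                for e in table]
    return ShiftTable(jittered)
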