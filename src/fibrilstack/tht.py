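"""Sigmoidal fitting of thioflavin-T aggregation kinetics.

The model is the Boltzmann sigmoid

    y(t) = y0 + a / (1 + exp(-(t - t_inflection) / tau))

where y0 is the ThT background, a the fluorescence amplitude (plateau =
y0 + a), t_inflection the inflection time and tau the time constant.  The
elongation rate is 1/tau and the lag time is t_inflection - 2*tau (the
intercept of the inflection-point tangent with the baseline).

Traces showing an early reversible fluorescence transient are handled by
restricting the fit window to the main growth phase rather than by adding a
model term.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import DomainError, FitFailureError, SizeError
from .types import MIN_FIT_POINTS, KineticTrace

_MAX_RESTARTS = 5


def boltzmann(t, y0, a, t_inflection, tau):
    """Boltzmann sigmoid evaluated at time t (hours)."""
    return y0 + a / (1.0 + np.exp(-(t - t_inflection) / tau))


def lag_time(t_inflection: float, tau: float) -> float:
    """Lag time of a sigmoidal growth curve: t_inflection - 2*tau.

    Raises DomainError for non-positive tau.
    """
    if tau <= 0:
        raise DomainError(f"tau must be positive, got {tau}")
    return t_inflection - 2.0 * tau


@dataclass
class SigmoidFit:
    """Fitted sigmoid parameters with derived kinetic quantities."""

    y0: float
    a: float
    t_inflection: float
    tau: float
    r_squared: float = float("nan")
    stderr: dict = field(default_factory=dict)
    converged: bool = True

    def __post_init__(self):
        if self.tau <= 0:
            raise DomainError(f"tau must be positive, got {self.tau}")

    @property
    def rate(self) -> float:
        """Elongation rate 1/tau (h⁻¹)."""
        return 1.0 / self.tau

    @property
    def lag(self) -> float:
        """Lag time t_inflection - 2*tau (h)."""
        return lag_time(self.t_inflection, self.tau)

    @property
    def plateau(self) -> float:
        """Final fluorescence level y0 + a (RFU)."""
        return self.y0 + self.a

    def predict(self, t) -> np.ndarray:
        return boltzmann(np.asarray(t, dtype=float), self.y0, self.a,
                         self.t_inflection, self.tau)


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    y0 = float(y.min())
    a = float(y.max() - y.min())
    rise = (y - y0) / a
    # time of half rise, and the 25-75% rise span for tau
    t_half = float(np.interp(0.5, rise, t)) if np.all(np.diff(rise) >= 0) else \
        float(t[np.argmin(np.abs(rise - 0.5))])
    t25 = float(t[np.searchsorted(rise, 0.25, side="left").clip(0, t.size - 1)])
    t75 = float(t[np.searchsorted(rise, 0.75, side="left").clip(0, t.size - 1)])
    tau = max((t75 - t25) / 2.2, 1e-3 * (t[-1] - t[0]))
    return y0, a, t_half, tau


def fit_tht(trace: KineticTrace,
            fit_window: tuple[float | None, float | None] | None = None,
            init: SigmoidFit | None = None,
            seed: int = 0) -> SigmoidFit:
    """Nonlinear least-squares Boltzmann-sigmoid fit of a ThT trace.

    Parameters
    ----------
    trace : KineticTrace
    fit_window : optional (t_min, t_max) restriction; at least 5 points
        must remain inside it.  Use this to exclude an early reversible
        fluorescence transient from the fit.
    init : optional starting parameters; otherwise estimated from the data.
    seed : seeds the jittered restarts used on convergence failure.

    Returns a SigmoidFit with per-parameter standard errors and R².
    Degenerate (flat) traces and persistent non-convergence raise
    FitFailureError carrying the best residual reached.
    """
    if fit_window is not None:
        trace = trace.window(*fit_window)
    t, y = trace.time, trace.signal
    if t.size < MIN_FIT_POINTS:
        raise SizeError(f"{t.size} points; at least {MIN_FIT_POINTS} required")

    scale = float(y.max() - y.min())
    if scale <= 0 or scale < 1e-9 * max(1.0, abs(float(y.mean()))):
        raise FitFailureError("degenerate (flat) trace: no amplitude to fit")

    if init is not None:
        p0 = (init.y0, init.a, init.t_inflection, init.tau)
    else:
        p0 = _initial_guess(t, y)

    span = float(t[-1] - t[0])
    bounds = ([-np.inf, 0.0, t[0] - span, 1e-6],
              [np.inf, np.inf, t[-1] + span, 10.0 * span])
    rng = np.random.default_rng(seed)
    best_resid = np.inf
    last_exc: Exception | None = None
    for attempt in range(_MAX_RESTARTS + 1):
        if attempt == 0:
            guess = p0
        else:
            jitter = rng.normal(1.0, 0.2, size=4)
            guess = (p0[0], abs(p0[1] * jitter[1]),
                     p0[2] * jitter[2], abs(p0[3] * jitter[3]))
        guess = np.clip(guess, bounds[0], bounds[1])
        try:
            popt, pcov = curve_fit(boltzmann, t, y, p0=guess, bounds=bounds,
                                   maxfev=20000)
        except (RuntimeError, ValueError) as exc:
            last_exc = exc
            continue
        resid = y - boltzmann(t, *popt)
        rss = float(resid @ resid)
        if rss < best_resid:
            best_resid = rss
            best = (popt, pcov)
        # accept the first converged solution with a sane amplitude
        if popt[1] > 0 and rss <= best_resid:
            break
    else:
        if not np.isfinite(best_resid):
            raise FitFailureError(
                f"sigmoid fit failed after {_MAX_RESTARTS} restarts: {last_exc}",
                best_residual=None)

    if not np.isfinite(best_resid):
        raise FitFailureError(
            f"sigmoid fit failed after {_MAX_RESTARTS} restarts: {last_exc}")

    popt, pcov = best
    y0, a, t_i, tau = (float(v) for v in popt)
    se = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    stderr = dict(zip(("y0", "a", "t_inflection", "tau"), (float(s) for s in se)))
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - best_resid / ss_tot if ss_tot > 0 else float("nan")
    return SigmoidFit(y0=y0, a=a, t_inflection=t_i, tau=tau,
                      r_squared=r2, stderr=stderr, converged=True)


def goodness(fit: SigmoidFit, trace: KineticTrace,
             fit_window: tuple[float | None, float | None] | None = None) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot on the fitted window."""
    if fit_window is not None:
        trace = trace.window(*fit_window)
    y = trace.signal
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise DomainError("zero-variance trace: R² undefined")
    resid = y - fit.predict(trace.time)
    return 1.0 - float(resid @ resid) / ss_tot
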