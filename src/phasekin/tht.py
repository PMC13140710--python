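"""Sigmoidal ThT aggregation kinetics.

A thioflavin-T time course F(t) is fit to the Boltzmann sigmoid

    F(t) = Fi + (Ff - Fi) / (1 + exp((t50 - t) / k))

with baseline Fi, plateau Ff, midpoint t50 and slope parameter k (all in the
trace's units / seconds). From the fit we derive the maximal elongation rate
(Ff - Fi)/(4k) (the slope at t50), two lag-time constructions, the endpoint
intensity, the fluorescence amplitude used for % protection, and a per-well
aggregation event for survival analysis.

Two lag formulas are reported. The tangent construction intersects the
midpoint tangent with the *zero* line shifted to Fi, giving t50 - 2k. The
variant with an explicit baseline term,

    t_lag = 4*k*Fi/(Ff - Fi) + t50 - 2*k,

intersects the tangent with F = Fi measured from zero; the two coincide
exactly when Fi = 0 and otherwise differ by 4*k*Fi/(Ff - Fi). Both are
computed; the baseline-term form is the default event time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .io import ThTTrace


def boltzmann(t: np.ndarray, Fi: float, Ff: float, t50: float, k: float) -> np.ndarray:
    """Boltzmann sigmoid F(t); the closed form every fit is checked against."""
    z = np.clip((t50 - np.asarray(t, dtype=float)) / k, -700.0, 700.0)
    return Fi + (Ff - Fi) / (1.0 + np.exp(z))


def boltzmann_slope(t: np.ndarray, Fi: float, Ff: float, t50: float, k: float) -> np.ndarray:
    """dF/dt of the sigmoid; equals (Ff-Fi)/(4k) at t = t50."""
    e = np.exp((t50 - np.asarray(t, dtype=float)) / k)
    return (Ff - Fi) / k * e / (1.0 + e) ** 2


def elongation_rate(Fi: float, Ff: float, k: float) -> float:
    """Maximal slope of the sigmoid, attained at the midpoint: (Ff-Fi)/(4k)."""
    return (Ff - Fi) / (4.0 * k)


def lag_time_tangent(t50: float, k: float) -> float:
    """Tangent-construction lag: intercept of the midpoint tangent with the
    baseline level, t50 - 2k."""
    return t50 - 2.0 * k


def lag_time_baseline(Fi: float, Ff: float, t50: float, k: float) -> float:
    """Lag time with the explicit baseline term:
    4*k*Fi/(Ff - Fi) + t50 - 2*k. Identical to the tangent form when Fi=0."""
    if Ff == Fi:
        raise ZeroDivisionError("Ff == Fi: lag time undefined")
    return 4.0 * k * Fi / (Ff - Fi) + t50 - 2.0 * k


@dataclass
class BoltzmannFit:
    Fi: float
    Ff: float
    t50_s: float
    k_s: float
    param_se: dict[str, float] = field(default_factory=dict)
    r2: float = np.nan
    converged: bool = False
    reason: str = ""

    def curve(self, t: np.ndarray) -> np.ndarray:
        return boltzmann(t, self.Fi, self.Ff, self.t50_s, self.k_s)


@dataclass
class KineticSummary:
    elongation_rate: float
    t_lag_baseline_s: float
    t_lag_tangent_s: float
    endpoint: float
    delta_I: float


@dataclass
class EventRecord:
    well_id: str
    event: int
    time_s: float


@dataclass
class EventCriteria:
    """What counts as a 'significant increase in ThT'.

    A well is an aggregation event iff the fit converged, the fitted
    amplitude exceeds ``min_fold`` times the s.d. of the first
    ``n_baseline`` points, and the fit r2 is at least ``min_r2``.
    ``lag_formula`` selects which lag becomes the event time.
    """

    min_fold: float = 10.0
    n_baseline: int = 10
    min_r2: float = 0.9
    lag_formula: str = "baseline"


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    n = len(y)
    m = max(1, int(round(0.05 * n)))
    Fi0 = float(np.mean(y[:m]))
    Ff0 = float(np.mean(y[-m:]))
    mid = 0.5 * (Fi0 + Ff0)
    if Ff0 >= Fi0:
        cross = np.nonzero(y >= mid)[0]
    else:
        cross = np.nonzero(y <= mid)[0]
    t50_0 = float(t[cross[0]]) if len(cross) else float(0.5 * (t[0] + t[-1]))
    k0 = (t[-1] - t[0]) / 20.0
    return Fi0, Ff0, t50_0, k0


def fit_boltzmann(
    trace: ThTTrace,
    r2_threshold: float = 0.5,
    noise_floor: float = 1e-12,
) -> BoltzmannFit:
    """Nonlinear least-squares Boltzmann fit of one trace.

    Initialization: Fi/Ff from the first/last 5% of points, t50 from the
    first midpoint crossing, k from span/20. Only k > 0 is bounded; Ff >= Fi
    is not enforced (a negative amplitude conveys a decreasing transition).
    ``converged`` is False for flat traces ("no transition"), optimizer
    failure, r2 below ``r2_threshold``, or a midpoint outside the observed
    window by more than one span.
    """
    t, y = trace.time_s, trace.intensity
    sd = float(np.std(y))
    if sd < max(noise_floor, 1e-12 * abs(float(np.mean(y)))):
        return BoltzmannFit(float(np.mean(y)), float(np.mean(y)), np.nan, np.nan,
                            converged=False, reason="no transition")
    p0 = _initial_guess(t, y)
    span = t[-1] - t[0]
    try:
        popt, pcov = curve_fit(
            boltzmann, t, y, p0=p0,
            bounds=([-np.inf, -np.inf, -np.inf, 1e-9], [np.inf] * 4),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        return BoltzmannFit(*p0, converged=False, reason=f"optimizer failed: {exc}")
    Fi, Ff, t50, k = (float(v) for v in popt)
    resid = y - boltzmann(t, *popt)
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    se = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(4, np.nan)
    param_se = dict(zip(("Fi", "Ff", "t50_s", "k_s"), (float(v) for v in se)))
    fit = BoltzmannFit(Fi, Ff, t50, k, param_se=param_se, r2=r2, converged=True)
    if r2 < r2_threshold:
        fit.converged, fit.reason = False, f"r2 {r2:.3f} below threshold {r2_threshold}"
    elif not (t[0] - span <= t50 <= t[-1] + span):
        fit.converged, fit.reason = False, "fitted midpoint outside observed window"
    return fit


def kinetic_summary(fit: BoltzmannFit, trace: ThTTrace) -> KineticSummary:
    """Kinetic summaries from a converged fit.

    elongation_rate = (Ff-Fi)/(4k); both lag constructions; endpoint = mean
    of the final 3 raw points (robust to last-cycle artifacts); delta_I =
    fitted amplitude Ff - Fi (the quantity entering % protection).
    """
    if not fit.converged:
        raise ValueError(f"fit did not converge ({fit.reason}); no summary")
    if fit.Ff == fit.Fi:
        raise ZeroDivisionError("Ff == Fi: elongation rate and lag undefined")
    return KineticSummary(
        elongation_rate=elongation_rate(fit.Fi, fit.Ff, fit.k_s),
        t_lag_baseline_s=lag_time_baseline(fit.Fi, fit.Ff, fit.t50_s, fit.k_s),
        t_lag_tangent_s=lag_time_tangent(fit.t50_s, fit.k_s),
        endpoint=float(np.mean(trace.intensity[-3:])),
        delta_I=fit.Ff - fit.Fi,
    )


def percent_protection(delta_I_ref: float, delta_I_chaperone: float) -> float:
    """Chaperone efficacy: (dI - dI_chaperone) / dI * 100.

    100% means aggregation fully suppressed, 0% no effect; negative values
    mean the chaperone *increased* the fluorescence amplitude.
    """
    if delta_I_ref == 0:
        raise ZeroDivisionError("reference delta_I is zero")
    return (delta_I_ref - delta_I_chaperone) / delta_I_ref * 100.0


def detect_event(trace: ThTTrace, fit: BoltzmannFit,
                 criteria: EventCriteria | None = None) -> EventRecord:
    """Classify one well as aggregation event (1) or censored (0).

    Event time is the chosen lag formula (clipped positive); censored wells
    carry the final observation time.
    """
    criteria = criteria or EventCriteria()
    censor_time = float(trace.time_s[-1])
    if not fit.converged:
        return EventRecord(trace.well_id, 0, censor_time)
    baseline_sd = float(np.std(trace.intensity[: criteria.n_baseline]))
    amplitude = fit.Ff - fit.Fi
    if amplitude <= criteria.min_fold * baseline_sd or fit.r2 < criteria.min_r2:
        return EventRecord(trace.well_id, 0, censor_time)
    if criteria.lag_formula == "tangent":
        lag = lag_time_tangent(fit.t50_s, fit.k_s)
    else:
        lag = lag_time_baseline(fit.Fi, fit.Ff, fit.t50_s, fit.k_s)
    return EventRecord(trace.well_id, 1, max(lag, 1e-6))
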