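"""FRAP normalization and recovery fitting.

The three-ROI series (bleached region, whole-condensate reference,
off-condensate background) is reduced in three steps: background
subtraction, double normalization against the reference (which cancels
acquisition photobleaching and gain), and full-scale rescaling so the
pre-bleach mean is 1 and the first post-bleach frame is exactly 0. The
normalized recovery is then fit with a single exponential
a*(1 - exp(-b*t)); the mobile fraction is the plateau a and the half-time
is ln(2)/b. A two-component option is available for recoveries with two
clearly separated timescales.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, curve_fit

from .io import FrapSeries, ValidationError


@dataclass
class NormalizedFrap:
    """Full-scale-normalized recovery. ``time_from_bleach_s`` is 0 at the
    first post-bleach frame (negative pre-bleach); ``value`` is exactly 0
    there and the pre-bleach double-normalized mean is 1 by construction.
    ``gap_depth`` is the double-normalized first post-bleach value before
    rescaling (how deep the bleach cut)."""

    time_from_bleach_s: np.ndarray
    value: np.ndarray
    gap_depth: float
    pre_bleach_mean_dn: float
    bleach_index: int
    meta: dict = field(default_factory=dict)

    @property
    def post_time(self) -> np.ndarray:
        return self.time_from_bleach_s[self.bleach_index:]

    @property
    def post_value(self) -> np.ndarray:
        return self.value[self.bleach_index:]


@dataclass
class FrapFit:
    mobile_fraction: float
    t_half_s: float
    mobile_fraction_se: float = np.nan
    t_half_se: float = np.nan
    fit_r2: float = np.nan
    converged: bool = False
    low_recovery: bool = False
    reason: str = ""


def normalize_full_scale(series: FrapSeries) -> NormalizedFrap:
    """Background-subtract, double-normalize, full-scale rescale.

    dn(t) = [roi(t) - bg(t)] / [ref(t) - bg(t)] / mean_pre(roi - bg over ref - bg)
    fs(t) = (dn(t) - dn(t0)) / (1 - dn(t0)),  t0 = first post-bleach frame.

    Normalizing the per-frame ratio by its own pre-bleach mean makes the
    pre-bleach dn average exactly 1 regardless of noise.
    """
    roi = series.roi - series.background
    ref = series.reference - series.background
    if np.any(ref <= 0):
        raise ValidationError("reference <= background: cannot normalize")
    b = series.bleach_index
    ratio = roi / ref
    pre_ratio = float(np.mean(ratio[:b]))
    if pre_ratio <= 0:
        raise ValidationError("pre-bleach ROI <= background: cannot normalize")
    dn = ratio / pre_ratio
    gap = float(dn[b])
    if gap >= 1.0:
        raise ValidationError("no bleach detected (first post-bleach frame not below pre-bleach level)")
    fs = (dn - gap) / (1.0 - gap)
    return NormalizedFrap(
        time_from_bleach_s=series.time_s - series.time_s[b],
        value=fs,
        gap_depth=gap,
        pre_bleach_mean_dn=float(np.mean(dn[:b])),
        bleach_index=b,
        meta=dict(series.meta),
    )


def _single(t, a, bconst):
    return a * (1.0 - np.exp(-bconst * t))


def _double(t, a1, b1, a2, b2):
    return a1 * (1.0 - np.exp(-b1 * t)) + a2 * (1.0 - np.exp(-b2 * t))


def fit_recovery(norm: NormalizedFrap, model: str = "single") -> FrapFit:
    """Fit the post-bleach recovery and derive mobile fraction and half-time.

    The single model is fs(t) = a*(1 - exp(-b t)): mobile fraction a,
    t_half = ln2/b. For the double model the mobile fraction is a1+a2 and
    the half-time solves fs(t) = (a1+a2)/2 numerically. The half-time is
    always taken from the fitted rate(s), never read off the noisy curve.
    """
    t, y = norm.post_time, norm.post_value
    if len(t) < 20:
        raise ValueError("need >= 20 post-bleach frames")
    plateau0 = float(np.mean(y[-max(3, len(y) // 10):]))
    half_idx = np.nonzero(y >= 0.5 * plateau0)[0]
    t_half0 = float(t[half_idx[0]]) if len(half_idx) and t[half_idx[0]] > 0 else (t[-1] - t[0]) / 4.0
    b0 = np.log(2.0) / max(t_half0, 1e-9)

    low = plateau0 < 0.02
    try:
        if model == "single":
            popt, pcov = curve_fit(_single, t, y, p0=(max(plateau0, 0.05), b0), maxfev=20000)
            a, bconst = (float(v) for v in popt)
            mobile, se = a, np.sqrt(np.diag(pcov))
            mf_se = float(se[0])
            t_half = np.log(2.0) / bconst if bconst > 0 else np.nan
            t_half_se = float(np.log(2.0) / bconst**2 * se[1]) if bconst > 0 else np.nan
            rate_ok = bconst > 0
        elif model == "double":
            p0 = (0.5 * max(plateau0, 0.05), 3.0 * b0, 0.5 * max(plateau0, 0.05), 0.3 * b0)
            popt, pcov = curve_fit(_double, t, y, p0=p0, maxfev=40000)
            a1, b1, a2, b2 = (float(v) for v in popt)
            mobile = a1 + a2
            se = np.sqrt(np.diag(pcov))
            mf_se = float(np.hypot(se[0], se[2]))
            rate_ok = b1 > 0 and b2 > 0
            if rate_ok and mobile > 0:
                f = lambda tt: _double(tt, *popt) - 0.5 * mobile
                t_hi = 10.0 / min(b1, b2)
                t_half = float(brentq(f, 1e-12, t_hi)) if f(t_hi) > 0 else np.nan
            else:
                t_half = np.nan
            t_half_se = np.nan
        else:
            raise ValueError(f"unknown model {model!r}")
    except RuntimeError as exc:
        return FrapFit(np.nan, np.nan, converged=False, reason=f"optimizer failed: {exc}")

    resid = y - (_single(t, *popt) if model == "single" else _double(t, *popt))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    fit = FrapFit(mobile_fraction=mobile, t_half_s=t_half,
                  mobile_fraction_se=mf_se, t_half_se=t_half_se,
                  fit_r2=r2, converged=True, low_recovery=low)
    if not rate_ok:
        if low:
            # immobile limit: mobile ~ 0 is meaningful, the rate is not
            fit.reason = "flat recovery: half-time indeterminate"
        else:
            fit.converged, fit.reason = False, "non-positive recovery rate"
    elif not -0.05 <= mobile <= 1.1:
        fit.converged, fit.reason = False, f"mobile fraction {mobile:.3f} out of range"
    return fit
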