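"""Synthetic datasets with known ground truth.

Every generator is seed-deterministic and, in its noiseless limit, agrees
with a closed form, so each downstream estimator can be checked against the
truth it was given. The generators emulate the statistical structure of the
assays (sigmoidal ThT time courses with well-to-well stochastic lag and a
censored non-aggregating fraction, single-exponential FRAP recovery under
mild acquisition photobleaching, two-channel photon traces with Gaussian
background and a controlled coincident-burst fraction, saturating turbidity)
— not the underlying physics (no nucleation-elongation moment equations, no
spatial diffusion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import FrapSeries, PhotonTrace, PlateKinetics, ThTTrace, TurbiditySeries
from .tht import boltzmann, lag_time_baseline


# ---------------------------------------------------------------------------
# truth parameter sets
# ---------------------------------------------------------------------------

@dataclass
class ThTTruth:
    """Ground-truth sigmoid parameters for one plate condition.

    Defaults follow the plate-assay conditions: baseline 100 a.u., plateau
    1100 a.u., midpoint 3600 s, slope parameter 400 s, 2% of the amplitude
    as Gaussian noise. ``lag_cv`` is the coefficient of variation of the
    per-well lognormal midpoint; ``nonaggregating_frac`` is the Bernoulli
    probability that a well never aggregates (flat baseline, later censored).
    """

    Fi: float = 100.0
    Ff: float = 1100.0
    t50_s: float = 3600.0
    k_s: float = 400.0
    lag_cv: float = 0.0
    nonaggregating_frac: float = 0.0
    noise_sd: float = 20.0

    def __post_init__(self) -> None:
        if not (self.Ff > self.Fi >= 0):
            raise ValueError("require Ff > Fi >= 0")
        if self.k_s <= 0:
            raise ValueError("require k_s > 0")
        for name in ("lag_cv", "nonaggregating_frac"):
            v = getattr(self, name)
            if name == "nonaggregating_frac" and not 0 <= v <= 1:
                raise ValueError("nonaggregating_frac must be in [0,1]")
        if self.lag_cv < 0 or self.noise_sd < 0:
            raise ValueError("lag_cv and noise_sd must be >= 0")


@dataclass
class FrapTruth:
    """Ground truth for one bleach series: recoverable fraction, half-time,
    fraction of the signal removed by the bleach, and relative noise."""

    mobile_fraction: float = 0.7
    t_half_s: float = 5.0
    bleach_depth: float = 0.8
    noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if not 0 <= self.mobile_fraction <= 1:
            raise ValueError("mobile_fraction must be in [0,1]")
        if self.t_half_s <= 0:
            raise ValueError("t_half_s must be > 0")
        if not 0 < self.bleach_depth <= 1:
            raise ValueError("bleach_depth must be in (0,1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class TccdTruth:
    """Ground truth for one two-channel acquisition.

    ``burst_width_ms`` is the Gaussian sigma of the burst profile; bursts
    are kept at least 3x this width apart within a channel (dilute regime).
    A ``coincident_fraction`` of bursts share a center time across channels
    to within ``jitter_ms``. Defaults mimic a 10 s acquisition with sparse
    oligomer transits over a background of ~10 counts per 1 ms bin.
    """

    n_bursts_per_channel: int = 30
    coincident_fraction: float = 0.25
    burst_amplitude: float = 40.0
    burst_width_ms: float = 15.0
    bg_mean: float = 10.0
    bg_sd: float = 2.0
    duration_s: float = 10.0
    jitter_ms: float = 2.0

    def __post_init__(self) -> None:
        if self.burst_amplitude <= 0 or self.burst_width_ms <= 0:
            raise ValueError("burst amplitude and width must be > 0")
        if not 0 <= self.coincident_fraction <= 1:
            raise ValueError("coincident_fraction must be in [0,1]")
        if self.n_bursts_per_channel < 0 or self.duration_s <= 0:
            raise ValueError("need n_bursts >= 0 and duration > 0")


# ---------------------------------------------------------------------------
# ThT plate
# ---------------------------------------------------------------------------

def _well_ids(n: int) -> list[str]:
    rows = "ABCDEFGHIJKLMNOP"
    ids = []
    for i in range(n):
        suffix = f"_{i // 384 + 1}" if i >= 384 else ""  # beyond one 384-well plate
        ids.append(f"{rows[(i // 24) % 16]}{i % 24 + 1}{suffix}")
    return ids


def gen_tht_plate(
    truth: ThTTruth,
    n_wells: int = 96,
    duration_s: float = 180 * 350.0,
    cycle_s: float = 350.0,
    seed: int = 0,
) -> tuple[PlateKinetics, pd.DataFrame]:
    """Simulate a ThT plate; returns the plate and its per-well truth table.

    Aggregating wells follow the Boltzmann sigmoid with a per-well midpoint
    drawn lognormally (mean ``t50_s``, CV ``lag_cv``); non-aggregating wells
    are flat baseline. Gaussian noise of sd ``noise_sd`` is added everywhere.
    """
    if n_wells < 1:
        raise ValueError("n_wells must be >= 1")
    if duration_s < 10 * cycle_s:
        raise ValueError("duration must cover at least 10 cycles")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_s + 0.5 * cycle_s, cycle_s)
    ids = _well_ids(n_wells)

    aggregating = rng.random(n_wells) >= truth.nonaggregating_frac
    if truth.lag_cv > 0:
        sigma = np.sqrt(np.log1p(truth.lag_cv**2))
        mu = np.log(truth.t50_s) - 0.5 * sigma**2
        t50s = rng.lognormal(mu, sigma, n_wells)
    else:
        t50s = np.full(n_wells, truth.t50_s)

    traces, rows = [], []
    for i, well in enumerate(ids):
        if aggregating[i]:
            clean = boltzmann(t, truth.Fi, truth.Ff, t50s[i], truth.k_s)
            true_lag = lag_time_baseline(truth.Fi, truth.Ff, t50s[i], truth.k_s)
        else:
            clean = np.full_like(t, truth.Fi)
            true_lag = np.nan
        y = clean + (rng.normal(0.0, truth.noise_sd, len(t)) if truth.noise_sd > 0 else 0.0)
        traces.append(ThTTrace(well_id=well, time_s=t, intensity=y))
        rows.append({
            "well": well,
            "aggregating": bool(aggregating[i]),
            "Fi": truth.Fi,
            "Ff": truth.Ff if aggregating[i] else truth.Fi,
            "t50_s": t50s[i] if aggregating[i] else np.nan,
            "k_s": truth.k_s,
            "t_lag_baseline_s": true_lag,
            "t_lag_tangent_s": t50s[i] - 2 * truth.k_s if aggregating[i] else np.nan,
            "event": int(aggregating[i]),
            "censor_time_s": t[-1],
        })
    plate = PlateKinetics(traces=traces, cycle_s=cycle_s, meta={"seed": seed, "synthetic": True})
    return plate, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# FRAP
# ---------------------------------------------------------------------------

def gen_frap_series(
    truth: FrapTruth,
    n_pre: int = 10,
    n_post: int = 526,
    dt_s: float = 0.171,
    seed: int = 0,
    roi_level: float = 800.0,
    reference_level: float = 1000.0,
    background_level: float = 50.0,
    acquisition_decay_per_s: float = 5e-4,
) -> FrapSeries:
    """Simulate a bleach series with the default frame timing of a ~90 s
    acquisition at ~0.171 s intervals.

    The ROI drops instantaneously by ``bleach_depth`` at the bleach frame and
    recovers as mobile_fraction * (1 - 2^(-t/t_half)) of the bleached
    amplitude; ROI and reference share a mild exponential acquisition
    photobleaching decay so that the double normalization has real work to do.
    """
    if n_pre < 3 or n_post < 20:
        raise ValueError("need n_pre >= 3 and n_post >= 20")
    rng = np.random.default_rng(seed)
    n = n_pre + n_post
    t = np.arange(n) * dt_s
    tau = t - t[n_pre]

    decay = np.exp(-acquisition_decay_per_s * t)
    g = np.ones(n)
    post = np.arange(n) >= n_pre
    g[post] = (1.0 - truth.bleach_depth) + truth.bleach_depth * truth.mobile_fraction * (
        1.0 - 2.0 ** (-tau[post] / truth.t_half_s))

    roi = background_level + roi_level * decay * g
    reference = background_level + reference_level * decay
    background = np.full(n, background_level)
    if truth.noise_sd > 0:
        roi = roi + rng.normal(0.0, truth.noise_sd * roi_level, n)
        reference = reference + rng.normal(0.0, truth.noise_sd * reference_level, n)
        background = background + rng.normal(0.0, truth.noise_sd * background_level, n)
    return FrapSeries(time_s=t, roi=roi, reference=reference, background=background,
                      bleach_index=n_pre, meta={"seed": seed, "synthetic": True})


# ---------------------------------------------------------------------------
# two-channel photon traces
# ---------------------------------------------------------------------------

def _spaced_uniform(rng: np.random.Generator, n: int, lo: float, hi: float,
                    min_gap: float) -> np.ndarray:
    """n sorted points uniform on [lo, hi] conditioned on pairwise gaps
    >= min_gap (gap-subtraction construction, exact)."""
    if n == 0:
        return np.empty(0)
    span = hi - lo - (n - 1) * min_gap
    if span <= 0:
        raise ValueError("interval too crowded for requested minimum spacing")
    u = np.sort(rng.uniform(0.0, span, n))
    return lo + u + np.arange(n) * min_gap


def gen_photon_pair(
    truth: TccdTruth,
    bin_width_ms: float = 1.0,
    seed: int = 0,
) -> tuple[PhotonTrace, PhotonTrace, dict]:
    """Simulate a two-channel acquisition; returns (donor-like trace,
    acceptor-like trace, truth dict with per-channel and shared burst times).

    Background counts per bin are normal(bg_mean, bg_sd) truncated at zero
    and rounded. Bursts are Gaussian count excursions at uniformly random
    center times with minimum intra-channel spacing 3x burst width; a
    ``coincident_fraction`` of them share a center across channels to within
    +/- ``jitter_ms``.
    """
    rng = np.random.default_rng(seed)
    duration_ms = truth.duration_s * 1e3
    n_bins = int(round(duration_ms / bin_width_ms))
    w = truth.burst_width_ms
    occupancy = truth.n_bursts_per_channel * 3.0 * w / duration_ms
    if occupancy >= 0.2:
        raise ValueError(
            f"expected burst occupancy {occupancy:.0%} >= 20% of bins; "
            "lower the burst rate or widen the acquisition (dilute regime required)")

    margin = 3.0 * w
    n = truth.n_bursts_per_channel
    n_co = int(round(truth.coincident_fraction * n))
    a_times = _spaced_uniform(rng, n, margin, duration_ms - margin, 3.0 * w)
    shared = np.sort(rng.choice(a_times, size=n_co, replace=False)) if n_co else np.empty(0)
    if truth.jitter_ms > 0 and n_co:
        b_shared = shared + rng.uniform(-truth.jitter_ms, truth.jitter_ms, n_co)
    else:
        b_shared = shared.copy()
    # channel-exclusive B bursts by rejection against existing B centers
    b_times = list(b_shared)
    attempts = 0
    while len(b_times) < n and attempts < 10000 * n:
        cand = rng.uniform(margin, duration_ms - margin)
        if all(abs(cand - x) >= 3.0 * w for x in b_times):
            b_times.append(cand)
        attempts += 1
    if len(b_times) < n:
        raise ValueError("could not place channel-exclusive bursts; lower the burst rate")
    b_times = np.sort(np.asarray(b_times))

    centers = (np.arange(n_bins) + 0.5) * bin_width_ms

    def _trace(times: np.ndarray, channel: str) -> PhotonTrace:
        counts = np.maximum(rng.normal(truth.bg_mean, truth.bg_sd, n_bins), 0.0)
        for tc in times:
            lo = max(0, int((tc - 5 * w) / bin_width_ms))
            hi = min(n_bins, int((tc + 5 * w) / bin_width_ms) + 1)
            counts[lo:hi] += truth.burst_amplitude * np.exp(
                -0.5 * ((centers[lo:hi] - tc) / w) ** 2)
        return PhotonTrace(bin_width_ms=bin_width_ms, counts=np.rint(counts), channel=channel)

    truth_out = {
        "a_times_ms": a_times,
        "b_times_ms": b_times,
        "shared_times_ms": shared,
        "n_coincident": n_co,
        "seed": seed,
    }
    return _trace(a_times, "donor"), _trace(b_times, "acceptor"), truth_out


# ---------------------------------------------------------------------------
# turbidity
# ---------------------------------------------------------------------------

def gen_turbidity_series(
    od_max: float = 0.5,
    rate_per_s: float = 0.02,
    noise_sd: float = 0.005,
    duration_s: float = 300.0,
    seed: int = 0,
    cycle_s: float = 10.0,
    wavelength_scales: dict[str, float] | None = None,
    well_id: str = "A1",
) -> TurbiditySeries:
    """Saturating turbidity curve od_max*(1 - exp(-rate*t)) per wavelength.

    Defaults mimic a 30-cycle, 10 s-interval scattering read; the per-
    wavelength scale factors mimic the decrease of scattering with
    wavelength (340 > 400 > 600 nm).
    """
    if od_max < 0:
        raise ValueError("od_max must be >= 0")
    scales = wavelength_scales or {"340": 1.0, "400": 0.7, "600": 0.3}
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_s, cycle_s)
    od = {}
    for wl, sc in scales.items():
        clean = sc * od_max * (1.0 - np.exp(-rate_per_s * t))
        od[wl] = clean + (rng.normal(0.0, noise_sd, len(t)) if noise_sd > 0 else 0.0)
    return TurbiditySeries(well_id=well_id, time_s=t, od=od)
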