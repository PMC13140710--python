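"""Kaplan-Meier analysis of per-well aggregation events.

Each well contributes an (event, time) record: event = 1 with the lag time
when aggregation occurred, event = 0 with the final assay time when it never
did (right-censoring). The product-limit estimator, the Mantel-Cox log-rank
test with an observed/expected hazard ratio, and a mean time to failure read
off a decreasing sigmoid fit to the survival staircase mirror how plate-
level aggregation data are summarised when some technical replicates never
aggregate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import chi2 as chi2_dist

from .tht import EventRecord


@dataclass
class EventTable:
    records: list[EventRecord]
    group: str = ""

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("empty event table")
        if any(r.time_s <= 0 for r in self.records):
            raise ValueError("all event/censor times must be > 0")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, group: str = "") -> "EventTable":
        recs = [EventRecord(str(r.well), int(r.event), float(r.time_s))
                for r in df.itertuples()]
        return cls(records=recs, group=group)

    @property
    def times(self) -> np.ndarray:
        return np.array([r.time_s for r in self.records])

    @property
    def events(self) -> np.ndarray:
        return np.array([r.event for r in self.records], dtype=int)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class KMCurve:
    """Product-limit estimate: survival just after each distinct event time.

    S(0) = 1 by construction; ``survival`` is non-increasing. ``degenerate``
    flags a table with no events at all (flat curve)."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    t_max: float
    group: str = ""
    degenerate: bool = False

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Right-continuous step function S(t)."""
        t = np.asarray(t, dtype=float)
        s = np.concatenate(([1.0], self.survival))
        idx = np.searchsorted(self.times, t, side="right")
        return s[idx]


@dataclass
class LogrankResult:
    chi2: float
    p: float
    hazard_ratio: float
    hr_ci95: tuple[float, float]
    observed: tuple[float, float]
    expected: tuple[float, float]
    hr_infinite: bool = False


def km_estimate(table: EventTable) -> KMCurve:
    """Kaplan-Meier product-limit estimator with right-censoring.

    Ties are handled by letting all events at a shared time step together.
    """
    times, events = table.times, table.events
    event_times = np.unique(times[events == 1])
    surv, at_risk, n_ev = [], [], []
    s = 1.0
    for t in event_times:
        n = int(np.sum(times >= t))
        d = int(np.sum((times == t) & (events == 1)))
        s *= 1.0 - d / n
        surv.append(s)
        at_risk.append(n)
        n_ev.append(d)
    return KMCurve(
        times=event_times,
        survival=np.array(surv),
        at_risk=np.array(at_risk, dtype=int),
        n_events=np.array(n_ev, dtype=int),
        t_max=float(times.max()),
        group=table.group,
        degenerate=len(event_times) == 0,
    )


def logrank_test(a: EventTable, b: EventTable) -> LogrankResult:
    """Mantel-Cox log-rank test of group a versus group b.

    chi2 = (O_a - E_a)^2 / V with hypergeometric variance summed over pooled
    event times, p from chi-square with 1 df. The hazard ratio is the
    observed/expected ratio (O_a/E_a)/(O_b/E_b) with a 95% CI from the
    normal approximation on the log scale, se = sqrt(1/E_a + 1/E_b). If
    group b has no events the HR is +inf and flagged.
    """
    ta, ea = a.times, a.events
    tb, eb = b.times, b.events
    pooled = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    if len(pooled) == 0:
        raise ValueError("no events in either group")
    O_a = E_a = V = 0.0
    for t in pooled:
        n1 = int(np.sum(ta >= t))
        n2 = int(np.sum(tb >= t))
        d1 = int(np.sum((ta == t) & (ea == 1)))
        d2 = int(np.sum((tb == t) & (eb == 1)))
        n, d = n1 + n2, d1 + d2
        O_a += d1
        E_a += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    O_b = float(np.sum(eb))
    E_b = float(np.sum(ea) + O_b - E_a)  # E_a + E_b = total events
    stat = (O_a - E_a) ** 2 / V if V > 0 else 0.0
    p = float(chi2_dist.sf(stat, df=1)) if V > 0 else 1.0
    if O_b == 0 or E_a == 0 or E_b == 0:
        hr, ci, inf_flag = np.inf, (np.nan, np.nan), True
        if O_a == 0:
            hr, inf_flag = np.nan, True
    else:
        hr = (O_a / E_a) / (O_b / E_b)
        se = np.sqrt(1.0 / E_a + 1.0 / E_b)
        ci = (float(hr * np.exp(-1.959963984540054 * se)),
              float(hr * np.exp(1.959963984540054 * se)))
        inf_flag = False
    return LogrankResult(
        chi2=float(stat), p=p, hazard_ratio=float(hr), hr_ci95=ci,
        observed=(float(O_a), O_b), expected=(float(E_a), E_b),
        hr_infinite=inf_flag,
    )


def _falling_boltzmann(t, sf, t50, k):
    return sf + (1.0 - sf) / (1.0 + np.exp((t - t50) / k))


@dataclass
class MttfFit:
    mttf_s: float | None
    t50_s: float = np.nan
    k_s: float = np.nan
    plateau: float = np.nan
    converged: bool = False
    reason: str = ""


def mean_time_to_failure(curve: KMCurve, n_grid: int = 200) -> MttfFit:
    """Onset time of the survival decline.

    The KM staircase (sampled on a uniform grid over [0, t_max]) is fit with
    a decreasing sigmoid whose upper plateau is fixed at 1 and whose lower
    plateau is free; the mean time to failure is the tangent-construction
    onset t50 - 2|k|. Needs at least 3 distinct event times, otherwise the
    result is null and flagged.
    """
    if curve.degenerate or len(curve.times) < 3:
        return MttfFit(None, converged=False, reason="fewer than 3 distinct event times")
    t = np.linspace(0.0, curve.t_max, n_grid)
    s = curve.evaluate(t)
    s_min = float(s.min())
    mid = 0.5 * (1.0 + s_min)
    below = np.nonzero(s <= mid)[0]
    t50_0 = float(t[below[0]]) if len(below) else float(np.median(curve.times))
    p0 = (s_min, t50_0, max(curve.t_max / 20.0, 1e-6))
    try:
        popt, _ = curve_fit(
            _falling_boltzmann, t, s, p0=p0,
            bounds=([0.0, -np.inf, 1e-9], [1.0, np.inf, np.inf]), maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        return MttfFit(None, converged=False, reason=f"optimizer failed: {exc}")
    sf, t50, k = (float(v) for v in popt)
    return MttfFit(mttf_s=t50 - 2.0 * abs(k), t50_s=t50, k_s=k, plateau=sf, converged=True)


def pairwise_logrank(tables: list[EventTable]) -> pd.DataFrame:
    """All pairwise Mantel-Cox comparisons with Holm-adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    rows = []
    for a, b in combinations(tables, 2):
        res = logrank_test(a, b)
        rows.append({
            "group_a": a.group, "group_b": b.group,
            "chi2": res.chi2, "p": res.p,
            "hazard_ratio": res.hazard_ratio,
            "hr_ci95_low": res.hr_ci95[0], "hr_ci95_high": res.hr_ci95[1],
            "observed_a": res.observed[0], "observed_b": res.observed[1],
            "expected_a": res.expected[0], "expected_b": res.expected[1],
        })
    df = pd.DataFrame(rows)
    if len(df):
        df["p_holm"] = multipletests(df["p"].to_numpy(), method="holm")[1]
    return df
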