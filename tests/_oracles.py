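"""Independent brute-force oracles used only by the tests.

These deliberately avoid the package's own code paths: the product-limit
oracle walks the record list directly, and the log-rank oracle builds the
explicit 2x2 table at every event time and takes its first two moments from
scipy's hypergeometric distribution.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import chi2 as chi2_dist
from scipy.stats import hypergeom


def km_brute_force(times, events):
    """Product-limit survival by direct enumeration.

    Returns (distinct event times, survival just after each).
    """
    recs = sorted(zip(times, events))
    event_times = sorted({t for t, e in recs if e == 1})
    surv = []
    s = 1.0
    for t in event_times:
        at_risk = sum(1 for ti, _ in recs if ti >= t)
        deaths = sum(1 for ti, ei in recs if ti == t and ei == 1)
        s = s * (at_risk - deaths) / at_risk
        surv.append(s)
    return np.array(event_times), np.array(surv)


def logrank_brute_force(times_a, events_a, times_b, events_b):
    """Mantel-Cox statistic from explicitly enumerated 2x2 tables.

    At each pooled event time the table

                 event   no event
        group a   d1      n1-d1
        group b   d2      n2-d2

    has d1 ~ Hypergeom(M=n1+n2, n=d1+d2, N=n1) under the null; the moments
    come from scipy.stats.hypergeom. Returns (chi2, p, hazard_ratio).
    """
    pooled = sorted({t for t, e in zip(times_a, events_a) if e == 1}
                    | {t for t, e in zip(times_b, events_b) if e == 1})
    O = E = V = 0.0
    for t in pooled:
        n1 = sum(1 for ti in times_a if ti >= t)
        n2 = sum(1 for ti in times_b if ti >= t)
        d1 = sum(1 for ti, ei in zip(times_a, events_a) if ti == t and ei == 1)
        d2 = sum(1 for ti, ei in zip(times_b, events_b) if ti == t and ei == 1)
        rv = hypergeom(M=n1 + n2, n=d1 + d2, N=n1)
        O += d1
        with np.errstate(divide="ignore", invalid="ignore"):
            E += rv.mean()
            if n1 + n2 > 1:  # a 1-subject table has no variance (0/0 in scipy)
                V += rv.var()
    chi2 = (O - E) ** 2 / V if V > 0 else 0.0
    p = float(chi2_dist.sf(chi2, 1)) if V > 0 else 1.0
    O_b = float(sum(events_b))
    E_b = float(sum(events_a)) + O_b - E
    hr = np.inf if (O_b == 0 or E_b == 0) else (O / E) / (O_b / E_b)
    return chi2, p, hr


def best_matching_brute_force(times_a, times_b, window):
    """Maximum-cardinality one-to-one matching within the window, by
    exhaustive search over injections (only feasible for tiny peak sets)."""
    from itertools import permutations

    na, nb = len(times_a), len(times_b)
    if na > nb:
        return best_matching_brute_force(times_b, times_a, window)
    best = 0
    for perm in permutations(range(nb), na):
        n = sum(1 for i, j in enumerate(perm)
                if abs(times_a[i] - times_b[j]) <= window)
        best = max(best, n)
    return best
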