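"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — O(m²) loops, exact rational
arithmetic, explicit risk-set tabulation — and shares no code with the
package under test.
"""

from fractions import Fraction
from math import comb

import numpy as np


def bh_stepup(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up by direct minimisation, input order kept."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    for rank_i in range(m):
        candidates = [m * p[order[j]] / (j + 1) for j in range(rank_i, m)]
        q_sorted[rank_i] = min(1.0, min(candidates))
    q = np.empty(m)
    q[order] = q_sorted
    return q


def bonferroni(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    return np.minimum(1.0, p.size * p)


def fisher_two_sided(table) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration.

    Sums, in exact rational arithmetic, the probabilities of all tables with
    the observed margins whose probability does not exceed that of the
    observed table (the probability-ordering rule).
    """
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    pmf = {}
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pmf[k] = Fraction(comb(r1, k) * comb(r2, c1 - k), denom)
    p_obs = pmf[a]
    return float(sum(v for v in pmf.values() if v <= p_obs))


def km_product_limit(times, events):
    """(event_time, survival) pairs from the product-limit formula.

    Ties: events precede censorings at the same time, so a subject censored
    at t is still at risk for an event at t.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    s = 1.0
    out = []
    for t in sorted(set(times[events == 1])):
        n_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d / n_risk
        out.append((t, s))
    return out


def logrank_chi2(times, events, groups):
    """Two-group log-rank chi-square by explicit O/E/V tabulation."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = sorted(set(groups))
    assert len(labels) == 2
    in_a = groups == labels[0]
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = int(at_risk.sum())
        n_a = int((at_risk & in_a).sum())
        d = int(((times == t) & (events == 1)).sum())
        d_a = int(((times == t) & (events == 1) & in_a).sum())
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0
    return o_minus_e**2 / var
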