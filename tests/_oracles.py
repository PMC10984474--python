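"""Independent brute-force reference implementations used only by tests.

Deliberately naive (loops, textbook formulas) and kept free of any code
path from the package under test.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import chi2 as chi2_dist


def pearson_brute(x, y) -> float:
    """Textbook Pearson formula with explicit sums."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((x[i] - mx) * (y[i] - my) for i in range(n))
    den = math.sqrt(sum((x[i] - mx) ** 2 for i in range(n))) * math.sqrt(
        sum((y[i] - my) ** 2 for i in range(n))
    )
    return num / den


def auc_pairs_brute(values, events) -> float:
    """AUC by exhaustive comparison of every (death, survivor) pair."""
    deaths = [v for v, e in zip(values, events) if e == 1]
    survivors = [v for v, e in zip(values, events) if e == 0]
    total = 0.0
    for d in deaths:
        for s in survivors:
            if d > s:
                total += 1.0
            elif d == s:
                total += 0.5
    return total / (len(deaths) * len(survivors))


def auc_trapezoid(values, events) -> float:
    """Area under the empirical ROC curve by the trapezoidal rule."""
    v = np.asarray(values, dtype=float)
    e = np.asarray(events, dtype=int)
    thresholds = np.concatenate([[np.inf], np.unique(v)[::-1], [-np.inf]])
    tpr, fpr = [], []
    n1 = e.sum()
    n0 = len(e) - n1
    for c in thresholds:
        pred = v >= c
        tpr.append((pred & (e == 1)).sum() / n1)
        fpr.append((pred & (e == 0)).sum() / n0)
    return float(np.trapezoid(tpr, fpr))


def youden_brute(values, events, min_group_frac=0.1):
    """Exhaustive search over midpoint thresholds for the largest
    |sens + spec - 1|; ties toward balance, then the smaller cutoff.
    Returns (cutoff, j)."""
    v = np.asarray(values, dtype=float)
    e = np.asarray(events, dtype=int)
    uniq = np.unique(v)
    n = len(v)
    floor = max(1, math.ceil(min_group_frac * n))
    best = None
    for i in range(len(uniq) - 1):
        c = (uniq[i] + uniq[i + 1]) / 2.0
        n_high = int((v > c).sum())
        n_low = n - n_high
        if n_high < floor or n_low < floor:
            continue
        sens = ((v > c) & (e == 1)).sum() / e.sum()
        spec = ((v <= c) & (e == 0)).sum() / (n - e.sum())
        j = abs(sens + spec - 1.0)
        key = (j, -abs(n_high - n_low), -c)
        if best is None or key > best[0]:
            best = (key, c, j)
    return best[1], best[2]


def km_brute(times, events):
    """Product-limit estimator by direct tabulation; returns a function
    S(t) evaluated as a right-continuous step function."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    event_times = sorted(set(t[e == 1]))
    steps = []
    s = 1.0
    for tj in event_times:
        n_risk = int((t >= tj).sum())
        d = int(((t == tj) & (e == 1)).sum())
        s *= 1.0 - d / n_risk
        steps.append((tj, s))

    def S(query):
        out = 1.0
        for tj, sj in steps:
            if tj <= query:
                out = sj
        return out

    return S


def logrank_brute(times, events, groups):
    """Two-group log-rank by observed-minus-expected tabulation over the
    distinct event times; returns (chi2, p)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    labels = sorted(set(g.tolist()))
    a = g == labels[0]
    o_minus_e = 0.0
    var = 0.0
    for tj in sorted(set(t[e == 1])):
        at_risk = t >= tj
        n = int(at_risk.sum())
        n_a = int((at_risk & a).sum())
        d = int(((t == tj) & (e == 1)).sum())
        d_a = int(((t == tj) & (e == 1) & a).sum())
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1.0 - n_a / n) * (n - d) / (n - 1)
    chi2 = o_minus_e**2 / var
    p = float(chi2_dist.sf(chi2, df=1))
    return chi2, p
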