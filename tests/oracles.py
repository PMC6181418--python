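"""Independent brute-force reference implementations used as test oracles.

Deliberately written in the most literal, loop-based form possible — these
must stay independent of the vectorized package code paths they check.
"""

from __future__ import annotations

import numpy as np


def brute_logrank_2group(times, events, in_group2):
    """Two-group log-rank chi-square from the hypergeometric terms.

    Loops over distinct event times; at each, observed minus expected
    events in group 2 and the hypergeometric variance with tie correction.
    """
    times = list(map(float, times))
    events = list(map(int, events))
    g2 = list(map(bool, in_group2))
    event_times = sorted({t for t, e in zip(times, events) if e == 1})
    o_minus_e = 0.0
    var = 0.0
    for tt in event_times:
        at_risk = [i for i, t in enumerate(times) if t >= tt]
        n = len(at_risk)
        d = sum(1 for i in at_risk if times[i] == tt and events[i] == 1)
        n2 = sum(1 for i in at_risk if g2[i])
        d2 = sum(1 for i in at_risk
                 if times[i] == tt and events[i] == 1 and g2[i])
        o_minus_e += d2 - d * n2 / n
        if n > 1:
            var += d * (n2 / n) * (1 - n2 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0
    return o_minus_e ** 2 / var


def brute_km(times, events):
    """Product-limit estimate computed by the textbook recursion.

    Returns (event_times, survival just after each event time).
    """
    pairs = sorted(zip(map(float, times), map(int, events)))
    event_times = sorted({t for t, e in pairs if e == 1})
    s = 1.0
    out = []
    for tt in event_times:
        n = sum(1 for t, _ in pairs if t >= tt)
        d = sum(1 for t, e in pairs if t == tt and e == 1)
        s *= 1.0 - d / n
        out.append((tt, s))
    return [t for t, _ in out], [s for _, s in out]


def brute_bh(pvals):
    """Literal step-up Benjamini-Hochberg, one comparison at a time."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, pvals[i] * m / rank)
        q[i] = min(running_min, 1.0)
    return q


def brute_cox_1cov(times, events, x, grid=None):
    """Grid maximization of the written-out single-covariate partial
    likelihood (no ties assumed in the data used with it)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    x = np.asarray(x, float)

    def pl(beta):
        ll = 0.0
        for i in np.where(events == 1)[0]:
            risk = times >= times[i]
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
        return ll

    if grid is None:
        grid = np.linspace(-5, 5, 100001)
    vals = [pl(b) for b in grid]
    return float(grid[int(np.argmax(vals))])


def brute_ranksum_exact_p(a, b):
    """Exact two-sided rank-sum p by enumerating all label assignments."""
    from itertools import combinations

    pooled = list(a) + list(b)
    n1 = len(a)
    ranks = {}
    srt = sorted(pooled)
    # midranks for ties
    import collections
    positions = collections.defaultdict(list)
    for pos, v in enumerate(srt, start=1):
        positions[v].append(pos)
    rank_of = {v: sum(ps) / len(ps) for v, ps in positions.items()}
    obs = sum(rank_of[v] for v in a)
    mean = n1 * (len(pooled) + 1) / 2
    count = 0
    total = 0
    for combo in combinations(range(len(pooled)), n1):
        r = sum(rank_of[pooled[i]] for i in combo)
        total += 1
        if abs(r - mean) >= abs(obs - mean) - 1e-12:
            count += 1
    return count / total
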