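"""Independent brute-force oracles used to cross-check the implementation.

These deliberately use different algorithms from the package: explicit
rotation scans for circular runs, counting ECDFs, exact hypergeometric sums
with integer arithmetic, and exhaustive permutation enumeration.
"""

import itertools
import math
from fractions import Fraction

import numpy as np


def crescent_oracle(values, threshold):
    """(coverage, integrated_fi, position) by scanning every rotation.

    For each rotation that places a sub-threshold sample at the seam, find
    contiguous supra-threshold runs with a plain linear scan; pick the
    longest (earliest original start on ties); trapezoid-sum inside it.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    supra = v > threshold
    if supra.all():
        a = v - threshold
        integ = sum((a[i] + a[(i + 1) % n]) / 2 for i in range(n))
        ang = 2 * np.pi * np.arange(n) / n
        pos = (math.degrees(math.atan2((a * np.sin(ang)).sum(), (a * np.cos(ang)).sum()))
               % 360.0) / 360.0 * 100.0
        return 100.0, float(integ), pos
    if not supra.any():
        return 0.0, 0.0, None
    best = None  # (length, start)
    for rot in range(n):
        if supra[rot]:
            continue
        order = [(rot + k) % n for k in range(n)]
        run = []
        for idx in order + [order[0]]:  # sentinel sub-threshold sample flushes the tail
            if supra[idx]:
                run.append(idx)
            else:
                if run and (best is None or len(run) > best[0]
                            or (len(run) == best[0] and run[0] < best[1])):
                    best = (len(run), run[0])
                run = []
        break  # one valid rotation suffices; runs are rotation-independent
    length, start = best
    if length == 1:
        return 0.0, 0.0, None
    a = [v[(start + k) % n] - threshold for k in range(length)]
    integ = sum((a[k] + a[k + 1]) / 2 for k in range(length - 1))
    pos = ((start + (length - 1) / 2) * (100.0 / n)) % 100.0
    return (length - 1) * (100.0 / n), float(integ), pos


def ks_d_oracle(a, b):
    """sup |F_a - F_b| over all pooled sample points, by counting."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    best = 0.0
    for x in np.concatenate([a, b]):
        fa = np.mean(a <= x)
        fb = np.mean(b <= x)
        best = max(best, abs(fa - fb))
    return float(best)


def ecdf_oracle(values):
    """(unique sorted values, cumulative fraction) by direct counting."""
    v = np.asarray(values, float)
    ux = np.unique(v)
    frac = [np.mean(v <= x) for x in ux]
    return ux, np.asarray(frac)


def fisher_oracle(table):
    """Two-sided Fisher p by exact hypergeometric enumeration (Fractions)."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    ntot = r1 + r2

    def hyper(x):
        return (Fraction(math.comb(r1, x) * math.comb(r2, c1 - x), math.comb(ntot, c1)))

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = hyper(a)
    total = sum(hyper(x) for x in range(lo, hi + 1) if hyper(x) <= p_obs)
    return float(total)


def mann_whitney_exact_oracle(x, y):
    """Two-sided exact Mann-Whitney p by enumerating group assignments."""
    from scipy.stats import rankdata

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = len(x), len(y)
    ranks = rankdata(np.concatenate([x, y]))
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2
    le = ge = total = 0
    for combo in itertools.combinations(range(nx + ny), nx):
        u = ranks[list(combo)].sum() - nx * (nx + 1) / 2
        total += 1
        if u <= u_obs + 1e-9:
            le += 1
        if u >= u_obs - 1e-9:
            ge += 1
    return min(1.0, 2.0 * min(le, ge) / total)


def binomial_ci99(p, n):
    """Exact (Clopper-Pearson) central 99% interval for a Binomial(n, p) fraction."""
    from scipy.stats import binom

    lo = binom.ppf(0.005, n, p) / n
    hi = binom.ppf(0.995, n, p) / n
    return lo, hi
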