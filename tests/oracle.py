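"""Independent brute-force references for the MIC search.

Deliberately naive: plain-Python counting, math.log, and exhaustive
enumeration of every grid (all cut placements between distinct values on
both axes).  Shares no code path with the package implementation.
"""

import itertools
import math
from collections import Counter


def mi_bits(pairs):
    """Plug-in mutual information (bits) of labelled pairs [(a, b), ...]."""
    n = len(pairs)
    joint = Counter(pairs)
    px = Counter(a for a, _ in pairs)
    py = Counter(b for _, b in pairs)
    total = 0.0
    for (a, b), c in joint.items():
        p = c / n
        total += p * math.log2(p * n * n / (px[a] * py[b]))
    return total


def _cut_sets(values):
    """Positions (in sort order) where a cut separates distinct values."""
    s = sorted(values)
    return [i for i in range(1, len(s)) if s[i - 1] < s[i]]


def _bin_of(rank, cuts):
    b = 0
    for c in cuts:
        if rank >= c:
            b += 1
    return b


def best_mi_exhaustive(x, y, nx, ny):
    """Max MI (bits) over every nx-by-ny grid of the sample."""
    n = len(x)
    xr = _ranks(x)
    yr = _ranks(y)
    cx_all, cy_all = _cut_sets(x), _cut_sets(y)
    kx = min(nx - 1, len(cx_all))
    ky = min(ny - 1, len(cy_all))
    if kx == 0 or ky == 0:
        return 0.0
    best = 0.0
    for cx in itertools.combinations(cx_all, kx):
        xb = [_bin_of(r, cx) for r in xr]
        for cy in itertools.combinations(cy_all, ky):
            yb = [_bin_of(r, cy) for r in yr]
            best = max(best, mi_bits(list(zip(xb, yb))))
    return best


def _ranks(v):
    order = sorted(range(len(v)), key=lambda i: (v[i], i))
    r = [0] * len(v)
    for pos, i in enumerate(order):
        r[i] = pos
    return r


def mic_exhaustive(x, y, b_exponent=0.6):
    """MIC by full enumeration of all admissible grids (x*y <= B(n))."""
    n = len(x)
    budget = max(n ** b_exponent, 4.0)
    best = 0.0
    for nx in range(2, int(budget // 2) + 1):
        for ny in range(2, int(budget // nx) + 1):
            mi = best_mi_exhaustive(x, y, nx, ny)
            best = max(best, mi / math.log2(min(nx, ny)))
    return best


def auc_by_pair_counting(scores, labels):
    """AUC as the fraction of concordant (pos, neg) pairs, ties counting 1/2."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0
               for p in pos for q in neg)
    return wins / (len(pos) * len(neg))
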