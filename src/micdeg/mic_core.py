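"""Maximal information coefficient (MIC) between gene expression and phenotype.

MIC treats a (phenotype, expression) sample as points in the plane, grids the
plane with every x-by-y bin partition whose total cell count xy does not
exceed a budget B(n), and records the normalized maximal mutual information

    M[x][y] = max_grids I*(D; x, y) / log min{x, y}.

MIC is the largest entry of this characteristic matrix.  The normalization
makes every entry (and hence MIC) lie in [0, 1]; the ratio is invariant to
the logarithm base, so mutual information is computed in bits throughout.

Two search strategies are provided.  For small samples (n at or below
``exact_threshold``) every admissible grid is enumerated exhaustively, which
is exact.  For larger samples the conventional MINE-style search is used:
equipartition one axis, then a dynamic program over clump boundaries finds
the optimal partition of the free axis; both orientations are searched and
the elementwise maximum retained.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PairedSample",
    "GridPartition",
    "CharacteristicMatrix",
    "mutual_information",
    "optimize_partition",
    "characteristic_matrix",
    "mic",
    "mic_scores",
]

#: default exponent of the grid budget B(n) = n**B_exponent
DEFAULT_B_EXPONENT = 0.6
#: default multiplier bounding the number of superclumps in the DP search
DEFAULT_CLUMPS_FACTOR = 15
#: samples up to this size use exact exhaustive grid enumeration
DEFAULT_EXACT_THRESHOLD = 30


@dataclass(frozen=True)
class PairedSample:
    """A bivariate sample: phenotype values ``x`` paired with expression ``y``."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
            raise ValueError("x and y must be 1-D vectors of equal length")
        if x.size < 4:
            raise ValueError(f"need at least 4 paired observations, got {x.size}")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValueError("missing or non-finite values are not allowed")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return self.x.size


@dataclass(frozen=True)
class GridPartition:
    """Cut points (strictly increasing) inducing bins on each axis."""

    x_edges: np.ndarray
    y_edges: np.ndarray

    def __post_init__(self):
        for name in ("x_edges", "y_edges"):
            e = np.asarray(getattr(self, name), dtype=float)
            if e.ndim != 1 or (np.diff(e) <= 0).any():
                raise ValueError(f"{name} must be strictly increasing")
            object.__setattr__(self, name, e)


@dataclass
class CharacteristicMatrix:
    """Normalized maximal mutual information per grid size, indexed [x][y]."""

    entries: dict = field(default_factory=dict)  # (nx, ny) -> value in [0, 1]
    b_exponent: float = DEFAULT_B_EXPONENT

    def max_entry(self) -> float:
        return max(self.entries.values(), default=0.0)


def grid_budget(n: int, b_exponent: float = DEFAULT_B_EXPONENT) -> float:
    """Grid-size budget B(n) = n**b_exponent, floored at 4 so the 2x2 grid
    is always admissible."""
    if not 0.0 < b_exponent < 1.0:
        raise ValueError("b_exponent must lie in (0, 1)")
    return max(float(n) ** b_exponent, 4.0)


def mutual_information(counts) -> float:
    """Plug-in mutual information (bits) of a 2-D contingency table.

    Empty cells contribute nothing (0*log 0 == 0).  Raises on an empty or
    negative table.
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.size == 0:
        raise ValueError("counts must be a non-empty 2-D table")
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    total = table.sum()
    if total < 1:
        raise ValueError("table total must be at least 1")
    pxy = table / total
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = pxy / (px * py)
    return float(np.sum(pxy[nz] * np.log2(ratio[nz])))


def _mi_from_cells(cell_counts: np.ndarray) -> float:
    """MI in bits from a (rows, cols) count matrix; tolerates empty rows/cols."""
    return mutual_information(cell_counts)


def _cut_positions(sorted_vals: np.ndarray) -> np.ndarray:
    """Indices i where a cut between sorted_vals[i-1] and sorted_vals[i] is
    meaningful (the two values differ)."""
    return np.nonzero(np.diff(sorted_vals) > 0)[0] + 1


def _bin_assign(sorted_rank_positions: np.ndarray, cuts: tuple[int, ...], n: int) -> np.ndarray:
    """Bin index for each point given cut positions in the sorted order."""
    edges = np.array(cuts)
    return np.searchsorted(edges, sorted_rank_positions, side="right")


def _exhaustive_best_mi(xa: np.ndarray, ya: np.ndarray, nx: int, ny: int) -> float:
    """Best mutual information over *all* nx-by-ny grids of the sample.

    Cuts are placed between distinct values on each axis; every combination
    is evaluated.  Exact, intended for small n.
    """
    n = xa.size
    ox = np.argsort(xa, kind="stable")
    oy = np.argsort(ya, kind="stable")
    xr = np.empty(n, dtype=int)
    yr = np.empty(n, dtype=int)
    xr[ox] = np.arange(n)
    yr[oy] = np.arange(n)
    x_cuts = _cut_positions(xa[ox])
    y_cuts = _cut_positions(ya[oy])
    if len(x_cuts) < nx - 1 or len(y_cuts) < ny - 1:
        return 0.0 if (len(x_cuts) == 0 or len(y_cuts) == 0) else _exhaustive_best_mi(
            xa, ya, min(nx, len(x_cuts) + 1), min(ny, len(y_cuts) + 1)
        )
    best = 0.0
    for cx in itertools.combinations(x_cuts, nx - 1):
        xb = np.searchsorted(np.asarray(cx), xr, side="right")
        for cy in itertools.combinations(y_cuts, ny - 1):
            yb = np.searchsorted(np.asarray(cy), yr, side="right")
            table = np.zeros((nx, ny))
            np.add.at(table, (xb, yb), 1.0)
            mi = _mi_from_cells(table)
            if mi > best:
                best = mi
    return best


# ---------------------------------------------------------------------------
# MINE-style dynamic program for larger samples
# ---------------------------------------------------------------------------

def _equipartition(vals: np.ndarray, k: int) -> np.ndarray:
    """Assign each point to one of up to k bins of near-equal occupancy.

    Ties (equal values) always share a bin.  Returns a bin index per point
    (original order).
    """
    n = vals.size
    order = np.argsort(vals, kind="stable")
    sorted_vals = vals[order]
    assign_sorted = np.zeros(n, dtype=int)
    desired = n / k
    b = 0
    start = 0
    i = 0
    while i < n:
        j = i + 1
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        # place run [i, j) in current bin; open a new bin if current is full
        if i > start and (i - start) + 0.5 * (j - i) > desired and b < k - 1:
            b += 1
            start = i
        assign_sorted[i:j] = b
        i = j
    out = np.empty(n, dtype=int)
    out[order] = assign_sorted
    return out


def _clump_row_counts(row_assign_sorted: np.ndarray, free_sorted: np.ndarray,
                      n_rows: int) -> np.ndarray:
    """Collapse points (in free-axis order) into clumps of equal free values;
    return per-clump row-count matrix (clumps x rows)."""
    n = free_sorted.size
    boundaries = np.concatenate(([0], _cut_positions(free_sorted), [n]))
    m = len(boundaries) - 1
    counts = np.zeros((m, n_rows))
    for c in range(m):
        seg = row_assign_sorted[boundaries[c]: boundaries[c + 1]]
        counts[c] = np.bincount(seg, minlength=n_rows)
    return counts


def _superclump(counts: np.ndarray, limit: int) -> np.ndarray:
    """Merge adjacent clumps so at most ``limit`` remain (mass equipartition)."""
    m = counts.shape[0]
    if m <= limit:
        return counts
    mass = counts.sum(axis=1)
    cum = np.cumsum(mass)
    total = cum[-1]
    merged = []
    start = 0
    for b in range(limit):
        target = total * (b + 1) / limit
        end = int(np.searchsorted(cum, target - 1e-9) + 1)
        end = min(max(end, start + 1), m)
        merged.append(counts[start:end].sum(axis=0))
        start = end
        if start >= m:
            break
    return np.asarray(merged)


def _entropy_bits(counts: np.ndarray) -> float:
    total = counts.sum()
    if total <= 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def optimize_partition(row_assign_sorted, free_sorted, n_rows: int,
                       max_bins: int,
                       clumps_factor: int = DEFAULT_CLUMPS_FACTOR) -> np.ndarray:
    """Optimal free-axis partitions against a fixed row partition.

    Points must be given in sorted order of the free axis:
    ``row_assign_sorted[i]`` is the fixed-axis bin of the i-th point and
    ``free_sorted[i]`` its free-axis value.  Returns, for each bin count
    k = 2..max_bins, the maximum mutual information (bits) achievable with
    exactly k free-axis bins, via a dynamic program over clump boundaries.

    Relies on I(P;Q) = H(Q) - (1/n) * sum_j m_j H(Q | bin j): minimizing the
    summed within-bin row entropy over prefix clumps is an additive DP.
    """
    if max_bins < 2:
        raise ValueError("max_bins must be at least 2")
    row_assign_sorted = np.asarray(row_assign_sorted, dtype=int)
    free_sorted = np.asarray(free_sorted, dtype=float)
    n = free_sorted.size
    counts = _clump_row_counts(row_assign_sorted, free_sorted, n_rows)
    counts = _superclump(counts, max(clumps_factor * max_bins, max_bins))
    m = counts.shape[0]
    cum = np.vstack([np.zeros(n_rows), np.cumsum(counts, axis=0)])  # (m+1, rows)
    h_all = _entropy_bits(cum[m])

    # w[s, t]: mass * entropy of rows in clumps (s, t]
    w = np.full((m + 1, m + 1), np.inf)
    for s in range(m):
        for t in range(s + 1, m + 1):
            seg = cum[t] - cum[s]
            w[s, t] = seg.sum() * _entropy_bits(seg)

    kmax = min(max_bins, m)
    # G[l][t]: min summed within-bin entropy mass using first t clumps, l bins
    G = np.full((kmax + 1, m + 1), np.inf)
    G[0, 0] = 0.0
    for l in range(1, kmax + 1):
        for t in range(l, m + 1):
            G[l, t] = np.min(G[l - 1, l - 1:t] + w[l - 1:t, t])

    out = np.zeros(max_bins - 1)
    best = 0.0
    for k in range(2, max_bins + 1):
        if k <= kmax and np.isfinite(G[k, m]):
            val = h_all - G[k, m] / n
            best = max(best, val)
        out[k - 2] = max(best, 0.0)
    return out


def characteristic_matrix(sample: PairedSample,
                          b_exponent: float = DEFAULT_B_EXPONENT,
                          clumps_factor: int = DEFAULT_CLUMPS_FACTOR,
                          exact_threshold: int = DEFAULT_EXACT_THRESHOLD,
                          ) -> CharacteristicMatrix:
    """Characteristic matrix M[x][y] over all grids with x*y <= B(n)."""
    n = sample.n
    budget = grid_budget(n, b_exponent)
    entries: dict[tuple[int, int], float] = {}
    max_side = int(budget // 2)
    if n <= exact_threshold:
        for nx in range(2, max_side + 1):
            for ny in range(2, int(budget // nx) + 1):
                mi = _exhaustive_best_mi(sample.x, sample.y, nx, ny)
                entries[(nx, ny)] = mi / np.log2(min(nx, ny))
    else:
        acc: dict[tuple[int, int], float] = {}
        for xa, ya in ((sample.x, sample.y), (sample.y, sample.x)):
            # fixed partition on ya (rows), DP on xa (columns)
            for ny in range(2, max_side + 1):
                max_nx = int(budget // ny)
                if max_nx < 2:
                    continue
                rows = _equipartition(ya, ny)
                order = np.argsort(xa, kind="stable")
                vec = optimize_partition(rows[order], xa[order], ny, max_nx,
                                         clumps_factor)
                for nx in range(2, max_nx + 1):
                    key = (nx, ny) if xa is sample.x else (ny, nx)
                    val = vec[nx - 2]
                    if val > acc.get(key, -1.0):
                        acc[key] = val
        for (nx, ny), mi in acc.items():
            norm = mi / np.log2(min(nx, ny))
            key = (nx, ny)
            entries[key] = max(entries.get(key, 0.0), min(norm, 1.0))
    cm = CharacteristicMatrix(entries=entries, b_exponent=b_exponent)
    for k, v in cm.entries.items():
        cm.entries[k] = float(min(max(v, 0.0), 1.0))
    return cm


def mic(sample, b_exponent: float = DEFAULT_B_EXPONENT,
        clumps_factor: int = DEFAULT_CLUMPS_FACTOR,
        exact_threshold: int = DEFAULT_EXACT_THRESHOLD) -> float:
    """MIC of a paired sample: the largest characteristic-matrix entry."""
    if not isinstance(sample, PairedSample):
        sample = PairedSample(*sample)
    cm = characteristic_matrix(sample, b_exponent, clumps_factor, exact_threshold)
    return cm.max_entry()


def _binary_2x2_scores(matrix: np.ndarray, phenotype: np.ndarray) -> np.ndarray:
    """Vectorized exact MIC for a binary phenotype when only 2x2 grids are
    admissible: per gene, the best single y-cut normalized MI.

    With two phenotype values the only meaningful x-cut separates the
    classes, so the exhaustive search reduces to scanning the n-1 candidate
    expression cuts; this is done for all genes at once.
    """
    g, n = matrix.shape
    n1 = int(phenotype.sum())
    n0 = n - n1
    order = np.argsort(matrix, axis=1, kind="stable")
    ysort = np.take_along_axis(matrix, order, axis=1)
    psort = phenotype[order]  # (g, n)
    cases_below = np.cumsum(psort, axis=1)[:, :-1].astype(float)  # cut after t+1 pts
    t = np.arange(1, n, dtype=float)[None, :]
    a = cases_below            # cases in low bin
    b = t - a                  # controls in low bin
    c = n1 - a
    d = n0 - b
    cells = np.stack([a, b, c, d], axis=0)  # (4, g, n-1)
    rowm = np.stack([a + b, a + b, n - a - b, n - a - b], axis=0)
    colm = np.stack([n1, n0, n1, n0], axis=0)[:, None, None] * np.ones_like(cells)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = cells / n * np.log2(cells * n / (rowm * colm))
    term[cells == 0] = 0.0
    mi = term.sum(axis=0)  # (g, n-1)
    valid = ysort[:, 1:] > ysort[:, :-1]
    mi[~valid] = -np.inf
    scores = mi.max(axis=1)
    scores[~np.isfinite(scores)] = 0.0  # constant gene: no admissible cut
    return np.clip(scores, 0.0, 1.0)


def mic_scores(matrix, phenotype, b_exponent: float = DEFAULT_B_EXPONENT,
               clumps_factor: int = DEFAULT_CLUMPS_FACTOR,
               exact_threshold: int = DEFAULT_EXACT_THRESHOLD) -> np.ndarray:
    """Per-gene MIC between expression (rows of ``matrix``) and phenotype.

    ``matrix`` is genes x samples; ``phenotype`` a 0/1 vector with both
    classes present.  Returns a vector of MIC scores in [0, 1].
    """
    matrix = np.asarray(matrix, dtype=float)
    phenotype = np.asarray(phenotype)
    if matrix.ndim != 2 or matrix.shape[1] != phenotype.size:
        raise ValueError("matrix columns must align with phenotype length")
    classes = np.unique(phenotype)
    if classes.size < 2:
        raise ValueError("phenotype must contain both classes")
    n = phenotype.size
    budget = grid_budget(n, b_exponent)
    if classes.size == 2 and budget < 6.0:
        return _binary_2x2_scores(matrix, phenotype.astype(float))
    return np.array([
        mic(PairedSample(phenotype.astype(float), row), b_exponent,
            clumps_factor, exact_threshold)
        for row in matrix
    ])
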