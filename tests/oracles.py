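"""Independent brute-force oracles used to validate the fast implementations.

Everything here is written directly from the defining formulas (explicit
loops over haplotype pairs, literal transcription of the Weir-Cockerham 1984
and Tajima 1989 equations, stepwise EHH walks) and deliberately shares no
code with the package.
"""
from __future__ import annotations

import itertools
import math

import numpy as np

MISSING = -1


# ---------------------------------------------------------------------------
# diversity / differentiation
# ---------------------------------------------------------------------------

def pi_site_oracle(column: np.ndarray) -> float:
    """Mean pairwise difference at one site over non-missing haplotypes."""
    vals = [v for v in column if v != MISSING]
    n = len(vals)
    if n < 2:
        return 0.0
    diff = pairs = 0
    for a, b in itertools.combinations(vals, 2):
        pairs += 1
        diff += int(a != b)
    return diff / pairs


def window_pi_oracle(H: np.ndarray, site_idx, window_len: int) -> float:
    return sum(pi_site_oracle(H[:, j]) for j in site_idx) / window_len


def wc84_site_oracle(pop_haps: list) -> tuple:
    """WC84 variance components (a, b, c) at one site, diploid estimator.

    ``pop_haps`` holds one (2*n_i,) haplotype vector per population;
    consecutive entries form individuals. Literal transcription of the
    two-allele, r-population equations (eq. 2-4 of the 1984 paper).
    Returns (nan, nan, nan) where undefined.
    """
    r = len(pop_haps)
    n = []
    p = []
    h = []
    for hap in pop_haps:
        inds = [(hap[2 * i], hap[2 * i + 1]) for i in range(len(hap) // 2)]
        inds = [(a, b) for a, b in inds if a != MISSING and b != MISSING]
        if not inds:
            return (math.nan,) * 3
        n_i = len(inds)
        p_i = sum(a + b for a, b in inds) / (2 * n_i)
        h_i = sum(1 for a, b in inds if a != b) / n_i
        n.append(n_i)
        p.append(p_i)
        h.append(h_i)
    nbar = sum(n) / r
    if nbar <= 1:
        return (math.nan,) * 3
    nc = (r * nbar - sum(x * x for x in n) / (r * nbar)) / (r - 1)
    if nc <= 0:
        return (math.nan,) * 3
    pbar = sum(n_i * p_i for n_i, p_i in zip(n, p)) / (r * nbar)
    s2 = sum(n_i * (p_i - pbar) ** 2 for n_i, p_i in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(n_i * h_i for n_i, h_i in zip(n, h)) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    return a, b, c


def wc84_haploid_site_oracle(pop_haps: list) -> tuple:
    """Haploid WC84 variant: every haplotype an individual, no het term."""
    r = len(pop_haps)
    n, p = [], []
    for hap in pop_haps:
        vals = [v for v in hap if v != MISSING]
        if len(vals) < 2:
            return (math.nan,) * 2
        n.append(len(vals))
        p.append(sum(vals) / len(vals))
    nbar = sum(n) / r
    nc = (r * nbar - sum(x * x for x in n) / (r * nbar)) / (r - 1)
    if nbar <= 1 or nc <= 0:
        return (math.nan,) * 2
    pbar = sum(n_i * p_i for n_i, p_i in zip(n, p)) / (r * nbar)
    s2 = sum(n_i * (p_i - pbar) ** 2 for n_i, p_i in zip(n, p)) / ((r - 1) * nbar)
    a = (nbar / nc) * (s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2)
    return a, b


def window_fst_oracle(pop_haps_matrices: list, site_idx, variant="diploid") -> float:
    num = den = 0.0
    for j in site_idx:
        cols = [M[:, j] for M in pop_haps_matrices]
        if variant == "diploid":
            a, b, c = wc84_site_oracle(cols)
            if math.isnan(a):
                continue
            num += a
            den += a + b + c
        else:
            a, b = wc84_haploid_site_oracle(cols)
            if math.isnan(a):
                continue
            num += a
            den += a + b
    return num / den if den != 0 else math.nan


def tajima_d_oracle(H: np.ndarray, site_idx, n: int) -> float:
    """Tajima (1989) D from explicit constants; NaN when S = 0."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    S = 0
    pi_hat = 0.0
    for j in site_idx:
        col = H[:, j]
        vals = [v for v in col if v != MISSING]
        ones = sum(vals)
        if 0 < ones < len(vals):
            S += 1
        pi_hat += pi_site_oracle(col)
    if S == 0:
        return math.nan
    return (pi_hat - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def r2_oracle(x: np.ndarray, y: np.ndarray) -> float:
    keep = [(a, b) for a, b in zip(x, y) if a != MISSING and b != MISSING]
    if len(keep) < 2:
        return math.nan
    xa = [a for a, _ in keep]
    ya = [b for _, b in keep]
    pa = sum(xa) / len(xa)
    pb = sum(ya) / len(ya)
    if pa in (0, 1) or pb in (0, 1):
        return math.nan
    pab = sum(a * b for a, b in keep) / len(keep)
    d = pab - pa * pb
    return d * d / (pa * (1 - pa) * pb * (1 - pb))


# ---------------------------------------------------------------------------
# EHH machinery
# ---------------------------------------------------------------------------

def ehh_at_offset_oracle(M: np.ndarray, core: int, j: int) -> float:
    """Pairwise-identity EHH over the inclusive span between core and j."""
    lo, hi = min(core, j), max(core, j)
    m = M.shape[0]
    ident = 0
    for a, b in itertools.combinations(range(m), 2):
        if np.array_equal(M[a, lo:hi + 1], M[b, lo:hi + 1]):
            ident += 1
    return ident / (m * (m - 1) / 2)


def ehh_side_oracle(M, positions, core, step, mode,
                    cutoff=0.05, max_extend_bp=1_000_000,
                    max_extend_sites=200, max_gap=200_000):
    """Stepwise EHH walk with truncation rules; mirrors the documented scan
    semantics using only the pairwise-identity definition above."""
    S = len(positions)
    xs, ys = [], []
    k = 0
    while True:
        k += 1
        j = core + step * k
        if j < 0 or j >= S:
            return xs, ys, "edge"
        prev = core + step * (k - 1)
        if abs(int(positions[j]) - int(positions[prev])) > max_gap:
            return xs, ys, "gap"
        if mode == "bp":
            if abs(int(positions[j]) - int(positions[core])) > max_extend_bp:
                return xs, ys, "max"
        elif k > max_extend_sites:
            return xs, ys, "max"
        e = ehh_at_offset_oracle(M, core, j)
        xs.append(j)
        ys.append(e)
        if e < cutoff:
            return xs, ys, "ok"


def ihh_oracle(M, positions, core, mode, **kw):
    """Two-sided trapezoid integral of the stepwise oracle curve.

    Returns (ihh, status); status "edge"/"gap" voids the core.
    """
    total = 0.0
    for step in (-1, +1):
        xs, ys, status = ehh_side_oracle(M, positions, core, step, mode, **kw)
        if status in ("edge", "gap"):
            return math.nan, status
        if mode == "bp":
            x = [0.0] + [abs(float(positions[j]) - float(positions[core])) for j in xs]
        else:
            x = list(range(len(xs) + 1))
        y = [1.0] + list(ys)
        for i in range(1, len(x)):
            total += 0.5 * (y[i] + y[i - 1]) * (x[i] - x[i - 1])
    return total, "ok"


# ---------------------------------------------------------------------------
# rank-sum and jackknife
# ---------------------------------------------------------------------------

def ranksum_z_oracle(x, y) -> float:
    """Normal-approximation Mann-Whitney z with tie correction."""
    allv = sorted(list(x) + list(y))
    ranks = {}
    i = 0
    while i < len(allv):
        j = i
        while j < len(allv) and allv[j] == allv[i]:
            j += 1
        for k in range(i, j):
            ranks.setdefault(allv[i], (i + j + 1) / 2)
        i = j
    rx = sum(ranks[v] for v in x)
    n1, n2 = len(x), len(y)
    U = rx - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    tie_term = 0.0
    from collections import Counter

    for t in Counter(allv).values():
        tie_term += t ** 3 - t
    n = n1 + n2
    var = n1 * n2 / 12 * ((n + 1) - tie_term / (n * (n - 1)))
    return (U - mu) / math.sqrt(var)


def jackknife_se_oracle(num_blocks, den_blocks) -> float:
    """Delete-one jackknife SE for a ratio of sums, from per-block sums."""
    g = len(num_blocks)
    tot_n, tot_d = sum(num_blocks), sum(den_blocks)
    d_del = [(tot_n - nb) / (tot_d - db) for nb, db in zip(num_blocks, den_blocks)]
    mean = sum(d_del) / g
    return math.sqrt((g - 1) / g * sum((x - mean) ** 2 for x in d_del))


def dstat_oracle(freqs: np.ndarray) -> float:
    """D from per-site (p1, p2, p3, p4) frequencies by direct summation."""
    num = den = 0.0
    for p1, p2, p3, p4 in freqs:
        abba = (1 - p1) * p2 * p3 * (1 - p4)
        baba = p1 * (1 - p2) * p3 * (1 - p4)
        num += abba - baba
        den += abba + baba
    return num / den


# ---------------------------------------------------------------------------
# intervals
# ---------------------------------------------------------------------------

def overlap_oracle(genes, regions):
    """All (gene, region) index pairs with >= 1 bp overlap.

    genes: (contig, start0, end0) half-open; regions likewise.
    """
    hits = set()
    for gi, (gc, gs, ge) in enumerate(genes):
        for ri, (rc, rs, re) in enumerate(regions):
            if gc == rc and min(ge, re) - max(gs, rs) > 0:
                hits.add((gi, ri))
    return hits
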