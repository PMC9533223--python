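"""Windowed diversity and differentiation statistics.

Implements per-window nucleotide diversity (pi per bp), weighted
Weir & Cockerham (1984) F_ST, Tajima's D and linkage-disequilibrium decay,
on the phased haplotype container of :mod:`sweepkit.core`.

Conventions
-----------
* pi divides the summed per-site heterozygosity by the window length in bp
  (invariant sites contribute zero), matching the windowed-pi convention of
  standard VCF toolchains; typical values for a diverse plant cohort are of
  order 1e-3 - 1e-2 per bp.
* "Weighted" F_ST is the ratio of sums of the WC84 variance components over
  all defined sites in the window: sum(a) / sum(a + b + c). Small negative
  windows are reported as computed, never clamped.
* Tajima's D uses mean pairwise differences in count units (not per bp) and
  the Tajima (1989) constants computed from the population haplotype count.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, HaplotypeDataset, window_site_slices

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# per-site building blocks
# ---------------------------------------------------------------------------

def _pop_counts(ds: HaplotypeDataset, pop: str):
    """Non-missing allele counts (c0, c1) per site for one population."""
    Hp = ds.H[ds.haplotype_rows(pop)]
    c1 = (Hp == 1).sum(axis=0).astype(np.int64)
    c0 = (Hp == 0).sum(axis=0).astype(np.int64)
    return c0, c1


def site_pi(ds: HaplotypeDataset, pop: str) -> np.ndarray:
    """Per-site heterozygosity 2*c0*c1 / (n*(n-1)) over non-missing entries."""
    c0, c1 = _pop_counts(ds, pop)
    n = c0 + c1
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(n >= 2, 2.0 * c0 * c1 / (n * (n - 1.0)), 0.0)
    return pi


def wc84_components(ds: HaplotypeDataset, pop_a: str, pop_b: str,
                    variant: str = "diploid"):
    """Per-site Weir & Cockerham (1984) variance components for two populations.

    Returns arrays ``(a, b, c)`` (among-population, among-individual-within-
    population, within-individual). Sites where either population has fewer
    than two non-missing haplotypes, or where the mean sample size does not
    exceed one individual, are NaN.

    ``variant="diploid"`` uses individuals rebuilt from consecutive haplotype
    row pairs with the observed-heterozygosity term (the estimator of the
    standard VCF toolchain). ``variant="haploid"`` treats every haplotype as
    an individual with no heterozygosity term (c = 0), a simpler form useful
    for oracle testing.
    """
    if pop_a == pop_b:
        raise ValueError("pop_a and pop_b must differ")
    r = 2.0
    n_i = np.empty((2, ds.n_sites))
    p_i = np.empty((2, ds.n_sites))
    h_i = np.zeros((2, ds.n_sites))
    for k, pop in enumerate((pop_a, pop_b)):
        rows = ds.haplotype_rows(pop)
        A = ds.H[rows[0::2]]
        B = ds.H[rows[1::2]]
        if variant == "diploid":
            ok = (A != MISSING) & (B != MISSING)  # individual complete at site
            n_i[k] = ok.sum(axis=0)
            alt = (np.where(ok, A, 0) + np.where(ok, B, 0)).sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                p_i[k] = alt / (2.0 * n_i[k])
                h_i[k] = np.where(ok, A != B, False).sum(axis=0) / n_i[k]
        elif variant == "haploid":
            Hp = ds.H[rows]
            ok = Hp != MISSING
            n_i[k] = ok.sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                p_i[k] = (Hp == 1).sum(axis=0) / n_i[k]
        else:
            raise ValueError(f"unknown variant {variant!r}")

    nbar = n_i.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n_i ** 2).sum(axis=0) / (r * nbar)) / (r - 1.0)
        pbar = (n_i * p_i).sum(axis=0) / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1.0) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - (r - 1.0) / r * s2 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0

    min_haps = 2 if variant == "haploid" else 1
    defined = (n_i[0] >= min_haps) & (n_i[1] >= min_haps) & (nbar > 1.0) & (nc > 0)
    for arr in (a, b, c):
        arr[~defined] = np.nan
    return a, b, c


def tajima_constants(n: int) -> dict:
    """Tajima (1989) normalization constants for a sample of n haplotypes."""
    if n < 4:
        raise ValueError("Tajima's D needs at least 4 haplotypes")
    i = np.arange(1, n)
    a1 = np.sum(1.0 / i)
    a2 = np.sum(1.0 / i ** 2)
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n ** 2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


# ---------------------------------------------------------------------------
# windowed statistics
# ---------------------------------------------------------------------------

def window_pi(ds: HaplotypeDataset, pop: str, windows) -> np.ndarray:
    """Nucleotide diversity per bp in each window (monomorphic bp are zero)."""
    rows = ds.haplotype_rows(pop)
    if rows.size < 2:
        raise ValueError(f"population {pop!r} needs >=2 haplotypes")
    persite = site_pi(ds, pop)
    cumulative = np.concatenate([[0.0], np.cumsum(persite)])
    out = np.empty(len(windows))
    for w_idx, ((lo, hi), w) in enumerate(zip(window_site_slices(ds.positions, windows), windows)):
        out[w_idx] = (cumulative[hi] - cumulative[lo]) / w.length
    return out


def window_fst(ds: HaplotypeDataset, pop_a: str, pop_b: str, windows,
               variant: str = "diploid") -> np.ndarray:
    """Weighted WC84 F_ST per window: sum(a)/sum(a+b+c) over defined sites.

    Windows with no defined site (or zero denominator) are NaN.
    """
    a, b, c = wc84_components(ds, pop_a, pop_b, variant=variant)
    ok = np.isfinite(a)
    num = np.where(ok, a, 0.0)
    den = np.where(ok, a + b + c, 0.0)
    cnum = np.concatenate([[0.0], np.cumsum(num)])
    cden = np.concatenate([[0.0], np.cumsum(den)])
    out = np.full(len(windows), np.nan)
    for w_idx, (lo, hi) in enumerate(window_site_slices(ds.positions, windows)):
        d = cden[hi] - cden[lo]
        if d != 0.0:
            out[w_idx] = (cnum[hi] - cnum[lo]) / d
    return out


def window_tajima_d(ds: HaplotypeDataset, pop: str, windows) -> np.ndarray:
    """Tajima's D per window; NaN where the window has no segregating site.

    Pairwise differences use pairwise-complete missing-data handling (each
    site contributes with its own non-missing count); the constants use the
    full population haplotype count.
    """
    rows = ds.haplotype_rows(pop)
    n = rows.size
    if n < 4:
        logger.warning("window_tajima_d: %r has n=%d < 4 haplotypes", pop, n)
        return np.full(len(windows), np.nan)
    k = tajima_constants(n)
    c0, c1 = _pop_counts(ds, pop)
    nm = c0 + c1
    with np.errstate(invalid="ignore", divide="ignore"):
        pair_diffs = np.where(nm >= 2, 2.0 * c0 * c1 / (nm * (nm - 1.0)), 0.0)
    seg = ((c0 > 0) & (c1 > 0)).astype(np.int64)
    cpi = np.concatenate([[0.0], np.cumsum(pair_diffs)])
    cS = np.concatenate([[0], np.cumsum(seg)])
    out = np.full(len(windows), np.nan)
    for w_idx, (lo, hi) in enumerate(window_site_slices(ds.positions, windows)):
        S = int(cS[hi] - cS[lo])
        if S == 0:
            continue
        pi_hat = cpi[hi] - cpi[lo]
        var = k["e1"] * S + k["e2"] * S * (S - 1.0)
        out[w_idx] = (pi_hat - S / k["a1"]) / np.sqrt(var)
    return out


def window_stat_table(ds: HaplotypeDataset, windows, pops,
                      fst_pair: tuple | None = None) -> pd.DataFrame:
    """Assemble the per-window statistics table used by the outlier scans.

    Columns: ``contig, start, end, n_sites``, then ``pi_<pop>`` and
    ``tajima_d_<pop>`` for each requested population and ``fst`` for the
    requested pair.
    """
    slices = window_site_slices(ds.positions, windows)
    table = pd.DataFrame(
        {
            "contig": [w.contig or ds.contig for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "n_sites": [hi - lo for lo, hi in slices],
        }
    )
    for pop in pops:
        table[f"pi_{pop}"] = window_pi(ds, pop, windows)
        if ds.haplotype_rows(pop).size >= 4:
            table[f"tajima_d_{pop}"] = window_tajima_d(ds, pop, windows)
    if fst_pair is not None:
        table["fst"] = window_fst(ds, fst_pair[0], fst_pair[1], windows)
    return table


# ---------------------------------------------------------------------------
# LD decay
# ---------------------------------------------------------------------------

@dataclass
class LDDecayCurve:
    """Mean r^2 between site pairs, binned by physical distance."""

    bin_edges: np.ndarray  # len n_bins + 1, bp
    mean_r2: np.ndarray
    n_pairs: np.ndarray
    pop: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.bin_edges[:-1].astype(np.int64),
                "bin_end": self.bin_edges[1:].astype(np.int64),
                "mean_r2": self.mean_r2,
                "n_pairs": self.n_pairs.astype(np.int64),
            }
        )


def pair_r2(ds: HaplotypeDataset, pop: str, i: int, j: int) -> float:
    """Haplotype r^2 between sites i and j over jointly non-missing rows.

    NaN when either site is monomorphic within the complete subset.
    """
    rows = ds.haplotype_rows(pop)
    x = ds.H[rows, i]
    y = ds.H[rows, j]
    ok = (x != MISSING) & (y != MISSING)
    x, y = x[ok].astype(float), y[ok].astype(float)
    if x.size < 2:
        return np.nan
    pa, pb = x.mean(), y.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return np.nan
    pab = np.mean(x * y)
    d = pab - pa * pb
    return d * d / (pa * (1 - pa) * pb * (1 - pb))


def ld_decay(ds: HaplotypeDataset, pop: str, max_dist: int = 300_000,
             bin_width: int = 5_000, max_pairs: int | None = 1_000_000,
             seed: int | None = 0) -> LDDecayCurve:
    """LD decay curve: mean r^2 in distance bins over (sub)sampled site pairs.

    Pair subsampling (when the number of candidate pairs exceeds
    ``max_pairs``) is deterministic under ``seed``. Monomorphic or
    undefined pairs are skipped.
    """
    if not ds.phased:
        raise ValueError("ld_decay requires phased data")
    rows = ds.haplotype_rows(pop)
    if rows.size < 4:
        raise ValueError(f"population {pop!r} needs >=4 haplotypes")
    pos = ds.positions
    ii, jj = [], []
    hi_all = np.searchsorted(pos, pos + max_dist, side="right")
    for i in range(ds.n_sites):
        hi = hi_all[i]
        if hi > i + 1:
            jj.append(np.arange(i + 1, hi))
            ii.append(np.full(hi - i - 1, i))
    if not ii:
        edges = np.arange(0, max_dist + bin_width, bin_width)
        nb = len(edges) - 1
        return LDDecayCurve(edges, np.full(nb, np.nan), np.zeros(nb), pop)
    ii = np.concatenate(ii)
    jj = np.concatenate(jj)
    if max_pairs is not None and ii.size > max_pairs:
        rng = np.random.default_rng(seed)
        pick = rng.choice(ii.size, size=max_pairs, replace=False)
        pick.sort()
        ii, jj = ii[pick], jj[pick]

    Hp = ds.H[rows].astype(np.float64)
    Hp[ds.H[rows] == MISSING] = np.nan
    X, Y = Hp[:, ii], Hp[:, jj]
    ok = np.isfinite(X) & np.isfinite(Y)
    nok = ok.sum(axis=0).astype(float)
    X0 = np.where(ok, X, 0.0)
    Y0 = np.where(ok, Y, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pa = X0.sum(axis=0) / nok
        pb = Y0.sum(axis=0) / nok
        pab = (X0 * Y0).sum(axis=0) / nok
        denom = pa * (1 - pa) * pb * (1 - pb)
        r2 = (pab - pa * pb) ** 2 / denom
    valid = (nok >= 2) & (denom > 0)

    dist = (pos[jj] - pos[ii]).astype(np.int64)
    edges = np.arange(0, max_dist + bin_width, bin_width)
    nb = len(edges) - 1
    which = np.clip(dist // bin_width, 0, nb - 1)
    sums = np.bincount(which[valid], weights=r2[valid], minlength=nb)
    counts = np.bincount(which[valid], minlength=nb).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / counts, np.nan)
    return LDDecayCurve(edges, means, counts, pop)
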