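"""ABBA-BABA (Patterson's D) introgression tests with block-jackknife errors.

For the rooted four-taxon topology (((P1, P2), P3), outgroup), incomplete
lineage sorting produces ABBA and BABA site patterns in equal expectation;
an excess of one pattern indicates gene flow. Using population derived-allele
frequencies p1..p4 (polarized so the outgroup frequency weights the ancestral
state):

    abba = (1 - p1) * p2 * p3 * (1 - p4)
    baba = p1 * (1 - p2) * p3 * (1 - p4)
    D    = sum(abba - baba) / sum(abba + baba)

Gene flow between P2 and P3 gives D > 0; between P1 and P3, D < 0. The
standard error comes from a delete-one block jackknife over consecutive
blocks of informative sites, Z = D / SE, and p-values are two-sided normal.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import MISSING, HaplotypeDataset

logger = logging.getLogger(__name__)


@dataclass
class DStatResult:
    p1: str
    p2: str
    p3: str
    outgroup: str
    sum_abba: float
    sum_baba: float
    sum_bbaa: float
    D: float
    se: float
    Z: float
    p: float
    n_informative_sites: int
    n_blocks: int


def _pop_freqs(ds: HaplotypeDataset, pops):
    """Alt-allele frequency per site per population; NaN where all missing."""
    out = np.empty((len(pops), ds.n_sites))
    for k, pop in enumerate(pops):
        Hp = ds.H[ds.haplotype_rows(pop)]
        nm = (Hp != MISSING).sum(axis=0).astype(float)
        ones = (Hp == 1).sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[k] = np.where(nm > 0, ones / nm, np.nan)
    return out


def _jackknife_se(num: np.ndarray, den: np.ndarray, block_size: int):
    """Delete-one block jackknife SE of a ratio-of-sums statistic.

    Blocks are consecutive runs of ``block_size`` informative sites; a final
    partial block shorter than half a block is folded into its predecessor.
    """
    n = num.size
    n_blocks = n // block_size
    if n_blocks < 3:
        return np.nan, max(n_blocks, 1 if n else 0)
    bounds = [k * block_size for k in range(n_blocks)] + [n]
    if bounds[-1] - bounds[-2] < block_size / 2 and n_blocks > 1:
        # fold short tail into the last full block
        del bounds[-2]
        n_blocks -= 1
        if n_blocks < 3:
            return np.nan, n_blocks
    tot_num, tot_den = num.sum(), den.sum()
    d_del = np.empty(n_blocks)
    for k in range(n_blocks):
        lo, hi = bounds[k], bounds[k + 1]
        d_del[k] = (tot_num - num[lo:hi].sum()) / (tot_den - den[lo:hi].sum())
    se = np.sqrt((n_blocks - 1) / n_blocks * np.sum((d_del - d_del.mean()) ** 2))
    return float(se), n_blocks


def dstat(ds: HaplotypeDataset, p1: str, p2: str, p3: str, outgroup: str,
          block_size: int = 2000) -> DStatResult:
    """Patterson's D for (((P1, P2), P3), outgroup) with jackknife Z-score.

    Sites where any of the four populations is entirely missing are skipped;
    informative sites are those with abba + baba > 0. The jackknife operates
    on consecutive blocks of ``block_size`` informative sites (equal-weight
    blocks); fewer than three blocks leaves the SE undefined with a warning.
    """
    labels = (p1, p2, p3, outgroup)
    if len(set(labels)) != 4:
        raise ValueError("P1, P2, P3 and outgroup must be four distinct populations")
    f = _pop_freqs(ds, labels)
    usable = np.all(np.isfinite(f), axis=0)
    q1, q2, q3, q4 = f[:, usable]
    abba = (1 - q1) * q2 * q3 * (1 - q4)
    baba = q1 * (1 - q2) * q3 * (1 - q4)
    bbaa = q1 * q2 * (1 - q3) * (1 - q4)  # concordant pattern, for trio layout
    num = abba - baba
    den = abba + baba
    informative = den > 0
    num, den = num[informative], den[informative]
    abba_i, baba_i = abba[informative], baba[informative]
    if den.size == 0 or den.sum() == 0:
        raise ValueError("no informative sites: sum(abba + baba) = 0")
    D = float(num.sum() / den.sum())
    se, n_blocks = _jackknife_se(num, den, block_size)
    if not np.isfinite(se):
        logger.warning("dstat: <3 jackknife blocks (%d informative sites, "
                       "block_size=%d); SE undefined", den.size, block_size)
        Z = p = np.nan
    elif se == 0.0:
        Z = p = np.nan
    else:
        Z = D / se
        p = float(2.0 * stats.norm.sf(abs(Z)))
    return DStatResult(
        p1=p1, p2=p2, p3=p3, outgroup=outgroup,
        sum_abba=float(abba_i.sum()), sum_baba=float(baba_i.sum()),
        sum_bbaa=float(bbaa.sum()),
        D=D, se=float(se) if np.isfinite(se) else np.nan,
        Z=float(Z) if np.isfinite(se) else np.nan,
        p=p, n_informative_sites=int(den.size), n_blocks=n_blocks,
    )


def dstat_trios(ds: HaplotypeDataset, populations, outgroup: str,
                block_size: int = 2000) -> pd.DataFrame:
    """All rotations of every unordered ingroup trio against one outgroup.

    For each trio and each choice of P3, P1/P2 are oriented so that D >= 0
    (making the discordance-excess pair explicit, as trio-scan tools report
    it). Returns one row per rotation with D, Z, p, pattern sums and block
    counts. The rotation whose concordant pattern (BBAA: P1 and P2 share the
    derived allele) is the most common is marked ``best`` — the standard way
    trio tools pick the topology before reading D as introgression.
    """
    populations = list(populations)
    if len(populations) < 3:
        raise ValueError("need at least three ingroup populations")
    if outgroup in populations:
        raise ValueError("outgroup must not be an ingroup")
    rows = []
    for trio in itertools.combinations(populations, 3):
        results = []
        for p3 in trio:
            a, b = [x for x in trio if x != p3]
            r = dstat(ds, a, b, p3, outgroup, block_size=block_size)
            if r.D < 0:
                r = dstat(ds, b, a, p3, outgroup, block_size=block_size)
            results.append(r)
        best = int(np.argmax([r.sum_bbaa for r in results]))
        for k, r in enumerate(results):
            rows.append({
                "P1": r.p1, "P2": r.p2, "P3": r.p3, "outgroup": r.outgroup,
                "D": r.D, "Z": r.Z, "p": r.p,
                "nABBA": r.sum_abba, "nBABA": r.sum_baba, "nBBAA": r.sum_bbaa,
                "n_informative": r.n_informative_sites,
                "n_blocks": r.n_blocks, "best": k == best,
            })
    return pd.DataFrame(rows)
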