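"""EHH-family haplotype statistics: iHS, nSL, XP-EHH and XP-nSL.

Extended haplotype homozygosity (EHH) at an offset k from a core SNP is the
probability that two randomly drawn carrier haplotypes are identical over the
inclusive span from the core out to k:

    EHH(k) = sum_g C(m_g, 2) / C(m, 2)

with m carrier haplotypes partitioned into identical extended haplotypes of
sizes m_g. EHH(0) = 1 by convention (zero-length extension). Integrating the
EHH curve over physical distance gives iHH; the log-ratio of integrals is the
unstandardized statistic:

* iHS   = ln(iHH_ancestral / iHH_derived); large negative values mean
  unusually long derived haplotypes. Both signs are of interest, so the scan
  thresholds |iHS|.
* nSL   = the same construction with distance measured in segregating-site
  index units rather than bp (sensitive to incomplete sweeps).
* XP-EHH / XP-nSL = ln(iHH_observed / iHH_reference) with the pooled sample
  of each population; positive values mean longer haplotype homozygosity
  (a hard or soft sweep) in the observed population.

Raw scores are standardized either within derived-allele-frequency bins
(iHS, nSL; 100 equal-width bins by default) or genome-wide (XP statistics),
and significance is assessed through the proportion of extreme SNPs
(|score| > 2) per non-overlapping 500-kb window, ranked genome-wide with
95th/99th-percentile tiers.

Truncation rules (mirroring the defaults of the standard scan tool): the
curve is followed until EHH < 0.05; cores are voided when the curve is still
above the cutoff at a chromosome edge, or when consecutive SNPs are more than
200 kb apart; extension is capped at 1 Mb from the core (bp mode) or 200
sites (site mode), where the integral is truncated.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, HaplotypeDataset

logger = logging.getLogger(__name__)

EHH_CUTOFF = 0.05
MAX_EXTEND_BP = 1_000_000
MAX_EXTEND_SITES = 200
MAX_GAP_BP = 200_000
MAF_MIN = 0.05
MIN_CARRIERS = 2

SCORE_COLUMNS = ["contig", "pos", "freq", "ihh_a", "ihh_d", "unstd", "std", "statistic"]


@dataclass
class EHHCurve:
    """EHH values left and right of a core site (offset 0 = the core)."""

    core: int
    allele: object  # 0, 1 or "pooled"
    left_offsets: np.ndarray  # site indices, descending from core
    left_ehh: np.ndarray
    right_offsets: np.ndarray  # site indices, ascending from core
    right_ehh: np.ndarray
    truncation: str  # "ok", "edge", "gap", "max"


def _ehh_side(M: np.ndarray, positions: np.ndarray, core: int, step: int,
              mode: str, *, cutoff: float = EHH_CUTOFF,
              max_extend_bp: int = MAX_EXTEND_BP,
              max_extend_sites: int = MAX_EXTEND_SITES,
              max_gap: int = MAX_GAP_BP):
    """Scan one direction (step = +1 or -1) for one carrier matrix.

    Returns ``(indices, ehh, status)`` with status in {"ok", "edge", "gap",
    "max"}; "ok" means the cutoff was reached. The first below-cutoff point
    is included. The core's own column partitions the carriers from the
    first extension step (relevant for pooled classes only).
    """
    m = M.shape[0]
    denom = m * (m - 1) / 2.0
    S = M.shape[1]
    g = np.asarray(M[:, core], dtype=np.int64) + 1  # core column seeds groups
    idx_list, ehh_list = [], []
    prev_pos = positions[core]
    k = 0
    while True:
        k += 1
        j = core + step * k
        if j < 0 or j >= S:
            return np.array(idx_list), np.array(ehh_list), "edge"
        if abs(int(positions[j]) - int(prev_pos)) > max_gap:
            return np.array(idx_list), np.array(ehh_list), "gap"
        if mode == "bp":
            if abs(int(positions[j]) - int(positions[core])) > max_extend_bp:
                return np.array(idx_list), np.array(ehh_list), "max"
        else:
            if k > max_extend_sites:
                return np.array(idx_list), np.array(ehh_list), "max"
        prev_pos = positions[j]
        col = np.asarray(M[:, j], dtype=np.int64) + 1  # missing -> 0, own class
        _, g, counts = np.unique(g * 3 + col, return_inverse=True, return_counts=True)
        ehh = float(np.sum(counts * (counts - 1) / 2.0) / denom)
        idx_list.append(j)
        ehh_list.append(ehh)
        if ehh < cutoff:
            return np.array(idx_list), np.array(ehh_list), "ok"


def ehh_curve(ds: HaplotypeDataset, pop: str, core: int, allele,
              mode: str = "bp", **trunc) -> EHHCurve:
    """EHH decay curve around a core site for one allele class.

    ``allele`` is 0, 1 (haplotypes carrying that core allele) or ``"pooled"``
    (all haplotypes non-missing at the core). Requires phased data and at
    least two carriers. Missing entries along the extension break haplotype
    identity (they form their own allele class).
    """
    if not ds.phased:
        raise ValueError("EHH requires phased haplotypes")
    rows = ds.haplotype_rows(pop)
    col = ds.H[rows, core]
    if allele == "pooled":
        carriers = rows[col != MISSING]
    else:
        carriers = rows[col == allele]
    if carriers.size < MIN_CARRIERS:
        raise ValueError(
            f"allele class {allele!r} at core {core} has "
            f"{carriers.size} carriers (<{MIN_CARRIERS})"
        )
    M = ds.H[carriers]
    li, le, lstat = _ehh_side(M, ds.positions, core, -1, mode, **trunc)
    ri, re_, rstat = _ehh_side(M, ds.positions, core, +1, mode, **trunc)
    status = "ok"
    for s in (lstat, rstat):
        if s in ("edge", "gap"):
            status = s
            break
        if s == "max":
            status = "max"
    return EHHCurve(core=core, allele=allele,
                    left_offsets=li, left_ehh=le,
                    right_offsets=ri, right_ehh=re_, truncation=status)


def _ihh_from_side(indices, ehh, positions, core, mode: str) -> float:
    """Composite trapezoid of one side's EHH curve, anchored at EHH(0)=1."""
    if mode == "bp":
        x = np.concatenate([[0.0], np.abs(positions[indices] - positions[core]).astype(float)])
    else:
        x = np.arange(len(indices) + 1, dtype=float)
    y = np.concatenate([[1.0], ehh])
    return float(np.trapezoid(y, x))


def integrate_curve(curve: EHHCurve, positions: np.ndarray, mode: str) -> float:
    """iHH: summed left + right trapezoid integrals of an EHH curve."""
    return (_ihh_from_side(curve.left_offsets, curve.left_ehh, positions, curve.core, mode)
            + _ihh_from_side(curve.right_offsets, curve.right_ehh, positions, curve.core, mode))


# ---------------------------------------------------------------------------
# fast whole-chromosome scanning machinery
#
# Rather than regrouping haplotypes step by step at every core, the scanner
# precomputes, for every haplotype pair and every site, the index of the
# nearest mismatch to the right (and left). A pair is identical over the
# inclusive span core..core+k exactly when its first mismatch at or beyond
# the core lies beyond core+k, so the EHH curve at a core is the survival
# function of per-pair mismatch distances — obtained with one sort per core
# instead of a haplotype regrouping per extension step. Results are exactly
# those of the stepwise :func:`ehh_curve`.
# ---------------------------------------------------------------------------

class _PairScanner:
    """Per-population pairwise mismatch index for EHH scans."""

    def __init__(self, M: np.ndarray, positions: np.ndarray, mode: str, trunc: dict):
        self.positions = positions
        self.mode = mode
        self.cutoff = trunc.get("cutoff", EHH_CUTOFF)
        self.max_gap = trunc.get("max_gap", MAX_GAP_BP)
        self.max_extend_bp = trunc.get("max_extend_bp", MAX_EXTEND_BP)
        self.max_extend_sites = trunc.get("max_extend_sites", MAX_EXTEND_SITES)
        m, S = M.shape
        self.m = m
        self.iu, self.ju = np.triu_indices(m, 1)
        neq_T = (M[self.iu] != M[self.ju]).T  # (S, npairs)
        npairs = self.iu.size
        self.nxt = np.empty((S, npairs), dtype=np.int32)
        cur = np.full(npairs, S, dtype=np.int32)
        for s in range(S - 1, -1, -1):
            cur = np.where(neq_T[s], np.int32(s), cur)
            self.nxt[s] = cur
        self.prv = np.empty((S, npairs), dtype=np.int32)
        cur = np.full(npairs, -1, dtype=np.int32)
        for s in range(S):
            cur = np.where(neq_T[s], np.int32(s), cur)
            self.prv[s] = cur
        self.gap_idx = np.flatnonzero(np.diff(positions) > self.max_gap)
        if mode == "bp":
            self.hi = np.searchsorted(positions, positions + self.max_extend_bp,
                                      side="right") - 1
            self.lo = np.searchsorted(positions, positions - self.max_extend_bp,
                                      side="left")

    def side_curve(self, core: int, step: int, pair_mask=None):
        """Full EHH curve of one side up to the first truncation limit.

        Returns ``(site_indices, ehh, limit_status)`` where limit_status is
        the rule that would void/truncate the scan at the end of the curve
        ("edge", "gap" or "max"); the decay cutoff is applied by the caller.
        """
        S = self.positions.size
        if step > 0:
            k_edge = S - core
            g = np.searchsorted(self.gap_idx, core, side="left")
            k_gap = self.gap_idx[g] + 1 - core if g < self.gap_idx.size else S + 1
            k_max = (self.hi[core] + 1 - core) if self.mode == "bp" \
                else self.max_extend_sites + 1
            d = self.nxt[core] - core
        else:
            k_edge = core + 1
            g = np.searchsorted(self.gap_idx, core, side="left") - 1
            k_gap = core - self.gap_idx[g] if g >= 0 else S + 1
            k_max = (core - self.lo[core] + 1) if self.mode == "bp" \
                else self.max_extend_sites + 1
            d = core - self.prv[core]
        k_viol = min(k_edge, k_gap, k_max)
        if k_viol == k_edge:
            status = "edge"
        elif k_viol == k_gap:
            status = "gap"
        else:
            status = "max"
        if pair_mask is not None:
            d = d[pair_mask]
        npairs = d.size
        ks = np.arange(1, k_viol)
        if npairs == 0:
            return core + step * ks, np.full(ks.size, np.nan), status
        surv = npairs - np.searchsorted(np.sort(d), ks, side="right")
        return core + step * ks, surv / npairs, status

    def scan_side(self, core: int, step: int, pair_mask=None):
        """One side's curve truncated at the decay cutoff.

        Returns ``(site_indices, ehh, status)`` with status "ok" when the
        cutoff was reached, else the limit status ("max" truncates the
        integral, "edge"/"gap" void the core).
        """
        idx, ehh, limit = self.side_curve(core, step, pair_mask)
        below = np.flatnonzero(ehh < self.cutoff)
        if below.size:
            stop = below[0] + 1  # include first below-cutoff point
            return idx[:stop], ehh[:stop], "ok"
        return idx, ehh, limit


# ---------------------------------------------------------------------------
# single-population scan (iHS / nSL)
# ---------------------------------------------------------------------------

def _class_rows(H, rows, core, allele):
    col = H[rows, core]
    if allele == "pooled":
        return rows[col != MISSING]
    return rows[col == allele]


def ihs_scan(ds: HaplotypeDataset, pop: str, mode: str = "bp",
             maf_min: float = MAF_MIN, **trunc) -> pd.DataFrame:
    """Unstandardized iHS (mode="bp") or nSL (mode="sites") for one population.

    Requires phased data and per-site ancestral states; cores without a known
    ancestral allele, below the MAF floor, with fewer than two carriers in
    either class, or voided by truncation rules are omitted/NaN. The sign
    convention is ln(iHH_ancestral / iHH_derived): strongly negative scores
    mean unusually long derived haplotypes.
    """
    if not ds.phased:
        raise ValueError("iHS/nSL require phased haplotypes")
    if ds.ancestral is None:
        raise ValueError("iHS/nSL require ancestral allele states")
    statistic = "iHS" if mode == "bp" else "nSL"
    rows = ds.haplotype_rows(pop)
    Hp = ds.H[rows]
    scanner = _PairScanner(Hp, ds.positions, mode, trunc)
    nonmiss = (Hp != MISSING).sum(axis=0).astype(float)
    ones = (Hp == 1).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = ones / nonmiss
    records = []
    for core in range(ds.n_sites):
        anc = ds.ancestral[core]
        if anc == MISSING:
            continue
        der = 1 - int(anc)
        p_der = p1[core] if der == 1 else 1.0 - p1[core]
        if not np.isfinite(p_der) or min(p_der, 1 - p_der) < maf_min:
            continue
        col = Hp[:, core]
        ihh = {}
        for allele in (int(anc), der):
            car = col == allele
            if car.sum() < MIN_CARRIERS:
                ihh = None
                break
            pair_mask = car[scanner.iu] & car[scanner.ju]
            total = 0.0
            for step in (-1, +1):
                idx, ehh, status = scanner.scan_side(core, step, pair_mask)
                if status in ("edge", "gap"):
                    total = np.nan
                    break
                total += _ihh_from_side(idx, ehh, ds.positions, core, mode)
            ihh[allele] = total
        if ihh is None:
            continue
        ihh_a, ihh_d = ihh.get(int(anc), np.nan), ihh.get(der, np.nan)
        unstd = (np.log(ihh_a / ihh_d)
                 if (np.isfinite(ihh_a) and np.isfinite(ihh_d)
                     and ihh_a > 0 and ihh_d > 0) else np.nan)
        records.append((ds.contig, int(ds.positions[core]), float(p_der),
                        ihh_a, ihh_d, unstd, np.nan, statistic))
    return pd.DataFrame(records, columns=SCORE_COLUMNS)


# ---------------------------------------------------------------------------
# cross-population scan (XP-EHH / XP-nSL)
# ---------------------------------------------------------------------------

def xp_scan(ds: HaplotypeDataset, pop_obs: str, pop_ref: str,
            mode: str = "bp", maf_min: float = MAF_MIN, **trunc) -> pd.DataFrame:
    """Unstandardized XP-EHH (mode="bp") or XP-nSL (mode="sites").

    Pooled-sample EHH is integrated separately within each population over a
    shared support; the score is ln(iHH_obs / iHH_ref), positive when
    haplotype homozygosity extends further in the observed population. The
    MAF floor applies to the pooled frequency over both populations; no
    ancestral polarization is needed.
    """
    if pop_obs == pop_ref:
        raise ValueError("pop_obs and pop_ref must be different populations")
    if not ds.phased:
        raise ValueError("XP statistics require phased haplotypes")
    statistic = "XP-EHH" if mode == "bp" else "XP-nSL"
    rows_o = ds.haplotype_rows(pop_obs)
    rows_r = ds.haplotype_rows(pop_ref)
    Ho, Hr = ds.H[rows_o], ds.H[rows_r]
    sc_o = _PairScanner(Ho, ds.positions, mode, trunc)
    sc_r = _PairScanner(Hr, ds.positions, mode, trunc)
    cutoff = trunc.get("cutoff", EHH_CUTOFF)
    Hb = np.concatenate([Ho, Hr], axis=0)
    nonmiss = (Hb != MISSING).sum(axis=0).astype(float)
    ones = (Hb == 1).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = ones / nonmiss
    records = []
    for core in range(ds.n_sites):
        p = p1[core]
        if not np.isfinite(p) or min(p, 1 - p) < maf_min:
            continue
        ok_o = Ho[:, core] != MISSING
        ok_r = Hr[:, core] != MISSING
        if ok_o.sum() < MIN_CARRIERS or ok_r.sum() < MIN_CARRIERS:
            continue
        mask_o = None if ok_o.all() else ok_o[sc_o.iu] & ok_o[sc_o.ju]
        mask_r = None if ok_r.all() else ok_r[sc_r.iu] & ok_r[sc_r.ju]
        voided = False
        ihh = [0.0, 0.0]
        for step in (-1, +1):
            # both pools share one support: the side ends where both pooled
            # EHH values have decayed below the cutoff
            idx, ehh_o, lim_o = sc_o.side_curve(core, step, mask_o)
            _, ehh_r, lim_r = sc_r.side_curve(core, step, mask_r)
            below = np.flatnonzero((ehh_o < cutoff) & (ehh_r < cutoff))
            if below.size:
                stop = below[0] + 1
                idx, ehh_o, ehh_r = idx[:stop], ehh_o[:stop], ehh_r[:stop]
            elif lim_o in ("edge", "gap"):
                voided = True
                break
            for k, ehh in enumerate((ehh_o, ehh_r)):
                ihh[k] += _ihh_from_side(idx, ehh, ds.positions, core, mode)
        if voided:
            continue
        unstd = np.log(ihh[0] / ihh[1]) if ihh[0] > 0 and ihh[1] > 0 else np.nan
        records.append((ds.contig, int(ds.positions[core]), float(p),
                        ihh[0], ihh[1], unstd, np.nan, statistic))
    return pd.DataFrame(records, columns=SCORE_COLUMNS)


# ---------------------------------------------------------------------------
# standardization and window proportions
# ---------------------------------------------------------------------------

def standardize(table: pd.DataFrame, scheme: str | None = None,
                n_bins: int = 100) -> pd.DataFrame:
    """Fill the ``std`` column of a scan-score table.

    ``scheme="bins"`` (the default for iHS/nSL): scores are grouped into
    ``n_bins`` equal-width derived-allele-frequency bins on (0, 1) and
    centred/scaled within each bin using the sample standard deviation; bins
    with fewer than two scores (or zero spread) become missing.
    ``scheme="global"`` (the default for XP-EHH/XP-nSL): one genome-wide
    mean and sd.
    """
    out = table.copy()
    if out.empty:
        out["std"] = pd.Series(dtype=float)
        return out
    if scheme is None:
        stat = out["statistic"].iloc[0]
        scheme = "bins" if stat in ("iHS", "nSL") else "global"
    raw = out["unstd"].to_numpy(float)
    std = np.full(raw.size, np.nan)
    ok = np.isfinite(raw)
    if scheme == "global":
        if ok.sum() >= 2:
            sd = np.std(raw[ok], ddof=1)
            if sd > 0:
                std[ok] = (raw[ok] - np.mean(raw[ok])) / sd
            else:
                logger.warning("standardize: zero global sd")
    elif scheme == "bins":
        freq = out["freq"].to_numpy(float)
        which = np.clip((freq * n_bins).astype(int), 0, n_bins - 1)
        for b in range(n_bins):
            sel = (which == b) & ok
            if sel.sum() < 2:
                continue
            sd = np.std(raw[sel], ddof=1)
            if sd == 0:
                logger.warning("standardize: zero sd in frequency bin %d", b)
                continue
            std[sel] = (raw[sel] - np.mean(raw[sel])) / sd
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    out["std"] = std
    return out


def proportion_windows(table: pd.DataFrame, threshold: float = 2.0,
                       two_sided: bool | None = None, size: int = 500_000,
                       min_snps: int = 100,
                       contig_length: int | None = None) -> pd.DataFrame:
    """Proportion of extreme standardized scores per non-overlapping window.

    A SNP is extreme when ``score > threshold`` (one-sided; XP statistics)
    or ``|score| > threshold`` (two-sided; iHS and nSL — the default is
    chosen from the table's statistic name). Windows with fewer than
    ``min_snps`` scored SNPs are dropped; each retained window gets its
    genome-wide rank percentile of the proportion and a significance tier
    at the 95th / 99th percentiles.
    """
    if table.empty or not np.isfinite(table["std"].to_numpy(float)).any():
        raise ValueError("no standardized scores to window")
    if two_sided is None:
        two_sided = table["statistic"].iloc[0] in ("iHS", "nSL")
    rows = []
    for contig, sub in table.groupby("contig", sort=False):
        pos = sub["pos"].to_numpy(np.int64)
        score = sub["std"].to_numpy(float)
        ok = np.isfinite(score)
        extreme = np.abs(score) > threshold if two_sided else score > threshold
        length = contig_length if contig_length is not None else int(pos.max())
        n_windows = int(np.ceil(length / size))
        which = np.clip((pos - 1) // size, 0, n_windows - 1)
        for w in range(n_windows):
            sel = (which == w) & ok
            n_tested = int(sel.sum())
            if n_tested < min_snps:
                continue
            n_extreme = int((extreme & sel).sum())
            rows.append({
                "contig": contig,
                "start": w * size,
                "end": min((w + 1) * size, length) if contig_length else (w + 1) * size,
                "n_tested": n_tested,
                "n_extreme": n_extreme,
                "proportion": n_extreme / n_tested,
            })
    if not rows:
        raise ValueError(f"no windows retained (min_snps={min_snps})")
    out = pd.DataFrame(rows)
    prop = out["proportion"].to_numpy()
    n = prop.size
    pct = np.array([100.0 * np.sum(prop <= p) / n for p in prop])
    out["percentile"] = pct
    out["tier"] = np.select([pct >= 99.0, pct >= 95.0], ["99", "95"], default="none")
    return out
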