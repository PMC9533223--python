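"""Candidate divergent region (CDR) scan and region-vs-background testing.

A CDR is a genomic window that is simultaneously an upper-tail outlier for
between-group differentiation (Z-transformed F_ST) and a lower-tail outlier
for the within-group diversity ratio log2(pi_A / pi_B). Flagged windows on a
sliding grid are merged into maximal intervals, genes overlapping them are
pulled from a GFF3, and candidate regions are compared against the genomic
background with a Mann-Whitney U test.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class CDRConfig:
    """Thresholds of the joint outlier scan.

    ``fst_quantile`` is the upper-tail fraction on z_fst (default top 5%),
    ``ratio_quantile`` the lower-tail fraction on log2(pi_A/pi_B) (default
    bottom 5%). ``fst_abs_cutoff`` is the optional absolute weighted-F_ST
    track (default 0.15). ``min_snps`` excludes sparse windows from both
    quantile estimation and flagging.
    """

    fst_quantile: float = 0.05
    ratio_quantile: float = 0.05
    merge: bool = True
    fst_abs_cutoff: float | None = 0.15
    min_snps: int = 3
    per_contig: bool = False

    def __post_init__(self):
        for q in (self.fst_quantile, self.ratio_quantile):
            if not 0.0 < q <= 0.5:
                raise ValueError("quantiles must be in (0, 0.5]")


@dataclass
class CandidateRegion:
    """Merged interval of jointly flagged windows (0-based half-open bp)."""

    contig: str
    start: int
    end: int
    window_ids: list
    mean_z_fst: float
    mean_log2_pi_ratio: float
    gene_ids: list = field(default_factory=list)

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError("region start must precede end")


def z_transform(values) -> np.ndarray:
    """Z-scores (x - mean) / sd with sample sd (n-1) over non-missing values.

    Missing input stays missing; a zero standard deviation yields an
    all-missing result with a warning.
    """
    x = np.asarray(values, dtype=float)
    ok = np.isfinite(x)
    if ok.sum() < 2:
        raise ValueError("z_transform needs >=2 non-missing values")
    sd = np.std(x[ok], ddof=1)
    out = np.full(x.shape, np.nan)
    if sd == 0.0:
        warnings.warn("z_transform: zero standard deviation", RuntimeWarning)
        return out
    out[ok] = (x[ok] - np.mean(x[ok])) / sd
    return out


def log2_pi_ratio(pi_a, pi_b, pseudo: float = 1e-6) -> np.ndarray:
    """Per-window log2((pi_A + pseudo) / (pi_B + pseudo)).

    The pseudocount (default 1e-6 per bp, one substitution per Mb) keeps
    zero-diversity windows finite; windows where both pi are exactly zero are
    returned as missing.
    """
    a = np.asarray(pi_a, dtype=float)
    b = np.asarray(pi_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("pi_a and pi_b must share one window grid")
    if pseudo < 0:
        raise ValueError("pseudo must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log2((a + pseudo) / (b + pseudo))
    out[(a == 0) & (b == 0)] = np.nan
    out[~(np.isfinite(a) & np.isfinite(b))] = np.nan
    return out


def _merge_flagged(table: pd.DataFrame, flagged: np.ndarray) -> list:
    """Merge flagged windows that overlap or are book-ended, per contig."""
    regions = []
    sub = table.loc[flagged, ["contig", "start", "end", "z_fst", "log2_pi_ratio"]]
    sub = sub.sort_values(["contig", "start", "end"])
    idx_sorted = sub.index.to_numpy()
    cur = None
    for idx in idx_sorted:
        row = table.loc[idx]
        if (
            cur is not None
            and row["contig"] == cur["contig"]
            and row["start"] <= cur["end"]
        ):
            cur["end"] = max(cur["end"], int(row["end"]))
            cur["ids"].append(int(idx))
        else:
            if cur is not None:
                regions.append(cur)
            cur = {
                "contig": row["contig"],
                "start": int(row["start"]),
                "end": int(row["end"]),
                "ids": [int(idx)],
            }
    if cur is not None:
        regions.append(cur)
    out = []
    for r in regions:
        members = table.loc[r["ids"]]
        out.append(
            CandidateRegion(
                contig=r["contig"],
                start=r["start"],
                end=r["end"],
                window_ids=r["ids"],
                mean_z_fst=float(members["z_fst"].mean()),
                mean_log2_pi_ratio=float(members["log2_pi_ratio"].mean()),
            )
        )
    return out


def detect_cdr(table: pd.DataFrame, cfg: CDRConfig | None = None) -> list:
    """Flag windows jointly in the F_ST upper tail and pi-ratio lower tail.

    ``table`` must carry ``contig, start, end, n_sites, z_fst,
    log2_pi_ratio``. A window is flagged iff
    ``z_fst >= quantile(1 - fst_quantile)`` and
    ``log2_pi_ratio <= quantile(ratio_quantile)``, with empirical quantiles
    (linear interpolation between order statistics) over non-missing,
    sufficiently dense windows — genome-wide by default, per contig when
    configured. Ties at a threshold fall in the tail. Returns merged
    :class:`CandidateRegion` objects (or one region per window when
    ``cfg.merge`` is off).
    """
    cfg = cfg or CDRConfig()
    for col in ("z_fst", "log2_pi_ratio"):
        if col not in table.columns:
            raise ValueError(f"table lacks required column {col!r}")
    usable = (
        np.isfinite(table["z_fst"].to_numpy(float))
        & np.isfinite(table["log2_pi_ratio"].to_numpy(float))
        & (table["n_sites"].to_numpy() >= cfg.min_snps)
    )
    if usable.sum() < 20:
        raise ValueError(
            f"only {int(usable.sum())} usable windows; quantile thresholds need >=20"
        )
    flagged = np.zeros(len(table), dtype=bool)
    groups = table["contig"] if cfg.per_contig else pd.Series("*", index=table.index)
    for _, idx in groups.groupby(groups).groups.items():
        mask = usable & table.index.isin(idx)
        if mask.sum() < 20:
            continue
        z = table.loc[mask, "z_fst"].to_numpy(float)
        r = table.loc[mask, "log2_pi_ratio"].to_numpy(float)
        z_thr = np.quantile(z, 1.0 - cfg.fst_quantile)
        r_thr = np.quantile(r, cfg.ratio_quantile)
        flagged |= mask & (table["z_fst"] >= z_thr) & (table["log2_pi_ratio"] <= r_thr)
    if not flagged.any():
        return []
    if cfg.merge:
        return _merge_flagged(table, flagged)
    out = []
    for idx in np.flatnonzero(flagged.to_numpy() if hasattr(flagged, "to_numpy") else flagged):
        row = table.iloc[idx]
        out.append(
            CandidateRegion(
                contig=row["contig"],
                start=int(row["start"]),
                end=int(row["end"]),
                window_ids=[int(table.index[idx])],
                mean_z_fst=float(row["z_fst"]),
                mean_log2_pi_ratio=float(row["log2_pi_ratio"]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# gene overlap
# ---------------------------------------------------------------------------

def genes_in_regions(gff_path, regions, feature: str = "gene") -> pd.DataFrame:
    """Genes whose span overlaps any candidate region by >= 1 bp.

    GFF3 features are 1-based inclusive and converted internally to the
    0-based half-open convention of regions. Each gene is reported once,
    with the regions hit and the total overlap. Unknown seqids produce a
    warning only.
    """
    import gffutils

    db = gffutils.create_db(
        str(gff_path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    region_contigs = {r.contig for r in regions}
    rows = []
    seen_seqids = set()
    for g in db.features_of_type(feature):
        seen_seqids.add(g.seqid)
        g_start0, g_end0 = g.start - 1, g.end  # to 0-based half-open
        hits, overlap = [], 0
        for k, r in enumerate(regions):
            if r.contig != g.seqid:
                continue
            ov = min(g_end0, r.end) - max(g_start0, r.start)
            if ov > 0:
                hits.append(k)
                overlap += ov
        if hits:
            gene_id = g.id or g.attributes.get("ID", ["?"])[0]
            rows.append(
                {
                    "gene_id": gene_id,
                    "contig": g.seqid,
                    "gene_start": g_start0,
                    "gene_end": g_end0,
                    "regions": ",".join(str(k) for k in hits),
                    "overlap_bp": overlap,
                }
            )
            for k in hits:
                regions[k].gene_ids.append(gene_id)
    unknown = seen_seqids - region_contigs
    if unknown and region_contigs:
        logger.warning("genes_in_regions: GFF seqids not in any region: %s",
                       sorted(unknown)[:5])
    return pd.DataFrame(
        rows, columns=["gene_id", "contig", "gene_start", "gene_end",
                       "regions", "overlap_bp"]
    )


# ---------------------------------------------------------------------------
# region vs background
# ---------------------------------------------------------------------------

def region_vs_background(table: pd.DataFrame, region, column: str) -> dict:
    """Two-sided Mann-Whitney U comparing a statistic inside vs outside a region.

    ``region`` is ``(contig, start, end)`` (0-based half-open) or a
    :class:`CandidateRegion`. A window counts as inside when it overlaps the
    region. Exact null distribution when both samples have size <= 8 and no
    ties occur; normal approximation with tie correction otherwise. Returns
    ``{"U", "n_in", "n_out", "p", "median_in", "median_out"}``.
    """
    if hasattr(region, "contig"):
        contig, start, end = region.contig, region.start, region.end
    else:
        contig, start, end = region
    vals = table[column].to_numpy(float)
    ok = np.isfinite(vals)
    inside = (
        (table["contig"] == contig)
        & (table["start"].to_numpy() < end)
        & (table["end"].to_numpy() > start)
    ).to_numpy()
    x = vals[inside & ok]
    y = vals[~inside & ok]
    if x.size < 3 or y.size < 3:
        raise ValueError(
            f"need >=3 windows on each side, got {x.size} inside / {y.size} outside"
        )
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size <= 8 and y.size <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=False)
    return {
        "U": float(res.statistic),
        "n_in": int(x.size),
        "n_out": int(y.size),
        "p": float(res.pvalue),
        "median_in": float(np.median(x)),
        "median_out": float(np.median(y)),
        "method": method,
    }


def regions_to_bed(regions, path=None) -> pd.DataFrame:
    """Candidate regions as a BED-like frame (0-based half-open); optionally written."""
    bed = pd.DataFrame(
        {
            "contig": [r.contig for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "mean_z_fst": [r.mean_z_fst for r in regions],
            "mean_log2_pi_ratio": [r.mean_log2_pi_ratio for r in regions],
            "n_windows": [len(r.window_ids) for r in regions],
        }
    )
    if path is not None:
        bed.to_csv(path, sep="\t", index=False, header=False, float_format="%.6g")
    return bed
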