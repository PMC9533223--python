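"""Phased haplotype matrices, VCF I/O, site filtering and genome windowing.

The central container is :class:`HaplotypeDataset`: a sites-by-haplotypes view
of biallelic SNPs on one contig, with two haplotype rows per diploid sample.
Every downstream statistic (windowed diversity, EHH-family scans, D-statistics)
operates on this container. Coordinates follow each format's native
convention: VCF and ``positions`` are 1-based; windows and BED exports are
0-based half-open.
"""
from __future__ import annotations

import logging
import os
from dataclasses import dataclass, replace

import numpy as np

logger = logging.getLogger(__name__)

#: sentinel for a missing haplotype entry in ``H``
MISSING = -1


class PopmapError(ValueError):
    """Sample/population map inconsistent with the variant data."""


@dataclass
class HaplotypeDataset:
    """Biallelic SNP haplotypes for one contig.

    Parameters
    ----------
    contig : str
        Contig/chromosome name.
    positions : ndarray of int64
        Strictly increasing 1-based physical coordinates (bp).
    alleles : ndarray of str, shape (n_sites, 2)
        (ref, alt) nucleotide per site.
    H : ndarray of int8, shape (2 * n_samples, n_sites)
        Haplotype matrix over {0, 1, MISSING}; rows ``2i`` and ``2i + 1``
        are the two haplotypes of sample ``i``.
    sample_ids : list of str
        Sample identifiers in row-pair order.
    pop_of_sample : dict
        Sample identifier -> population label.
    ancestral : ndarray of int8 or None
        Per-site ancestral allele index (0/1), MISSING where unknown.
    phased : bool
        False when the source contained unphased heterozygotes; haplotype-based
        scans refuse such data rather than pseudo-phase it.
    contig_length : int or None
        Contig length in bp when known (VCF header or supplied table).
    mean_depth : ndarray or None
        Per-site mean sample depth when the source provides it.
    """

    contig: str
    positions: np.ndarray
    alleles: np.ndarray
    H: np.ndarray
    sample_ids: list
    pop_of_sample: dict
    ancestral: np.ndarray | None = None
    phased: bool = True
    contig_length: int | None = None
    mean_depth: np.ndarray | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.H = np.asarray(self.H, dtype=np.int8)
        if self.H.ndim != 2 or self.H.shape[0] != 2 * len(self.sample_ids):
            raise ValueError(
                f"H must have 2 rows per sample: got {self.H.shape} for "
                f"{len(self.sample_ids)} samples"
            )
        if self.H.shape[1] != self.positions.size:
            raise ValueError("H column count does not match positions")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        missing_pop = [s for s in self.sample_ids if s not in self.pop_of_sample]
        if missing_pop:
            raise PopmapError(f"samples without population label: {missing_pop[:5]}")
        if self.ancestral is not None:
            self.ancestral = np.asarray(self.ancestral, dtype=np.int8)
            if self.ancestral.size != self.positions.size:
                raise ValueError("ancestral length mismatch")

    # -- basic geometry ----------------------------------------------------
    @property
    def n_sites(self) -> int:
        return self.positions.size

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_haplotypes(self) -> int:
        return self.H.shape[0]

    def populations(self) -> list:
        seen = {}
        for s in self.sample_ids:
            seen.setdefault(self.pop_of_sample[s], None)
        return list(seen)

    def sample_indices(self, pop: str) -> np.ndarray:
        idx = np.array(
            [i for i, s in enumerate(self.sample_ids) if self.pop_of_sample[s] == pop],
            dtype=np.int64,
        )
        if idx.size == 0:
            raise PopmapError(f"population {pop!r} has no samples")
        return idx

    def haplotype_rows(self, pop: str) -> np.ndarray:
        """Row indices in ``H`` belonging to population ``pop``."""
        si = self.sample_indices(pop)
        return np.stack([2 * si, 2 * si + 1], axis=1).reshape(-1)

    # -- subsetting --------------------------------------------------------
    def take_sites(self, index: np.ndarray) -> "HaplotypeDataset":
        index = np.asarray(index)
        return replace(
            self,
            positions=self.positions[index],
            alleles=self.alleles[index],
            H=self.H[:, index],
            ancestral=None if self.ancestral is None else self.ancestral[index],
            mean_depth=None if self.mean_depth is None else self.mean_depth[index],
        )

    def restrict(self, start: int, end: int) -> "HaplotypeDataset":
        """Subset to sites with 0-based position in ``[start, end)``."""
        lo = np.searchsorted(self.positions, start + 1, side="left")
        hi = np.searchsorted(self.positions, end, side="right")
        return self.take_sites(np.arange(lo, hi))


@dataclass
class SiteFilter:
    """SNP retention criteria applied jointly (logical AND).

    ``max_missing`` is the tolerated fraction of missing haplotype entries at
    a site; ``min_maf`` the minimum minor-allele frequency over non-missing
    entries. Depth bounds apply only when the dataset carries per-site mean
    depth. Defaults mirror a resequencing sweep-scan setup: drop sites with
    more than 20% missing entries or MAF below 0.05.
    """

    biallelic_only: bool = True
    max_missing: float = 0.2
    min_maf: float = 0.05
    min_mean_dp: float | None = None
    max_mean_dp: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.max_missing <= 1.0:
            raise ValueError("max_missing must be in [0, 1]")
        if not 0.0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must be in [0, 0.5]")


@dataclass
class GenomicWindow:
    """Half-open window ``[start, end)`` in 0-based bp coordinates."""

    contig: str
    start: int
    end: int
    n_sites: int = 0

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad window [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# population map
# ---------------------------------------------------------------------------

def read_popmap(path) -> dict:
    """Read a two-column ``sample<TAB>population`` text file ('#' comments)."""
    popmap = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise PopmapError(f"{path}:{ln}: expected 'sample population'")
            popmap[parts[0]] = parts[1]
    if not popmap:
        raise PopmapError(f"{path}: empty population map")
    return popmap


def write_popmap(popmap: dict, path) -> None:
    with open(path, "w") as fh:
        for sample, pop in popmap.items():
            fh.write(f"{sample}\t{pop}\n")


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def _parse_region(region: str):
    if ":" not in region:
        return region, None, None
    contig, span = region.rsplit(":", 1)
    start_s, end_s = span.split("-")
    return contig, int(start_s), int(end_s)


def read_vcf(path, popmap, region: str | None = None) -> list:
    """Load biallelic SNPs from a VCF into one :class:`HaplotypeDataset` per contig.

    Parameters
    ----------
    path : str
        VCF file (plain or bgzipped) with GT fields.
    popmap : dict or str
        Sample -> population map (or path to one). Samples are restricted to
        the popmap; every popmap sample must exist in the VCF.
    region : str, optional
        ``contig`` or ``contig:start-end`` (1-based inclusive, samtools
        dialect).

    Returns
    -------
    list of HaplotypeDataset, ordered by first appearance of each contig.
    Non-SNP and multiallelic records are skipped with a logged count.
    """
    from cyvcf2 import VCF

    if not os.path.exists(str(path)):
        raise FileNotFoundError(path)
    if not isinstance(popmap, dict):
        popmap = read_popmap(popmap)

    vcf = VCF(str(path))
    vcf_samples = list(vcf.samples)
    absent = [s for s in popmap if s not in vcf_samples]
    if absent:
        raise PopmapError(
            f"popmap samples missing from VCF (popmap/VCF mismatch): {absent[:5]}"
        )
    keep_names = [s for s in vcf_samples if s in popmap]
    keep_cols = np.array([vcf_samples.index(s) for s in keep_names], dtype=np.int64)

    contig_lengths = {}
    for raw in vcf.raw_header.splitlines():
        if raw.startswith("##contig"):
            body = raw.split("<", 1)[-1].rstrip(">")
            kv = dict(p.split("=", 1) for p in body.split(",") if "=" in p)
            if "ID" in kv and "length" in kv:
                contig_lengths[kv["ID"]] = int(kv["length"])

    want_contig = want_lo = want_hi = None
    if region is not None:
        want_contig, want_lo, want_hi = _parse_region(region)

    per_contig: dict = {}
    n_skipped = 0
    for v in vcf:
        if want_contig is not None:
            if v.CHROM != want_contig:
                continue
            if want_lo is not None and not (want_lo <= v.POS <= want_hi):
                continue
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1
            continue
        rec = per_contig.setdefault(
            v.CHROM, {"pos": [], "alleles": [], "gts": [], "aa": [], "dp": []}
        )
        rec["pos"].append(v.POS)
        rec["alleles"].append((v.REF, v.ALT[0]))
        gt = np.array(v.genotypes, dtype=np.int64)  # (n_samples, 3): a, b, phased
        rec["gts"].append(gt[keep_cols])
        rec["aa"].append(v.INFO.get("AA"))
        dps = v.gt_depths
        rec["dp"].append(
            float(np.mean(dps[keep_cols][dps[keep_cols] >= 0]))
            if dps is not None and np.any(dps[keep_cols] >= 0)
            else np.nan
        )
    if n_skipped:
        logger.info("read_vcf: skipped %d non-SNP/multiallelic records", n_skipped)

    datasets = []
    for contig, rec in per_contig.items():
        gts = np.stack(rec["gts"], axis=0)  # (S, n, 3)
        n = gts.shape[1]
        H = np.empty((2 * n, len(rec["pos"])), dtype=np.int8)
        a = gts[:, :, 0].T  # (n, S)
        b = gts[:, :, 1].T
        H[0::2] = np.where(a < 0, MISSING, a).astype(np.int8)
        H[1::2] = np.where(b < 0, MISSING, b).astype(np.int8)
        # unphased hets make haplotype identity meaningless
        het = (a >= 0) & (b >= 0) & (a != b)
        phased = not np.any(het & (gts[:, :, 2].T == 0))
        alleles = np.array(rec["alleles"], dtype="U8")
        anc = None
        if all(x is not None for x in rec["aa"]):
            anc = np.full(len(rec["aa"]), MISSING, dtype=np.int8)
            for j, aa in enumerate(rec["aa"]):
                if aa == alleles[j, 0]:
                    anc[j] = 0
                elif aa == alleles[j, 1]:
                    anc[j] = 1
        dp = np.array(rec["dp"], dtype=float)
        datasets.append(
            HaplotypeDataset(
                contig=contig,
                positions=np.array(rec["pos"], dtype=np.int64),
                alleles=alleles,
                H=H,
                sample_ids=keep_names,
                pop_of_sample={s: popmap[s] for s in keep_names},
                ancestral=anc,
                phased=phased,
                contig_length=contig_lengths.get(contig),
                mean_depth=dp if np.any(np.isfinite(dp)) else None,
            )
        )
    return datasets


def read_vcf_one(path, popmap, region: str | None = None) -> HaplotypeDataset:
    """:func:`read_vcf` asserting the result covers exactly one contig."""
    datasets = read_vcf(path, popmap, region=region)
    if len(datasets) != 1:
        raise ValueError(f"expected one contig, found {len(datasets)}")
    return datasets[0]


def write_vcf(ds: HaplotypeDataset, path) -> None:
    """Write a dataset as a phased VCF 4.2 text file (AA INFO when known)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        length = ds.contig_length or (int(ds.positions[-1]) if ds.n_sites else 1)
        fh.write(f"##contig=<ID={ds.contig},length={length}>\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(ds.sample_ids)
            + "\n"
        )
        sep = "|" if ds.phased else "/"
        for j in range(ds.n_sites):
            ref, alt = ds.alleles[j]
            if ds.ancestral is not None and ds.ancestral[j] != MISSING:
                info = f"AA={ref if ds.ancestral[j] == 0 else alt}"
            else:
                info = "."
            col = ds.H[:, j]
            gts = "\t".join(
                f"{'.' if col[2 * i] < 0 else col[2 * i]}{sep}"
                f"{'.' if col[2 * i + 1] < 0 else col[2 * i + 1]}"
                for i in range(ds.n_samples)
            )
            fh.write(
                f"{ds.contig}\t{ds.positions[j]}\t.\t{ref}\t{alt}\t.\tPASS\t"
                f"{info}\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# site filtering
# ---------------------------------------------------------------------------

def apply_site_filters(ds: HaplotypeDataset, f: SiteFilter):
    """Restrict a dataset to sites passing all enabled criteria.

    Returns ``(filtered_dataset, tally)`` where ``tally`` counts, per
    criterion, the sites failing it (a site may fail several), plus
    ``input`` and ``retained`` totals. An all-removed result is returned as
    an empty dataset with a warning, not an error.
    """
    S = ds.n_sites
    keep = np.ones(S, dtype=bool)
    tally = {"input": S}

    miss = np.mean(ds.H == MISSING, axis=0) if S else np.zeros(0)
    fail_miss = miss > f.max_missing
    tally["max_missing"] = int(fail_miss.sum())
    keep &= ~fail_miss

    nonmiss = (ds.H != MISSING).sum(axis=0).astype(float)
    ones = (ds.H == 1).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(nonmiss > 0, ones / np.maximum(nonmiss, 1), np.nan)
        maf = np.minimum(p, 1.0 - p)
    fail_maf = ~(maf >= f.min_maf)  # NaN (all-missing) fails too
    tally["min_maf"] = int(fail_maf.sum())
    keep &= ~fail_maf

    if (f.min_mean_dp is not None or f.max_mean_dp is not None) and ds.mean_depth is not None:
        dp = ds.mean_depth
        fail_dp = np.zeros(S, dtype=bool)
        if f.min_mean_dp is not None:
            fail_dp |= dp < f.min_mean_dp
        if f.max_mean_dp is not None:
            fail_dp |= dp > f.max_mean_dp
        tally["depth"] = int(fail_dp.sum())
        keep &= ~fail_dp
    else:
        tally["depth"] = 0

    tally["retained"] = int(keep.sum())
    if tally["retained"] == 0 and S:
        logger.warning("apply_site_filters: all %d sites removed", S)
    return ds.take_sites(np.flatnonzero(keep)), tally


# ---------------------------------------------------------------------------
# windowing
# ---------------------------------------------------------------------------

def make_windows(contig_length: int, size: int, step: int | None = None,
                 contig: str = "", ds: HaplotypeDataset | None = None) -> list:
    """Sliding-window grid ``[k*step, k*step + size)`` covering a contig.

    The last window is truncated at ``contig_length``. ``step == size``
    yields the non-overlapping grid. When a dataset is supplied its
    per-window retained SNP counts fill ``n_sites``.
    """
    if size <= 0 or (step is not None and step <= 0):
        raise ValueError("window size and step must be positive")
    step = size if step is None else step
    if step > size:
        raise ValueError("step must not exceed window size")
    if ds is not None and not contig:
        contig = ds.contig
    windows = []
    k = 0
    while k * step < contig_length:
        start = k * step
        end = min(start + size, contig_length)
        w = GenomicWindow(contig=contig, start=start, end=end)
        if ds is not None:
            lo = np.searchsorted(ds.positions, start + 1, side="left")
            hi = np.searchsorted(ds.positions, end, side="right")
            w.n_sites = int(hi - lo)
        windows.append(w)
        k += 1
    return windows


def window_site_slices(positions: np.ndarray, windows) -> list:
    """Per-window ``(lo, hi)`` index slices into a sorted 1-based position array."""
    out = []
    for w in windows:
        lo = np.searchsorted(positions, w.start + 1, side="left")
        hi = np.searchsorted(positions, w.end, side="right")
        out.append((int(lo), int(hi)))
    return out
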