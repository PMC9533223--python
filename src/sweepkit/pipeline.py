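"""End-to-end pipelines tying the analysis stages together.

Three orchestrations mirror the study designs the library targets:

* :func:`run_cdr_pipeline` — between-group candidate divergent region scan
  (10-kb/5-kb windowed pi and F_ST, Z-F_ST, log2 pi-ratio, joint-tail CDRs,
  candidate genes).
* :func:`run_sweep_pipeline` — within/cross-population haplotype scan
  (F_ST Manhattan track with absolute cutoff, XP-EHH/XP-nSL/iHS/nSL,
  standardization, 500-kb proportion windows, region-vs-background tests).
* :func:`run_dstat_pipeline` — ABBA-BABA trios with block-jackknife Z.

Every pipeline is a pure function of (inputs, config, seed): reruns write
byte-identical outputs. Output tables carry a header comment with the tool
version, a config hash and the seed.
"""
from __future__ import annotations

import dataclasses
import hashlib
import logging
import os
from dataclasses import dataclass

import pandas as pd

from . import __version__
from .core import (SiteFilter, apply_site_filters, make_windows, read_popmap,
                   read_vcf)
from .popgen import window_stat_table
from .sweep import (CDRConfig, detect_cdr, genes_in_regions, log2_pi_ratio,
                    region_vs_background, regions_to_bed, z_transform)
from .haplostats import ihs_scan, proportion_windows, standardize, xp_scan
from .introgression import dstat_trios

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Flat, file-loadable run configuration (CLI flags override file values)."""

    vcf: str = ""
    popmap: str = ""
    gff3: str | None = None
    out_dir: str = "sweepkit_out"
    seed: int = 0
    # filters
    max_missing: float = 0.2
    min_maf: float = 0.05
    # window grids
    window_size: int = 10_000
    window_step: int = 5_000
    prop_window_size: int = 500_000
    prop_min_snps: int = 100
    # CDR scan
    group_a: str = ""
    group_b: str = ""
    fst_quantile: float = 0.05
    ratio_quantile: float = 0.05
    fst_abs_cutoff: float = 0.15
    # haplotype scan
    pop_obs: str = ""
    pop_ref: str = ""
    score_threshold: float = 2.0
    max_extend_bp: int = 1_000_000  # EHH integration cap; scale to the genome
    region: str | None = None  # contig:start-end, 1-based inclusive
    # D statistics
    outgroup: str = ""
    ingroups: tuple = ()
    block_size: int = 2000
    log_level: str = "INFO"

    _INT = ("seed", "window_size", "window_step", "prop_window_size",
            "prop_min_snps", "block_size", "max_extend_bp")
    _FLOAT = ("max_missing", "min_maf", "fst_quantile", "ratio_quantile",
              "fst_abs_cutoff", "score_threshold")

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        """Parse a flat ``key = value`` config document ('#' comments)."""
        kv = {}
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{ln}: expected key = value")
                k, v = (s.strip() for s in line.split("=", 1))
                kv[k] = v
        kv.update({k: v for k, v in overrides.items() if v is not None})
        return cls.from_mapping(kv)

    @classmethod
    def from_mapping(cls, kv: dict) -> "RunConfig":
        args = {}
        names = {f.name for f in dataclasses.fields(cls)}
        for k, v in kv.items():
            if k not in names:
                raise ValueError(f"unknown config key {k!r}")
            if k in cls._INT:
                v = int(v)
            elif k in cls._FLOAT:
                v = float(v)
            elif k == "ingroups" and isinstance(v, str):
                v = tuple(s for s in v.replace(",", " ").split() if s)
            args[k] = v
        return cls(**args)

    def validate(self, need=()) -> None:
        for attr in ("vcf", "popmap"):
            path = getattr(self, attr)
            if not path or not os.path.exists(path):
                raise FileNotFoundError(f"{attr}: {path!r} does not exist")
        popmap = read_popmap(self.popmap)
        pops = set(popmap.values())
        for attr in need:
            name = getattr(self, attr)
            names = name if isinstance(name, tuple) else (name,)
            for nm in names:
                if not nm:
                    raise ValueError(f"config field {attr!r} is required")
                if nm not in pops:
                    raise ValueError(
                        f"{attr}={nm!r} not among popmap populations {sorted(pops)}"
                    )

    def hash(self) -> str:
        """Hash of the analysis-relevant configuration (output location and
        logging verbosity excluded, so reruns into a different directory are
        recognizably the same analysis)."""
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)
        d.pop("log_level", None)
        canon = repr(sorted(d.items()))
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _write_table(df: pd.DataFrame, path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# sweepkit v{__version__} config={cfg.hash()} seed={cfg.seed}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA", float_format="%.8g")


def _load(cfg: RunConfig):
    popmap = read_popmap(cfg.popmap)
    datasets = read_vcf(cfg.vcf, popmap)
    if not datasets or all(ds.n_sites == 0 for ds in datasets):
        raise ValueError(f"no SNP records loaded from {cfg.vcf}")
    filt = SiteFilter(max_missing=cfg.max_missing, min_maf=cfg.min_maf)
    out = []
    for ds in datasets:
        fds, tally = apply_site_filters(ds, filt)
        logger.info("%s: %d sites in, %d retained (%s)",
                    ds.contig, tally["input"], tally["retained"], tally)
        out.append(fds)
    return out


def _parse_region_0based(region: str):
    contig, span = region.rsplit(":", 1)
    lo, hi = span.split("-")
    return contig, int(lo) - 1, int(hi)


def run_cdr_pipeline(cfg: RunConfig) -> dict:
    """Between-group CDR scan; writes window stats, CDR BED/TSV and gene table."""
    cfg.validate(need=("group_a", "group_b"))
    os.makedirs(cfg.out_dir, exist_ok=True)
    datasets = _load(cfg)
    tables = []
    for ds in datasets:
        length = ds.contig_length or int(ds.positions[-1])
        windows = make_windows(length, cfg.window_size, cfg.window_step,
                               contig=ds.contig, ds=ds)
        tables.append(window_stat_table(ds, windows, [cfg.group_a, cfg.group_b],
                                        fst_pair=(cfg.group_a, cfg.group_b)))
    table = pd.concat(tables, ignore_index=True)
    table["z_fst"] = z_transform(table["fst"])
    table["log2_pi_ratio"] = log2_pi_ratio(table[f"pi_{cfg.group_a}"],
                                           table[f"pi_{cfg.group_b}"])
    cdr_cfg = CDRConfig(fst_quantile=cfg.fst_quantile,
                        ratio_quantile=cfg.ratio_quantile,
                        fst_abs_cutoff=cfg.fst_abs_cutoff)
    regions = detect_cdr(table, cdr_cfg)
    unmerged = detect_cdr(table, dataclasses.replace(cdr_cfg, merge=False))
    logger.info("CDR scan: %d windows, %d flagged windows, %d merged regions",
                len(table), len(unmerged), len(regions))
    genes = None
    if cfg.gff3:
        genes = genes_in_regions(cfg.gff3, regions)
        _write_table(genes, os.path.join(cfg.out_dir, "cdr_genes.tsv"), cfg)
    _write_table(table, os.path.join(cfg.out_dir, "window_stats.tsv"), cfg)
    regions_to_bed(regions, os.path.join(cfg.out_dir, "cdr.bed"))
    _write_table(regions_to_bed(regions), os.path.join(cfg.out_dir, "cdr.tsv"), cfg)
    return {"table": table, "regions": regions, "unmerged": unmerged,
            "genes": genes}


def run_sweep_pipeline(cfg: RunConfig) -> dict:
    """Haplotype sweep scan between an observed and a reference population."""
    cfg.validate(need=("pop_obs", "pop_ref"))
    os.makedirs(cfg.out_dir, exist_ok=True)
    datasets = _load(cfg)
    for ds in datasets:
        if not ds.phased:
            raise ValueError(
                f"{ds.contig}: haplotype scans require phased genotypes"
            )

    win_tables, scans, props = [], {}, {}
    scan_defs = [("XP-EHH", "bp"), ("XP-nSL", "sites"),
                 ("iHS", "bp"), ("nSL", "sites")]
    parts = {name: [] for name, _ in scan_defs}
    for ds in datasets:
        length = ds.contig_length or int(ds.positions[-1])
        windows = make_windows(length, cfg.window_size, cfg.window_step,
                               contig=ds.contig, ds=ds)
        win_tables.append(window_stat_table(ds, windows, [cfg.pop_obs, cfg.pop_ref],
                                            fst_pair=(cfg.pop_obs, cfg.pop_ref)))
        ext = {"max_extend_bp": cfg.max_extend_bp}
        parts["XP-EHH"].append(xp_scan(ds, cfg.pop_obs, cfg.pop_ref, mode="bp", **ext))
        parts["XP-nSL"].append(xp_scan(ds, cfg.pop_obs, cfg.pop_ref, mode="sites"))
        if ds.ancestral is not None:
            parts["iHS"].append(ihs_scan(ds, cfg.pop_obs, mode="bp", **ext))
            parts["nSL"].append(ihs_scan(ds, cfg.pop_obs, mode="sites"))
        else:
            logger.warning("%s: no ancestral states; iHS/nSL skipped", ds.contig)

    fst_table = pd.concat(win_tables, ignore_index=True)
    fst_table["above_cutoff"] = fst_table["fst"] > cfg.fst_abs_cutoff
    _write_table(fst_table, os.path.join(cfg.out_dir, "fst_manhattan.tsv"), cfg)

    lengths = {ds.contig: ds.contig_length or int(ds.positions[-1])
               for ds in datasets}
    single = len(lengths) == 1
    for name, _mode in scan_defs:
        if not parts[name]:
            continue
        raw = pd.concat(parts[name], ignore_index=True)
        scans[name] = standardize(raw)
        _write_table(scans[name],
                     os.path.join(cfg.out_dir, f"scan_{name.lower().replace('-', '')}.tsv"),
                     cfg)
        try:
            props[name] = proportion_windows(
                scans[name], threshold=cfg.score_threshold,
                size=cfg.prop_window_size, min_snps=cfg.prop_min_snps,
                contig_length=next(iter(lengths.values())) if single else None,
            )
            _write_table(props[name],
                         os.path.join(cfg.out_dir,
                                      f"prop_{name.lower().replace('-', '')}.tsv"),
                         cfg)
        except ValueError as exc:
            logger.warning("%s proportion windows: %s", name, exc)

    # region vs background (user-specified or top XP-EHH proportion window)
    mwu_rows = []
    region = None
    if cfg.region:
        region = _parse_region_0based(cfg.region)
    elif "XP-EHH" in props and len(props["XP-EHH"]):
        top = props["XP-EHH"].sort_values("proportion").iloc[-1]
        region = (top["contig"], int(top["start"]), int(top["end"]))
    if region is not None:
        for col in ("fst", f"pi_{cfg.pop_obs}", f"pi_{cfg.pop_ref}",
                    f"tajima_d_{cfg.pop_obs}", f"tajima_d_{cfg.pop_ref}"):
            if col not in fst_table.columns:
                continue
            try:
                rep = region_vs_background(fst_table, region, col)
            except ValueError as exc:
                logger.warning("region_vs_background %s: %s", col, exc)
                continue
            rep["column"] = col
            rep["region"] = f"{region[0]}:{region[1]}-{region[2]}"
            mwu_rows.append(rep)
        if mwu_rows:
            _write_table(pd.DataFrame(mwu_rows),
                         os.path.join(cfg.out_dir, "region_tests.tsv"), cfg)
    return {"fst_table": fst_table, "scans": scans, "proportions": props,
            "region": region, "region_tests": pd.DataFrame(mwu_rows)}


def run_dstat_pipeline(cfg: RunConfig) -> dict:
    """ABBA-BABA trios over the configured ingroups against the outgroup."""
    cfg.validate(need=("outgroup",))
    popmap = read_popmap(cfg.popmap)
    pops = sorted(set(popmap.values()))
    ingroups = list(cfg.ingroups) if cfg.ingroups else [
        p for p in pops if p != cfg.outgroup
    ]
    if len(ingroups) + 1 < 4:
        raise ValueError(
            f"D statistics need >=3 ingroups + outgroup; popmap has {pops}"
        )
    os.makedirs(cfg.out_dir, exist_ok=True)
    datasets = _load(cfg)
    frames = []
    for ds in datasets:
        frames.append(dstat_trios(ds, ingroups, cfg.outgroup,
                                  block_size=cfg.block_size))
    # pool per-contig pattern sums would change the jackknife; at desk scale
    # a single contig is the norm, so multiple contigs are reported separately
    table = pd.concat(frames, ignore_index=True)
    _write_table(table, os.path.join(cfg.out_dir, "dstat_trios.tsv"), cfg)
    return {"table": table}
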