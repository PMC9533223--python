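"""Seeded forward-in-time Wright-Fisher simulator with sweep and introgression.

The generator produces phased haplotype data with the statistical structure
the scans assume: a split demography of 1-4 ingroup populations plus an
outgroup, an optional one-generation introgression pulse, and an optional
hard selective sweep (additive fitness 1, 1+s, 1+2s), together with exact
machine-readable truth (demography, sweep trajectory outcome, ancestral
states, realized pulse fraction).

Model
-----
Discrete non-overlapping generations; each population holds N diploids
(2N haplotypes). Every offspring haplotype is a gamete of one sampled parent:
crossover count ~ Poisson(rho * L) with uniform breakpoints, then new
mutations ~ Poisson(mu * L) at uniform continuous positions (infinite sites;
positions are rounded to distinct integer bp only at VCF output). Splits
copy the parental pool; the outgroup is itself an early split so its sampled
allele frequencies can be polymorphic. A pulse replaces a fraction f of the
target population's parents with parents from the source population for one
generation. All randomness flows through one integer-seeded PCG64 stream, so
identical parameters and seed reproduce byte-identical output.

Every mutation is derived relative to the simulated ancestor, so the REF
allele is the true ancestral allele at every emitted site.

The default rates are scaled for desk-scale inference: with N = 200 and
mu = rho = 2.5e-7 per bp per generation, theta = 4*N*mu = 2e-4 per bp, which
gives a 500-kb window several hundred sample SNPs (so the proportion-scan
SNP floor is meaningful) and enough recombination that window statistics
average over many genealogies.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .core import HaplotypeDataset, write_popmap, write_vcf

logger = logging.getLogger(__name__)

_PRUNE_EVERY = 4
_NUCS = ("A", "C", "G", "T")


class SweepFixationError(RuntimeError):
    """The beneficial allele failed to fix within the restart budget."""


class _SweepLost(Exception):
    pass


@dataclass
class PulseSpec:
    """One-generation admixture pulse: fraction of target parents drawn
    from the source population at ``time`` generations before present."""

    source: str
    target: str
    fraction: float
    time: int

    def __post_init__(self):
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("pulse fraction must be in [0, 1]")


@dataclass
class SweepSpec:
    """Hard sweep: one beneficial copy injected into ``pop`` at ``time``
    generations before present, at physical position ``position`` bp, with
    additive selection coefficient ``s``."""

    pop: str
    position: float
    s: float
    time: int
    require_fixation: bool = True
    max_restarts: int = 100

    def __post_init__(self):
        if self.s <= 0:
            raise ValueError("selection coefficient must be positive")


@dataclass
class SimParams:
    """Forward-simulation parameters.

    ``split_times`` are generations before present, oldest first: the first
    entry is the outgroup split; each later entry splits off the last,
    second-to-last, ... listed ingroup from the ancestor lineage (carried by
    the first ingroup), giving the caterpillar topology
    (((P1, P2), P3), outgroup) for three ingroups. ``burn_in`` defaults to
    8N generations of neutral evolution before the first split.
    """

    L: int = 1_000_000
    N: int = 200
    mu: float = 2.5e-7
    rho: float = 2.5e-7
    pop_names: tuple = ("p1", "p2")
    outgroup: str = "outgroup"
    split_times: tuple = (400, 200)
    pulse: PulseSpec | None = None
    sweep: SweepSpec | None = None
    sample_sizes: int | dict = 20
    burn_in: int | None = None
    seed: int = 0
    contig: str = "chr1"

    def __post_init__(self):
        if not 1 <= len(self.pop_names) <= 4:
            raise ValueError("1-4 ingroup populations supported")
        if len(self.split_times) != len(self.pop_names):
            raise ValueError(
                "need one split time per ingroup (outgroup split first)"
            )
        if any(t2 >= t1 for t1, t2 in zip(self.split_times, self.split_times[1:])):
            raise ValueError("split_times must be strictly decreasing (oldest first)")
        if min(self.mu, self.rho) < 0 or self.L <= 0 or self.N < 2:
            raise ValueError("rates must be >= 0, L > 0, N >= 2")
        if self.burn_in is None:
            self.burn_in = 8 * self.N

    def samples_for(self, pop: str) -> int:
        if isinstance(self.sample_sizes, dict):
            return int(self.sample_sizes[pop])
        return int(self.sample_sizes)


@dataclass
class SimulationTruth:
    """Exact generator ground truth for one realization."""

    params: SimParams
    seed: int
    n_sites: int
    sweep_outcome: str | None  # "fixed" / "segregating" / None
    sweep_final_freq: float | None
    sweep_restarts: int
    pulse_realized_fraction: float | None
    pi_per_pop: dict
    n_fixed_dropped: int
    ancestral_note: str = "REF is the true ancestral allele at every site"


class ForwardSimulator:
    """Runs one realization of :class:`SimParams`. Not reusable."""

    def __init__(self, params: SimParams):
        self.p = params
        self.rng = np.random.default_rng(params.seed)
        self.positions = np.empty(0, dtype=np.float64)
        self.pops: dict = {}
        self.pop_order: list = []
        self.n_fixed_dropped = 0
        self._used_positions: set = set()
        self._sweep_pos: float | None = None
        self._sweep_injected = False
        self._sweep_restarts = 0
        self._pulse_realized: float | None = None
        self._gen_counter = 0
        # desk-scale guard; the sparse representation makes cost scale with
        # (mu + rho) * L * N * generations, not N * L * generations
        ops = (params.mu + params.rho) * params.L * 2 * params.N * (
            params.burn_in + params.split_times[0]
        )
        if ops > 5e7:
            warnings.warn(
                f"large simulation (~{ops:.2g} expected recombination/mutation "
                "events); this may take hours",
                RuntimeWarning,
            )

    # -- low-level reproduction -------------------------------------------
    def _draw_mut_positions(self, count: int) -> np.ndarray:
        out = self.rng.uniform(0.0, self.p.L, count)
        # infinite sites: re-draw the (vanishingly rare) float collisions
        for i in range(count):
            while out[i] in self._used_positions:
                out[i] = self.rng.uniform(0.0, self.p.L)
            self._used_positions.add(float(out[i]))
        return out

    def _gametes(self, M: np.ndarray, parents: np.ndarray) -> np.ndarray:
        """Recombinant gametes, one per entry of ``parents`` (individual ids).

        Site columns are kept sorted by position, so a gamete with k
        crossovers is assembled from k + 1 contiguous column slices of the
        two parental haplotypes.
        """
        n_g = parents.size
        start = self.rng.integers(0, 2, n_g)
        n_x = self.rng.poisson(self.p.rho * self.p.L, n_g)
        out = M[2 * parents + start]
        S = self.positions.size
        if S:
            for i in np.flatnonzero(n_x):
                bps = np.sort(self.rng.uniform(0.0, self.p.L, n_x[i]))
                bounds = np.concatenate(
                    [[0], np.searchsorted(self.positions, bps), [S]]
                )
                row_b = 2 * parents[i] + 1 - start[i]
                for seg in range(1, bounds.size - 1, 2):
                    lo, hi = bounds[seg], bounds[seg + 1]
                    out[i, lo:hi] = M[row_b, lo:hi]
        return out

    def _parent_choice(self, name: str, n_g: int) -> np.ndarray:
        """Parent individuals for a pop's gametes, fitness-weighted under a sweep."""
        M = self.pops[name]
        N = M.shape[0] // 2
        sw = self.p.sweep
        if (
            sw is not None
            and self._sweep_injected
            and name == sw.pop
            and self._sweep_idx() is not None
        ):
            col = M[:, self._sweep_idx()]
            g = col[0::2].astype(np.int64) + col[1::2].astype(np.int64)
            w = 1.0 + sw.s * g
            return self.rng.choice(N, size=n_g, p=w / w.sum())
        return self.rng.integers(0, N, n_g)

    def _sweep_idx(self) -> int | None:
        if self._sweep_pos is None:
            return None
        hits = np.flatnonzero(self.positions == self._sweep_pos)
        return int(hits[0]) if hits.size else None

    # -- one generation ----------------------------------------------------
    def _step(self, pulse: PulseSpec | None):
        new_pops = {}
        muts = []  # (name, gamete_rows, positions)
        for name in self.pop_order:
            M = self.pops[name]
            n_g = M.shape[0]
            if pulse is not None and pulse.target == name:
                mig = self.rng.uniform(size=n_g) < pulse.fraction
                self._pulse_realized = float(mig.mean())
                own_par = self._parent_choice(name, int((~mig).sum()))
                src = self.pops[pulse.source]
                mig_par = self.rng.integers(0, src.shape[0] // 2, int(mig.sum()))
                out = np.empty_like(M)
                out[~mig] = self._gametes(M, own_par)
                out[mig] = self._gametes(src, mig_par)
            else:
                out = self._gametes(M, self._parent_choice(name, n_g))
            n_new = self.rng.poisson(self.p.mu * self.p.L * n_g)
            if n_new:
                gam = self.rng.integers(0, n_g, n_new)
                pos = self._draw_mut_positions(n_new)
                muts.append((name, gam, pos))
            new_pops[name] = out

        total_new = sum(len(m[2]) for m in muts)
        if total_new:
            add_pos = np.concatenate([m[2] for m in muts])
            pos_all = np.concatenate([self.positions, add_pos])
            order = np.argsort(pos_all, kind="stable")  # keep columns sorted
            self.positions = pos_all[order]
            offset = 0
            blocks = {n: np.zeros((new_pops[n].shape[0], total_new), dtype=np.int8)
                      for n in self.pop_order}
            for name, gam, pos in muts:
                blocks[name][gam, offset + np.arange(len(pos))] = 1
                offset += len(pos)
            for n in self.pop_order:
                new_pops[n] = np.concatenate([new_pops[n], blocks[n]], axis=1)[:, order]
        self.pops = new_pops

        if self._sweep_injected:
            idx = self._sweep_idx()
            if idx is None or sum(int((M[:, idx] == 1).sum()) for M in self.pops.values()) == 0:
                raise _SweepLost
        self._gen_counter += 1
        if self._gen_counter % _PRUNE_EVERY == 0:
            self._prune()

    def _prune(self):
        if self.positions.size == 0:
            return
        total = sum(M.shape[0] for M in self.pops.values())
        counts = np.zeros(self.positions.size, dtype=np.int64)
        for M in self.pops.values():
            counts += (M == 1).sum(axis=0)
        keep = (counts > 0) & (counts < total)
        if self._sweep_pos is not None:
            keep |= self.positions == self._sweep_pos
        self.n_fixed_dropped += int(np.sum((counts == total) & ~keep))
        if keep.all():
            return
        for x in self.positions[~keep]:
            self._used_positions.discard(float(x))
        self.positions = self.positions[keep]
        self.pops = {n: M[:, keep] for n, M in self.pops.items()}

    # -- demography --------------------------------------------------------
    def _split_schedule(self) -> dict:
        """time -> new population name."""
        sched = {self.p.split_times[0]: self.p.outgroup}
        k = len(self.p.pop_names)
        for i, t in enumerate(self.p.split_times[1:], start=1):
            sched[t] = self.p.pop_names[k - i]
        return sched

    def _snapshot(self):
        return (
            self.positions.copy(),
            {n: M.copy() for n, M in self.pops.items()},
            list(self.pop_order),
            self.n_fixed_dropped,
            set(self._used_positions),
        )

    def _restore(self, snap):
        self.positions, pops, order, nfd, used = snap
        self.positions = self.positions.copy()
        self.pops = {n: M.copy() for n, M in pops.items()}
        self.pop_order = list(order)
        self.n_fixed_dropped = nfd
        self._used_positions = set(used)

    def run(self) -> tuple:
        p = self.p
        anchor = p.pop_names[0]
        self.pops = {anchor: np.zeros((2 * p.N, 0), dtype=np.int8)}
        self.pop_order = [anchor]
        for _ in range(p.burn_in):
            self._step(None)

        sched = self._split_schedule()
        snap = None
        snap_time = None
        t = p.split_times[0]
        while t > 0:
            if t in sched and sched[t] not in self.pops:
                new = sched[t]
                self.pops[new] = self.pops[anchor].copy()
                self.pop_order.append(new)
            if p.sweep is not None and t == p.sweep.time and not self._sweep_injected:
                if p.sweep.pop not in self.pops:
                    raise ValueError(
                        f"sweep population {p.sweep.pop!r} does not exist at "
                        f"generation {t} before present"
                    )
                self._inject_sweep()
                snap = self._snapshot()
                snap_time = t
            pulse = p.pulse if (p.pulse is not None and p.pulse.time == t
                                and p.pulse.target in self.pops) else None
            try:
                self._step(pulse)
            except _SweepLost:
                t = self._retry_sweep(snap, snap_time)
                continue
            t -= 1
            if t == 0 and p.sweep is not None and p.sweep.require_fixation:
                if self._sweep_freq() < 1.0:
                    t = self._retry_sweep(snap, snap_time)

        return self._emit()

    def _inject_sweep(self):
        sw = self.p.sweep
        pos = float(sw.position)
        while pos in self._used_positions:
            pos = float(self.rng.uniform(0.0, self.p.L))
        self._used_positions.add(pos)
        self._sweep_pos = pos
        at = int(np.searchsorted(self.positions, pos))
        self.positions = np.insert(self.positions, at, pos)
        for n in self.pop_order:
            M = self.pops[n]
            self.pops[n] = np.insert(M, at, 0, axis=1)
        carrier = int(self.rng.integers(0, self.pops[sw.pop].shape[0]))
        self.pops[sw.pop][carrier, at] = 1
        self._sweep_injected = True

    def _retry_sweep(self, snap, snap_time) -> int:
        self._sweep_restarts += 1
        if self._sweep_restarts > self.p.sweep.max_restarts:
            raise SweepFixationError(
                f"sweep failed to fix within {self.p.sweep.max_restarts} restarts"
            )
        self._restore(snap)
        return snap_time

    def _sweep_freq(self) -> float:
        idx = self._sweep_idx()
        if idx is None:
            return 0.0
        M = self.pops[self.p.sweep.pop]
        return float((M[:, idx] == 1).mean())

    # -- output ------------------------------------------------------------
    def _emit(self):
        p = self.p
        sweep_freq = self._sweep_freq() if self._sweep_injected else None

        all_names = list(p.pop_names) + [p.outgroup]
        sample_rows, sample_ids, popmap = [], [], {}
        for name in all_names:
            M = self.pops[name]
            N = M.shape[0] // 2
            n_s = p.samples_for(name)
            if n_s > N:
                raise ValueError(f"cannot sample {n_s} diploids from N={N}")
            pick = np.sort(self.rng.choice(N, size=n_s, replace=False))
            for i, ind in enumerate(pick):
                sid = f"{name}_{i:03d}"
                sample_ids.append(sid)
                popmap[sid] = name
                sample_rows.append(M[2 * ind])
                sample_rows.append(M[2 * ind + 1])
        H = np.array(sample_rows, dtype=np.int8)

        order = np.argsort(self.positions, kind="stable")
        H = H[:, order]
        fpos = self.positions[order]
        counts = (H == 1).sum(axis=0)
        poly = (counts > 0) & (counts < H.shape[0])
        H, fpos = H[:, poly], fpos[poly]

        ipos = np.empty(fpos.size, dtype=np.int64)
        prev = 0
        for j, x in enumerate(fpos):
            ipos[j] = max(int(np.floor(x)) + 1, prev + 1)
            prev = ipos[j]
        alleles = np.array(
            [(_NUCS[j % 4], _NUCS[(j + 1) % 4]) for j in range(fpos.size)], dtype="U1"
        ).reshape(-1, 2) if fpos.size else np.zeros((0, 2), dtype="U1")

        ds = HaplotypeDataset(
            contig=p.contig,
            positions=ipos,
            alleles=alleles,
            H=H,
            sample_ids=sample_ids,
            pop_of_sample=popmap,
            ancestral=np.zeros(fpos.size, dtype=np.int8),
            phased=True,
            contig_length=max(p.L, int(ipos[-1]) if ipos.size else p.L),
        )

        from .popgen import window_pi
        from .core import GenomicWindow

        pi = {}
        full = [GenomicWindow(contig=p.contig, start=0, end=ds.contig_length)]
        for name in all_names:
            if 2 * p.samples_for(name) >= 2:
                pi[name] = float(window_pi(ds, name, full)[0])

        truth = SimulationTruth(
            params=p,
            seed=p.seed,
            n_sites=ds.n_sites,
            sweep_outcome=(None if sweep_freq is None
                           else "fixed" if sweep_freq == 1.0 else "segregating"),
            sweep_final_freq=sweep_freq,
            sweep_restarts=self._sweep_restarts,
            pulse_realized_fraction=self._pulse_realized,
            pi_per_pop=pi,
            n_fixed_dropped=self.n_fixed_dropped,
        )
        return ds, truth


def simulate(params: SimParams):
    """Run one forward simulation; returns ``(HaplotypeDataset, SimulationTruth)``."""
    return ForwardSimulator(params).run()


def write_truth(truth: SimulationTruth, path) -> None:
    """Key=value truth file (format v1)."""
    p = truth.params
    with open(path, "w") as fh:
        fh.write("# sweepkit simulation truth, format v1\n")
        fh.write(f"seed={p.seed}\nL={p.L}\nN={p.N}\nmu={p.mu}\nrho={p.rho}\n")
        fh.write(f"pop_names={','.join(p.pop_names)}\noutgroup={p.outgroup}\n")
        fh.write(f"split_times={','.join(str(t) for t in p.split_times)}\n")
        fh.write(f"burn_in={p.burn_in}\nn_sites={truth.n_sites}\n")
        if p.sweep is not None:
            fh.write(f"sweep_pop={p.sweep.pop}\nsweep_position={p.sweep.position}\n")
            fh.write(f"sweep_s={p.sweep.s}\nsweep_time={p.sweep.time}\n")
            fh.write(f"sweep_outcome={truth.sweep_outcome}\n")
            fh.write(f"sweep_final_freq={truth.sweep_final_freq}\n")
            fh.write(f"sweep_restarts={truth.sweep_restarts}\n")
        if p.pulse is not None:
            fh.write(f"pulse_source={p.pulse.source}\npulse_target={p.pulse.target}\n")
            fh.write(f"pulse_fraction={p.pulse.fraction}\npulse_time={p.pulse.time}\n")
            fh.write(f"pulse_realized_fraction={truth.pulse_realized_fraction}\n")
        for name, v in truth.pi_per_pop.items():
            fh.write(f"pi_{name}={v:.8g}\n")
        fh.write(f"n_fixed_dropped={truth.n_fixed_dropped}\n")
        fh.write("ancestral=REF\n")


def simulate_to_files(params: SimParams, vcf_path, popmap_path, truth_path):
    """Simulate and write phased VCF + popmap + truth; returns (ds, truth)."""
    ds, truth = simulate(params)
    write_vcf(ds, vcf_path)
    write_popmap(ds.pop_of_sample, popmap_path)
    write_truth(truth, truth_path)
    return ds, truth


# ---------------------------------------------------------------------------
# divergence-segment implant (test fixture generator for the CDR scan)
# ---------------------------------------------------------------------------

def implant_divergence_segment(ds_a: HaplotypeDataset, ds_b: HaplotypeDataset,
                               segment: tuple, strength: float = 0.8,
                               fix_fraction: float = 0.4, seed: int = 0):
    """Implant a diverged, diversity-depleted segment into a dataset pair.

    Within ``segment`` (0-based half-open bp), population A haplotypes are
    collapsed toward A's first haplotype (each entry replaced by the template
    with probability ``strength``), and a deterministic, seeded fraction
    ``strength * fix_fraction`` of segment sites is driven to a fixed
    difference between A and B. ``strength = 0`` is the identity;
    ``strength = 1`` gives pi_A = 0 inside the segment. Returns
    ``(new_a, new_b, truth)`` with the implanted interval recorded.
    """
    if not np.array_equal(ds_a.positions, ds_b.positions):
        raise ValueError("datasets must share one coordinate grid")
    start, end = segment
    if start < 0 or end <= start or (ds_a.contig_length and start >= ds_a.contig_length):
        raise ValueError(f"segment [{start}, {end}) outside coordinate range")
    if not 0.0 <= strength <= 1.0:
        raise ValueError("strength must be in [0, 1]")
    rng = np.random.default_rng(seed)
    A = ds_a.H.copy()
    B = ds_b.H.copy()
    lo = np.searchsorted(ds_a.positions, start + 1, side="left")
    hi = np.searchsorted(ds_a.positions, end, side="right")
    seg = np.arange(lo, hi)
    if seg.size and strength > 0:
        template = A[0, seg].copy()
        collapse = rng.uniform(size=(A.shape[0], seg.size)) < strength
        block = A[:, seg]
        block[collapse] = np.broadcast_to(template, block.shape)[collapse]
        A[:, seg] = block
        n_fix = int(round(strength * fix_fraction * seg.size))
        fix_sites = rng.choice(seg.size, size=n_fix, replace=False) if n_fix else []
        for k in fix_sites:
            j = seg[k]
            x = template[k] if template[k] in (0, 1) else 1
            A[:, j] = x
            B[:, j] = 1 - x
    from dataclasses import replace
    new_a = replace(ds_a, H=A)
    new_b = replace(ds_b, H=B)
    truth = {"segment": (int(start), int(end)), "strength": strength,
             "fix_fraction": fix_fraction, "seed": seed}
    return new_a, new_b, truth


def split_by_population(ds: HaplotypeDataset):
    """One single-population dataset per population, sharing the site grid."""
    out = {}
    for pop in ds.populations():
        si = ds.sample_indices(pop)
        rows = np.stack([2 * si, 2 * si + 1], axis=1).reshape(-1)
        out[pop] = HaplotypeDataset(
            contig=ds.contig,
            positions=ds.positions,
            alleles=ds.alleles,
            H=ds.H[rows],
            sample_ids=[ds.sample_ids[i] for i in si],
            pop_of_sample={ds.sample_ids[i]: pop for i in si},
            ancestral=ds.ancestral,
            phased=ds.phased,
            contig_length=ds.contig_length,
        )
    return out


def merge_datasets(ds_a: HaplotypeDataset, ds_b: HaplotypeDataset) -> HaplotypeDataset:
    """Stack two single-grid datasets into one (sample ids must be disjoint)."""
    if not np.array_equal(ds_a.positions, ds_b.positions):
        raise ValueError("datasets must share one coordinate grid")
    if set(ds_a.sample_ids) & set(ds_b.sample_ids):
        raise ValueError("sample ids must be disjoint")
    return HaplotypeDataset(
        contig=ds_a.contig,
        positions=ds_a.positions,
        alleles=ds_a.alleles,
        H=np.concatenate([ds_a.H, ds_b.H], axis=0),
        sample_ids=list(ds_a.sample_ids) + list(ds_b.sample_ids),
        pop_of_sample={**ds_a.pop_of_sample, **ds_b.pop_of_sample},
        ancestral=ds_a.ancestral,
        phased=ds_a.phased and ds_b.phased,
        contig_length=ds_a.contig_length,
    )


# ---------------------------------------------------------------------------
# canned study scenarios (fixed parameter sets used by tests and examples)
# ---------------------------------------------------------------------------

def neutral_scenario(seed: int, L: int = 1_000_000, N: int = 200) -> SimParams:
    """Two recently split ingroups + outgroup, fully neutral; within-population
    diversity is essentially at the single-population equilibrium 4*N*mu."""
    return SimParams(
        L=L, N=N, mu=2.5e-7, rho=2.5e-7,
        pop_names=("p1", "p2"), outgroup="outgroup",
        split_times=(100, 50), sample_sizes=20, seed=seed,
    )


def sweep_scenario(seed: int, s: float = 0.1, position: float = 250_000.0,
                   sweep: bool = True) -> SimParams:
    """Firm-vs-soft style design: two ingroups split 200 generations ago and
    a hard sweep (selection coefficient s) injected into the observed
    population ('firm') 115 generations before sampling, required to fix.

    The injection time is late so that sampling happens close to fixation:
    carrier haplotypes accumulate new mutations at rate 2*mu per bp per
    generation from the moment of injection, and at the scaled rates the
    swept-region homozygosity would otherwise erode within tens of
    generations. ``sweep=False`` gives the matched neutral control.
    """
    return SimParams(
        L=1_000_000, N=200, mu=2.5e-7, rho=2.5e-7,
        pop_names=("firm", "soft"), outgroup="outgroup",
        split_times=(400, 200),
        sweep=(SweepSpec(pop="firm", position=position, s=s, time=115,
                         max_restarts=1000) if sweep else None),
        sample_sizes=30, seed=seed,
    )


#: extension cap (bp) used when EHH-family scans run on the 1-Mb synthetic
#: genome: at desk-scale N a noticeable share of haplotype pairs coalesce
#: recently enough to stay identical across the whole chromosome, so pooled
#: EHH never reaches the decay cutoff and the informative contrast sits
#: within the sweep footprint (~tens of kb); integrating further only adds a
#: contrast-free common tail, and a 1-Mb cap equals the whole genome anyway.
SCALED_SCAN_EXTEND_BP = 50_000


def pulse_scenario(seed: int, fraction: float = 0.2) -> SimParams:
    """Three ingroups on a caterpillar topology (((p1, p2), p3), outgroup)
    with an optional one-generation admixture pulse p3 -> p2 in the sampled
    generation's parents, emulating a recent introduction-route admixture
    signal. Scaled down (N = 50, elevated rates) so replicated calibration
    runs stay cheap; the internal branch (P3 split at 120, P1/P2 split at 30
    generations) is long enough that P3 carries clearly distinct variation,
    and 1.6 Mb of sequence yields enough informative sites for ~20+
    jackknife blocks of 25, keeping the null Z close to standard normal."""
    pulse = (PulseSpec(source="p3", target="p2", fraction=fraction, time=1)
             if fraction > 0 else None)
    return SimParams(
        L=1_600_000, N=50, mu=4e-6, rho=2e-6,
        pop_names=("p1", "p2", "p3"), outgroup="outgroup",
        split_times=(200, 120, 30), pulse=pulse,
        sample_sizes=20, seed=seed,
    )


def implant_scenario(seed: int) -> SimParams:
    """Small neutral two-ingroup dataset used as the substrate for
    :func:`implant_divergence_segment`."""
    return SimParams(
        L=1_000_000, N=50, mu=1e-6, rho=1e-6,
        pop_names=("pA", "pB"), outgroup="outgroup",
        split_times=(100, 50), sample_sizes=20, seed=seed,
    )
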