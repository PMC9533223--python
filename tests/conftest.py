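"""Shared fixtures: random dataset builders and cached simulation runs."""
from __future__ import annotations

import numpy as np
import pytest

from sweepkit.core import MISSING, HaplotypeDataset
from sweepkit.simulate import simulate, sweep_scenario


def make_dataset(seed=0, n_samples=10, n_sites=50, pops=("A", "B"),
                 missing_rate=0.0, contig="chr1", span=100_000,
                 maf_floor=0.0, phased=True, with_ancestral=True):
    """Random biallelic dataset with the requested shape.

    Sites are guaranteed polymorphic before missingness is applied.
    """
    rng = np.random.default_rng(seed)
    n_h = 2 * n_samples
    H = np.zeros((n_h, n_sites), dtype=np.int8)
    for j in range(n_sites):
        while True:
            p = rng.uniform(maf_floor, 1 - maf_floor) if maf_floor else rng.uniform()
            col = (rng.uniform(size=n_h) < p).astype(np.int8)
            if 0 < col.sum() < n_h:
                break
        H[:, j] = col
    if missing_rate:
        H[rng.uniform(size=H.shape) < missing_rate] = MISSING
    positions = np.sort(rng.choice(np.arange(1, span + 1), size=n_sites,
                                   replace=False))
    samples = [f"s{i:03d}" for i in range(n_samples)]
    popmap = {s: pops[i % len(pops)] for i, s in enumerate(samples)}
    alleles = np.array([("A", "T")] * n_sites, dtype="U1") if n_sites else \
        np.zeros((0, 2), dtype="U1")
    return HaplotypeDataset(
        contig=contig,
        positions=positions.astype(np.int64),
        alleles=alleles,
        H=H,
        sample_ids=samples,
        pop_of_sample=popmap,
        ancestral=np.zeros(n_sites, dtype=np.int8) if with_ancestral else None,
        phased=phased,
        contig_length=span,
    )


@pytest.fixture
def dataset_factory():
    return make_dataset


@pytest.fixture(scope="session")
def sweep_sim():
    """One cached hard-sweep realization, reused across tests."""
    return simulate(sweep_scenario(19))
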