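"""EHH curves, iHS/nSL/XP scans, standardization and proportion windows."""
import numpy as np
import pandas as pd
import pytest

from sweepkit.core import MISSING, HaplotypeDataset
from sweepkit.haplostats import (_PairScanner, ehh_curve, ihs_scan,
                                 integrate_curve, proportion_windows,
                                 standardize, xp_scan)

import oracles
from conftest import make_dataset


def single_pop(H, positions=None, span=None, ancestral=True):
    H = np.asarray(H, dtype=np.int8)
    n_h, S = H.shape
    assert n_h % 2 == 0
    positions = np.arange(1, S + 1) * 100 if positions is None else np.asarray(positions)
    samples = [f"s{i}" for i in range(n_h // 2)]
    return HaplotypeDataset(
        contig="chr1", positions=positions.astype(np.int64),
        alleles=np.array([("A", "T")] * S, dtype="U1"),
        H=H, sample_ids=samples, pop_of_sample={s: "P" for s in samples},
        ancestral=np.zeros(S, dtype=np.int8) if ancestral else None,
        contig_length=int(positions[-1]) + 100,
    )


class TestEHHCurve:
    def test_group_partition_value(self):
        # 4 derived carriers whose extended haplotypes partition {2,1,1} at
        # offset 1: one identical pair of C(4,2)=6 -> EHH = 1/6
        H = np.array([
            [1, 0, 0],
            [1, 0, 0],
            [1, 1, 0],
            [1, 1, 1],
            [0, 0, 0],
            [0, 0, 0],
        ])
        ds = single_pop(H)
        curve = ehh_curve(ds, "P", core=0, allele=1)
        assert curve.right_ehh[0] == pytest.approx(2 / 6)  # {2,2} at offset 1
        assert curve.right_ehh[1] == pytest.approx(1 / 6)  # {2,1,1} at offset 2

    def test_core_offset_is_one(self):
        ds = make_dataset(seed=61, n_samples=6, n_sites=30, pops=("P",),
                          maf_floor=0.3)
        curve = ehh_curve(ds, "P", core=10, allele="pooled")
        # EHH(0) = 1 by convention; stored curves start at offset 1
        assert curve.left_ehh.size == 0 or curve.left_ehh[0] <= 1.0

    def test_monotone_nonincreasing_and_bounded(self):
        ds = make_dataset(seed=62, n_samples=10, n_sites=80, pops=("P",),
                          maf_floor=0.25, span=8_000)
        for core in (20, 40, 60):
            for allele in (0, 1, "pooled"):
                curve = ehh_curve(ds, "P", core, allele)
                for ehh in (curve.left_ehh, curve.right_ehh):
                    assert np.all((ehh >= 0) & (ehh <= 1))
                    assert np.all(np.diff(ehh) <= 1e-12)

    def test_matches_pair_enumeration_oracle(self):
        ds = make_dataset(seed=63, n_samples=8, n_sites=60, pops=("P",),
                          missing_rate=0.05, maf_floor=0.25, span=6_000)
        rows = ds.haplotype_rows("P")
        for core in (15, 30, 45):
            for allele in (0, 1):
                carriers = rows[ds.H[rows, core] == allele]
                if carriers.size < 2:
                    continue
                curve = ehh_curve(ds, "P", core, allele)
                M = ds.H[carriers]
                for offs, ehhs in ((curve.right_offsets, curve.right_ehh),
                                   (curve.left_offsets, curve.left_ehh)):
                    for j, e in zip(offs, ehhs):
                        assert e == pytest.approx(
                            oracles.ehh_at_offset_oracle(M, core, int(j)),
                            abs=1e-12)

    def test_too_few_carriers_rejected(self):
        ds = make_dataset(seed=64, n_samples=4, n_sites=10, pops=("P",))
        ds.H[:, 5] = 0
        ds.H[0, 5] = 1
        with pytest.raises(ValueError, match="carriers"):
            ehh_curve(ds, "P", core=5, allele=1)

    def test_unphased_refused(self):
        ds = make_dataset(seed=65, n_samples=4, n_sites=10, pops=("P",),
                          phased=False)
        with pytest.raises(ValueError, match="phased"):
            ehh_curve(ds, "P", core=5, allele="pooled")


class TestIHSScan:
    def test_mirror_symmetry_zero_score(self):
        # derived and ancestral classes with identical flank structure
        rng = np.random.default_rng(66)
        flank = (rng.uniform(size=(4, 41)) < 0.4).astype(np.int8)
        H = np.vstack([flank, flank.copy()])
        H[:4, 20] = 0
        H[4:, 20] = 1
        ds = single_pop(H)
        out = ihs_scan(ds, "P", mode="sites", maf_min=0.0)
        row = out[out["pos"] == ds.positions[20]]
        assert len(row) == 1
        assert row["unstd"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_long_derived_haplotype_negative_score(self):
        # derived carriers share one long haplotype around the core (but
        # diverge further out, so the curve still decays); ancestral
        # background is diverse
        rng = np.random.default_rng(67)
        S = 81
        anc = (rng.uniform(size=(6, S)) < 0.5).astype(np.int8)
        der = (rng.uniform(size=(6, S)) < 0.5).astype(np.int8)
        shared = (rng.uniform(size=20) < 0.5).astype(np.int8)
        der[:, 30:50] = shared
        H = np.vstack([anc, der])
        H[:6, 40] = 0
        H[6:, 40] = 1
        ds = single_pop(H)
        out = ihs_scan(ds, "P", mode="sites", maf_min=0.0)
        row = out[out["pos"] == ds.positions[40]]
        assert row["unstd"].iloc[0] < 0  # ln(iHH_A / iHH_D), iHH_D >> iHH_A

    @pytest.mark.parametrize("mode", ["bp", "sites"])
    def test_integrals_match_trapezoid_oracle(self, mode):
        ds = make_dataset(seed=68, n_samples=10, n_sites=200, pops=("P",),
                          maf_floor=0.15, span=20_000)
        out = ihs_scan(ds, "P", mode=mode)
        rows = ds.haplotype_rows("P")
        checked = 0
        for _, rec in out.iterrows():
            core = int(np.searchsorted(ds.positions, rec["pos"]))
            for allele, col in ((0, "ihh_a"), (1, "ihh_d")):
                carriers = rows[ds.H[rows, core] == allele]
                exp, status = oracles.ihh_oracle(ds.H[carriers], ds.positions,
                                                 core, mode)
                if status != "ok":
                    assert np.isnan(rec[col])
                else:
                    assert rec[col] == pytest.approx(exp, abs=1e-9)
                    checked += 1
        assert checked > 20

    def test_row_permutation_invariant(self):
        ds = make_dataset(seed=69, n_samples=8, n_sites=100, pops=("P",),
                          maf_floor=0.2, span=10_000)
        base = ihs_scan(ds, "P", mode="sites")
        rng = np.random.default_rng(0)
        ds.H = ds.H[rng.permutation(ds.n_haplotypes)]
        perm = ihs_scan(ds, "P", mode="sites")
        pd.testing.assert_frame_equal(base, perm)

    def test_requires_ancestral_and_phase(self):
        ds = make_dataset(seed=70, n_samples=6, n_sites=20, pops=("P",),
                          with_ancestral=False)
        with pytest.raises(ValueError, match="ancestral"):
            ihs_scan(ds, "P")
        ds2 = make_dataset(seed=70, n_samples=6, n_sites=20, pops=("P",),
                           phased=False)
        with pytest.raises(ValueError, match="phased"):
            ihs_scan(ds2, "P")


class TestXPScan:
    def test_identical_populations_zero_scores(self):
        ds = make_dataset(seed=71, n_samples=12, n_sites=120, pops=("A", "B"),
                          maf_floor=0.2, span=12_000)
        ds.H[ds.haplotype_rows("B")] = ds.H[ds.haplotype_rows("A")]
        out = xp_scan(ds, "A", "B", mode="sites")
        assert len(out) > 20
        np.testing.assert_allclose(out["unstd"], 0.0, atol=1e-12)

    @pytest.mark.parametrize("mode", ["bp", "sites"])
    def test_population_swap_negates_exactly(self, mode):
        ds = make_dataset(seed=72, n_samples=14, n_sites=150, pops=("A", "B"),
                          maf_floor=0.15, span=15_000)
        fwd = xp_scan(ds, "A", "B", mode=mode)
        rev = xp_scan(ds, "B", "A", mode=mode)
        assert len(fwd) == len(rev) > 20
        np.testing.assert_allclose(fwd["unstd"].to_numpy(),
                                   -rev["unstd"].to_numpy(), atol=1e-12)
        np.testing.assert_allclose(fwd["ihh_a"], rev["ihh_d"], atol=1e-12)

    def test_same_population_twice_rejected(self):
        ds = make_dataset(seed=73, n_samples=6, n_sites=20)
        with pytest.raises(ValueError):
            xp_scan(ds, "A", "A")

    def test_sweep_signal_localizes(self, sweep_sim):
        ds, truth = sweep_sim
        out = standardize(xp_scan(ds, "firm", "soft", mode="bp"))
        pos = out["pos"].to_numpy()
        std = out["std"].to_numpy(float)
        near = np.abs(pos - truth.params.sweep.position) < 50_000
        ok = np.isfinite(std)
        assert (near & ok).sum() >= 5
        assert np.mean(std[near & ok]) > np.mean(std[ok])


class TestStandardize:
    def test_bin_means_and_sds(self):
        rng = np.random.default_rng(74)
        n = 5000
        freq = rng.uniform(0.02, 0.98, n)
        tab = pd.DataFrame({
            "contig": "c", "pos": np.arange(1, n + 1), "freq": freq,
            "ihh_a": 1.0, "ihh_d": 1.0,
            "unstd": rng.normal(size=n) + 3 * freq,
            "std": np.nan, "statistic": "iHS",
        })
        out = standardize(tab, scheme="bins")
        which = np.clip((out["freq"] * 100).astype(int), 0, 99)
        for b in np.unique(which):
            vals = out.loc[which == b, "std"].dropna()
            if len(vals) >= 2:
                assert abs(vals.mean()) < 1e-10
                assert abs(vals.std(ddof=1) - 1) < 1e-10

    def test_two_scores_single_bin(self):
        # {-1, 1} has mean 0 and sample sd sqrt(2): scaled to +/- 1/sqrt(2)
        tab = pd.DataFrame({
            "contig": "c", "pos": [1, 2], "freq": [0.501, 0.502],
            "ihh_a": 1.0, "ihh_d": 1.0, "unstd": [-1.0, 1.0],
            "std": np.nan, "statistic": "iHS",
        })
        out = standardize(tab, scheme="bins")
        np.testing.assert_allclose(out["std"], [-2 ** -0.5, 2 ** -0.5])

    def test_bins_remove_frequency_confound_global_does_not(self):
        rng = np.random.default_rng(75)
        n = 4000
        freq = rng.uniform(0.02, 0.98, n)
        tab = pd.DataFrame({
            "contig": "c", "pos": np.arange(1, n + 1), "freq": freq,
            "ihh_a": 1.0, "ihh_d": 1.0,
            "unstd": freq + rng.normal(scale=0.05, size=n),
            "std": np.nan, "statistic": "iHS",
        })
        binned = standardize(tab, scheme="bins")
        glob = standardize(tab, scheme="global")
        lo_b = binned.loc[freq < 0.2, "std"].mean()
        hi_b = binned.loc[freq > 0.8, "std"].mean()
        lo_g = glob.loc[freq < 0.2, "std"].mean()
        hi_g = glob.loc[freq > 0.8, "std"].mean()
        assert abs(hi_b - lo_b) < 0.3
        assert hi_g - lo_g > 1.0

    def test_default_scheme_by_statistic(self):
        tab = pd.DataFrame({
            "contig": "c", "pos": [1, 2, 3], "freq": [0.1, 0.5, 0.9],
            "ihh_a": 1.0, "ihh_d": 1.0, "unstd": [0.0, 1.0, 2.0],
            "std": np.nan, "statistic": "XP-EHH",
        })
        out = standardize(tab)  # global for XP
        assert np.isfinite(out["std"]).all()


class TestProportionWindows:
    def make_table(self, pos, std, statistic="XP-EHH"):
        return pd.DataFrame({
            "contig": "chr1", "pos": pos, "freq": 0.5,
            "ihh_a": 1.0, "ihh_d": 1.0, "unstd": std, "std": std,
            "statistic": statistic,
        })

    def test_proportion_arithmetic(self):
        rng = np.random.default_rng(76)
        pos = np.sort(rng.choice(np.arange(1, 500_001), 150, replace=False))
        std = np.zeros(150)
        std[:30] = 3.0
        out = proportion_windows(self.make_table(pos, std), min_snps=100,
                                 contig_length=500_000)
        assert len(out) == 1
        assert out["n_tested"].iloc[0] == 150
        assert out["proportion"].iloc[0] == pytest.approx(0.2)

    def test_sparse_window_excluded(self):
        rng = np.random.default_rng(77)
        pos1 = np.sort(rng.choice(np.arange(1, 500_001), 120, replace=False))
        pos2 = np.sort(rng.choice(np.arange(500_001, 1_000_001), 99,
                                  replace=False))
        pos = np.concatenate([pos1, pos2])
        out = proportion_windows(self.make_table(pos, np.zeros(pos.size)),
                                 min_snps=100, contig_length=1_000_000)
        assert len(out) == 1 and out["start"].iloc[0] == 0

    def test_two_sided_for_ihs(self):
        rng = np.random.default_rng(78)
        pos = np.sort(rng.choice(np.arange(1, 500_001), 120, replace=False))
        std = np.zeros(120)
        std[:10] = -3.0  # negative extremes count for |iHS|
        ihs = proportion_windows(self.make_table(pos, std, "iHS"),
                                 min_snps=100, contig_length=500_000)
        xp = proportion_windows(self.make_table(pos, std, "XP-EHH"),
                                min_snps=100, contig_length=500_000)
        assert ihs["proportion"].iloc[0] == pytest.approx(10 / 120)
        assert xp["proportion"].iloc[0] == 0.0

    def test_percentile_tiers(self):
        rng = np.random.default_rng(79)
        parts, base = [], 0
        for w in range(100):
            pos = np.sort(rng.choice(np.arange(1, 500_001), 110,
                                     replace=False)) + base
            std = np.zeros(110)
            std[: w + 1] = 3.0  # strictly increasing proportions
            parts.append(self.make_table(pos, std))
            base += 500_000
        tab = pd.concat(parts, ignore_index=True)
        out = proportion_windows(tab, min_snps=100, contig_length=base)
        assert (out["tier"] == "99").sum() == 2  # percentile >= 99: top 2 of 100
        assert (out["tier"].isin(["95", "99"])).sum() == 6
        top = out.sort_values("proportion").iloc[-1]
        assert top["percentile"] == 100.0


class TestScannerConsistency:
    def test_fast_scanner_equals_stepwise_curves(self):
        ds = make_dataset(seed=80, n_samples=10, n_sites=120, pops=("P",),
                          missing_rate=0.04, maf_floor=0.2, span=12_000)
        rows = ds.haplotype_rows("P")
        sc = _PairScanner(ds.H[rows], ds.positions, "bp", {})
        for core in range(20, 100, 13):
            for allele in (0, 1):
                car = ds.H[rows, core] == allele
                if car.sum() < 2:
                    continue
                mask = car[sc.iu] & car[sc.ju]
                curve = ehh_curve(ds, "P", core, allele, mode="bp")
                for step, (offs, ehhs) in (
                    (+1, (curve.right_offsets, curve.right_ehh)),
                    (-1, (curve.left_offsets, curve.left_ehh)),
                ):
                    idx, e, status = sc.scan_side(core, step, mask)
                    np.testing.assert_array_equal(idx, offs)
                    np.testing.assert_allclose(e, ehhs, atol=1e-12)
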