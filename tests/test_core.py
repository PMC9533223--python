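"""Core container, VCF round-trip, site filters and windowing."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sweepkit.core import (MISSING, GenomicWindow, HaplotypeDataset,
                           PopmapError, SiteFilter, apply_site_filters,
                           make_windows, read_popmap, read_vcf, read_vcf_one,
                           write_popmap, write_vcf)
from sweepkit.simulate import simulate, implant_scenario

from conftest import make_dataset


class TestHaplotypeDataset:
    def test_shape_contract(self):
        ds = make_dataset(n_samples=2, n_sites=3)
        assert ds.H.shape == (4, 3)
        assert ds.n_haplotypes == 2 * ds.n_samples

    def test_rejects_nonincreasing_positions(self):
        ds = make_dataset(n_samples=2, n_sites=3)
        with pytest.raises(ValueError, match="strictly increasing"):
            HaplotypeDataset(ds.contig, ds.positions[::-1], ds.alleles, ds.H,
                             ds.sample_ids, ds.pop_of_sample)

    def test_rejects_unlabelled_sample(self):
        ds = make_dataset(n_samples=2, n_sites=3)
        with pytest.raises(PopmapError):
            HaplotypeDataset(ds.contig, ds.positions, ds.alleles, ds.H,
                             ds.sample_ids, {ds.sample_ids[0]: "A"})

    def test_haplotype_rows_partition_pops(self):
        ds = make_dataset(n_samples=6, pops=("A", "B", "C"))
        rows = np.concatenate([ds.haplotype_rows(p) for p in ("A", "B", "C")])
        assert sorted(rows) == list(range(ds.n_haplotypes))


class TestVcfIO:
    def test_write_read_round_trip(self, tmp_path):
        ds = make_dataset(seed=5, n_samples=8, n_sites=60, missing_rate=0.05)
        path = tmp_path / "x.vcf"
        write_vcf(ds, path)
        back = read_vcf_one(path, ds.pop_of_sample)
        np.testing.assert_array_equal(back.H, ds.H)
        np.testing.assert_array_equal(back.positions, ds.positions)
        np.testing.assert_array_equal(back.ancestral, ds.ancestral)
        assert back.sample_ids == ds.sample_ids
        assert back.contig_length == ds.contig_length
        assert back.phased

    def test_simulated_round_trip_identical(self, tmp_path):
        ds, _ = simulate(implant_scenario(3))
        path = tmp_path / "sim.vcf"
        write_vcf(ds, path)
        back = read_vcf_one(path, ds.pop_of_sample)
        np.testing.assert_array_equal(back.H, ds.H)
        np.testing.assert_array_equal(back.positions, ds.positions)
        np.testing.assert_array_equal(back.ancestral, ds.ancestral)

    def test_missing_genotype_loaded_as_missing(self, tmp_path):
        path = tmp_path / "m.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=c1,length=1000>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
            "c1\t10\t.\tA\tT\t.\tPASS\t.\tGT\t0|1\t./.\n"
        )
        ds = read_vcf_one(path, {"s1": "A", "s2": "A"})
        assert list(ds.H[:, 0]) == [0, 1, MISSING, MISSING]

    def test_popmap_sample_absent_from_vcf(self, tmp_path):
        ds = make_dataset(n_samples=2, n_sites=3)
        path = tmp_path / "x.vcf"
        write_vcf(ds, path)
        with pytest.raises(PopmapError, match="mismatch"):
            read_vcf(path, {"nope": "A"})

    def test_non_snp_records_skipped(self, tmp_path):
        path = tmp_path / "i.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=c1,length=1000>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "c1\t10\t.\tA\tT\t.\tPASS\t.\tGT\t0|1\n"
            "c1\t20\t.\tAC\tA\t.\tPASS\t.\tGT\t0|1\n"
            "c1\t30\t.\tA\tT,G\t.\tPASS\t.\tGT\t0|1\n"
        )
        ds = read_vcf_one(path, {"s1": "A"})
        assert ds.n_sites == 1 and ds.positions[0] == 10

    def test_unphased_het_clears_phased_flag(self, tmp_path):
        path = tmp_path / "u.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=c1,length=1000>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "c1\t10\t.\tA\tT\t.\tPASS\t.\tGT\t0/1\n"
        )
        ds = read_vcf_one(path, {"s1": "A"})
        assert not ds.phased

    def test_region_query(self, tmp_path):
        ds = make_dataset(seed=1, n_samples=4, n_sites=50, span=10_000)
        path = tmp_path / "r.vcf"
        write_vcf(ds, path)
        lo, hi = int(ds.positions[10]), int(ds.positions[20])
        sub = read_vcf_one(path, ds.pop_of_sample, region=f"chr1:{lo}-{hi}")
        assert sub.n_sites == 11
        assert sub.positions[0] == lo and sub.positions[-1] == hi

    def test_popmap_file_round_trip(self, tmp_path):
        pm = {"a": "X", "b": "Y"}
        path = tmp_path / "pm.txt"
        write_popmap(pm, path)
        assert read_popmap(path) == pm

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            read_vcf("/nonexistent.vcf", {"a": "A"})


class TestSiteFilters:
    def test_missingness_threshold(self):
        # 10 haplotypes, 3 missing entries -> 0.3 > 0.2 removed
        ds = make_dataset(seed=2, n_samples=5, n_sites=4)
        ds.H[:3, 1] = MISSING
        out, tally = apply_site_filters(ds, SiteFilter(max_missing=0.2, min_maf=0.0))
        assert tally["max_missing"] == 1
        assert ds.positions[1] not in out.positions

    def test_maf_on_nonmissing_denominator(self):
        # counts 1/9 non-missing -> MAF 0.1 retained at floor 0.05
        ds = make_dataset(seed=3, n_samples=6, n_sites=2)
        ds.H[:, 0] = 0
        ds.H[0, 0] = 1
        ds.H[10:, 0] = MISSING  # 10 non-missing: counts 1/9
        out, _ = apply_site_filters(ds, SiteFilter(max_missing=0.5, min_maf=0.05))
        assert ds.positions[0] in out.positions

    def test_matches_site_by_site_oracle(self):
        ds = make_dataset(seed=7, n_samples=10, n_sites=200, missing_rate=0.15)
        f = SiteFilter(max_missing=0.2, min_maf=0.05)
        out, _ = apply_site_filters(ds, f)
        expected = []
        for j in range(ds.n_sites):
            col = ds.H[:, j]
            vals = [v for v in col if v != MISSING]
            miss = 1 - len(vals) / len(col)
            p = sum(vals) / len(vals) if vals else float("nan")
            maf = min(p, 1 - p) if vals else float("nan")
            if miss <= 0.2 and maf == maf and maf >= 0.05:
                expected.append(ds.positions[j])
        np.testing.assert_array_equal(out.positions, expected)

    def test_idempotent(self):
        ds = make_dataset(seed=9, n_samples=8, n_sites=120, missing_rate=0.1)
        f = SiteFilter()
        once, _ = apply_site_filters(ds, f)
        twice, tally = apply_site_filters(once, f)
        np.testing.assert_array_equal(once.H, twice.H)
        assert tally["retained"] == once.n_sites

    def test_all_removed_warns_not_raises(self, caplog):
        ds = make_dataset(seed=4, n_samples=4, n_sites=5)
        ds.H[:] = MISSING
        out, tally = apply_site_filters(ds, SiteFilter())
        assert out.n_sites == 0 and tally["retained"] == 0

    def test_validation(self):
        with pytest.raises(ValueError):
            SiteFilter(max_missing=1.5)
        with pytest.raises(ValueError):
            SiteFilter(min_maf=0.6)


class TestWindows:
    def test_sliding_grid_arithmetic(self):
        ws = make_windows(25_000, 10_000, 5_000)
        assert [w.start for w in ws] == [0, 5_000, 10_000, 15_000, 20_000]
        assert (ws[-1].start, ws[-1].end) == (20_000, 25_000)

    def test_nonoverlapping_500kb_grid(self):
        ws = make_windows(1_600_000, 500_000, 500_000)
        assert [(w.start, w.end) for w in ws] == [
            (0, 500_000), (500_000, 1_000_000),
            (1_000_000, 1_500_000), (1_500_000, 1_600_000)]

    def test_short_contig_single_truncated_window(self):
        ws = make_windows(4_000, 10_000, 5_000)
        assert len(ws) == 1 and ws[0].end == 4_000

    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            make_windows(1000, 0, 5)
        with pytest.raises(ValueError):
            make_windows(1000, 10, -1)
        with pytest.raises(ValueError):
            make_windows(1000, 10, 20)

    def test_n_sites_filled_from_dataset(self):
        ds = make_dataset(seed=6, n_sites=40, span=20_000)
        ws = make_windows(20_000, 10_000, 5_000, ds=ds)
        assert sum(w.n_sites for w in make_windows(20_000, 10_000, 10_000, ds=ds)) \
            == ds.n_sites

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(length=st.integers(1, 100_000), size=st.integers(1, 20_000),
           data=st.data())
    def test_every_bp_covered_expected_number_of_times(self, length, size, data):
        step = data.draw(st.integers(1, size))
        ws = make_windows(length, size, step)
        probe = np.linspace(0, length - 1, num=25).astype(int)
        for bp in probe:
            n_cover = sum(w.start <= bp < w.end for w in ws)
            # interior bp sit in ceil(size/step) windows; fewer near edges
            assert 1 <= n_cover <= -(-size // step)

    def test_bad_window(self):
        with pytest.raises(ValueError):
            GenomicWindow("c", 10, 10)
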