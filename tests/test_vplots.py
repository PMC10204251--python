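import gzip

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import vplotvae as vv
from vplotvae.vplots import Fragments


@pytest.fixture()
def cfg():
    return vv.VPlotConfig()


class TestReadFragments:
    def test_bed_row_maps_to_fragment_fields(self, tmp_path):
        p = tmp_path / "f.bed"
        p.write_text("chr1\t100\t300\n")
        frags = vv.read_fragments(p)
        f = next(iter(frags))
        assert (f.chrom, f.start, f.end) == ("chr1", 100, 300)
        assert f.length == 200 and f.midpoint == 200

    def test_empty_file_gives_empty_collection(self, tmp_path):
        p = tmp_path / "f.bed"
        p.write_text("")
        assert len(vv.read_fragments(p)) == 0

    def test_bedpe_collapses_to_outer_span(self, tmp_path):
        p = tmp_path / "f.bedpe"
        p.write_text("chr1\t100\t150\tchr1\t280\t330\tname\t60\n")
        f = next(iter(vv.read_fragments(p, format="BEDPE")))
        assert (f.start, f.end) == (100, 330)

    def test_gzip_roundtrip(self, tmp_path):
        p = tmp_path / "f.bed.gz"
        with gzip.open(p, "wt") as fh:
            fh.write("chrX\t5\t105\n")
        assert len(vv.read_fragments(p)) == 1

    @pytest.mark.parametrize("line,msg", [
        ("chr1\t100\n", "columns"),
        ("chr1\tabc\t300\n", "non-integer"),
        ("chr1\t300\t100\n", "start"),
    ])
    def test_malformed_rows_name_the_line(self, tmp_path, line, msg):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t1\t2\n" + line)
        with pytest.raises(ValueError, match="line 2"):
            vv.read_fragments(p)


class TestMakeVplot:
    def test_binning_arithmetic(self, cfg):
        region = vv.GenomicRegion("chr1", 1000, 1640)
        frags = Fragments(np.array(["chr1"]), np.array([1000]), np.array([1100]))
        vp = vv.make_vplot(frags, region, cfg)
        # midpoint offset 50 -> bin 10; length 100 -> bin 9
        assert vp.counts[10, 9] == 1 and vp.counts.sum() == 1

    def test_length_and_window_cutoffs(self, cfg):
        region = vv.GenomicRegion("chr1", 0, 640)
        frags = Fragments(np.array(["chr1"] * 3),
                          np.array([0, 0, 320]),
                          np.array([700, 640, 960]))  # too long; ok; midpoint=640
        vp = vv.make_vplot(frags, region, cfg)
        assert vp.n_reads == 1  # only the length-640 fragment counts

    def test_other_chrom_gives_empty(self, cfg):
        region = vv.GenomicRegion("chr2", 0, 640)
        frags = Fragments(np.array(["chr1"]), np.array([100]), np.array([300]))
        assert vv.make_vplot(frags, region, cfg).n_reads == 0

    def test_region_width_mismatch_raises(self, cfg):
        region = vv.GenomicRegion("chr1", 0, 500)
        with pytest.raises(ValueError, match="window"):
            vv.make_vplot(Fragments.empty(), region, cfg)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 639), st.integers(1, 640)),
                    min_size=1, max_size=50))
    def test_counts_partition_the_fragments(self, items):
        """Every in-window, in-range fragment lands in exactly one bin."""
        cfg = vv.VPlotConfig()
        region = vv.GenomicRegion("c", 0, 640)
        mids, lengths = zip(*items)
        start = np.array(mids) - np.array(lengths) // 2
        frags = Fragments(np.array(["c"] * len(items)), start,
                          start + np.array(lengths))
        vp = vv.make_vplot(frags, region, cfg)
        in_win = sum(1 for f in frags if 0 <= f.midpoint < 640 and f.length <= 640)
        assert vp.counts.sum() == in_win

    def test_shift_equivariance_by_one_genomic_bin(self, cfg, small_fragments,
                                                   small_truth):
        region = vv.GenomicRegion(small_truth.chrom, 20_000, 20_640)
        a = vv.make_vplot(small_fragments, region, cfg).counts
        shifted = vv.shift_fragments(small_fragments, cfg.genomic_bin_bp)
        b = vv.make_vplot(shifted, region, cfg).counts
        assert np.array_equal(a[:-1], b[1:])


class TestNormalize:
    def test_column_normalization_and_zero_columns(self):
        counts = np.zeros((4, 3))
        counts[0] = [2, 2, 0]
        d = vv.normalize_vplot(counts)
        assert np.allclose(d[0], [0.5, 0.5, 0])
        assert np.all(d[1:] == 0)
        # total mass equals the number of non-empty columns
        assert d.sum() == 1.0

    def test_idempotent(self, rng):
        counts = rng.random((128, 64))
        once = vv.normalize_vplot(counts)
        assert np.allclose(vv.normalize_vplot(once), once)

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            vv.normalize_vplot(np.array([[-1.0, 2.0]]))


class TestAggregate:
    def test_identity_and_mean(self, rng):
        m1, m2 = rng.random((8, 4)), rng.random((8, 4))
        assert np.allclose(vv.aggregate_vplots([m1]), m1)
        assert np.allclose(vv.aggregate_vplots([m1, m2]), (m1 + m2) / 2)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            vv.aggregate_vplots([])


class TestFragmentSizeProfile:
    def test_single_length_unit_mass(self):
        frags = Fragments(np.array(["c"] * 5), np.zeros(5, int),
                          np.full(5, 200))
        prof = vv.fragment_size_profile(frags)
        assert prof[19] == 1.0 and prof.sum() == 1.0

    def test_uniform_lengths_near_uniform_profile(self):
        lengths = np.arange(1, 641)
        frags = Fragments(np.array(["c"] * 640), np.zeros(640, int), lengths)
        prof = vv.fragment_size_profile(frags)
        assert np.allclose(prof, 1 / 64)

    def test_mixture_is_read_weighted(self, small_truth):
        f1 = vv.simulate_fragments(small_truth, vv.BatchProfile(), 5_000, seed=1)
        f2 = vv.simulate_fragments(small_truth, vv.BatchProfile(
            weights=(0.1, 0.6, 0.2, 0.1)), 15_000, seed=2)
        both = Fragments(np.concatenate([f1.chrom, f2.chrom]),
                         np.concatenate([f1.start, f2.start]),
                         np.concatenate([f1.end, f2.end]))
        p1, p2 = vv.fragment_size_profile(f1), vv.fragment_size_profile(f2)
        w1 = len(f1) / (len(f1) + len(f2))
        assert np.allclose(vv.fragment_size_profile(both),
                           w1 * p1 + (1 - w1) * p2, atol=1e-12)

    def test_zero_mass_raises(self):
        with pytest.raises(ValueError):
            vv.fragment_size_profile(Fragments.empty())


def test_vplot_hdf5_roundtrip(tmp_path, small_fragments, small_truth):
    cfg = vv.VPlotConfig()
    regions = [vv.GenomicRegion(small_truth.chrom, s, s + 640)
               for s in (10_000, 20_000, 30_000)]
    counts, _ = vv.build_vplot_matrix(small_fragments, regions, cfg)
    path = tmp_path / "vp.h5"
    vv.save_vplots(path, counts[:, None], regions, [0], cfg)
    c2, r2, sids, cfg2 = vv.load_vplots(path)
    assert np.array_equal(c2[:, 0], counts)
    assert [r.start for r in r2] == [r.start for r in regions]
    assert cfg2 == cfg


def test_build_vplot_matrix_matches_single_region_path(small_fragments,
                                                       small_truth):
    cfg = vv.VPlotConfig()
    regions = [vv.GenomicRegion(small_truth.chrom, s, s + 640)
               for s in range(5_000, 50_000, 5_000)]
    mat, n_reads = vv.build_vplot_matrix(small_fragments, regions, cfg)
    for i, region in enumerate(regions):
        single = vv.make_vplot(small_fragments, region, cfg)
        assert np.array_equal(mat[i], single.counts)
        assert n_reads[i] == single.n_reads
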