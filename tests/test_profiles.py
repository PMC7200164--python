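"""Profile normalization, smoothing, contact-frequency ratios, track I/O."""

import numpy as np
import pytest

from fourcat import (
    DataValidationError,
    FragmentCounts,
    GenomicInterval,
    NumericError,
    Viewpoint,
    combine_replicates,
    contact_frequency,
    normalize_rpm,
    read_bedgraph,
    read_counts_table,
    smooth_profile,
    uniform_fragment_map,
    write_bedgraph,
    write_counts_table,
)


def make_counts(small_map, counts, flank=2_000, vp_pos=50_000, sample="s"):
    vp = Viewpoint.at(small_map, vp_pos, exclusion_flank=flank)
    return FragmentCounts(small_map, vp, sample, np.asarray(counts))


class TestCombineReplicates:
    def test_single_replicate_identity(self, small_counts):
        combined = combine_replicates([small_counts])
        assert np.array_equal(combined.counts, small_counts.counts)

    def test_elementwise_sum(self, small_map):
        a = make_counts(small_map, [1, 2, 3] + [0] * 97, sample="a")
        b = make_counts(small_map, [0, 1, 0] + [0] * 97, sample="b")
        combined = combine_replicates([a, b])
        assert list(combined.counts[:3]) == [1, 3, 3]
        assert combined.sample == "a+b"

    def test_totals_preserved(self, small_map, rng):
        for _ in range(10):
            reps = [
                make_counts(small_map, rng.integers(0, 50, 100), sample=f"r{i}")
                for i in range(3)
            ]
            combined = combine_replicates(reps)
            assert combined.total == sum(r.total for r in reps)

    def test_mismatched_maps_rejected(self, small_map):
        other = uniform_fragment_map(GenomicInterval("chrT", 0, 100_000), 50)
        a = make_counts(small_map, np.ones(100, int))
        vp = Viewpoint.at(other, 50_000)
        b = FragmentCounts(other, vp, "b", np.ones(50, int))
        with pytest.raises(DataValidationError, match="fragment map"):
            combine_replicates([a, b])


class TestRPM:
    def test_forced_by_formula(self, small_map):
        c = make_counts(small_map, [1, 1, 2] + [0] * 97)
        rpm = normalize_rpm(c)
        assert rpm[:3] == pytest.approx([250_000, 250_000, 500_000])

    def test_uniform_counts(self, small_map):
        rpm = normalize_rpm(make_counts(small_map, np.full(100, 7)))
        assert rpm == pytest.approx(np.full(100, 1e6 / 100))

    def test_sum_is_one_million(self, small_map, rng):
        for _ in range(50):
            c = make_counts(small_map, rng.integers(0, 1000, 100))
            assert normalize_rpm(c).sum() == pytest.approx(1e6, rel=1e-6)

    def test_empty_profile_rejected(self, small_map):
        with pytest.raises(NumericError, match="empty profile"):
            normalize_rpm(make_counts(small_map, np.zeros(100, int)))


class TestSmoothing:
    def test_constant_vector_unchanged(self):
        assert smooth_profile(np.full(20, 3.5), 7) == pytest.approx(np.full(20, 3.5))

    def test_window_one_is_identity(self, rng):
        x = rng.random(30)
        assert smooth_profile(x, 1) == pytest.approx(x)

    def test_impulse_and_brute_force(self, rng):
        x = np.array([0, 0, 7, 0, 0, 0, 0, 0, 0], dtype=float)
        sm = smooth_profile(x, 7)
        assert sm[3] == pytest.approx(1.0)
        # every index against an independent truncated-window mean
        for x in (x, rng.random(25)):
            sm = smooth_profile(x, 7)
            for i in range(len(x)):
                lo, hi = max(0, i - 3), min(len(x), i + 4)
                assert sm[i] == pytest.approx(np.mean(x[lo:hi]))

    def test_even_window_rejected(self):
        with pytest.raises(DataValidationError):
            smooth_profile(np.ones(10), 4)

    def test_interior_mass_conserved(self, rng):
        x = np.zeros(50)
        x[10:40] = rng.random(30)
        assert smooth_profile(x, 7).sum() == pytest.approx(x.sum(), rel=1e-9)


class TestContactFrequency:
    def test_whole_locus_ratio_is_one(self, small_counts):
        cf = contact_frequency(small_counts, small_counts.fragment_map.locus)
        assert cf.ratio == 1.0

    def test_empty_interval_ratio_is_zero(self, small_map):
        counts = np.zeros(100, int)
        counts[80:] = 5
        c = make_counts(small_map, counts)
        cf = contact_frequency(c, GenomicInterval("chrT", 0, 10_000))
        assert cf.ratio == 0.0

    def test_additivity_over_partition(self, small_counts):
        edges = [0, 13_000, 40_000, 61_000, 100_000]
        parts = [
            contact_frequency(small_counts, GenomicInterval("chrT", lo, hi)).ratio
            for lo, hi in zip(edges[:-1], edges[1:])
        ]
        assert sum(parts) == pytest.approx(1.0, abs=1e-12)

    def test_exclusion_monotonicity(self, small_map, rng):
        counts = rng.integers(0, 100, 100)
        denominators = []
        for flank in (0, 2_000, 5_000, 20_000):
            c = make_counts(small_map, counts, flank=flank)
            cf = contact_frequency(c, GenomicInterval("chrT", 0, 30_000))
            denominators.append(cf.denominator_reads)
        assert denominators == sorted(denominators, reverse=True)

    def test_viewpoint_zone_excluded_from_both_sides(self, small_map):
        # all reads inside the exclusion zone -> no informative reads
        counts = np.zeros(100, int)
        counts[48:53] = 10  # 48-53 kb, inside vp fragment +-2 kb zone
        c = make_counts(small_map, counts, flank=2_000)
        with pytest.raises(NumericError, match="no informative reads"):
            contact_frequency(c, GenomicInterval("chrT", 0, 30_000))

    def test_interval_outside_locus_rejected(self, small_counts):
        with pytest.raises(DataValidationError):
            contact_frequency(small_counts, GenomicInterval("chrT", 0, 200_000))


class TestTrackIO:
    def test_bedgraph_round_trip(self, small_map, rng):
        values = rng.random(100)
        path_values = []
        import tempfile, os

        with tempfile.TemporaryDirectory() as d:
            path = os.path.join(d, "x.bedgraph")
            write_bedgraph(values, small_map, path)
            df = read_bedgraph(path)
            assert df["value"].to_numpy() == pytest.approx(values, abs=0)
            assert (df["start"].to_numpy() == small_map.starts).all()

    def test_format_line(self, tmp_path):
        fmap = uniform_fragment_map(GenomicInterval("chr", 100, 200), 1)
        path = tmp_path / "one.bedgraph"
        write_bedgraph(np.array([2.5]), fmap, path)
        data_lines = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert data_lines == ["chr\t100\t200\t2.5"]

    def test_nan_rejected(self, small_map, tmp_path):
        values = np.ones(100)
        values[3] = np.nan
        with pytest.raises(DataValidationError, match="finite"):
            write_bedgraph(values, small_map, tmp_path / "bad.bedgraph")

    def test_empty_file_rejected_on_read(self, tmp_path):
        path = tmp_path / "empty.bedgraph"
        path.write_text("#header only\n")
        with pytest.raises(DataValidationError, match="no data lines"):
            read_bedgraph(path)

    def test_counts_table_round_trip(self, small_counts, tmp_path):
        path = tmp_path / "counts.tsv"
        write_counts_table(small_counts, path)
        back = read_counts_table(
            path, small_counts.fragment_map, small_counts.viewpoint, "rand"
        )
        assert np.array_equal(back.counts, small_counts.counts)

    def test_counts_table_map_mismatch(self, small_counts, tmp_path):
        path = tmp_path / "counts.tsv"
        write_counts_table(small_counts, path)
        other = uniform_fragment_map(GenomicInterval("chrT", 0, 100_000), 40)
        vp = Viewpoint.at(other, 50_000)
        with pytest.raises(DataValidationError):
            read_counts_table(path, other, vp)


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(derandomize=True, max_examples=60)
@given(
    values=st.lists(st.floats(0, 1e6, allow_nan=False), min_size=1, max_size=40),
    w=st.sampled_from([1, 3, 5, 7, 9]),
)
def test_smoothing_equals_truncated_window_mean_property(values, w):
    x = np.asarray(values)
    sm = smooth_profile(x, w)
    half = w // 2
    tol = 1e-12 * max(1.0, float(np.max(x)))  # roundoff scales with magnitude
    for i in range(len(x)):
        lo, hi = max(0, i - half), min(len(x), i + half + 1)
        assert sm[i] == pytest.approx(np.mean(x[lo:hi]), rel=1e-12, abs=tol)
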