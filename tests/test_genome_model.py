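"""Coordinate system, ROI replication and insertion placement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from locosim.genome_model import (
    InsertionSpec,
    _choose_sites,
    build_layout,
    draw_insertion_count,
    make_roi_targets,
    place_insertions,
    shift_for_insertion,
)


class TestLayout:
    def test_concatenation_offsets(self):
        lay = build_layout([("chr1", 1000), ("chr2", 500)], 1)
        assert lay.reference_length == 1500
        assert lay.global_offsets == {"chr1": 0, "chr2": 1000}

    def test_barcode_spans_disjoint_width_g(self):
        lay = build_layout([("c", 100)], 3)
        assert lay.barcode_spans == ((0, 100), (100, 200), (200, 300))

    def test_global_local_round_trip_example(self, two_chrom_layout):
        assert two_chrom_layout.global_to_local(1200) == (0, "chr2", 200)
        assert two_chrom_layout.local_to_global(0, "chr2", 200) == 1200

    @settings(deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=4499))
    def test_round_trip_identity_property(self, pos):
        lay = build_layout([("chr1", 1000), ("chr2", 500)], 3)
        b, chrom, local = lay.global_to_local(pos)
        assert lay.local_to_global(b, chrom, local) == pos

    @pytest.mark.parametrize(
        "chroms,n,err",
        [
            ([("a", 10), ("a", 20)], 1, "duplicate"),
            ([("a", 0)], 1, "length"),
            ([("a", 10)], 0, "n_barcodes"),
            ([], 1, "chromosome"),
        ],
    )
    def test_invalid_inputs(self, chroms, n, err):
        with pytest.raises(ValueError, match=err):
            build_layout(chroms, n)


class TestRoiTargets:
    def test_replicated_across_barcodes(self):
        lay = build_layout([("chr1", 1000)], 2)
        ts = make_roi_targets(lay, [("chr1", 10, 20, "g")])
        assert len(ts) == 2
        locals_ = [(e.start - lay.barcode_spans[e.barcode][0], e.length) for e in ts.entries]
        assert locals_ == [(10, 10), (10, 10)]

    def test_empty_roi_list_is_valid(self, two_chrom_layout):
        assert len(make_roi_targets(two_chrom_layout, [])) == 0

    def test_roi_beyond_chromosome_end(self):
        lay = build_layout([("chr1", 1000)], 1)
        with pytest.raises(ValueError, match="bounds"):
            make_roi_targets(lay, [("chr1", 990, 1010, "g")])
        with pytest.raises(ValueError, match="chromosome"):
            make_roi_targets(lay, [("chrX", 0, 10, "g")])
        with pytest.raises(ValueError, match="start"):
            make_roi_targets(lay, [("chr1", 20, 10, "g")])


class TestInsertionCount:
    def test_fixed_mode_exact(self, rng):
        spec = InsertionSpec(n_insertions=3, insert_length=10)
        assert draw_insertion_count(spec, rng) == 3
        assert draw_insertion_count(InsertionSpec(0, 10), rng) == 0

    def test_poisson_zero_degenerate(self, rng):
        spec = InsertionSpec(n_insertions=0, insert_length=10, poisson=True)
        assert all(draw_insertion_count(spec, rng) == 0 for _ in range(100))

    def test_poisson_mean_recovery(self, rng):
        spec = InsertionSpec(n_insertions=5, insert_length=10, poisson=True)
        n = 100_000
        draws = np.array([draw_insertion_count(spec, rng) for _ in range(n)])
        tol = 3 * np.sqrt(5 / n)
        assert abs(draws.mean() - 5) < tol


class TestPlacement:
    def test_shift_rule_forced_example(self):
        # insertion A at [500,550); new insertion at 200 shifts A downstream
        placed = [[500, 550]]
        shift_for_insertion(placed, 200, 50)
        placed.append([200, 250])
        assert sorted(placed) == [[200, 250], [550, 600]]

    def test_zero_insertions_leaves_genome_unchanged(self, rng):
        lay = build_layout([("c", 1000)], 2)
        ts, lengths = place_insertions(lay, InsertionSpec(0, 50), rng)
        assert len(ts) == 0
        assert lengths == (1000, 1000)

    def test_genome_length_inflation_exact(self, rng):
        lay = build_layout([("c", 10_000)], 3)
        spec = InsertionSpec(n_insertions=4, insert_length=250)
        ts, lengths = place_insertions(lay, spec, rng)
        assert lengths == (11_000, 11_000, 11_000)
        assert len(ts) == 12

    def test_insertions_pairwise_disjoint_many_runs(self):
        lay = build_layout([("c", 5000)], 1)
        spec = InsertionSpec(n_insertions=5, insert_length=100)
        for seed in range(1000):
            ts, _ = place_insertions(lay, spec, np.random.default_rng(seed))
            ivs = sorted((e.start, e.end) for e in ts.entries)
            assert all(a[1] <= b[0] for a, b in zip(ivs, ivs[1:]))

    def test_targets_within_barcode_spans(self, rng):
        lay = build_layout([("c", 2000)], 3)
        spec = InsertionSpec(n_insertions=3, insert_length=100, poisson=True)
        ts, lengths = place_insertions(lay, spec, rng)
        spans = lay.with_barcode_lengths(lengths).barcode_spans
        for e in ts.entries:
            s, t = spans[e.barcode]
            assert s <= e.start < e.end <= t

    def test_uniform_placement_midpoints_ks(self):
        lay = build_layout([("c", 100_000)], 1)
        spec = InsertionSpec(n_insertions=1, insert_length=10)
        mids = np.array(
            [
                np.mean(place_insertions(lay, spec, np.random.default_rng(s))[0].entries[0].start)
                for s in range(10_000)
            ]
        )
        stat = sps.kstest(mids / 100_000, "uniform")
        assert stat.pvalue > 0.001

    def test_semi_random_length_proportional_frequencies(self, rng):
        # site choice follows P = length / total length
        sites = [(0, 300), (500, 600)]
        idx = _choose_sites(sites, None, 100_000, rng)
        freq = np.mean(idx == 0)
        assert abs(freq - 0.75) < 3 * np.sqrt(0.75 * 0.25 / 100_000)
        chi = sps.chisquare(
            [np.sum(idx == 0), np.sum(idx == 1)], [75_000, 25_000]
        )
        assert chi.pvalue > 0.001

    def test_semi_random_custom_weights(self, rng):
        sites = [(0, 300), (500, 600)]
        idx = _choose_sites(sites, [0.1, 0.9], 100_000, rng)
        assert abs(np.mean(idx == 1) - 0.9) < 3 * np.sqrt(0.09 / 100_000)

    def test_semi_random_end_to_end_in_sites(self, rng):
        lay = build_layout([("c", 10_000)], 1)
        spec = InsertionSpec(
            n_insertions=3,
            insert_length=10,
            placement="semi_random",
            candidate_sites=(("c", 1000, 1300), ("c", 5000, 5100)),
        )
        ts, _ = place_insertions(lay, spec, rng)
        assert len(ts) == 3

    def test_semi_random_requires_sites(self):
        with pytest.raises(ValueError, match="candidate_sites"):
            InsertionSpec(1, 10, placement="semi_random")

    def test_site_weights_validation(self):
        with pytest.raises(ValueError, match="site_weights"):
            InsertionSpec(
                1, 10, placement="semi_random",
                candidate_sites=(("c", 0, 10),), site_weights=(0.5, 0.5),
            )
        with pytest.raises(ValueError, match="positive"):
            InsertionSpec(
                1, 10, placement="semi_random",
                candidate_sites=(("c", 0, 10),), site_weights=(0.0,),
            )
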