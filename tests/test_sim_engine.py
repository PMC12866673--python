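"""Monte Carlo engine: placement, masking, stopping rule, determinism."""

import numpy as np
import pytest
from scipy import stats as sps

from locosim.genome_model import InsertionSpec, build_layout, make_roi_targets
from locosim.read_lengths import ReadLengthModel
from locosim.sim_engine import (
    MaskSet,
    PlacedRead,
    SimulationConfig,
    assign_barcode,
    mask_decision,
    place_read,
    run_iteration,
    run_simulation,
)

CONST300 = ReadLengthModel(kind="empirical", lengths=np.array([300]))


def small_config(**kw):
    defaults = dict(
        chrom_sizes=(("c", 1000),),
        coverages=(2.0,),
        read_model=CONST300,
        rois=(("c", 100, 200, "t"),),
        iterations=1,
        seed=1,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestAssignBarcode:
    def test_single_weight_always_zero(self, rng):
        assert assign_barcode([1.0], rng) == 0

    def test_zero_weight_never_chosen(self, rng):
        assert all(assign_barcode([0.0, 1.0], rng) == 1 for _ in range(100))

    def test_frequencies_match_weights(self, rng):
        draws = np.array([assign_barcode([0.9, 0.1], rng) for _ in range(100_000)])
        freq0 = np.mean(draws == 0)
        assert abs(freq0 - 0.9) < 3 * np.sqrt(0.09 / 100_000)

    def test_all_zero_weights_error(self, rng):
        with pytest.raises(ValueError):
            assign_barcode([0.0, 0.0], rng)


class TestPlaceRead:
    def test_full_length_read_pinned_at_zero(self, rng):
        lay = build_layout([("c", 1000)], 1)
        for _ in range(20):
            r = place_read(lay, 0, 1000, rng)
            assert (r.start, r.end) == (0, 1000)

    def test_read_longer_than_genome_errors(self, rng):
        lay = build_layout([("c", 1000)], 1)
        with pytest.raises(ValueError, match="exceeds"):
            place_read(lay, 0, 1001, rng)

    def test_read_within_own_barcode_span(self, rng):
        lay = build_layout([("c", 500)], 4)
        for _ in range(200):
            b = int(rng.integers(0, 4))
            r = place_read(lay, b, 100, rng)
            s, e = lay.barcode_spans[b]
            assert s <= r.start < r.end <= e

    def test_start_uniformity_ks(self, rng):
        lay = build_layout([("c", 1_000_000)], 1)
        starts = np.array([place_read(lay, 0, 100, rng).start for _ in range(10_000)])
        res = sps.kstest(starts / (1_000_000 - 100), "uniform")
        assert res.pvalue > 0.001


class TestMaskDecision:
    def _bound(self, weight, layout):
        return MaskSet((("c", 0, 1000, weight),)).bind(layout)

    def test_weight_one_always_rejects(self, rng):
        lay = build_layout([("c", 1000)], 1)
        mask = self._bound(1.0, lay)
        assert not any(
            mask_decision(PlacedRead(0, 10, 50), mask, rng) for _ in range(100)
        )

    def test_weight_zero_always_accepts(self, rng):
        lay = build_layout([("c", 1000)], 1)
        mask = self._bound(0.0, lay)
        assert all(
            mask_decision(PlacedRead(0, 10, 50), mask, rng) for _ in range(100)
        )

    def test_no_overlap_always_accepts(self, rng):
        lay = build_layout([("c", 1000)], 1)
        mask = MaskSet((("c", 0, 100, 1.0),)).bind(lay)
        assert mask_decision(PlacedRead(0, 100, 200), mask, rng)  # half-open touch

    def test_rejection_rate_matches_weight(self, rng):
        lay = build_layout([("c", 1000)], 1)
        mask = self._bound(0.3, lay)
        n = 100_000
        rejected = sum(
            not mask_decision(PlacedRead(0, 10, 50), mask, rng) for _ in range(n)
        )
        assert abs(rejected / n - 0.3) < 3 * np.sqrt(0.3 * 0.7 / n)

    def test_max_weight_combination(self, rng):
        lay = build_layout([("c", 1000)], 1)
        mask = MaskSet((("c", 0, 50, 0.0), ("c", 40, 80, 1.0))).bind(lay)
        # read overlaps both; max weight 1.0 wins
        assert not mask_decision(PlacedRead(0, 30, 60), mask, rng)

    def test_weight_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            MaskSet((("c", 0, 10, 1.5),))


class TestRunIteration:
    def test_stopping_rule_exact_read_count(self, rng):
        # C*G = 2000; 300-base reads -> exactly 7 (6*300 < 2000 <= 7*300)
        cfg = small_config()
        lay = build_layout(cfg.chrom_sizes, 1)
        tg = make_roi_targets(lay, cfg.rois)
        res = run_iteration(cfg, lay, tg, CONST300, None, rng)
        assert res.n_sampled == 7
        assert res.yield_total == 2100

    def test_stopping_rule_tightness_random_models(self):
        lay = build_layout([("c", 10_000)], 1)
        tg = make_roi_targets(lay, [("c", 100, 200, "t")])
        for seed in range(30):
            model = ReadLengthModel(kind="parametric", mean_length=500, sigma=1.0)
            cfg = small_config(chrom_sizes=(("c", 10_000),), coverages=(3.0,))
            res = run_iteration(
                cfg, lay, tg, model, None, np.random.default_rng(seed), coverage=3.0
            )
            need = 3.0 * 10_000
            assert res.yield_total >= need
            assert res.yield_total - res.last_counted_length < need

    def test_full_mask_consuming_yield_burned(self, rng):
        cfg = small_config(masks=MaskSet((("c", 0, 1000, 1.0),)), consuming=True)
        lay = build_layout(cfg.chrom_sizes, 1)
        tg = make_roi_targets(lay, cfg.rois)
        res = run_iteration(cfg, lay, tg, CONST300, cfg.masks.bind(lay), rng)
        assert res.n_sampled == 7
        assert res.n_accepted == 0
        assert res.records[0].otb == 0
        assert res.yield_total >= 2000  # yield still reaches the target

    def test_full_mask_non_consuming_aborts(self, rng):
        cfg = small_config(masks=MaskSet((("c", 0, 1000, 1.0),)), consuming=False)
        lay = build_layout(cfg.chrom_sizes, 1)
        tg = make_roi_targets(lay, cfg.rois)
        with pytest.raises(RuntimeError, match="consecutive"):
            run_iteration(cfg, lay, tg, CONST300, cfg.masks.bind(lay), rng)

    def test_masked_target_zero_otb_unmasked_target_unaffected(self, rng):
        # mask covers only the first target; second target still sees reads
        cfg = small_config(
            chrom_sizes=(("c", 10_000),),
            rois=(("c", 1000, 2000, "hidden"), ("c", 5000, 6000, "open")),
            masks=MaskSet((("c", 500, 2500, 1.0),)),
            consuming=True,
            coverages=(5.0,),
        )
        lay = build_layout(cfg.chrom_sizes, 1)
        tg = make_roi_targets(lay, cfg.rois)
        model = ReadLengthModel(kind="empirical", lengths=np.array([400]))
        res = run_iteration(cfg, lay, tg, model, cfg.masks.bind(lay), rng, coverage=5.0)
        by_label = {r.label: r for r in res.records}
        assert by_label["hidden"].otb == 0
        assert by_label["open"].otb > 0

    def test_barcode_conservation(self, rng):
        cfg = small_config(
            chrom_sizes=(("c", 5000),),
            n_barcodes=3,
            rois=(("c", 100, 200, "t"),),
            coverages=(3.0,),
        )
        lay = build_layout(cfg.chrom_sizes, 3)
        tg = make_roi_targets(lay, cfg.rois)
        model = ReadLengthModel(kind="empirical", lengths=np.array([250]))
        res = run_iteration(
            cfg, lay, tg, model, None, rng, coverage=3.0, keep_reads=True
        )
        spans = lay.barcode_spans
        for s, e, b in zip(
            res.accepted_starts, res.accepted_ends, res.accepted_barcodes
        ):
            lo, hi = spans[b]
            assert lo <= s < e <= hi


class TestRunSimulation:
    def test_iteration_record_counts(self):
        cfg = small_config(iterations=5, coverages=(1.0, 2.0))
        out = run_simulation(cfg)
        assert len(out.iterations) == 5 * 2 * 1  # 2 coverages x 1 target
        assert set(out.iterations["iteration"]) == set(range(5))
        assert len(out.summary) == 2

    def test_interior_target_expectation(self):
        # E[depth at an interior base] = C, so E[OTB] = C * target length
        cfg = SimulationConfig(
            chrom_sizes=(("c", 1_000_000),),
            coverages=(10.0,),
            read_model=ReadLengthModel(kind="parametric", mean_length=5000, sigma=0.25),
            rois=(("c", 495_000, 505_000, "t"),),
            iterations=200,
            seed=11,
        )
        out = run_simulation(cfg)
        row = out.summary.iloc[0]
        assert abs(row["mean_otb"] - 100_000) < 3 * row["se"]

    def test_mean_otb_monotone_in_coverage(self):
        cfg = SimulationConfig(
            chrom_sizes=(("c", 200_000),),
            coverages=(5.0, 10.0, 20.0),
            read_model=ReadLengthModel(kind="parametric", mean_length=2000, sigma=0.5),
            rois=(("c", 95_000, 105_000, "t"),),
            iterations=200,
            seed=5,
        )
        out = run_simulation(cfg)
        s = out.summary.sort_values("coverage")
        means, ses = s["mean_otb"].to_numpy(), s["se"].to_numpy()
        assert means[0] < means[1] + 3 * (ses[0] + ses[1])
        assert means[1] < means[2] + 3 * (ses[1] + ses[2])
        # and linear scaling in C: mean/C constant within sampling error
        ratios = means / np.array([5, 10, 20])
        assert np.allclose(ratios, ratios.mean(), rtol=0.05)

    def test_same_seed_any_worker_count_identical(self):
        cfg = small_config(iterations=6, seed=42, workers=1)
        out1 = run_simulation(cfg)
        cfg2 = small_config(iterations=6, seed=42, workers=2)
        out2 = run_simulation(cfg2)
        assert out1.iterations.equals(out2.iterations)
        assert out1.summary.equals(out2.summary)

    def test_insertion_mode_runs_and_summarises(self):
        cfg = SimulationConfig(
            chrom_sizes=(("c", 50_000),),
            coverages=(3.0,),
            read_model=ReadLengthModel(kind="parametric", mean_length=1000, sigma=0.5),
            mode="I",
            insertions=InsertionSpec(n_insertions=2, insert_length=500),
            iterations=20,
            seed=9,
        )
        out = run_simulation(cfg)
        assert set(out.iterations["target_label"]) == {"insertion_0", "insertion_1"}
        assert (out.summary["m"] == 20).all()
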