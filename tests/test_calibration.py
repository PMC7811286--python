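import numpy as np
import pytest

from nichespread.calibration import (
    BinaryMap,
    EvalRecord,
    CandidateConfig,
    aicc,
    binarize,
    consensus_median,
    consensus_sum,
    enumerate_candidates,
    independent_test,
    kfold_splits,
    lpt_threshold,
    omission_rate,
    partial_roc,
    select_models,
)

from conftest import make_template


class TestEnumerateCandidates:
    def test_single_minimal_config(self):
        assert len(enumerate_candidates(["a", "b"], [1.0], ["lq"])) == 1

    @pytest.mark.parametrize("p", [2, 3, 4, 5])
    def test_count_matches_closed_form(self, p):
        names = [f"v{i}" for i in range(p)]
        rms = [0.5, 1.0, 2.0]
        class_sets = ["lq", "lp"]
        configs = enumerate_candidates(names, rms, class_sets)
        assert len(configs) == (2**p - p - 1) * len(rms) * len(class_sets)
        assert len(set(configs)) == len(configs)  # all distinct

    def test_order_is_deterministic(self):
        a = enumerate_candidates(["x", "y", "z"], [1.0, 2.0], ["lq"])
        b = enumerate_candidates(["x", "y", "z"], [1.0, 2.0], ["lq"])
        assert a == b

    def test_too_few_variables_rejected(self):
        with pytest.raises(ValueError):
            enumerate_candidates(["a"], [1.0], ["lq"])


class TestKfoldSplits:
    def test_even_split_sizes(self):
        splits = kfold_splits(10, k=5, seed=0)
        assert len(splits) == 5
        for train, test in splits:
            assert len(train) == 5 and len(test) == 5
            assert sorted(np.concatenate([train, test])) == list(range(10))

    def test_seed_determinism(self):
        a = kfold_splits(20, k=5, seed=3)
        b = kfold_splits(20, k=5, seed=3)
        for (ta, sa), (tb, sb) in zip(a, b):
            assert np.array_equal(ta, tb) and np.array_equal(sa, sb)

    def test_train_frequency_balanced_over_many_runs(self):
        counts = np.zeros(20)
        n_runs = 1000
        for s in range(n_runs):
            for train, _ in kfold_splits(20, k=1, seed=s):
                counts[train] += 1
        freq = counts / n_runs
        assert np.all(freq >= 0.4) and np.all(freq <= 0.6)

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            kfold_splits(3)


class TestPartialRoc:
    def test_null_rejection_rate_is_nominal(self):
        """Test points drawn from the landscape's own suitability
        distribution should be declared significant at roughly the
        nominal rate (small-scale version of the full calibration run)."""
        rng = np.random.default_rng(10)
        rej = 0
        n_sim = 50
        for i in range(n_sim):
            land = rng.uniform(0, 1, 1000)
            test = rng.choice(land, 20)
            _, p = partial_roc(test, land, n_boot=200, seed=i)
            rej += p < 0.05
        assert rej / n_sim <= 0.12

    def test_separable_fixture_is_significant(self):
        rng = np.random.default_rng(0)
        land = np.sort(rng.uniform(0, 1, 2000))
        test = land[-20:]  # strictly the largest landscape values
        ratio, p = partial_roc(test, land, n_boot=500, seed=1)
        assert ratio > 1.0
        assert p < 0.05

    def test_e_zero_equals_full_curve_trapezoid_oracle(self):
        from nichespread.calibration import _partial_auc_ratio, _roc_curve_points

        rng = np.random.default_rng(5)
        land = rng.uniform(0, 1, 10)
        test = rng.uniform(0, 1, 6)
        thresholds, counts = np.unique(land, return_counts=True)
        area = np.cumsum(counts[::-1])[::-1] / land.size
        _, sens = _roc_curve_points(test, thresholds, area)
        ratio = _partial_auc_ratio(area, sens, 0.0)
        # independent full-curve trapezoid on explicitly built points
        xs, ys = [1.0], [1.0]
        for t, x in zip(thresholds, area):
            xs.append(x)
            ys.append(np.mean(test >= t))
        xs.append(0.0)
        ys.append(0.0)
        auc = np.trapezoid(ys[::-1], xs[::-1])
        rand = np.trapezoid(xs[::-1], xs[::-1])
        assert abs(ratio - auc / rand) < 1e-10

    def test_degenerate_constant_inputs_flagged(self):
        assert partial_roc(np.ones(5), np.ones(100)) == (1.0, 1.0)

    def test_mean_ratio_null_expectation_near_one(self):
        rng = np.random.default_rng(2)
        ratios = []
        for i in range(40):
            land = rng.uniform(0, 1, 500)
            ratio, _ = partial_roc(rng.choice(land, 20), land, n_boot=100, seed=i)
            ratios.append(ratio)
        assert 0.9 <= np.mean(ratios) <= 1.1


class TestOmissionRate:
    @pytest.mark.parametrize(
        "values,threshold,expected",
        [
            ([0.1, 0.4, 0.6, 0.9], 0.05, 0.0),
            ([0.1, 0.4, 0.6, 0.9], 0.95, 1.0),
            ([0.1, 0.4, 0.6, 0.9], 0.5, 0.5),
            ([0.5, 0.5], 0.5, 0.0),  # strict inequality
        ],
    )
    def test_fraction_strictly_below(self, values, threshold, expected):
        assert omission_rate(values, threshold) == expected


class TestAicc:
    def test_uniform_closed_form(self):
        occ_raw = np.full(10, 1.0 / 100)
        land_raw = np.full(100, 1.0 / 100)
        val = aicc(occ_raw, land_raw, n_params=2)
        lnL = 10 * np.log(1 / 100)
        expected = 4 - 2 * lnL + 12 / 7
        assert abs(val - expected) < 1e-3
        assert abs(expected - 97.8177) < 1e-3

    def test_correction_blowup_boundary(self):
        occ_raw = np.full(5, 0.1)
        land_raw = np.full(10, 0.1)
        assert aicc(occ_raw, land_raw, n_params=4) == np.inf

    def test_zero_density_occurrence_is_infinite(self):
        occ_raw = np.array([0.1, 0.0])
        assert aicc(occ_raw, np.full(10, 0.1), n_params=1) == np.inf

    def test_random_fixture_matches_direct_arithmetic(self):
        rng = np.random.default_rng(9)
        land = rng.uniform(0.01, 1, 50)
        occ = rng.choice(land, 5)
        k = 3
        val = aicc(occ, land, n_params=k)
        lnL = sum(np.log(v / land.sum()) for v in occ)
        expected = 2 * k - 2 * lnL + 2 * k * (k + 1) / (5 - k - 1)
        assert abs(val - expected) < 1e-10


def rec(p, om, a, rm=1.0):
    return EvalRecord(
        config=CandidateConfig(rm, "lq", ("a", "b")),
        proc_p=p,
        mean_auc_ratio=1.5,
        omission_rate=om,
        aicc=a,
        n_params=3,
    )


class TestSelectModels:
    def test_single_qualifying_record_has_delta_zero(self):
        out = select_models([rec(0.001, 0.0, 100.0)])
        assert len(out) == 1 and out[0].delta_aicc == 0.0 and out[0].selected

    def test_all_insignificant_gives_empty_selection(self):
        assert select_models([rec(0.9, 0.0, 100.0), rec(0.5, 0.0, 90.0)]) == []

    def test_six_record_table_matches_hand_filtering(self):
        records = [
            rec(0.001, 0.01, 100.0, rm=0.1),  # selected, delta 0
            rec(0.001, 0.02, 101.5, rm=0.25),  # selected, delta 1.5
            rec(0.001, 0.03, 103.0, rm=0.5),  # delta 3 -> dropped
            rec(0.20, 0.01, 99.0, rm=0.75),  # insignificant (best AICc ignored)
            rec(0.001, 0.20, 98.0, rm=1.0),  # high omission (best AICc ignored)
            rec(0.001, 0.01, 150.0, rm=2.0),  # delta 50 -> dropped
        ]
        out = select_models(records)
        assert [r.config.rm for r in out] == [0.1, 0.25]
        assert out[0].delta_aicc == 0.0
        assert abs(out[1].delta_aicc - 1.5) < 1e-12

    def test_selection_invariant_to_input_order(self):
        records = [rec(0.001, 0.01, 100.0, rm=0.1), rec(0.001, 0.01, 101.0, rm=0.5)]
        a = select_models(list(records))
        b = select_models(list(reversed(records)))
        assert [r.config.rm for r in a] == [r.config.rm for r in b]


class TestBinarize:
    def test_e_zero_threshold_is_minimum_calibration_value(self, template):
        vals = np.linspace(0, 1, 100).reshape(10, 10)
        layer = template.copy_with(vals)
        bmap = binarize(layer, [0.3, 0.5, 0.7], E=0.0)
        assert bmap.threshold == 0.3

    def test_index_arithmetic_on_twenty_values(self):
        calib = [0.05 * i for i in range(20)]
        assert lpt_threshold(calib, E=0.05) == calib[1]  # second smallest

    def test_calibration_omission_bounded(self, template):
        rng = np.random.default_rng(0)
        for n in (5, 17, 50):
            for E in (0.0, 0.05, 0.10):
                calib = rng.uniform(0, 1, n)
                thr = lpt_threshold(calib, E)
                assert omission_rate(calib, thr) <= E + 1.0 / n

    def test_suitable_areas_nested_in_e(self, template):
        rng = np.random.default_rng(1)
        layer = template.copy_with(rng.uniform(0, 1, (10, 10)))
        calib = rng.uniform(0, 1, 30)
        b_small = binarize(layer, calib, E=0.02)
        b_big = binarize(layer, calib, E=0.10)
        assert np.all(b_big.values <= b_small.values)


class TestConsensus:
    def test_median_of_identical_layers_is_that_layer(self, template):
        rng = np.random.default_rng(2)
        layer = template.copy_with(rng.uniform(0, 1, (10, 10)))
        out = consensus_median([layer, layer, layer])
        assert np.allclose(out.values, layer.values)

    def test_median_of_three_distinct_values(self, template):
        layers = [template.copy_with(np.full((10, 10), v)) for v in (0.0, 0.5, 1.0)]
        assert consensus_median(layers).values[3, 3] == 0.5

    def test_sum_of_all_suitable_maps(self, template):
        ones = template.copy_with(np.ones((10, 10), dtype=np.uint8), nodata=255)
        maps = [BinaryMap(ones, 0.1, 0.05) for _ in range(4)]
        assert np.all(consensus_sum(maps).values == 4)

    def test_geometry_mismatch_rejected(self, template):
        other = make_template(n_rows=5, n_cols=5)
        with pytest.raises(ValueError):
            consensus_median([template, other])


class TestIndependentTest:
    def make_map(self, template):
        vals = np.zeros((10, 10), dtype=np.uint8)
        vals[0:5, :] = 1  # northern half suitable
        return BinaryMap(template.copy_with(vals, nodata=255), 0.1, 0.05)

    def test_all_records_in_suitable_cells_pass(self, template):
        bmap = self.make_map(template)
        lon, lat = template.cell_center(2, 3)
        ok, flags = independent_test(bmap, [lon], [lat])
        assert ok and flags == [True]

    def test_single_unsuitable_record_fails_with_flag(self, template):
        bmap = self.make_map(template)
        lon1, lat1 = template.cell_center(2, 3)
        lon2, lat2 = template.cell_center(8, 3)
        ok, flags = independent_test(bmap, [lon1, lon2], [lat1, lat2])
        assert not ok and flags == [True, False]

    def test_record_outside_extent_raises(self, template):
        bmap = self.make_map(template)
        with pytest.raises(ValueError):
            independent_test(bmap, [999.0], [0.0])

    def test_record_on_nodata_cell_raises(self, template):
        vals = np.ones((10, 10), dtype=np.uint8)
        vals[4, 4] = 255
        bmap = BinaryMap.__new__(BinaryMap)  # bypass binary check for nodata cell
        bmap.grid = template.copy_with(vals, nodata=255)
        bmap.threshold, bmap.E = 0.1, 0.05
        lon, lat = template.cell_center(4, 4)
        with pytest.raises(ValueError):
            independent_test(bmap, [lon], [lat])
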