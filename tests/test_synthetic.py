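import numpy as np
import pytest

from histoquant import quantify
from histoquant.colocalization import pearson_coloc
from histoquant.synthetic import (
    DEFAULT_NOISE,
    NO_NOISE,
    ClusterSpec,
    FieldParams,
    NoiseModel,
    PairParams,
    apply_noise,
    make_log2_table,
    make_midgut_field,
    make_mitotic_early,
    make_mitotic_late,
    make_pair,
    make_ratio_table,
    plan_field,
    render_field,
    sample_cluster_sizes,
)
from histoquant.tissue import block_average, cluster_cells, profile_trace


class TestNoiseModel:
    def test_rejects_negative_parameters(self):
        with pytest.raises(ValueError):
            NoiseModel(gain=-1)

    def test_zero_noise_is_identity(self, rng):
        sig = rng.uniform(0, 1000, size=(4, 8, 8))
        out = apply_noise(sig, NO_NOISE, rng)
        np.testing.assert_array_equal(out, sig)

    def test_expected_total_is_planted_plus_baseline(self, rng):
        # zero read noise, large sample: E[sum] = planted + baseline * n
        sig = np.full((20, 50, 50), 40.0)
        noise = NoiseModel(gain=1.0, read_sigma=0.0, baseline=10.0)
        out = apply_noise(sig, noise, rng)
        n = sig.size
        expect = sig.sum() + noise.baseline * n
        # Poisson sd of the sum = sqrt(sum(signal)) / sqrt(gain)
        tol = 5 * np.sqrt(sig.sum())
        assert abs(out.sum() - expect) < tol

    def test_clipping(self, rng):
        sig = np.full((2, 2, 2), 70000.0)
        out = apply_noise(sig, NoiseModel(gain=0, read_sigma=0, baseline=0), rng)
        assert out.max() <= 65535


class TestSeedDeterminism:
    @pytest.mark.parametrize("maker,args", [
        (make_mitotic_early, (0.4,)),
        (make_mitotic_late, (0.6,)),
        (make_pair, ()),
    ])
    def test_bit_identical_for_same_seed(self, maker, args):
        s1, _ = maker(*args, seed=7)
        s2, _ = maker(*args, seed=7)
        np.testing.assert_array_equal(s1.data, s2.data)

    def test_different_seed_differs(self):
        s1, _ = make_pair(seed=1)
        s2, _ = make_pair(seed=2)
        assert not np.array_equal(s1.data, s2.data)

    def test_field_plan_deterministic(self):
        params = FieldParams(clusters=[ClusterSpec((50.0, 50.0), 2)])
        t1 = plan_field(params, seed=3)
        t2 = plan_field(params, seed=3)
        assert t1.cells == t2.cells


class TestMitoticEarly:
    def test_overlap_mix_out_of_range(self):
        with pytest.raises(ValueError):
            make_mitotic_early(1.5)

    def test_nucleus_must_fit(self):
        with pytest.raises(ValueError, match="larger than frame"):
            make_mitotic_early(0.5, shape=(4, 20, 20), nucleus_radii_px=(2, 30, 30))

    def test_full_overlap_zero_noise_pearson_exactly_one(self):
        stack, truth = make_mitotic_early(1.0, noise=NO_NOISE, seed=0)
        r = pearson_coloc(stack, truth.rois["nucleus"], "old", "new").pearson_r
        assert r == 1.0

    def test_disjoint_zero_noise_pearson_negative(self):
        stack, truth = make_mitotic_early(0.0, noise=NO_NOISE, seed=0)
        r = pearson_coloc(stack, truth.rois["nucleus"], "old", "new").pearson_r
        assert r < 0

    def test_mean_pearson_monotone_in_overlap_mix(self):
        mixes = [0.0, 0.25, 0.5, 0.75, 1.0]
        means = []
        for mix in mixes:
            rs = []
            for seed in range(20):
                stack, truth = make_mitotic_early(mix, seed=seed)
                rs.append(pearson_coloc(stack, truth.rois["nucleus"], "old", "new").pearson_r)
            means.append(np.mean(rs))
        assert all(a < b for a, b in zip(means, means[1:]))


class TestMitoticLate:
    def test_partition_fraction_bounds(self):
        for bad in (0.0, 1.0, -0.2):
            with pytest.raises(ValueError):
                make_mitotic_late(bad)

    def test_separation_minimum_enforced(self):
        with pytest.raises(ValueError, match="separation"):
            make_mitotic_late(0.5, separation_px=5.0)

    def test_even_split_planted_ratio_one(self):
        _, truth = make_mitotic_late(0.5, noise=NO_NOISE)
        assert truth.params["planted_ratio"] == 1.0

    def test_paper_scale_partition(self):
        _, truth = make_mitotic_late(0.574)
        assert truth.params["planted_ratio"] == pytest.approx(1.35, abs=0.005)

    def test_planted_totals_conserved_exactly(self):
        _, truth = make_mitotic_late(0.574, total_old=123456.0)
        totals = truth.params["totals_old"]
        assert totals["A"] + totals["B"] == pytest.approx(123456.0, abs=1e-6)

    def test_monte_carlo_ratio_recovery(self):
        # planted f = 0.574 -> ratio 1.3568; measured mean within +/- 0.05 of 1.35
        ratios = []
        for seed in range(50):
            stack, truth = make_mitotic_late(0.574, seed=seed)
            a = quantify.background_corrected_total(
                stack, truth.rois["A"], truth.rois["background"], "old"
            ).corrected_total
            b = quantify.background_corrected_total(
                stack, truth.rois["B"], truth.rois["background"], "old"
            ).corrected_total
            ratios.append(max(a, b) / min(a, b))
        assert np.mean(ratios) == pytest.approx(1.35, abs=0.05)


class TestPair:
    def test_overlapping_nuclei_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            make_pair(PairParams(separation_um=1.0))

    def test_symmetric_pair_ground_truth(self):
        p = PairParams(delta=(100.0, 100.0), old=(100.0, 100.0), new=(100.0, 100.0))
        _, truth = make_pair(p, noise=NO_NOISE)
        assert truth.params["delta_class"] == "symmetric"
        assert truth.params["old_log2"] == 0
        assert truth.params["new_log2"] == 0
        assert truth.params["quadrant"] == "origin"

    def test_asymmetric_pair_ground_truth_quadrant_iv(self):
        # Delta ratio 3, old log2 +0.65, new log2 -0.56 (printed scale)
        p = PairParams(
            delta=(300.0, 100.0),
            old=(100.0 * 2**0.65, 100.0),
            new=(100.0 * 2**-0.56, 100.0),
        )
        _, truth = make_pair(p, noise=NO_NOISE)
        assert truth.params["delta_class"] == "asymmetric"
        assert truth.params["old_log2"] == pytest.approx(0.65)
        assert truth.params["new_log2"] == pytest.approx(-0.56)
        assert truth.params["quadrant"] == "IV"

    def test_edu_channel_positive_cell(self):
        stack, truth = make_pair(PairParams(edu=(True, False)), noise=NO_NOISE)
        bg = truth.rois["background"]
        c1 = quantify.measure_cell(
            stack, truth.rois["cell1"], bg, ["old"], edu_channel="EdU"
        )
        c2 = quantify.measure_cell(
            stack, truth.rois["cell2"], bg, ["old"], edu_channel="EdU"
        )
        assert c1.edu_positive and not c2.edu_positive


class TestField:
    def test_border_straddling_cluster_rejected(self):
        params = FieldParams(clusters=[ClusterSpec((1.0, 1.0), 2)])
        with pytest.raises(ValueError, match="border"):
            plan_field(params)

    def test_singletons_far_apart_recovered(self):
        clusters = [ClusterSpec((50.0 + 40 * i, 100.0), 1) for i in range(10)]
        truth = plan_field(FieldParams(shape_yx=(256, 512), clusters=clusters), seed=0)
        pos = np.array([[c["x_um"], c["y_um"]] for c in truth.cells])
        cs = cluster_cells([c["cell_id"] for c in truth.cells], pos, 10.0)
        assert cs.size_histogram == {"1": 10, "2": 0, "3+": 0}

    def test_planted_cluster_distribution_recovered(self):
        # 1000 clusters drawn from the printed {1: 87.7%, 2: 11.9%, >=3: 0.4%}
        rng = np.random.default_rng(0)
        sizes = sample_cluster_sizes({1: 0.877, 2: 0.119, 3: 0.004}, 1000, rng)
        # virtual field: grid with 40 um pitch keeps clusters > radius apart
        clusters = [
            ClusterSpec((40.0 * (i % 40) + 30.0, 40.0 * (i // 40) + 30.0), int(s))
            for i, s in enumerate(sizes)
        ]
        params = FieldParams(shape_yx=(1100, 1700), clusters=clusters)
        truth = plan_field(params, seed=1)
        pos = np.array([[c["x_um"], c["y_um"]] for c in truth.cells])
        cs = cluster_cells([c["cell_id"] for c in truth.cells], pos, 10.0)
        assert cs.n_clusters == 1000
        hist = cs.size_histogram
        # multinomial sampling error: ~3 sd of n*p*(1-p)
        assert hist["1"] == pytest.approx(877, abs=3 * np.sqrt(1000 * 0.877 * 0.123))
        assert hist["2"] == pytest.approx(119, abs=3 * np.sqrt(1000 * 0.119 * 0.881))

    def test_step_profile_recovered(self):
        w = 512
        profile = np.where(np.arange(w) < w // 2, 100.0, 1000.0)
        params = FieldParams(shape_yx=(64, w), eyfp_profile=profile)
        stack, truth = make_midgut_field(params, seed=2)
        trace = profile_trace(stack, [(0.0, 32.0), (float(w - 1), 32.0)], width_px=40, channel="eYFP")
        blocks = block_average(trace, block=128)
        baseline = DEFAULT_NOISE.baseline
        assert blocks[0] == pytest.approx(100.0 + baseline, rel=0.05)
        assert blocks[-1] == pytest.approx(1000.0 + baseline, rel=0.05)

    def test_render_counts_match_plan(self):
        params = FieldParams(
            clusters=[ClusterSpec((60.0, 60.0), 2)], n_ee=3, n_ec=2, n_mitotic=1
        )
        truth = plan_field(params, seed=5)
        types = [c["type"] for c in truth.cells]
        assert types.count("delta") == 2
        assert types.count("ee") == 3
        assert types.count("ec") == 2
        assert types.count("mitotic") == 1
        stack = render_field(params, truth)
        assert stack.channel_names == ("DlnLacZ", "eYFP", "H3S10ph", "Prospero", "DAPI")

    def test_sample_cluster_sizes_validates_probs(self, rng):
        with pytest.raises(ValueError, match="sum"):
            sample_cluster_sizes({1: 0.5, 2: 0.1}, 10, rng)


class TestSyntheticTables:
    def test_ratio_table_planted_categories_and_mean(self):
        table = make_ratio_table(
            {"symmetric": 8, "medium": 5, "high": 19}, mean=1.35, seed=0
        )
        assert len(table) == 32
        assert table.mean() == pytest.approx(1.35, abs=1e-12)
        assert ((table <= 1.15).sum(), ((table > 1.15) & (table <= 1.22)).sum(),
                (table > 1.22).sum()) == (8, 5, 19)

    def test_ratio_table_impossible_mean_raises(self):
        with pytest.raises(ValueError, match="incompatible"):
            make_ratio_table({"symmetric": 19, "high": 1}, mean=0.9, seed=0)

    def test_log2_table_exact_mean(self):
        t = make_log2_table(33, 0.65, seed=1)
        assert len(t) == 33
        assert t.mean() == pytest.approx(0.65, abs=1e-12)
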