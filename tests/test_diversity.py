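"""Diversity statistics: S, H', similarity, moving-window change, Rr and
unique-band counts, checked against brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dggekit import (
    Band,
    BandMatrix,
    Fingerprint,
    GradientSpec,
    build_report,
    moving_window,
    pairwise_similarity,
    percent_change,
    range_weighted_richness,
    rate_of_change,
    richness,
    shannon,
    unique_band_counts,
)


def matrix_from_rows(rows, positions=None):
    rows = np.asarray(rows, dtype=int)
    n_lanes, n_classes = rows.shape
    if positions is None:
        positions = np.linspace(40.0, 70.0, n_classes)
    return BandMatrix(
        lane_ids=[f"L{i}" for i in range(n_lanes)],
        class_positions=np.asarray(positions, dtype=float),
        presence=rows,
        intensity=rows * 0.5,
    )


def fp_from_rel(rel, lane="L"):
    total = 100.0
    bands = [
        Band(position=0.05 * (i + 1), height=p * total, rel_intensity=p)
        for i, p in enumerate(rel)
    ]
    return Fingerprint(lane, bands)


class TestRichness:
    def test_counts_presence(self):
        assert richness(np.array([1, 0, 1, 1])) == 3
        assert richness(np.zeros(5, dtype=int)) == 0

    @given(st.lists(st.integers(0, 1), min_size=0, max_size=40))
    @settings(max_examples=50, derandomize=True)
    def test_equals_brute_force_sum(self, row):
        assert richness(np.array(row, dtype=int)) == sum(row)


class TestShannon:
    def test_uniform_four_bands(self):
        assert shannon(fp_from_rel([0.25] * 4)) == pytest.approx(math.log(4), abs=1e-9)

    def test_single_band_is_zero(self):
        assert shannon(fp_from_rel([1.0])) == 0.0

    def test_hand_computed_value(self):
        assert shannon(fp_from_rel([0.1, 0.3, 0.6])) == pytest.approx(0.8979, abs=1e-4)

    def test_empty_is_nan_not_zero(self):
        assert math.isnan(shannon(Fingerprint("L", [])))

    def test_log_base_flag(self):
        h2 = shannon(fp_from_rel([0.5, 0.5]), base=2)
        assert h2 == pytest.approx(1.0, abs=1e-9)

    @given(
        st.lists(st.floats(0.01, 1.0, allow_nan=False), min_size=1, max_size=20)
    )
    @settings(max_examples=100, derandomize=True)
    def test_bounds_and_maximum_at_uniformity(self, weights):
        p = np.array(weights) / sum(weights)
        fp = fp_from_rel(list(p))
        h = shannon(fp)
        s = len(weights)
        assert -1e-9 <= h <= math.log(s) + 1e-9
        # brute-force evaluation agrees
        brute = -sum(q * math.log(q) for q in p if q > 0)
        assert h == pytest.approx(brute, abs=1e-12)


class TestSimilarity:
    def test_identical_rows_100(self):
        r = np.array([1, 1, 0, 1])
        assert pairwise_similarity(r, r) == 100.0

    def test_disjoint_rows_0(self):
        assert pairwise_similarity([1, 1, 0], [0, 0, 1]) == 0.0

    def test_dice_arithmetic(self):
        a, b = [1, 1, 1, 0], [1, 1, 0, 1]
        assert pairwise_similarity(a, b) == pytest.approx(66.67, abs=0.01)
        assert percent_change(a, b) == pytest.approx(33.33, abs=0.01)

    def test_both_empty_defined_100(self):
        assert pairwise_similarity([0, 0], [0, 0]) == 100.0

    @given(
        st.lists(st.integers(0, 1), min_size=1, max_size=30),
        st.data(),
    )
    @settings(max_examples=200, derandomize=True)
    def test_matches_set_based_oracle(self, a, data):
        b = data.draw(st.lists(st.integers(0, 1), min_size=len(a), max_size=len(a)))
        a, b = np.array(a), np.array(b)
        set_a = {i for i, v in enumerate(a) if v}
        set_b = {i for i, v in enumerate(b) if v}
        if set_a or set_b:
            expected = 100.0 * 2 * len(set_a & set_b) / (len(set_a) + len(set_b))
            assert pairwise_similarity(a, b) == pytest.approx(expected, abs=1e-9)
        sim = pairwise_similarity(a, b)
        assert 0.0 <= sim <= 100.0
        assert sim == pairwise_similarity(b, a)


class TestMovingWindow:
    def test_constant_series_all_zero(self):
        bm = matrix_from_rows([[1, 0, 1]] * 7)
        curve = moving_window(bm, bm.lane_ids)
        assert len(curve) == 6
        assert all(v == 0.0 for _, v in curve)
        assert rate_of_change(curve) == 0.0

    def test_alternating_disjoint_lanes(self):
        bm = matrix_from_rows([[1, 0], [0, 1], [1, 0], [0, 1]])
        curve = moving_window(bm, bm.lane_ids)
        assert [v for _, v in curve] == [100.0, 100.0, 100.0]

    def test_needs_two_lanes(self):
        bm = matrix_from_rows([[1, 0], [0, 1]])
        with pytest.raises(ValueError):
            moving_window(bm, ["L0"])

    def test_rate_of_change_examples(self):
        assert rate_of_change([("a", 0.0), ("b", 100.0)]) == 50.0
        assert rate_of_change(
            [("a", 33.33), ("b", 0.0), ("c", 100.0)]
        ) == pytest.approx(44.44, abs=0.01)

    def test_dt_is_mean_of_random_curves(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            vals = rng.uniform(0, 100, rng.integers(1, 10))
            curve = [(str(i), float(v)) for i, v in enumerate(vals)]
            assert rate_of_change(curve) == pytest.approx(vals.mean(), abs=1e-9)


class TestRangeWeightedRichness:
    def test_single_band_degenerate(self):
        g = GradientSpec(35, 75)
        rr, dg = range_weighted_richness(np.array([50.0]), g)
        assert rr == 0.0 and dg == 0.0

    def test_rr_identity_and_intensity_invariance(self):
        g = GradientSpec(35, 75)
        dens = np.array([40.0, 45.0, 52.0, 60.0])
        rr, dg = range_weighted_richness(dens, g)
        assert rr == pytest.approx(len(dens) ** 2 * dg, abs=1e-9)
        assert dg == pytest.approx((60.0 - 40.0) / 40.0, abs=1e-12)

    def test_band_outside_span_increases_rr(self):
        g = GradientSpec(35, 75)
        base = np.array([45.0, 50.0, 55.0])
        rr0, _ = range_weighted_richness(base, g)
        rr1, _ = range_weighted_richness(np.append(base, 65.0), g)
        assert rr1 > rr0

    def test_missing_denaturant_rejected(self):
        fp = Fingerprint("L", [Band(0.5, 10.0), Band(0.6, 10.0)])
        with pytest.raises(ValueError):
            range_weighted_richness(fp, GradientSpec(35, 75))


class TestUniqueBands:
    def test_exclusive_class_counted(self):
        bm = matrix_from_rows([[1, 1, 0], [0, 1, 1], [0, 1, 0]])
        res = unique_band_counts(bm, ["L0", "L1"])
        assert res["per_lane"] == {"L0": 1, "L1": 1}
        assert res["total"] == 2

    def test_all_shared_counts_zero(self):
        bm = matrix_from_rows([[1, 1], [1, 1]])
        res = unique_band_counts(bm, ["L0", "L1"])
        assert res["total"] == 0

    def test_disjoint_focal_lanes_sum(self):
        # 5 classes exclusive to L0, 6 to L1, 4 shared by everyone
        rows = np.zeros((3, 15), dtype=int)
        rows[0, :5] = 1
        rows[1, 5:11] = 1
        rows[:, 11:] = 1
        res = unique_band_counts(matrix_from_rows(rows), ["L0", "L1"])
        assert res["per_lane"] == {"L0": 5, "L1": 6}
        assert res["total"] == 11

    def test_unknown_lane_rejected(self):
        bm = matrix_from_rows([[1, 0], [0, 1]])
        with pytest.raises(KeyError):
            unique_band_counts(bm, ["nope"])


class TestBuildReport:
    def test_shapes_and_invariants_on_synthetic_series(self):
        rng = np.random.default_rng(5)
        rows = (rng.uniform(size=(7, 20)) < 0.5).astype(int)
        rows[:, 0] = 1  # avoid empty lanes
        bm = matrix_from_rows(rows)
        g = GradientSpec(35, 75)
        rep = build_report(bm, [], g, order=bm.lane_ids)
        assert len(rep.per_lane) == 7
        assert len(rep.mwa_curve) == 6
        assert rep.Dt == pytest.approx(
            np.mean([v for _, v in rep.mwa_curve]), abs=1e-9
        )
        np.testing.assert_allclose(rep.similarity, rep.similarity.T, atol=1e-9)
        assert np.all(np.diag(rep.similarity) == 100.0)
        for lane in bm.lane_ids:
            row = rep.per_lane[lane]
            assert row["Rr"] == pytest.approx(row["S"] ** 2 * row["Dg"], abs=1e-9)
            assert 0.0 <= row["Dg"] <= 1.0

    def test_identical_lanes_give_zero_change(self):
        bm = matrix_from_rows([[1, 0, 1]] * 7)
        rep = build_report(bm, [], GradientSpec(35, 75), order=bm.lane_ids)
        assert rep.Dt == 0.0
        assert np.all(rep.similarity == 100.0)
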