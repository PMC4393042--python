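"""I/O round trips, format validation and the position↔denaturant map."""

import numpy as np
import pandas as pd
import pytest

from dggekit import (
    Band,
    BandMatrix,
    Fingerprint,
    FormatError,
    Gel,
    GradientSpec,
    LaneProfile,
    position_to_denaturant,
    read_band_table,
    read_matrix,
    read_profiles,
    write_band_table,
    write_matrix,
    write_profiles,
)


class TestGradientMap:
    @pytest.mark.parametrize(
        "position, low, high, expected",
        [
            (0.0, 35.0, 75.0, 35.0),
            (1.0, 40.0, 65.0, 65.0),
            (0.5, 35.0, 75.0, 55.0),
        ],
    )
    def test_linear_map(self, position, low, high, expected):
        assert position_to_denaturant(position, GradientSpec(low, high)) == pytest.approx(expected)

    def test_strictly_increasing(self):
        g = GradientSpec(30.0, 60.0)
        xs = np.linspace(0, 1, 101)
        ys = [position_to_denaturant(x, g) for x in xs]
        assert np.all(np.diff(ys) > 0)
        assert ys[0] == g.low and ys[-1] == g.high

    def test_out_of_range_position(self):
        with pytest.raises(ValueError):
            position_to_denaturant(1.2, GradientSpec(35, 75))

    @pytest.mark.parametrize("low, high", [(75, 35), (-5, 50), (20, 20), (10, 120)])
    def test_invalid_gradient(self, low, high):
        with pytest.raises(ValueError):
            GradientSpec(low, high)


class TestProfilesIO:
    def test_parse_simple_tsv(self, tmp_path):
        path = tmp_path / "p.tsv"
        pos = np.linspace(0, 1, 100)
        pd.DataFrame({"position": pos, "A": pos * 2, "B": pos + 1}).to_csv(
            path, sep="\t", index=False
        )
        gel = read_profiles(path)
        assert gel.lane_ids == ["A", "B"]
        assert all(lane.positions.size == 100 for lane in gel.lanes)

    def test_descending_positions_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        pd.DataFrame({"position": [0.3, 0.2, 0.1], "A": [1, 2, 3]}).to_csv(
            path, sep="\t", index=False
        )
        with pytest.raises(FormatError):
            read_profiles(path)

    def test_negative_intensity_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        pd.DataFrame({"position": [0.1, 0.2], "A": [1.0, -0.5]}).to_csv(
            path, sep="\t", index=False
        )
        with pytest.raises(FormatError):
            read_profiles(path)

    def test_other_units_rescaled(self, tmp_path):
        path = tmp_path / "mm.tsv"
        pd.DataFrame({"position": [0.0, 50.0, 100.0], "A": [1, 2, 3]}).to_csv(
            path, sep="\t", index=False
        )
        gel = read_profiles(path)
        np.testing.assert_allclose(gel.lanes[0].positions, [0, 0.5, 1.0])

    def test_round_trip(self, tmp_path):
        pos = np.linspace(0, 1, 57)
        rng = np.random.default_rng(1)
        gel = Gel(
            lanes=[
                LaneProfile("L1", pos, rng.uniform(0, 100, 57)),
                LaneProfile("L2", pos, rng.uniform(0, 100, 57)),
            ]
        )
        path = tmp_path / "rt.tsv"
        write_profiles(gel, path)
        back = read_profiles(path)
        assert back.lane_ids == gel.lane_ids
        for a, b in zip(gel.lanes, back.lanes):
            np.testing.assert_allclose(b.positions, a.positions, atol=1e-9)
            np.testing.assert_allclose(b.intensities, a.intensities, atol=1e-9)


class TestBandTableIO:
    def test_parse_and_rel_intensity(self, tmp_path):
        path = tmp_path / "b.csv"
        path.write_text(
            "lane_id,position,height\nL1,0.5,30\nL1,0.1,10\nL1,0.9,60\n"
        )
        (fp,) = read_band_table(path)
        assert fp.richness == 3
        # sorted by position, rel_intensity = height / total
        assert [b.position for b in fp.bands] == [0.1, 0.5, 0.9]
        np.testing.assert_allclose(
            [b.rel_intensity for b in fp.bands], [0.1, 0.3, 0.6]
        )

    def test_duplicate_position_rejected(self, tmp_path):
        path = tmp_path / "b.csv"
        path.write_text("lane_id,position,height\nL1,0.5,30\nL1,0.5,10\n")
        with pytest.raises(FormatError):
            read_band_table(path)

    def test_negative_height_rejected(self, tmp_path):
        path = tmp_path / "b.csv"
        path.write_text("lane_id,position,height\nL1,0.5,-3\n")
        with pytest.raises(FormatError):
            read_band_table(path)

    def test_empty_list_gives_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_band_table([], path)
        assert path.read_text().strip() == "lane_id,position,denaturant,height,rel_intensity"

    def test_round_trip(self, tmp_path):
        fp = Fingerprint(
            "L1",
            [
                Band(0.123456, 10.0, denaturant=40.0),
                Band(0.6, 30.0, denaturant=59.0),
            ],
        ).with_rel_intensity()
        path = tmp_path / "rt.csv"
        write_band_table([fp], path)
        (back,) = read_band_table(path)
        assert back.lane_id == "L1"
        for a, b in zip(fp.bands, back.bands):
            assert b.position == pytest.approx(a.position, abs=1e-6)
            assert b.height == pytest.approx(a.height, abs=1e-9)
            assert b.denaturant == pytest.approx(a.denaturant, abs=1e-9)
            assert b.rel_intensity == pytest.approx(a.rel_intensity, abs=1e-9)


class TestMatrixIO:
    def _matrix(self):
        rng = np.random.default_rng(7)
        presence = (rng.uniform(size=(7, 20)) < 0.5).astype(int)
        intensity = presence * rng.uniform(0.01, 1.0, size=(7, 20))
        return BandMatrix(
            lane_ids=[f"L{i}" for i in range(7)],
            class_positions=np.sort(rng.uniform(36, 74, 20)),
            presence=presence,
            intensity=intensity,
        )

    def test_shape_on_disk(self, tmp_path):
        bm = self._matrix()
        path = tmp_path / "m.tsv"
        write_matrix(bm, path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 8  # header + 7 lanes

    def test_round_trip(self, tmp_path):
        bm = self._matrix()
        path = tmp_path / "m.tsv"
        write_matrix(bm, path)
        back = read_matrix(path)
        assert back.lane_ids == bm.lane_ids
        np.testing.assert_array_equal(back.presence, bm.presence)
        np.testing.assert_allclose(back.intensity, bm.intensity, atol=1e-9)
        np.testing.assert_allclose(back.class_positions, bm.class_positions, atol=1e-4)


class TestInvariants:
    def test_band_validation(self):
        with pytest.raises(ValueError):
            Band(position=1.5, height=1.0)
        with pytest.raises(ValueError):
            Band(position=0.5, height=-1.0)

    def test_fingerprint_ordering_enforced(self):
        with pytest.raises(ValueError):
            Fingerprint("L", [Band(0.5, 1.0), Band(0.2, 1.0)])

    def test_rel_intensity_sums_to_one(self):
        fp = Fingerprint("L", [Band(0.1, 5.0), Band(0.4, 15.0)]).with_rel_intensity()
        assert sum(b.rel_intensity for b in fp.bands) == pytest.approx(1.0, abs=1e-9)

    def test_band_matrix_consistency_enforced(self):
        with pytest.raises(ValueError):
            BandMatrix(
                lane_ids=["A"],
                class_positions=np.array([50.0]),
                presence=np.array([[1]]),
                intensity=np.array([[0.0]]),  # present but zero intensity
            )
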