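"""Physical-unit metrics: ESD, IEq, ellipsoid volumes, shape descriptors."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from isletflow import (
    ScaleCalibration,
    Track,
    V150_UM3,
    assign_ieq,
    circularity,
    dtz_ratio,
    ellipsoid_volume,
    equivalent_diameter,
    ieq_volume,
    records_from_tracks,
    solidity,
    summarize,
    track_volume,
)
from conftest import make_detection

UNIT_SCALE = ScaleCalibration(delta_um_per_px=1.0)


class TestEquivalentDiameter:
    def test_disk_identity(self):
        assert equivalent_diameter(math.pi * 100**2, UNIT_SCALE) == pytest.approx(200)

    def test_with_chip_scale(self):
        scale = ScaleCalibration(delta_um_per_px=2.1739)
        d = equivalent_diameter(10000, scale)
        assert d == pytest.approx(2 * math.sqrt(10000 / math.pi) * 2.1739, rel=1e-9)
        assert d == pytest.approx(245.3, abs=0.1)

    @pytest.mark.parametrize("area", [0, -10])
    def test_nonpositive_area_rejected(self, area):
        with pytest.raises(ValueError):
            equivalent_diameter(area, UNIT_SCALE)


class TestAssignIeq:
    def test_single_150um_islet_is_one_bin_two(self):
        bins, total = assign_ieq([150.0])
        assert bins == [1]
        assert total == pytest.approx(0.667, abs=1e-12)

    def test_sum_of_multipliers(self):
        _, total = assign_ieq([150.0, 150.0, 175.0])
        assert total == pytest.approx(0.667 + 0.667 + 1.685, abs=1e-12)

    def test_fragment_contributes_zero(self):
        bins, total = assign_ieq([30.0])
        assert bins == [None]
        assert total == 0.0

    @pytest.mark.parametrize(
        "diameter,expected_bin",
        [(50.0, 0), (100.4, 0), (100.6, 1), (150.5, 2), (400.4, 6), (401.0, 7), (900.0, 7)],
    )
    def test_rounding_bin_edges(self, diameter, expected_bin):
        bins, _ = assign_ieq([diameter])
        assert bins == [expected_bin]

    @given(
        diams=st.lists(st.floats(10, 600), min_size=1, max_size=20),
        idx=st.integers(0, 19),
        bump=st.floats(0, 300),
    )
    def test_monotone_in_every_diameter(self, diams, idx, bump):
        idx = idx % len(diams)
        _, total = assign_ieq(diams)
        bigger = list(diams)
        bigger[idx] = bigger[idx] + bump
        _, total_bigger = assign_ieq(bigger)
        assert total_bigger >= total


class TestEllipsoidVolume:
    def test_sphere_of_diameter_150(self):
        for variant in ("major", "minor"):
            assert ellipsoid_volume(75, 75, variant) == pytest.approx(
                1.767e6, rel=1e-3
            )

    def test_major_variant_formula(self):
        assert ellipsoid_volume(100, 50, "major") == pytest.approx(
            (4 / 3) * math.pi * 100**2 * 50
        )

    def test_variant_ratio_is_axis_ratio(self):
        v_major = ellipsoid_volume(100, 50, "major")
        v_minor = ellipsoid_volume(100, 50, "minor")
        assert v_major / v_minor == pytest.approx(2.0)

    def test_axis_order_enforced(self):
        with pytest.raises(ValueError):
            ellipsoid_volume(50, 100, "major")

    @given(
        major=st.floats(1, 500),
        minor=st.floats(1, 500),
    )
    def test_major_variant_dominates(self, major, minor):
        major, minor = max(major, minor), min(major, minor)
        v_major = ellipsoid_volume(major, minor, "major")
        v_minor = ellipsoid_volume(major, minor, "minor")
        assert v_major >= v_minor * (1 - 1e-12)  # ulp slack when Ma == Mi
        if major > minor * (1 + 1e-12):
            assert v_major > v_minor


class TestTrackVolume:
    def test_spherical_track_gives_v150(self):
        track = Track(
            0, [make_detection(major=75, minor=75, frame_index=f) for f in range(3)]
        )
        assert track_volume(track, UNIT_SCALE) == pytest.approx(V150_UM3)

    def test_frame_averaging(self):
        r1 = (1.0e6 / ((4 / 3) * math.pi)) ** (1 / 3)
        r2 = (2.0e6 / ((4 / 3) * math.pi)) ** (1 / 3)
        track = Track(
            0,
            [
                make_detection(major=r1, minor=r1, frame_index=0),
                make_detection(major=r2, minor=r2, frame_index=1),
            ],
        )
        assert track_volume(track, UNIT_SCALE) == pytest.approx(1.5e6)

    def test_cubic_scale_conversion(self):
        track = Track(0, [make_detection(major=30, minor=20)])
        v1 = track_volume(track, ScaleCalibration(delta_um_per_px=1.0))
        v2 = track_volume(track, ScaleCalibration(delta_um_per_px=2.0))
        assert v2 == pytest.approx(8 * v1)

    def test_edge_only_track_rejected(self):
        track = Track(0, [make_detection(touches_edge=True)])
        with pytest.raises(ValueError):
            track_volume(track, UNIT_SCALE)


class TestIeqVolume:
    def test_one_ieq_is_v150(self):
        assert ieq_volume(1.0) == pytest.approx(1.767e6, rel=1e-3)

    def test_zero(self):
        assert ieq_volume(0.0) == 0.0

    def test_scales_linearly(self):
        assert ieq_volume(0.667) == pytest.approx(0.667 * V150_UM3)
        assert ieq_volume(0.667) == pytest.approx(1.179e6, rel=1e-3)


class TestShapeDescriptors:
    def test_ideal_circle_circularity_one(self):
        r = 37.0
        assert circularity(math.pi * r**2, 2 * math.pi * r) == pytest.approx(1.0)

    def test_square_circularity(self):
        s = 10.0
        assert circularity(s**2, 4 * s) == pytest.approx(math.pi / 4)

    def test_circularity_clamped_to_one(self):
        # slightly-too-short perimeter (rasterization) must clamp, not exceed 1
        r = 50.0
        assert circularity(math.pi * r**2, 2 * math.pi * r * 0.99) == 1.0

    def test_solidity_of_convex_shape(self):
        assert solidity(5000, 5000) == 1.0

    def test_solidity_of_star(self):
        assert solidity(5000, 10000) == 0.5

    def test_hull_smaller_than_area_rejected(self):
        with pytest.raises(ValueError):
            solidity(1000, 900)

    def test_dtz_extremes_and_half(self):
        assert dtz_ratio(0, 1000) == 0.0
        assert dtz_ratio(1000, 1000) == 1.0
        assert dtz_ratio(500, 1000) == 0.5

    def test_dtz_domain_errors(self):
        with pytest.raises(ValueError):
            dtz_ratio(10, 0)
        with pytest.raises(ValueError):
            dtz_ratio(200, 100)

    @given(
        area=st.floats(1, 1e6),
        perimeter=st.floats(0.1, 1e4),
        hull_excess=st.floats(1.0, 3.0),
    )
    def test_descriptors_always_in_unit_interval(self, area, perimeter, hull_excess):
        assert 0 <= circularity(area, perimeter) <= 1
        assert 0 <= solidity(area, area * hull_excess) <= 1


class TestRecordsAndSummary:
    def _spherical_track(self, track_id, radius_px, frames=3, dtz_frac=0.5):
        area = math.pi * radius_px**2
        return Track(
            track_id,
            [
                make_detection(
                    area=area,
                    major=radius_px,
                    minor=radius_px,
                    frame_index=f,
                    dtz=dtz_frac * area,
                )
                for f in range(frames)
            ],
        )

    def test_record_fields_from_spherical_track(self):
        track = self._spherical_track(0, 75.0)
        rec = records_from_tracks([track], UNIT_SCALE)[0]
        assert rec.diameter_um == pytest.approx(150.0)
        assert rec.ieq_bin == 1
        assert rec.ieq_contribution == pytest.approx(0.667)
        assert rec.volume_major_um3 == pytest.approx(V150_UM3)
        assert rec.circularity == pytest.approx(1.0)
        assert rec.solidity == pytest.approx(1.0)
        assert rec.dtz_ratio == pytest.approx(0.5)

    def test_edge_only_track_dropped(self):
        track = Track(0, [make_detection(touches_edge=True)])
        assert records_from_tracks([track], UNIT_SCALE) == []

    def test_mean_and_sample_sd(self):
        tracks = [self._spherical_track(i, r) for i, r in enumerate((50.0, 75.0, 100.0))]
        records = records_from_tracks(tracks, UNIT_SCALE)
        report = summarize(records)
        mean, sd = report.mean_sd["diameter_um"]
        assert mean == pytest.approx(150.0)
        assert sd == pytest.approx(50.0)  # n-1 denominator

    def test_empty_sample(self):
        report = summarize([])
        assert report.islet_count == 0
        assert report.total_ieq == 0.0
        assert report.mean_sd["diameter_um"] is None
        assert report.sample_dtz_ratio is None

    def test_ieq_totals_and_ieqv_identity(self):
        tracks = [
            self._spherical_track(0, 75.0),  # 150 um -> 0.667
            self._spherical_track(1, 75.0),  # 150 um -> 0.667
            self._spherical_track(2, 87.5),  # 175 um -> 1.685
        ]
        report = summarize(records_from_tracks(tracks, UNIT_SCALE))
        assert report.total_ieq == pytest.approx(3.019, abs=1e-12)
        assert report.ieqv_um3 == pytest.approx(3.019 * V150_UM3)
        # exact inverse relation, not merely approximate
        assert report.ieqv_um3 / report.v150_um3 == pytest.approx(
            report.total_ieq, rel=1e-12
        )

    def test_sample_dtz_is_area_weighted(self):
        big = self._spherical_track(0, 100.0, dtz_frac=1.0)
        small = self._spherical_track(1, 50.0, dtz_frac=0.0)
        report = summarize(records_from_tracks([big, small], UNIT_SCALE))
        expected = (100.0**2) / (100.0**2 + 50.0**2)
        assert report.sample_dtz_ratio == pytest.approx(expected)
        assert report.mean_dtz_ratio == pytest.approx(0.5)

    def test_histograms_cover_all_records(self):
        tracks = [self._spherical_track(i, 40.0 + 7 * i) for i in range(5)]
        report = summarize(records_from_tracks(tracks, UNIT_SCALE))
        assert sum(report.histograms["diameter_um"]["counts"]) == 5
        assert sum(report.histograms["dtz_ratio"]["counts"]) == 5
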