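"""Echo-integration, Sv-band classification and shelf filtering."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from echolayers.echo import (
    DEFAULT_CLASSES,
    NASC_COEFF,
    EchoClass,
    Echogram,
    classify_sv,
    integrate_esdu,
    records_by_depth_frame,
    shelf_filter,
)
from conftest import make_echogram, make_record

FLOOR = -100.0


class TestClassifySv:
    @pytest.mark.parametrize(
        "sv, expected",
        [
            (-70.0, "PG"),
            (-65.0, "PFG"),  # band bounds are half-open: -65 belongs to PFG
            (-80.0, "PG"),
            (-20.0, "excluded"),
            (-80.0001, "excluded"),
            (-30.0, "PFG"),
        ],
    )
    def test_band_membership(self, sv, expected):
        assert classify_sv(sv) == expected

    def test_overlapping_partition_classes_rejected(self):
        bad = (EchoClass("PG", -80, -60), EchoClass("PFG", -65, -20))
        with pytest.raises(ValueError, match="overlap"):
            classify_sv(-70.0, bad)


class TestIntegrateEsdu:
    def test_single_cell_closed_form(self):
        """One 1-m cell at -70 dB integrates to 4*pi*1852^2*1e-7 m^2/nmi^2."""
        eg = make_echogram(np.full((1, 1), -70.0), depths=[20.0])
        (rec,) = integrate_esdu(eg)
        expected = 4.0 * math.pi * 1852.0**2 * 1e-7
        assert rec.nasc["PG"] == pytest.approx(expected, rel=1e-12)
        assert rec.nasc["PFG"] == 0.0
        assert rec.nasc["TG"] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(4.31, abs=0.005)

    def test_noise_floor_integrates_to_zero(self):
        eg = make_echogram(np.full((30, 8), FLOOR))
        for rec in integrate_esdu(eg):
            assert all(v == 0.0 for v in rec.nasc.values())

    def test_band_additivity(self):
        rng = np.random.default_rng(7)
        sv = rng.uniform(-85, -15, size=(40, 12))
        eg = make_echogram(sv)
        for rec in integrate_esdu(eg):
            assert rec.nasc["TG"] == pytest.approx(
                rec.nasc["PG"] + rec.nasc["PFG"], rel=1e-9
            )

    def test_by_depth_sums_to_total(self):
        rng = np.random.default_rng(3)
        eg = make_echogram(rng.uniform(-85, -15, size=(50, 10)))
        for rec in integrate_esdu(eg):
            for cname, total in rec.nasc.items():
                assert rec.nasc_by_depth[cname].sum() == pytest.approx(
                    total, rel=1e-6, abs=1e-12
                )

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        sv = rng.uniform(-90, -25, size=(5, 5))
        depths = np.array([5.0, 15.0, 25.0, 35.0, 45.0])
        eg = make_echogram(sv, depths=depths, bottom=40.0, col_spacing_nmi=0.04)
        records = integrate_esdu(eg, esdu_length_nmi=0.1)
        d_bins = np.floor(np.cumsum([0.0, 0.04, 0.04, 0.04, 0.04]) / 0.1).astype(int)
        for cls in DEFAULT_CLASSES:
            expected = oracles.brute_force_nasc(
                sv, depths, eg.bottom_depth, d_bins, cls.sv_low, cls.sv_high,
                surface_offset=10.0, dz=10.0,
            )
            for rec in records:
                assert rec.nasc[cls.name] == pytest.approx(
                    expected[rec.esdu_index], rel=1e-12, abs=1e-15
                )

    def test_surface_offset_cells_never_contribute(self):
        rng = np.random.default_rng(5)
        sv = rng.uniform(-75, -30, size=(30, 6))
        eg = make_echogram(sv)
        base = integrate_esdu(eg)
        perturbed = sv.copy()
        perturbed[:9, :] = -30.0  # depths 0.5..8.5 m, all above the offset
        eg2 = make_echogram(perturbed)
        for a, b in zip(base, integrate_esdu(eg2)):
            for k in a.nasc:
                assert a.nasc[k] == b.nasc[k]

    def test_cells_below_bottom_excluded(self):
        sv = np.full((30, 2), -70.0)
        deep = integrate_esdu(make_echogram(sv, bottom=200.0))
        shallow = integrate_esdu(make_echogram(sv, bottom=20.0))
        assert shallow[0].nasc["PG"] < deep[0].nasc["PG"]
        # exactly the ten bin centres 10.5..19.5 m survive with a 20 m bottom
        assert shallow[0].nasc["PG"] == pytest.approx(
            NASC_COEFF * 1e-7 * 10, rel=1e-12
        )

    def test_raising_in_band_cell_increases_nasc(self):
        sv = np.full((20, 3), -72.0)
        base = integrate_esdu(make_echogram(sv))[0].nasc["PG"]
        sv2 = sv.copy()
        sv2[15, 1] = -66.0
        bumped = integrate_esdu(make_echogram(sv2))[0].nasc["PG"]
        assert bumped > base

    def test_linear_domain_additivity(self):
        """Integrating the cell-wise linear-sv sum of two grids sums NASCs."""
        rng = np.random.default_rng(9)
        a = rng.uniform(-78, -70, size=(25, 4))
        b = rng.uniform(-78, -70, size=(25, 4))
        merged = 10.0 * np.log10(10 ** (a / 10.0) + 10 ** (b / 10.0))
        assert merged.max() < -65  # stays inside the PG band
        na = integrate_esdu(make_echogram(a))[0].nasc["PG"]
        nb = integrate_esdu(make_echogram(b))[0].nasc["PG"]
        nm = integrate_esdu(make_echogram(merged))[0].nasc["PG"]
        assert nm == pytest.approx(na + nb, rel=1e-9)

    def test_missing_cells_contribute_zero_and_flag(self):
        sv = np.full((30, 4), -70.0)
        sv[10:, :] = np.nan  # most of the water column missing
        (rec,) = integrate_esdu(make_echogram(sv, bottom=30.0))
        assert rec.flagged
        assert np.isfinite(rec.nasc["PG"])

    def test_nan_equivalent_to_floor(self):
        sv = np.full((20, 2), -70.0)
        sv[5, 0] = np.nan
        sv2 = sv.copy()
        sv2[5, 0] = -150.0  # far below every band
        r1 = integrate_esdu(make_echogram(sv))[0]
        r2 = integrate_esdu(make_echogram(sv2))[0]
        assert r1.nasc == pytest.approx(r2.nasc)

    @given(st.integers(min_value=1, max_value=40))
    @settings(max_examples=20, deadline=None)
    def test_esdu_nasc_independent_of_ping_density(self, reps):
        """Duplicating columns within an ESDU leaves its NASC unchanged."""
        sv_col = np.linspace(-78, -68, 20)[:, None]
        eg1 = make_echogram(sv_col, col_spacing_nmi=0.0)
        eg2 = make_echogram(np.repeat(sv_col, reps, axis=1), col_spacing_nmi=0.0)
        n1 = integrate_esdu(eg1)[0].nasc["PG"]
        n2 = integrate_esdu(eg2)[0].nasc["PG"]
        assert n2 == pytest.approx(n1, rel=1e-12)


class TestShelfFilter:
    def test_closed_interval_bounds(self):
        records = [make_record(bottom_depth=d) for d in (5.0, 10.0, 150.0, 151.0)]
        kept = shelf_filter(records)
        assert [r.bottom_depth for r in kept] == [10.0, 150.0]

    def test_empty_and_all_kept(self):
        assert shelf_filter([]) == []
        records = [make_record(bottom_depth=100.0) for _ in range(5)]
        assert shelf_filter(records) == records

    def test_order_preserved(self):
        records = [make_record(esdu_index=i, bottom_depth=50.0 + i) for i in range(6)]
        kept = shelf_filter(records, 52.0, 54.0)
        assert [r.esdu_index for r in kept] == [2, 3, 4]


class TestEchogramIO:
    def test_csv_round_trip_lossless(self, tmp_path):
        rng = np.random.default_rng(2)
        eg = make_echogram(rng.uniform(-90, -30, size=(12, 7)))
        eg.to_csv(tmp_path / "cells.csv", tmp_path / "track.csv")
        back = Echogram.from_csv(tmp_path / "cells.csv", tmp_path / "track.csv")
        np.testing.assert_array_equal(back.sv, eg.sv)
        np.testing.assert_array_equal(back.depths, eg.depths)
        np.testing.assert_array_equal(back.lats, eg.lats)
        assert list(back.times) == list(eg.times)

    def test_netcdf_round_trip(self, tmp_path):
        rng = np.random.default_rng(4)
        eg = make_echogram(rng.uniform(-90, -30, size=(10, 5)))
        eg.to_netcdf(tmp_path / "eg.nc")
        back = Echogram.from_netcdf(tmp_path / "eg.nc")
        np.testing.assert_allclose(back.sv, eg.sv)
        np.testing.assert_allclose(back.bottom_depth, eg.bottom_depth)

    def test_by_depth_frame_long_format(self):
        rec = make_record()
        frame = records_by_depth_frame([rec])
        assert set(frame["class"]) == {"PG", "PFG", "TG"}
        assert len(frame) == 3 * len(rec.depth_bins)

    def test_invalid_depths_rejected(self):
        with pytest.raises(ValueError, match="ascending"):
            make_echogram(np.zeros((3, 2)), depths=[3.0, 2.0, 1.0])
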