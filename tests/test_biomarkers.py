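import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octlayers.biomarkers import (
    UndefinedZoneError,
    band_area,
    compute_record,
    locate_fovea,
    partition_zones,
    smoothness_index,
)
from octlayers.segment import BoundaryCurve, LayerSet

from .conftest import polyline_si


def curve(depths, start=0, role="IPL", valid=None):
    return BoundaryCurve(np.asarray(depths, float), start, role, valid)


def flat_layers(width=400, rows=(50, 80, 95, 150)):
    return LayerSet(*(curve(np.full(width, r), role=role)
                      for r, role in zip(rows, ("IPL", "OPL_upper", "OPL_lower", "EZ"))))


class TestSmoothnessIndex:
    def test_straight_segment_is_exactly_one(self):
        assert smoothness_index(curve(7 + 0.3 * np.arange(200)), (10, 150)) == 1.0

    def test_semicircle_limit_two_over_pi(self):
        n = 10_000
        r = (n - 1) / 2
        x = np.arange(n, dtype=float)
        y = np.sqrt(np.clip(r * r - (x - r) ** 2, 0, None))
        si = smoothness_index(curve(y + 5), (0, n))
        assert si == pytest.approx(2 / np.pi, abs=1e-3)

    def test_matches_arc_length_oracle_on_random_polylines(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(10, 200))
            y = rng.normal(50, 5, n)
            si = smoothness_index(curve(y), (0, n))
            assert si == pytest.approx(polyline_si(np.arange(n), y), abs=1e-9)

    @given(shift=st.floats(-100, 100), seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_invariant_under_depth_shift_and_reflection(self, shift, seed):
        y = np.random.default_rng(seed).normal(60, 4, 80)
        base = smoothness_index(curve(y), (0, 80))
        assert smoothness_index(curve(y + shift), (0, 80)) == pytest.approx(base, abs=1e-12)
        assert smoothness_index(curve(y[::-1]), (0, 80)) == pytest.approx(base, abs=1e-12)

    def test_monotone_decrease_with_perturbation_amplitude(self):
        x = np.arange(200)
        prev = 1.0
        for amp in (0.5, 1, 2, 4, 8):
            si = smoothness_index(curve(100 + amp * np.sin(2 * np.pi * x / 40)), (0, 200))
            assert si < prev
            prev = si

    def test_bridges_excluded_columns_with_true_gap(self):
        y = np.full(100, 50.0)
        v = np.ones(100, bool)
        v[40:60] = False
        si = smoothness_index(curve(y, valid=v), (0, 100))
        assert si == pytest.approx(1.0)

    def test_too_few_columns_rejected(self):
        with pytest.raises(UndefinedZoneError):
            smoothness_index(curve(np.full(50, 5.0), valid=np.zeros(50, bool)), (0, 50))


class TestBandArea:
    def test_flat_band_rectangle(self):
        up = curve(np.full(200, 40.0), role="OPL_upper")
        low = curve(np.full(200, 50.0), role="OPL_lower")
        assert band_area(up, low, (0, 124)) == pytest.approx(10 * 123)

    def test_degenerate_zero_band(self):
        up = curve(np.full(50, 40.0))
        low = curve(np.full(50, 40.0))
        assert band_area(up, low, (0, 50)) == 0.0

    def test_wedge_closed_form(self):
        w = 101
        up = curve(np.zeros(w))
        low = curve(np.linspace(0, 20, w))
        # trapezoid of a linear gap equals the exact integral
        assert band_area(up, low, (0, w)) == pytest.approx(0.5 * 20 * (w - 1))

    def test_supersampled_riemann_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            n = 150
            u = 40 + np.cumsum(rng.normal(0, 0.3, n))
            g = 5 + 2 * np.abs(np.sin(np.arange(n) / 17))
            area = band_area(curve(u), curve(u + g), (0, n))
            xs = np.arange(n, dtype=float)
            fine = np.linspace(0, n - 1, 10 * (n - 1) + 1)
            gap = np.interp(fine, xs, g)
            riemann = np.trapezoid(gap, fine)
            assert area == pytest.approx(riemann, rel=5e-3)

    def test_crossing_curves_rejected(self):
        up = curve(np.full(50, 45.0))
        low = curve(np.full(50, 40.0))
        with pytest.raises(ValueError, match="[Cc]rossing"):
            band_area(up, low, (0, 50))

    def test_area_additivity_telescopes(self, clean_scan):
        from octlayers.segment import segment_layers

        layers = segment_layers(clean_scan["denoised"])
        iv = (50, 400)
        total = band_area(layers.ipl, layers.ez, iv)
        parts = (band_area(layers.ipl, layers.opl_upper, iv)
                 + band_area(layers.opl_upper, layers.opl_lower, iv)
                 + band_area(layers.opl_lower, layers.ez, iv))
        assert parts == pytest.approx(total, rel=1e-6)


class TestPartitionZones:
    def test_spec_geometry_example(self):
        part = partition_zones((0, 619), 310, "horizontal", disc_side="right")
        assert part["fovea"] == (248, 372)
        assert part["fovea"][1] - part["fovea"][0] == round(0.2 * 619) == 124

    def test_nasal_is_on_disc_side(self):
        part = partition_zones((0, 619), 310, "horizontal", disc_side="right")
        assert part["Nasal"][0] > part["Temporal"][1] - 1  # nasal = right interval
        part = partition_zones((0, 619), 310, "horizontal", disc_side="left")
        assert part["Nasal"] == (0, 248)

    def test_vertical_superior_is_low_columns(self):
        part = partition_zones((0, 728), 364, "vertical")
        assert part["SUP"][0] == 0 and part["INF"][1] == 728

    def test_random_geometries_cover_domain(self):
        rng = np.random.default_rng(17)
        for _ in range(1000):
            start = int(rng.integers(0, 200))
            width = int(rng.integers(30, 1500))
            fovea = int(rng.integers(start, start + width))
            part = partition_zones((start, start + width), fovea, "vertical")
            spans = sorted(part.intervals.values())
            assert spans[0][0] == start and spans[-1][1] == start + width
            assert spans[0][1] == spans[1][0] and spans[1][1] == spans[2][0]
            fl, fh = part["fovea"]
            assert fh - fl == max(round(0.2 * width), 1)

    def test_edge_fovea_shifts_inward_with_flag(self):
        part = partition_zones((0, 500), 3, "vertical")
        assert part.shifted
        assert part["fovea"][0] >= 1

    def test_fovea_outside_domain_rejected(self):
        with pytest.raises(ValueError):
            partition_zones((0, 500), 600, "vertical")


class TestLocateFovea:
    def test_finds_generated_pit(self, clean_scan):
        from octlayers.segment import segment_layers

        tr, off = clean_scan["truth"], clean_scan["offset"]
        layers = segment_layers(clean_scan["denoised"])
        res = locate_fovea(layers, tr.orientation)
        assert abs(res.column + off - tr.fovea_col) <= 3
        assert not res.fallback

    def test_shifted_pit(self):
        x = np.arange(728, dtype=float)
        pit = 20 * np.exp(-0.5 * ((x - 250) / 50) ** 2)
        layers = LayerSet(
            curve(60 + pit, role="IPL"), curve(90 + pit, role="OPL_upper"),
            curve(100 + pit, role="OPL_lower"), curve(np.full(728, 160.0), role="EZ"))
        res = locate_fovea(layers, "horizontal")
        assert abs(res.column - 250) <= 3

    def test_flat_scan_falls_back_to_midpoint(self):
        layers = flat_layers(width=600)
        res = locate_fovea(layers, "horizontal")
        assert res.fallback and res.column == 300


class TestComputeRecord:
    def test_schema_has_18_biomarkers(self, clean_scan):
        from octlayers.segment import segment_layers

        tr = clean_scan["truth"]
        layers = segment_layers(clean_scan["denoised"])
        res = locate_fovea(layers, tr.orientation)
        part = partition_zones((0, layers.end), res.column, tr.orientation,
                               disc_side=clean_scan["covariates"]["disc_side"])
        rec = compute_record(layers, part, patient_id="p0", eye="OD",
                             group="normal", age=50, sex="M")
        assert len(rec.values) == 18
        assert "SI_IPL.H.fovea" in rec.values
        assert "SI_OPL_up.H.Nasal" in rec.values
        # SI of the lower OPL border is deliberately not reported
        assert not any(k.startswith("SI_OPL_low") for k in rec.values)
        for k, v in rec.values.items():
            if k.startswith("SI"):
                assert 0 < v <= 1
            else:
                assert v >= 0
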