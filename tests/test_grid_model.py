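"""Grid representation, classification and serialisation."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hegrid import (
    GlucosePair,
    GridSchemaError,
    RiskZone,
    is_false_negative,
    load_grid,
    save_grid,
)
from hegrid.grid import ClampWarning, RiskGrid

from .oracles import MGDL, clarke_zone_rules, parkes_zone_polylines


class TestClassification:
    @pytest.mark.parametrize(
        "smbg,cgm,expected",
        [
            (5.0, 5.0, {"A"}),          # identity in normoglycaemia: no risk
            (3.0, 6.0, {"B", "C"}),     # missed hypo is never no-risk, never severe
            (11.0, 11.0, None),         # extension carries the same lines
        ],
    )
    def test_heg_point_classification(self, heg, smbg, cgm, expected):
        zone = heg.classify(smbg, cgm)
        if expected is None:
            assert zone == heg.classify(9.9, 9.9)
        else:
            assert zone.name in expected

    def test_boundary_assigned_to_more_severe_zone(self, heg):
        # (4, 2) sits on the A/B false-positive boundary; (3.5, 8) on the
        # A/C edge of the false-negative column
        assert heg.classify(4.0, 2.0) == RiskZone.B
        assert heg.classify(3.5, 8.0) == RiskZone.C
        assert heg.classify(3.5, 3.5) >= RiskZone.B

    def test_clamp_above_ceiling_warns(self, heg):
        with pytest.warns(ClampWarning):
            zone = heg.classify(14.5, 14.5)
        assert zone == heg.classify(12.0, 12.0)

    @pytest.mark.parametrize("bad", [0.0, -1.0, float("nan"), float("inf")])
    def test_invalid_glucose_rejected(self, heg, bad):
        with pytest.raises(ValueError):
            heg.classify(bad, 5.0)

    @settings(max_examples=200, deadline=None)
    @given(
        st.floats(min_value=0.01, max_value=11.99),
        st.floats(min_value=0.01, max_value=11.99),
    )
    def test_every_domain_point_gets_exactly_one_zone(self, heg, smbg, cgm):
        zone = heg.classify(smbg, cgm)
        assert isinstance(zone, RiskZone)

    def test_tiling_bulk_sample(self, heg, clarke, parkes):
        rng = np.random.default_rng(42)
        for grid in (heg, clarke, parkes):
            (xlo, xhi), (ylo, yhi) = grid.domain
            x = rng.uniform(xlo + 1e-6, xhi, 10_000)
            y = rng.uniform(ylo + 1e-6, yhi, 10_000)
            zones = grid.classify_points(x, y)
            assert all(isinstance(z, RiskZone) for z in zones)


class TestHegSafetyProperties:
    def test_false_negative_cells_are_slight_or_moderate(self, heg):
        """Cells with SMBG < 3.5 and CGM >= 3.5 are B or C: never invisible
        (A), and the consensus never escalates them to severe (D)."""
        c = heg.cell_centres(0, 12)
        xx, yy = np.meshgrid(c, c, indexing="ij")
        mask = (xx < 3.5) & (yy >= 3.5)
        zones = heg.classify_points(xx[mask], yy[mask])
        names = {z.name for z in zones}
        assert names <= {"B", "C"}

    def test_severity_monotone_in_cgm_at_hypoglycaemia(self, heg):
        for smbg in (0.5, 1.7, 2.9, 3.1, 3.4):
            cgms = np.arange(smbg, 12.0, 0.05)
            zones = heg.classify_points(np.full_like(cgms, smbg), cgms)
            sev = np.array([int(z) for z in zones])
            assert (np.diff(sev) >= 0).all()

    def test_risk_constant_beyond_four(self, heg):
        for x in (0.7, 2.5, 3.2, 5.0, 9.0):
            ys = np.arange(4.05, 12.0, 0.1)
            zones = heg.classify_points(np.full_like(ys, x), ys)
            assert len({z for z in zones}) == 1

    def test_default_raster_is_100_by_100(self, heg):
        raster = heg.raster()
        assert raster.shape == (100, 100)
        assert raster.size == 10_000


class TestFalseNegativeFlag:
    @pytest.mark.parametrize(
        "smbg,cgm,thr,expected",
        [
            (3.0, 5.0, 3.5, True),
            (5.0, 3.0, 3.5, False),   # false positive, not negative
            (3.5, 5.0, 3.5, False),   # hypoglycaemia is strictly below threshold
            (3.4, 3.5, 3.5, True),    # CGM exactly at threshold still misses
        ],
    )
    def test_flag(self, smbg, cgm, thr, expected):
        assert is_false_negative(GlucosePair(smbg, cgm), thr) is expected

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            is_false_negative(GlucosePair(3.0, 5.0), 0.0)


class TestSerialisation:
    def test_round_trip_identical_at_all_cell_centres(self, heg, tmp_path):
        path = tmp_path / "heg.json"
        save_grid(heg, path)
        reloaded = load_grid(path)
        c = heg.cell_centres(0, 12)
        xx, yy = np.meshgrid(c, c, indexing="ij")
        za = heg.classify_points(xx.ravel(), yy.ravel())
        zb = reloaded.classify_points(xx.ravel(), yy.ravel())
        assert xx.size == 14_400
        assert all(a == b for a, b in zip(za, zb))

    def test_grid_with_hole_rejected_listing_cells(self, tmp_path):
        payload = {
            "name": "holey",
            "unit": "mmol/L",
            "domain": [[0, 2], [0, 2]],
            "zones": [
                {"label": "A", "polygon": [[0, 0], [2, 0], [2, 1], [0, 1], [0, 0]]},
                # upper half only partially covered
                {"label": "B", "polygon": [[0, 1], [1, 1], [1, 2], [0, 2], [0, 1]]},
            ],
        }
        path = tmp_path / "holey.json"
        path.write_text(json.dumps(payload))
        with pytest.raises(GridSchemaError, match="uncovered"):
            load_grid(path)

    def test_mgdl_grid_converted_on_load(self, clarke):
        assert clarke.unit == "mmol/L"
        point = 70.0 / MGDL
        assert clarke.classify(point, point) == RiskZone.A

    def test_unknown_unit_rejected(self, tmp_path):
        payload = {"name": "x", "unit": "lb/gal", "domain": [[0, 1], [0, 1]],
                   "zones": [{"label": "A", "polygon": [[0, 0], [1, 0], [1, 1], [0, 1]]}]}
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(payload))
        with pytest.raises((GridSchemaError, ValueError)):
            load_grid(path)


class TestLegacyGridsAgainstPublishedDefinitions:
    """The bundled Clarke/Parkes polygons must reproduce the published zone
    assignments; oracles are independent (rule set / polyline interpolation)."""

    def test_clarke_matches_rule_oracle(self, clarke):
        rng = np.random.default_rng(7)
        ref = rng.uniform(5, 395, 400)
        pred = rng.uniform(5, 395, 400)
        for r, p in zip(ref, pred):
            # skip points within 1 mg/dL of a rule boundary, where the
            # severity tie-break may legitimately differ
            nbhd = {
                clarke_zone_rules(r + dr, p + dp)
                for dr in (-1.0, 0.0, 1.0)
                for dp in (-1.0, 0.0, 1.0)
            }
            if len(nbhd) > 1:
                continue
            got = clarke.classify(r / MGDL, p / MGDL)
            assert got.name == clarke_zone_rules(r, p), (r, p)

    def test_parkes_matches_polyline_oracle(self, parkes):
        rng = np.random.default_rng(11)
        ref = rng.uniform(5, 545, 400)
        pred = rng.uniform(5, 545, 400)
        for r, p in zip(ref, pred):
            nbhd = {
                parkes_zone_polylines(r + dr, p + dp)
                for dr in (-1.5, 0.0, 1.5)
                for dp in (-1.5, 0.0, 1.5)
            }
            if len(nbhd) > 1:
                continue
            got = parkes.classify(r / MGDL, p / MGDL)
            assert got.name == parkes_zone_polylines(r, p), (r, p)

    @pytest.mark.parametrize("mgdl", [40, 70, 100, 180, 250, 380])
    def test_identity_line_is_zone_a(self, clarke, parkes, mgdl):
        v = mgdl / MGDL
        assert clarke.classify(v, v) == RiskZone.A
        assert parkes.classify(v, v) == RiskZone.A
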