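"""Geometric model: layer radii, positional addresses, wedge regions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scst.geometry import (
    EmbryoModelConfig,
    GeometryError,
    AddressError,
    PositionRegion,
    address_coordinates,
    build_geometry,
    enumerate_addresses,
    expanded_layer_regions,
    region_for_address,
)


class TestLayerRadii:
    def test_published_late_gastrula_radii(self, e75_config):
        """Outer diameter 9 with two 1.2 ratios gives the printed ring radii."""
        geom = build_geometry(e75_config)
        assert geom.radii["endoderm"] == 4.5
        assert geom.radii["mesoderm"] == 3.75
        assert geom.radii["endoderm"] / geom.radii["mesoderm"] == pytest.approx(1.2)

    def test_unit_ratios_identity(self):
        config = EmbryoModelConfig(
            stage="S",
            proximal_distal_length=2.0,
            n_sections=2,
            layer_diameters={"ectoderm": 2.0},
            sector_schemes={"ectoderm": [("P", 0.0)]},
        )
        assert build_geometry(config).radii["ectoderm"] == 1.0

    @given(
        outer=st.floats(1.0, 50.0),
        r1=st.floats(1.05, 3.0),
        r2=st.floats(1.05, 3.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_radii_equal_diameter_chain(self, outer, r1, r2):
        """Radii derived from ratio form equal the direct half-diameter chain."""
        config = EmbryoModelConfig.from_ratios(
            "S", 5.0, outer, r1, r2, 3, {"ectoderm": [("P", 0.0)]}
        )
        geom = build_geometry(config)
        assert geom.radii["endoderm"] == pytest.approx(outer / 2.0)
        assert geom.radii["mesoderm"] == pytest.approx(outer / r1 / 2.0)
        assert geom.radii["ectoderm"] == pytest.approx(outer / r1 / r2 / 2.0)

    def test_invalid_configs_rejected(self):
        with pytest.raises(GeometryError):
            EmbryoModelConfig(
                stage="S", proximal_distal_length=-1.0, n_sections=2,
                layer_diameters={"ectoderm": 2.0},
                sector_schemes={"ectoderm": [("P", 0.0)]},
            )
        with pytest.raises(GeometryError):
            EmbryoModelConfig.from_ratios("S", 5.0, 5.0, -1.2, 1.2, 3,
                                          {"ectoderm": [("P", 0.0)]})
        # non-nesting radii
        with pytest.raises(GeometryError):
            build_geometry(
                EmbryoModelConfig(
                    stage="S", proximal_distal_length=5.0, n_sections=2,
                    layer_diameters={"ectoderm": 4.0, "mesoderm": 3.0, "endoderm": 5.0},
                    sector_schemes={"ectoderm": [("P", 0.0)]},
                )
            )


class TestAddressCoordinates:
    @pytest.mark.parametrize(
        "section,sector,expected",
        [
            (9, "MA", (-3.75, 0.0, 9.0)),
            (9, "EP", (4.5, 0.0, 9.0)),
            (9, "EA", (-4.5, 0.0, 9.0)),
            (9, "A", (-3.0, 0.0, 9.0)),
        ],
    )
    def test_printed_section9_addresses(self, e75_config, section, sector, expected):
        addr = address_coordinates(e75_config, section, sector)
        assert addr.coordinate == pytest.approx(expected)

    def test_midline_sectors_on_axis(self, e75_config):
        for sector in ["A", "P", "MA", "MP", "EA", "EP"]:
            addr = address_coordinates(e75_config, 5, sector)
            assert addr.coordinate[1] == 0.0

    def test_left_right_symmetry(self, e75_config):
        r1 = address_coordinates(e75_config, 9, "R1").coordinate
        l1 = address_coordinates(e75_config, 9, "L1").coordinate
        assert r1[0] == pytest.approx(l1[0])
        assert r1[1] == pytest.approx(-l1[1])
        assert r1[1] > 0  # right side on positive y

    def test_unknown_sector_raises(self, e75_config):
        with pytest.raises(AddressError):
            address_coordinates(e75_config, 5, "XX")
        with pytest.raises(AddressError):
            address_coordinates(e75_config, 1, "MA")  # mesoderm absent at the tip


class TestRegions:
    def test_printed_section8_posterior_z_interval(self, e75_config):
        addr = address_coordinates(e75_config, 8, "P")
        region = region_for_address(e75_config, addr)
        assert (region.z_lo, region.z_hi) == (7.5, 8.5)

    def test_one_sector_ring_full_circle(self):
        config = EmbryoModelConfig(
            stage="S", proximal_distal_length=3.0, n_sections=3,
            layer_diameters={"ectoderm": 2.0},
            sector_schemes={"ectoderm": [("C", 0.0)]},
            ectoderm_inner_radius=0.0,
        )
        region = region_for_address(config, address_coordinates(config, 2, "C"))
        assert region.is_full_circle

    def test_every_address_inside_its_region(self, e75_config):
        for addr in enumerate_addresses(e75_config):
            region = region_for_address(e75_config, addr)
            assert region.contains(addr.coordinate), addr

    def test_layer_nesting(self, e75_config):
        ect = region_for_address(e75_config, address_coordinates(e75_config, 5, "P"))
        mes = region_for_address(e75_config, address_coordinates(e75_config, 5, "MP"))
        end = region_for_address(e75_config, address_coordinates(e75_config, 5, "EP"))
        assert ect.r_outer == mes.r_inner
        assert mes.r_outer == end.r_inner
        assert ect.r_inner < mes.r_inner < mes.r_outer < end.r_outer

    def test_sector_wedges_partition_the_ring(self, e75_config):
        """Wedges of one ring are disjoint and jointly cover the annulus."""
        regions = [
            region_for_address(e75_config, address_coordinates(e75_config, 5, s))
            for s in ["P", "R2", "R1", "A", "L1", "L2"]
        ]
        widths = [r.theta_width for r in regions]
        assert sum(widths) == pytest.approx(2.0 * math.pi)
        rng = np.random.default_rng(0)
        r = regions[0]
        for _ in range(300):
            theta = rng.uniform(-math.pi, math.pi)
            rad = rng.uniform(r.r_inner + 1e-6, r.r_outer - 1e-6)
            p = (rad * math.cos(theta), rad * math.sin(theta), 5.0)
            hits = sum(reg.contains(p, tol=0.0) for reg in regions)
            assert hits >= 1  # cover
            assert sum(reg.contains(p, tol=-1e-9) for reg in regions) <= 1  # disjoint interiors

    def test_pole_region_is_disc(self, e75_config):
        addr = address_coordinates(e75_config, 1, "T")
        region = region_for_address(e75_config, addr)
        assert region.r_inner == 0.0 and region.is_full_circle
        assert region.contains((0.0, 0.0, 1.0))


class TestExpandedLayers:
    def test_full_extent_matches_single_sector_ring(self):
        config = EmbryoModelConfig(
            stage="S", proximal_distal_length=4.0, n_sections=4,
            layer_diameters={"ectoderm": 2.0, "mesoderm": 3.0},
            sector_schemes={"ectoderm": [("P", 0.0)], "mesoderm": [("M", 0.0)]},
        )
        expanded = expanded_layer_regions(config, "mesoderm", {2: 1.0})
        direct = region_for_address(config, address_coordinates(config, 2, "M"))
        assert expanded[2].r_inner == direct.r_inner
        assert expanded[2].r_outer == direct.r_outer
        assert expanded[2].is_full_circle and direct.is_full_circle

    def test_half_extent_is_pi_wide(self, e75_config):
        regions = expanded_layer_regions(e75_config, "mesoderm", {3: 0.5})
        assert regions[3].theta_width == pytest.approx(math.pi)

    def test_monotone_extents_give_monotone_widths(self, e75_config):
        extents = {s: 0.2 + 0.1 * s for s in range(2, 8)}
        regions = expanded_layer_regions(e75_config, "mesoderm", extents)
        widths = [regions[s].theta_width for s in sorted(extents)]
        assert all(a < b for a, b in zip(widths, widths[1:]))

    def test_extent_out_of_range_rejected(self, e75_config):
        with pytest.raises(GeometryError):
            expanded_layer_regions(e75_config, "mesoderm", {3: 0.0})
        with pytest.raises(GeometryError):
            expanded_layer_regions(e75_config, "mesoderm", {3: 1.5})


class TestRegionGeometryHelpers:
    @pytest.mark.parametrize(
        "region",
        [
            PositionRegion(1.0, 2.0, 0.3, math.pi / 3, 0.0, 1.0),
            PositionRegion(0.5, 3.0, -1.2, math.pi / 2, 2.0, 4.0),
            PositionRegion(1.0, 2.0, 0.0, 2 * math.pi, 0.0, 1.0),
            PositionRegion(2.0, 2.5, 1.0, 1.5 * math.pi, 0.0, 0.5),
        ],
    )
    def test_max_chord_matches_sampled_diameter(self, region):
        """Analytic max chord bounds (and nearly attains) the sampled one."""
        rng = np.random.default_rng(1)
        pts = region.sample(1200, rng)
        p, q = region.max_chord_endpoints()
        assert region.contains(p) and region.contains(q)
        analytic = region.max_chord()
        assert np.linalg.norm(p - q) == pytest.approx(analytic, rel=1e-9)
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2).max()
        assert d <= analytic + 1e-9
        assert d >= 0.9 * analytic

    def test_clamp_projects_into_region(self):
        region = PositionRegion(1.0, 2.0, 0.0, math.pi / 3, 4.5, 5.5)
        rng = np.random.default_rng(2)
        for _ in range(200):
            p = rng.uniform(-5, 5, 3)
            assert region.contains(region.clamp(p))

    def test_clamp_is_identity_inside(self):
        region = PositionRegion(1.0, 2.0, 0.5, math.pi / 2, 0.0, 1.0)
        inside = region.sample(50, np.random.default_rng(3))
        for p in inside:
            assert np.allclose(region.clamp(p), p)


def test_config_json_round_trip(e75_config):
    restored = EmbryoModelConfig.from_json(e75_config.to_json())
    assert restored.layer_diameters == dict(e75_config.layer_diameters)
    assert [a.coordinate for a in enumerate_addresses(restored)] == [
        a.coordinate for a in enumerate_addresses(e75_config)
    ]


def test_address_count_matches_published_design(e75_config):
    assert len(enumerate_addresses(e75_config)) == 81
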