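"""Packed-bed layout generation and wall-shear estimates."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial import distance_matrix

from bioflow import chamber
from bioflow.chamber import (
    ChannelFlow,
    DegenerateLayoutError,
    ObliquePlaneError,
    cross_section,
    pack_spheres,
    perturb_radii,
    scale_to_physical,
    wall_shear_stress,
)


def brute_force_fcc_sites(n_cells: int) -> int:
    """Independent FCC enumeration: corners + face centres of each cell, deduplicated."""
    sites = set()
    corners = [(i, j, k) for i in (0, 1) for j in (0, 1) for k in (0, 1)]
    faces = [
        (0.5, 0.5, 0), (0.5, 0.5, 1),
        (0.5, 0, 0.5), (0.5, 1, 0.5),
        (0, 0.5, 0.5), (1, 0.5, 0.5),
    ]
    for i in range(n_cells):
        for j in range(n_cells):
            for k in range(n_cells):
                for dx, dy, dz in corners + faces:
                    sites.add((round(2 * (i + dx)), round(2 * (j + dy)), round(2 * (k + dz))))
    return len(sites)


class TestPackSpheres:
    def test_touching_unit_spheres(self):
        bed = pack_spheres(2)
        d = distance_matrix(bed.centers, bed.centers)
        np.fill_diagonal(d, np.inf)
        nn = d.min(axis=1)
        assert np.allclose(nn, 2.0)
        assert np.all(bed.radii == 1.0)

    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_count_matches_independent_enumeration(self, n):
        assert pack_spheres(n).n_spheres == brute_force_fcc_sites(n)

    def test_rejects_tiny_bed(self):
        with pytest.raises(ValueError):
            pack_spheres(1)


class TestPerturbRadii:
    def test_identity_when_range_collapses(self):
        bed = perturb_radii(pack_spheres(3), r_min=1.0, r_max=1.0, seed=0)
        assert np.all(bed.radii == 1.0)

    def test_bounds_and_mean_of_large_sample(self):
        bed = pack_spheres(14)  # > 10^4 spheres
        assert bed.n_spheres >= 10_000
        pert = perturb_radii(bed, seed=42)
        assert pert.radii.min() >= 0.4
        assert pert.radii.max() <= 1.0
        # Uniform(0.4, 1.0): mean 0.7, sd 0.6/sqrt(12).
        se = 0.6 / np.sqrt(12) / np.sqrt(pert.n_spheres)
        assert abs(pert.radii.mean() - 0.7) < 3 * se

    def test_centers_unchanged(self):
        bed = pack_spheres(3)
        pert = perturb_radii(bed, seed=1)
        assert np.array_equal(bed.centers, pert.centers)

    def test_invalid_range(self):
        with pytest.raises(ValueError):
            perturb_radii(pack_spheres(2), r_min=0.9, r_max=0.5)


class TestCrossSection:
    def _single_sphere(self, r=1.0):
        return chamber.PackedBed(
            centers=np.zeros((1, 3)), radii=np.array([r]), arrangement="fcc"
        )

    def test_great_circle(self):
        circ = cross_section(self._single_sphere(), (1.0, 0.37, 0.22), 0.0)
        assert len(circ) == 1
        assert circ[0, 2] == pytest.approx(1.0)

    def test_offset_plane_chord(self):
        n = np.array([1.0, 0.37, 0.22])
        n = n / np.linalg.norm(n)
        circ = cross_section(self._single_sphere(), n, 0.6)
        assert circ[0, 2] == pytest.approx(0.8)  # sqrt(1 - 0.36)

    def test_missing_sphere_omitted(self):
        n = np.array([1.0, 0.37, 0.22])
        n = n / np.linalg.norm(n)
        assert len(cross_section(self._single_sphere(), n, 1.5)) == 0

    @pytest.mark.parametrize("normal", [(1, 0, 0), (1, 1, 0), (1, 1, 1), (0, 1.01, 1)])
    def test_symmetry_plane_rejected(self, normal):
        with pytest.raises(ObliquePlaneError):
            cross_section(pack_spheres(2), normal, 0.0)

    def test_zero_normal_rejected(self):
        with pytest.raises(ValueError):
            cross_section(pack_spheres(2), (0, 0, 0), 0.0)

    @settings(max_examples=25, deadline=None)
    @given(offset=st.floats(-3.0, 3.0), seed=st.integers(0, 100))
    def test_circle_radii_never_exceed_sphere_radii(self, offset, seed):
        bed = perturb_radii(pack_spheres(2), seed=seed)
        circ = cross_section(bed, chamber.DEFAULT_PLANE_NORMAL, offset)
        if len(circ):
            assert circ[:, 2].max() <= bed.radii.max() + 1e-12


class TestScaleToPhysical:
    def test_linear_anchor(self):
        circles = np.array([[0.0, 0.0, 0.5], [10.0, 0.0, 1.0], [5.0, 8.0, 0.9]])
        layout = scale_to_physical(circles, 5000.0, 5000.0)
        assert layout.radii.max() == pytest.approx(200.0)
        assert sorted(np.round(layout.radii)) == [100.0, 180.0, 200.0]

    def test_filters_small_and_outside(self):
        circles = np.array(
            [[0.0, 0.0, 1.0], [5.0, 0.0, 0.39], [10.0, 0.0, 0.8], [5.0, 8.0, 0.6]]
        )
        layout = scale_to_physical(circles, 5000.0, 5000.0)
        assert np.all(layout.radii >= 80.0)
        assert np.all(layout.radii <= 200.0)
        assert layout.n_columns == 3  # the 0.39 circle scales below the cutoff

    def test_degenerate_layout_raises(self):
        circles = np.array([[0.0, 0.0, 1.0], [1.0, 0.0, 0.1], [2.0, 0.0, 0.1]])
        with pytest.raises(DegenerateLayoutError):
            scale_to_physical(circles, 5000.0, 5000.0)

    def test_overlaps_resolved_with_gap(self):
        # Two circles overlapping after perturbation: smaller one shrinks.
        circles = np.array([[0.0, 0.0, 1.0], [1.5, 0.0, 0.9], [0.0, 6.0, 0.95]])
        layout = scale_to_physical(circles, 6000.0, 6000.0)
        c = layout.columns
        for i in range(len(c)):
            for j in range(i + 1, len(c)):
                d = np.hypot(c[i, 0] - c[j, 0], c[i, 1] - c[j, 1])
                assert d >= c[i, 2] + c[j, 2] + 5.0 - 1e-6


class TestWallShear:
    def test_zero_speed_zero_shear(self):
        assert wall_shear_stress(ChannelFlow(mean_speed=0.0)) == 0.0

    def test_hand_computed_value(self):
        # 6 * 1e-3 Pa s * 175 um/s / 75 um = 0.014 Pa
        flow = ChannelFlow(mean_speed=175.0, viscosity=1e-3, height=75.0)
        assert wall_shear_stress(flow) == pytest.approx(0.014)

    def test_linear_in_speed(self):
        t1 = wall_shear_stress(ChannelFlow(mean_speed=100.0))
        t2 = wall_shear_stress(ChannelFlow(mean_speed=200.0))
        assert t2 == pytest.approx(2 * t1)

    def test_duct_series_agrees_with_parallel_plates_when_wide(self):
        # Side-wall drag vanishes as W/H grows; at W/H = 100 the
        # pressure-drop route and 6*alpha*U/H agree within 1%.
        plate = ChannelFlow(mean_speed=150.0, height=75.0, width=7500.0)
        duct = ChannelFlow(
            mean_speed=150.0, height=75.0, width=7500.0, model="rectangular_duct"
        )
        assert duct.wall_shear == pytest.approx(plate.wall_shear, rel=0.01)

    def test_duct_exceeds_plate_shear_in_narrow_channels(self):
        plate = ChannelFlow(mean_speed=150.0, height=75.0, width=750.0)
        duct = ChannelFlow(
            mean_speed=150.0, height=75.0, width=750.0, model="rectangular_duct"
        )
        assert duct.wall_shear > plate.wall_shear

    def test_invalid_geometry(self):
        with pytest.raises(ValueError):
            ChannelFlow(mean_speed=10.0, height=0.0)
        with pytest.raises(ValueError):
            ChannelFlow(mean_speed=10.0, viscosity=-1.0)


class TestGenerateSoilLayout:
    def test_radii_in_design_range(self, soil_layout):
        assert np.all(soil_layout.radii >= 80.0)
        assert np.all(soil_layout.radii <= 200.0)

    def test_columns_inside_chamber(self, soil_layout):
        c = soil_layout.columns
        assert np.all(c[:, 0] - c[:, 2] >= 0)
        assert np.all(c[:, 0] + c[:, 2] <= soil_layout.width)
        assert np.all(c[:, 1] - c[:, 2] >= 0)
        assert np.all(c[:, 1] + c[:, 2] <= soil_layout.height)

    def test_bit_reproducible(self):
        a = chamber.generate_soil_layout(seed=5)
        b = chamber.generate_soil_layout(seed=5)
        assert np.array_equal(a.columns, b.columns)

    def test_seeds_differ(self):
        a = chamber.generate_soil_layout(seed=5)
        b = chamber.generate_soil_layout(seed=6)
        assert not np.array_equal(a.columns, b.columns)
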