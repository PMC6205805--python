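"""Sphere-pack generation and projection: counts, union semantics, transmission."""

import io
import math

import numpy as np
import pytest

from darkfield import (
    MaterialOptics,
    SpherePack,
    generate_sphere_pack,
    make_grid,
    object_transmission,
    plan_sphere_count,
    project_air_path,
    project_chord_sum,
    sphere_volume,
)
from darkfield.phantom import ProjectedObject

from conftest import MURINE_AIR, MURINE_TISSUE, make_pack, voxel_air_path


class TestPlanSphereCount:
    @pytest.mark.parametrize(
        "pixel, thickness, diameter, expected",
        [
            # murine: per 100 um pixel per 1.8 mm of lung
            (100e-6, 1.8e-3, 39e-6, 325),
            (100e-6, 1.8e-3, 60e-6, 89),
            (100e-6, 1.8e-3, 80e-6, 38),
            # human: per 150 um pixel per 25 mm of lung
            (150e-6, 25e-3, 200e-6, 75),
            (150e-6, 25e-3, 300e-6, 22),
            (150e-6, 25e-3, 400e-6, 9),
        ],
    )
    def test_printed_per_pixel_counts(self, pixel, thickness, diameter, expected):
        assert plan_sphere_count(pixel**2, thickness, diameter, 0.56) == expected

    def test_zero_fraction_gives_zero(self):
        assert plan_sphere_count(1e-8, 1e-3, 50e-6, 0.0) == 0

    def test_count_is_nominal_sum_of_volumes(self):
        area, t, s, f = 1e-8, 2e-3, 40e-6, 0.3
        assert plan_sphere_count(area, t, s, f) == round(f * area * t / sphere_volume(s))

    @pytest.mark.parametrize("bad", [(-1e-8, 1e-3, 5e-6), (1e-8, 0, 5e-6), (1e-8, 1e-3, -5e-6)])
    def test_nonpositive_arguments_rejected(self, bad):
        with pytest.raises(ValueError):
            plan_sphere_count(bad[0], bad[1], bad[2], 0.5)

    def test_fraction_of_one_rejected(self):
        with pytest.raises(ValueError):
            plan_sphere_count(1e-8, 1e-3, 5e-6, 1.0)


class TestGenerateSpherePack:
    def test_same_seed_identical(self, murine_desk_geometry):
        a = generate_sphere_pack(murine_desk_geometry, 60e-6, 1.8e-3, seed=7)
        b = generate_sphere_pack(murine_desk_geometry, 60e-6, 1.8e-3, seed=7)
        np.testing.assert_array_equal(a.centers, b.centers)

    def test_different_seed_differs(self, murine_desk_geometry):
        a = generate_sphere_pack(murine_desk_geometry, 60e-6, 1.8e-3, seed=7)
        b = generate_sphere_pack(murine_desk_geometry, 60e-6, 1.8e-3, seed=8)
        assert not np.array_equal(a.centers, b.centers)

    def test_count_scales_with_extent(self, murine_desk_geometry):
        """Density matches the printed per-pixel convention: 89 spheres of
        60 um per 100 um pixel per 1.8 mm."""
        pack = generate_sphere_pack(murine_desk_geometry, 60e-6, 1.8e-3, seed=0)
        (x0, x1), (y0, y1) = pack.lateral_extent
        area = (x1 - x0) * (y1 - y0)
        assert len(pack) == plan_sphere_count(area, 1.8e-3, 60e-6, 0.56)
        per_pixel = len(pack) * (100e-6) ** 2 / area
        assert per_pixel == pytest.approx(89, rel=0.02)

    def test_extent_covers_grid_plus_margin(self, murine_desk_geometry):
        grid = make_grid(murine_desk_geometry)
        pack = generate_sphere_pack(murine_desk_geometry, 80e-6, 1.8e-3, seed=0)
        (x0, x1), _ = pack.lateral_extent
        assert x0 <= -80e-6 and x1 >= grid.extent_x + 80e-6

    def test_centres_inside_slab(self, murine_desk_geometry):
        pack = generate_sphere_pack(murine_desk_geometry, 60e-6, 1.8e-3, seed=3)
        assert pack.centers[:, 2].min() >= 0
        assert pack.centers[:, 2].max() <= 1.8e-3

    def test_csv_round_trip(self, murine_desk_geometry, tmp_path):
        pack = generate_sphere_pack(murine_desk_geometry, 60e-6, 1.8e-3, seed=11)
        path = tmp_path / "pack.csv"
        pack.to_csv(path)
        back = SpherePack.from_csv(path)
        np.testing.assert_allclose(back.centers, pack.centers)
        assert back.diameter == pack.diameter
        assert back.seed == pack.seed
        assert back.lateral_extent == pack.lateral_extent


class TestProjection:
    def test_single_sphere_central_chord(self):
        S = 60e-6
        pack = make_pack([[0.0, 0.0, 100e-6]], S, 200e-6)
        proj = project_air_path(pack, 1e-6, (1, 1), origin=(0.0, 0.0))
        assert proj.air_path[0, 0] == pytest.approx(S, rel=1e-12)

    def test_union_idempotent_for_coincident_spheres(self):
        S = 60e-6
        one = make_pack([[0.0, 0.0, 100e-6]], S, 200e-6)
        two = make_pack([[0.0, 0.0, 100e-6]] * 2, S, 200e-6)
        shape, dx = (21, 21), 5e-6
        origin = (-50e-6, -50e-6)
        a = project_air_path(one, dx, shape, origin).air_path
        b = project_air_path(two, dx, shape, origin).air_path
        np.testing.assert_allclose(a, b, atol=1e-18)

    def test_additive_double_counts_coincident_spheres(self):
        S = 60e-6
        one = make_pack([[0.0, 0.0, 100e-6]], S, 200e-6)
        two = make_pack([[0.0, 0.0, 100e-6]] * 2, S, 200e-6)
        a = project_chord_sum(one, 5e-6, (5, 5), (-10e-6, -10e-6)).air_path
        b = project_chord_sum(two, 5e-6, (5, 5), (-10e-6, -10e-6)).air_path
        np.testing.assert_allclose(b, 2 * a, atol=1e-18)

    def test_union_order_independent(self):
        rng = np.random.default_rng(5)
        centers = np.column_stack(
            [
                rng.uniform(-100e-6, 100e-6, 40),
                rng.uniform(-100e-6, 100e-6, 40),
                rng.uniform(0, 300e-6, 40),
            ]
        )
        S, t = 50e-6, 300e-6
        base = make_pack(centers, S, t)
        shuffled = make_pack(centers[rng.permutation(40)], S, t)
        shape, dx, origin = (30, 30), 5e-6, (-75e-6, -75e-6)
        np.testing.assert_allclose(
            project_air_path(base, dx, shape, origin).air_path,
            project_air_path(shuffled, dx, shape, origin).air_path,
            rtol=0,
            atol=1e-18,
        )

    def test_union_matches_voxel_oracle(self):
        """Exact interval merge vs brute-force z marching at step S/200."""
        rng = np.random.default_rng(17)
        n, S, t = 50, 50e-6, 150e-6
        centers = np.column_stack(
            [
                rng.uniform(-80e-6, 80e-6, n),
                rng.uniform(-80e-6, 80e-6, n),
                rng.uniform(0, t, n),
            ]
        )
        pack = make_pack(centers, S, t)
        dx = 8e-6
        xs = np.arange(-40e-6, 40e-6, dx)
        ys = np.arange(-40e-6, 40e-6, dx)
        exact = project_air_path(pack, dx, (len(ys), len(xs)), (xs[0], ys[0])).air_path
        dz = S / 200
        oracle = voxel_air_path(pack, xs, ys, dz)
        # every chord edge can be off by at most one marching step; a ray
        # meets only a handful of spheres at this density
        assert np.max(np.abs(exact - oracle)) <= 10 * dz

    def test_union_bounded_by_thickness_additive_not(self, murine_desk_geometry):
        grid = make_grid(murine_desk_geometry)
        t = 1.8e-3
        pack = generate_sphere_pack(murine_desk_geometry, 60e-6, t, seed=2, grid=grid)
        shape = (64, 64)
        union = project_air_path(pack, grid.spacing, shape).air_path
        add = project_chord_sum(pack, grid.spacing, shape).air_path
        assert union.max() <= t * (1 + 1e-12)
        assert np.all(add >= union - 1e-18)

    def test_chords_clipped_to_slab_faces(self):
        """A sphere protruding beyond the slab contributes only its inside part."""
        S, t = 100e-6, 60e-6
        pack = make_pack([[0.0, 0.0, 0.0]], S, t)  # centre on the entrance face
        chord = project_air_path(pack, 1e-6, (1, 1)).air_path[0, 0]
        assert chord == pytest.approx(S / 2, rel=1e-12)

    def test_empty_pack_projects_to_zero(self):
        pack = make_pack(np.empty((0, 3)), 60e-6, 1e-3)
        assert not project_air_path(pack, 1e-6, (4, 4)).air_path.any()
        assert not project_chord_sum(pack, 1e-6, (4, 4)).air_path.any()

    def test_realized_union_fraction_below_nominal(self, murine_desk_geometry):
        grid = make_grid(murine_desk_geometry)
        pack = generate_sphere_pack(murine_desk_geometry, 60e-6, 5.4e-3, seed=9, grid=grid)
        proj = project_air_path(pack, grid.spacing, (grid.ny, grid.nx))
        # Boolean model: union fraction 1 - exp(-f) for nominal f
        assert proj.realized_air_fraction < 0.56
        assert proj.realized_air_fraction == pytest.approx(1 - math.exp(-0.56), abs=0.02)

    def test_mean_air_path_stable_across_seeds(self, murine_desk_geometry):
        means = []
        for seed in range(10):
            pack = generate_sphere_pack(murine_desk_geometry, 60e-6, 1.8e-3, seed=seed)
            proj = project_chord_sum(pack, 2.5e-6, (80, 80))
            means.append(proj.air_path.mean())
        assert np.std(means) / np.mean(means) < 0.05


class TestObjectTransmission:
    def test_zero_thickness_is_unity(self):
        proj = ProjectedObject(np.zeros((4, 4)), 1e-6, 0.0)
        out = object_transmission(proj, MURINE_TISSUE, MURINE_AIR, 4.476e-11)
        np.testing.assert_allclose(out, 1.0)

    def test_pure_tissue_magnitude_closed_form(self):
        t, lam = 1.8e-3, 4.476e-11
        proj = ProjectedObject(np.zeros((2, 2)), 1e-6, t)
        out = object_transmission(proj, MURINE_TISSUE, MURINE_AIR, lam)
        expected = math.exp(-2 * math.pi * 1.78e-10 * t / lam)
        np.testing.assert_allclose(np.abs(out), expected, rtol=1e-12)

    def test_doubling_thickness_squares_transmission(self):
        lam = 4.476e-11
        one = object_transmission(
            ProjectedObject(np.zeros((1, 1)), 1e-6, 1e-3), MURINE_TISSUE, MURINE_AIR, lam
        )
        two = object_transmission(
            ProjectedObject(np.zeros((1, 1)), 1e-6, 2e-3), MURINE_TISSUE, MURINE_AIR, lam
        )
        np.testing.assert_allclose(two, one**2, rtol=1e-12)

    def test_magnitude_bounded_by_one(self, murine_desk_geometry):
        grid = make_grid(murine_desk_geometry)
        pack = generate_sphere_pack(murine_desk_geometry, 60e-6, 1.8e-3, seed=1, grid=grid)
        proj = project_air_path(pack, grid.spacing, (128, 128))
        out = object_transmission(proj, MURINE_TISSUE, MURINE_AIR, 4.476e-11)
        assert np.abs(out).max() <= 1.0 + 1e-12

    def test_union_air_exceeding_slab_rejected(self):
        with pytest.raises(ValueError):
            ProjectedObject(np.full((2, 2), 2e-3), 1e-6, 1e-3, method="union")

    def test_material_validation(self):
        with pytest.raises(ValueError):
            MaterialOptics(delta=-1e-9, beta=0.0)
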