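"""Flow statistics: vorticity, streamlines, residence times, asymmetry."""

import numpy as np
import pytest

from coralflow.analysis import (
    ResidenceStats,
    Streamline,
    asymmetry_differences,
    axial_decomposition,
    coral_regions,
    residence_time,
    seed_particles,
    trace_streamlines,
    volume_flux,
    vorticity_enstrophy,
)
from coralflow.geometry import EXTERNAL_PORE, RegionSelection, VoxelGeometry
from coralflow.lbm import FlowField


def make_field(shape, velocity_fn, spacing=1.0, solid=None):
    nx, ny, nz = shape
    X, Y, Z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                          indexing="ij")
    vel = np.stack(velocity_fn(X * spacing, Y * spacing, Z * spacing), axis=-1)
    solid = np.zeros(shape, bool) if solid is None else solid
    vel[solid] = 0.0
    return FlowField(velocity=vel.astype(float),
                     density=np.ones(shape), pressure=np.zeros(shape),
                     spacing=spacing, solid=solid)


def open_geometry(shape, spacing=1.0):
    return VoxelGeometry(labels=np.full(shape, EXTERNAL_PORE, np.uint8),
                         spacing=spacing)


class TestVorticityEnstrophy:
    def test_uniform_flow_has_none(self):
        f = make_field((8, 8, 8), lambda x, y, z: (np.full_like(x, 2.0, float),
                                                   np.zeros_like(x, float),
                                                   np.zeros_like(x, float)))
        omega, ens = vorticity_enstrophy(f)
        assert np.allclose(omega, 0) and np.allclose(ens, 0)

    def test_rigid_rotation(self):
        """u = (-O y, O x, 0) has omega = (0,0,2O), E = 2 O^2 exactly."""
        O = 0.3
        f = make_field((10, 10, 6), lambda x, y, z: (-O * y, O * x,
                                                     np.zeros_like(x, float)))
        omega, ens = vorticity_enstrophy(f)
        interior = (slice(1, -1),) * 3
        assert np.allclose(omega[interior + (2,)], 2 * O)
        assert np.allclose(ens[interior], 2 * O**2)

    def test_simple_shear(self):
        g = 0.5
        f = make_field((8, 8, 8), lambda x, y, z: (g * z, np.zeros_like(x, float),
                                                   np.zeros_like(x, float)))
        _, ens = vorticity_enstrophy(f)
        assert np.allclose(ens[1:-1, 1:-1, 1:-1], g**2 / 2)

    def test_spacing_scales_gradients(self):
        g = 0.5
        f = make_field((8, 8, 8), lambda x, y, z: (g * z, np.zeros_like(x, float),
                                                   np.zeros_like(x, float)),
                       spacing=0.5)
        _, ens = vorticity_enstrophy(f)
        assert np.allclose(ens[1:-1, 1:-1, 1:-1], g**2 / 2)


class TestSeedParticles:
    def test_single_pore_voxel_returns_its_centre(self):
        labels = np.zeros((5, 5, 5), np.uint8)
        labels[2, 3, 1] = EXTERNAL_PORE
        g = VoxelGeometry(labels=labels)
        region = RegionSelection("one", box=((0, 5), (0, 5), (0, 5)))
        pts = seed_particles(region, g, n=1, radius=0.4, seed=0)
        assert pts.shape == (1, 3)
        assert np.all(pts.astype(int) == [2, 3, 1])

    def test_empirical_centroid_near_sphere_centre(self):
        g = open_geometry((40, 40, 40))
        region = RegionSelection("all", box=((0, 40), (0, 40), (0, 40)))
        n, radius = 10_000, 10.0
        pts = seed_particles(region, g, n=n, radius=radius, seed=1)
        # uniform ball: sd of each coordinate is r/sqrt(5)
        sigma = radius / np.sqrt(5) / np.sqrt(n)
        assert np.all(np.abs(pts.mean(axis=0) - 20.0) < 3 * sigma + 1e-9)

    def test_deterministic(self):
        g = open_geometry((20, 20, 20))
        region = RegionSelection("all", box=((0, 20), (0, 20), (0, 20)))
        a = seed_particles(region, g, n=50, radius=5, seed=9)
        b = seed_particles(region, g, n=50, radius=5, seed=9)
        assert np.array_equal(a, b)

    def test_solid_region_rejected(self):
        g = VoxelGeometry(labels=np.zeros((6, 6, 6), np.uint8))
        region = RegionSelection("solid", box=((0, 6), (0, 6), (0, 6)))
        with pytest.raises(ValueError, match="no pore"):
            seed_particles(region, g, n=5, radius=2, seed=0)


class TestTraceStreamlines:
    def test_uniform_field_gives_straight_line(self):
        g = open_geometry((32, 8, 8))
        f = make_field((32, 8, 8), lambda x, y, z: (np.full_like(x, 1.0, float),
                                                    np.zeros_like(x, float),
                                                    np.zeros_like(x, float)))
        [sl] = trace_streamlines(f, np.array([[2.0, 4.0, 4.0]]), g, step=0.5)
        assert sl.termination == "left_region"
        assert np.allclose(sl.positions[:, 1], 4.0, atol=1e-9)
        assert np.allclose(sl.positions[:, 2], 4.0, atol=1e-9)
        dx = np.diff(sl.positions[:, 0])
        assert np.allclose(dx, 0.5, atol=1e-9)

    def test_rigid_rotation_circle_radius_drift(self):
        """RK4 keeps a rotating tracer on its circle to < 0.1 % per lap."""
        n = 64
        c = n / 2.0
        g = open_geometry((n, n, 8))
        O = 1.0
        # array index i holds the sample at continuous position i + 0.5
        f = make_field((n, n, 8),
                       lambda x, y, z: (-O * (y + 0.5 - c), O * (x + 0.5 - c),
                                        np.zeros_like(x, float)))
        r0 = 15.0
        start = np.array([[c + r0, c, 4.0]])
        circumference = 2 * np.pi * r0
        steps_per_rev = int(np.ceil(circumference / 0.25))
        [sl] = trace_streamlines(f, start, g, step=0.25,
                                 max_steps=steps_per_rev)
        r = np.hypot(sl.positions[:, 0] - c, sl.positions[:, 1] - c)
        assert abs(r[-1] - r0) / r0 < 1e-3

    def test_start_on_solid_rejected(self):
        labels = np.full((8, 8, 8), EXTERNAL_PORE, np.uint8)
        labels[4, 4, 4] = 0
        g = VoxelGeometry(labels=labels)
        f = make_field((8, 8, 8), lambda x, y, z: (np.ones_like(x, float),) * 3)
        with pytest.raises(ValueError, match="solid"):
            trace_streamlines(f, np.array([[4.5, 4.5, 4.5]]), g)

    def test_stagnant_start_terminates_immediately(self):
        g = open_geometry((8, 8, 8))
        f = make_field((8, 8, 8), lambda x, y, z: (np.zeros_like(x, float),) * 3)
        f.velocity[7, 7, 7, 0] = 1.0  # reference speed so threshold > 0
        [sl] = trace_streamlines(f, np.array([[2.0, 2.0, 2.0]]), g)
        assert sl.termination == "stagnation"
        assert len(sl.positions) == 1


class TestResidenceTime:
    def test_uniform_flow_residence_is_length_over_speed(self):
        """Axis-aligned transit of a region of length L at speed u: t = L/u."""
        shape = (40, 8, 8)
        u0, spacing = 2.0, 0.5
        g = open_geometry(shape, spacing=spacing)
        f = make_field(shape, lambda x, y, z: (np.full_like(x, u0, float),
                                               np.zeros_like(x, float),
                                               np.zeros_like(x, float)),
                       spacing=spacing)
        region = RegionSelection("mid", box=((10, 30), (0, 8), (0, 8)))
        starts = np.array([[2.0, 3.5, 3.5], [2.0, 5.0, 2.5]])
        sls = trace_streamlines(f, starts, g, step=0.25)
        stats = residence_time(sls, region, g, confidence=1.0)
        L = 20 * spacing
        assert np.allclose(stats.times, L / u0, rtol=1e-6)
        assert np.isclose(stats.mean, L / u0, rtol=1e-6)

    def test_mean_of_two_times_with_full_confidence(self):
        region = RegionSelection("all", box=((0, 4), (0, 4), (0, 4)))
        g = open_geometry((4, 4, 4))
        # hand-built streamlines: 1 s and 3 s transits of unit length
        def line(speed):
            pos = np.array([[0.5, 1.0, 1.0], [1.5, 1.0, 1.0]])
            vel = np.full((2, 3), 0.0)
            vel[:, 0] = speed
            return Streamline(positions=pos, velocities=vel, termination="left_region")
        stats = residence_time([line(1.0), line(1.0 / 3.0)], region, g,
                               confidence=1.0)
        assert np.allclose(np.sort(stats.times), [1.0, 3.0])
        assert np.isclose(stats.mean, 2.0)

    def test_histogram_sums_to_one(self):
        region = RegionSelection("all", box=((0, 4), (0, 4), (0, 4)))
        g = open_geometry((4, 4, 4))
        rng = np.random.default_rng(0)
        sls = []
        for speed in rng.uniform(0.5, 2.0, 40):
            pos = np.array([[0.5, 1.0, 1.0], [1.5, 1.0, 1.0]])
            vel = np.zeros((2, 3))
            vel[:, 0] = speed
            sls.append(Streamline(pos, vel, "left_region"))
        stats = residence_time(sls, region, g, confidence=0.95)
        assert np.isclose(stats.hist_frequency.sum(), 1.0, atol=1e-12)
        assert len(stats.retained_times) <= len(stats.times)

    def test_velocity_scaling_inverts_times(self):
        """Scaling u by k scales every residence time by 1/k and flux by k."""
        shape = (40, 8, 8)
        g = open_geometry(shape)
        region = RegionSelection("mid", box=((10, 30), (0, 8), (0, 8)))
        start = np.array([[2.0, 4.0, 4.0]])
        means = []
        for u0 in (1.0, 3.0):
            f = make_field(shape, lambda x, y, z: (np.full_like(x, u0, float),
                                                   np.zeros_like(x, float),
                                                   np.zeros_like(x, float)))
            sls = trace_streamlines(f, start, g, step=0.25)
            means.append(residence_time(sls, region, g, confidence=1.0).mean)
        assert np.isclose(means[0] / means[1], 3.0, rtol=1e-6)
        assert np.isclose(volume_flux(1.0, means[1]) / volume_flux(1.0, means[0]),
                          3.0, rtol=1e-6)

    def test_no_crossing_raises(self):
        region = RegionSelection("far", box=((0, 2), (0, 2), (0, 2)))
        g = open_geometry((8, 8, 8))
        sl = Streamline(np.array([[5.0, 5.0, 5.0], [6.0, 5.0, 5.0]]),
                        np.array([[1.0, 0, 0], [1.0, 0, 0]]), "left_region")
        with pytest.raises(ValueError, match="crosses"):
            residence_time([sl], region, g)


class TestVolumeFlux:
    def test_division(self):
        assert volume_flux(1e-9, 10.0) == 1e-10

    def test_doubling_time_halves_flux(self):
        assert volume_flux(1e-9, 20.0) == 0.5 * volume_flux(1e-9, 10.0)

    def test_zero_time_rejected(self):
        with pytest.raises(ValueError):
            volume_flux(1e-9, 0.0)


class TestAsymmetry:
    def test_identical_slices_give_zero(self):
        shape = (16, 8, 8)
        g = open_geometry(shape)
        rng = np.random.default_rng(3)
        f = make_field(shape, lambda x, y, z: (rng.random(x.shape),) * 3)
        f.pressure = rng.random(shape)
        region = RegionSelection("same", box=((2, 6), (0, 8), (0, 8)))
        rep = asymmetry_differences(f, g, [(region, region)])
        assert rep.pressure_diff[0] == 0.0
        assert rep.velocity_diff[0] == 0.0
        assert rep.enstrophy_diff[0] == 0.0

    def test_mirrored_field_negates_differences(self):
        """Mirroring the field about the flow axis swaps up/downstream."""
        shape = (16, 8, 8)
        g = open_geometry(shape)
        rng = np.random.default_rng(4)
        vel = rng.normal(size=shape + (3,))
        press = rng.normal(size=shape)
        base = FlowField(velocity=vel, density=np.ones(shape), pressure=press,
                         spacing=1.0, solid=np.zeros(shape, bool))
        mirrored = FlowField(velocity=vel[::-1].copy() * np.array([-1, 1, 1]),
                             density=np.ones(shape), pressure=press[::-1].copy(),
                             spacing=1.0, solid=np.zeros(shape, bool))
        up = RegionSelection("up", box=((2, 6), (0, 8), (0, 8)))
        down = RegionSelection("down", box=((10, 14), (0, 8), (0, 8)))
        r1 = asymmetry_differences(base, g, [(up, down)])
        r2 = asymmetry_differences(mirrored, g, [(up, down)])
        assert np.isclose(r1.pressure_diff[0], -r2.pressure_diff[0])
        assert np.isclose(r1.velocity_diff[0], -r2.velocity_diff[0])

    def test_empty_slice_raises(self):
        g = VoxelGeometry(labels=np.zeros((8, 8, 8), np.uint8))  # all solid
        f = make_field((8, 8, 8), lambda x, y, z: (np.ones_like(x, float),) * 3)
        r = RegionSelection("r", box=((0, 4), (0, 8), (0, 8)))
        with pytest.raises(ValueError, match="empty slice"):
            asymmetry_differences(f, g, [(r, r)])


class TestAxialDecomposition:
    def test_pure_vertical_flow_ratio_one(self):
        shape = (8, 8, 16)
        g = open_geometry(shape)
        f = make_field(shape, lambda x, y, z: (np.zeros_like(x, float),
                                               np.zeros_like(x, float),
                                               np.full_like(x, 0.5, float)))
        secs = [RegionSelection("a", box=((0, 8), (0, 8), (0, 8))),
                RegionSelection("b", box=((0, 8), (0, 8), (8, 16)))]
        out = axial_decomposition(f, g, secs)
        assert np.isclose(out["a"][1], 1.0) and np.isclose(out["b"][1], 1.0)

    def test_pure_horizontal_flow_ratio_zero(self):
        shape = (8, 8, 16)
        g = open_geometry(shape)
        f = make_field(shape, lambda x, y, z: (np.full_like(x, 0.5, float),
                                               np.zeros_like(x, float),
                                               np.zeros_like(x, float)))
        out = axial_decomposition(f, g, [RegionSelection("a", box=((0, 8), (0, 8), (0, 16)))])
        assert np.isclose(out["a"][1], 0.0)
        assert np.isclose(out["a"][0], 0.5)

    def test_empty_section_raises(self):
        g = VoxelGeometry(labels=np.zeros((8, 8, 8), np.uint8))
        f = make_field((8, 8, 8), lambda x, y, z: (np.ones_like(x, float),) * 3)
        with pytest.raises(ValueError, match="no pore"):
            axial_decomposition(f, g, [RegionSelection("s", box=((0, 8), (0, 8), (0, 8)))])


class TestCoralRegions:
    def test_regions_partition_and_fit(self, small_coral_params, small_coral):
        regions = coral_regions(small_coral_params)
        shape = small_coral.shape
        for r in regions.values():
            m = r.mask_on(shape)
            assert m.any()
        # upstream/downstream pairs have equal voxel counts
        assert (regions["top_upstream"].mask_on(shape).sum()
                == regions["top_downstream"].mask_on(shape).sum())
        # channel sections are disjoint
        total = sum(regions[k].mask_on(shape).astype(int)
                    for k in ("channel_bottom", "channel_center",
                              "channel_top", "channel_tiptop"))
        assert total.max() == 1
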