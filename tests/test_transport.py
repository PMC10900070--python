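import math

import numpy as np
import pytest

from pdtplan.geometry import Region
from pdtplan.optics import OpticalProperties, OpticalVolume, assign_region_optics
from pdtplan.transport import (
    SourceModel,
    launch_flat_cleaved,
    launch_spherical_diffuser,
    scale_fluence,
    simulate_fluence,
)

from conftest import make_homogeneous_volume, radius_map_cm


def point_source(ov):
    n = ov.label_volume.shape[0]
    c = n * ov.label_volume.pitch_mm / 2
    return SourceModel(kind="isotropic_point", position_mm=(c, c, c))


class TestAnalyticOracles:
    def test_absorbing_medium_matches_beer_lambert_point_source(self):
        # mua = 1, mus = 0: phi(r) = exp(-mua r) / (4 pi r^2)
        ov = make_homogeneous_volume(64, 0.5, mua=1.0, mus=0.0, g=0.0)
        fmap = simulate_fluence(ov, point_source(ov), n_packets=300_000, seed=11)
        r = radius_map_cm(ov.label_volume.shape, 0.5, [16.0] * 3)
        band = np.abs(r - 1.0) < 0.025
        expected = (np.exp(-r[band]) / (4 * np.pi * r[band] ** 2)).mean()
        assert fmap.values[band].mean() == pytest.approx(expected, rel=0.03)

    def test_vacuum_inverse_square_law(self):
        ov = make_homogeneous_volume(64, 0.5, mua=0.0, mus=0.0, g=0.0)
        fmap = simulate_fluence(ov, point_source(ov), n_packets=300_000, seed=12)
        r = radius_map_cm(ov.label_volume.shape, 0.5, [16.0] * 3)
        for r0 in (0.5, 1.0):
            band = np.abs(r - r0) < 0.025
            expected = (1.0 / (4 * np.pi * r[band] ** 2)).mean()
            assert fmap.values[band].mean() == pytest.approx(expected, rel=0.03)

    def test_diffusion_limit_decay_length(self):
        # musp >> mua: fluence decays as exp(-mueff r)/r with
        # mueff = sqrt(3 mua (mua + musp))
        mua, mus = 0.1, 10.0
        ov = make_homogeneous_volume(70, 0.5, mua=mua, mus=mus, g=0.0)
        fmap = simulate_fluence(ov, point_source(ov), n_packets=100_000, seed=13)
        r = radius_map_cm(ov.label_volume.shape, 0.5, [17.5] * 3)
        band = (r > 0.4) & (r < 1.0) & (fmap.values > 0)
        slope = np.polyfit(r[band], np.log(fmap.values[band] * r[band]), 1)[0]
        mueff = math.sqrt(3 * mua * (mua + mus))
        assert -slope == pytest.approx(mueff, rel=0.15)

    def test_integrating_sphere_effect(self, sphere_lv):
        # hollow cavity + low-absorption scattering wall: wall fluence
        # exceeds the bare inverse-square baseline
        ov = OpticalVolume(sphere_lv, {
            Region.INTERIOR: OpticalProperties(0.0, 0.0, 0.7),
            Region.WALL: OpticalProperties(0.01, 100.0, 0.9),
            Region.TISSUE: OpticalProperties(0.01, 100.0, 0.9),
        }, 0.0)
        fmap = simulate_fluence(ov, point_source(ov), n_packets=100_000, seed=14)
        idx = np.argwhere(sphere_lv.wall_shell)
        center = np.array(sphere_lv.shape) * sphere_lv.pitch_mm / 2
        r = np.linalg.norm((idx + 0.5) * sphere_lv.pitch_mm - center, axis=1) / 10
        vacuum_baseline = 1.0 / (4 * np.pi * r**2)
        assert fmap.values[sphere_lv.wall_shell].mean() > vacuum_baseline.mean()


class TestEnergyBookkeeping:
    @pytest.mark.parametrize("mua,mus,g", [(1.0, 0.0, 0.0), (0.0, 0.0, 0.0),
                                           (0.5, 20.0, 0.8)])
    def test_absorbed_plus_escaped_equals_launched(self, mua, mus, g):
        ov = make_homogeneous_volume(40, 0.5, mua=mua, mus=mus, g=g)
        fmap = simulate_fluence(ov, point_source(ov), n_packets=20_000, seed=15)
        assert fmap.energy_balance_error() < 1e-9

    def test_fluence_non_negative(self):
        ov = make_homogeneous_volume(40, 0.5, mua=0.5, mus=20.0, g=0.8)
        fmap = simulate_fluence(ov, point_source(ov), n_packets=20_000, seed=16)
        assert (fmap.values >= 0).all()


class TestDeterminism:
    def test_same_seed_bit_identical(self, sphere_lv, rep_subject):
        ov = assign_region_optics(sphere_lv, rep_subject, condition="measured")
        src = SourceModel(kind="flat_cleaved",
                          position_mm=(12.0, 12.0, 12.0))
        a = simulate_fluence(ov, src, n_packets=5_000, seed=99)
        b = simulate_fluence(ov, src, n_packets=5_000, seed=99)
        assert np.array_equal(a.values, b.values)
        assert a.absorbed_weight == b.absorbed_weight

    def test_different_seeds_differ(self, sphere_lv, rep_subject):
        ov = assign_region_optics(sphere_lv, rep_subject, condition="measured")
        src = SourceModel(kind="flat_cleaved", position_mm=(12.0, 12.0, 12.0))
        a = simulate_fluence(ov, src, n_packets=5_000, seed=1)
        b = simulate_fluence(ov, src, n_packets=5_000, seed=2)
        assert not np.array_equal(a.values, b.values)


class TestScaling:
    def test_unit_power_is_identity(self, sphere_lv, rep_subject):
        ov = assign_region_optics(sphere_lv, rep_subject, condition="measured")
        src = SourceModel(kind="flat_cleaved", position_mm=(12.0, 12.0, 12.0))
        fmap = simulate_fluence(ov, src, n_packets=2_000, seed=3)
        assert np.array_equal(scale_fluence(fmap, 1.0).values, fmap.values)

    def test_scaling_is_exactly_multiplicative(self, sphere_lv, rep_subject):
        ov = assign_region_optics(sphere_lv, rep_subject, condition="measured")
        src = SourceModel(kind="flat_cleaved", position_mm=(12.0, 12.0, 12.0))
        fmap = simulate_fluence(ov, src, n_packets=2_000, seed=3)
        scaled = scale_fluence(fmap, 528.0)
        assert np.array_equal(scaled.values, fmap.values * 528.0)
        assert scaled.power_mw == 528.0

    def test_power_above_cap_rejected(self, sphere_lv, rep_subject):
        ov = assign_region_optics(sphere_lv, rep_subject, condition="measured")
        src = SourceModel(kind="flat_cleaved", position_mm=(12.0, 12.0, 12.0))
        fmap = simulate_fluence(ov, src, n_packets=2_000, seed=3)
        with pytest.raises(ValueError, match="10,?000"):
            scale_fluence(fmap, 10_001.0)


class TestFlatCleavedLaunch:
    SRC = SourceModel(kind="flat_cleaved", position_mm=(0, 0, 0), axis=(0, 0, 1))

    def test_acceptance_half_angle_arithmetic(self):
        # NA 0.22 in n = 1.37: theta_max = arcsin(0.22/1.37) = 9.24 deg
        assert math.degrees(self.SRC.acceptance_half_angle()) == pytest.approx(9.24, abs=0.01)

    def test_polar_angles_bounded_by_acceptance_cone(self):
        rng = np.random.default_rng(0)
        _, dirs = launch_flat_cleaved(self.SRC, rng, n=100_000)
        max_angle = np.arccos(np.clip(dirs[:, 2], -1, 1)).max()
        assert max_angle <= self.SRC.acceptance_half_angle() + 1e-12

    def test_positions_within_core_disk(self):
        rng = np.random.default_rng(0)
        pos, _ = launch_flat_cleaved(self.SRC, rng, n=10_000)
        assert np.abs(pos[:, 2]).max() < 1e-12  # disk perpendicular to axis
        assert np.linalg.norm(pos[:, :2], axis=1).max() <= 0.2 + 1e-12  # 400 um core

    def test_mean_direction_parallel_to_axis(self):
        rng = np.random.default_rng(1)
        _, dirs = launch_flat_cleaved(self.SRC, rng, n=100_000)
        assert dirs[:, 0].mean() == pytest.approx(0.0, abs=0.002)
        assert dirs[:, 1].mean() == pytest.approx(0.0, abs=0.002)
        assert dirs[:, 2].mean() > 0.98

    def test_na_to_zero_limit_collimates(self):
        src = SourceModel(kind="flat_cleaved", position_mm=(0, 0, 0), na=1e-9)
        rng = np.random.default_rng(2)
        _, dirs = launch_flat_cleaved(src, rng, n=1_000)
        assert dirs[:, 2].min() > 1 - 1e-12

    def test_na_at_least_medium_index_rejected(self):
        src = SourceModel(kind="flat_cleaved", position_mm=(0, 0, 0), na=0.9)
        with pytest.raises(ValueError):
            src.acceptance_half_angle(n_medium=0.8)


class TestSphericalDiffuserLaunch:
    SRC = SourceModel(kind="spherical_diffuser", position_mm=(0, 0, 0))

    def test_positions_on_bulb_surface_mean_at_center(self):
        rng = np.random.default_rng(0)
        pos, _ = launch_spherical_diffuser(self.SRC, rng, n=50_000)
        assert np.linalg.norm(pos, axis=1) == pytest.approx(1.0, abs=1e-9)  # 2 mm bulb
        assert pos.mean(axis=0) == pytest.approx([0, 0, 0], abs=0.02)

    def test_all_directions_point_outward(self):
        rng = np.random.default_rng(1)
        pos, dirs = launch_spherical_diffuser(self.SRC, rng, n=50_000)
        assert (np.einsum("ij,ij->i", dirs, pos) > 0).all()

    def test_wall_fluence_isotropy_in_vacuum(self, sphere_lv):
        ov = OpticalVolume(sphere_lv, {
            Region.INTERIOR: OpticalProperties(0, 0, 0.7),
            Region.WALL: OpticalProperties(0, 0, 0.9),
            Region.TISSUE: OpticalProperties(0, 0, 0.9),
        }, 0.0)
        center = np.array(sphere_lv.shape) * sphere_lv.pitch_mm / 2
        src = SourceModel(kind="spherical_diffuser", position_mm=tuple(center))
        fmap = simulate_fluence(ov, src, n_packets=300_000, seed=21)
        idx = np.argwhere(sphere_lv.wall_shell)
        r = np.linalg.norm((idx + 0.5) * sphere_lv.pitch_mm - center, axis=1) / 10
        # remove the geometric 1/r^2 trend; the residual spread is MC noise
        vals = fmap.values[sphere_lv.wall_shell] * 4 * np.pi * r**2
        assert vals.std() / vals.mean() < 0.07


class TestInputValidation:
    def test_source_outside_cavity_rejected(self, sphere_lv, rep_subject):
        ov = assign_region_optics(sphere_lv, rep_subject, condition="measured")
        src = SourceModel(kind="flat_cleaved", position_mm=(1.5, 1.5, 1.5))
        with pytest.raises(ValueError, match="INTERIOR"):
            simulate_fluence(ov, src, n_packets=2_000, seed=0)

    def test_too_few_packets_rejected(self, sphere_lv, rep_subject):
        ov = assign_region_optics(sphere_lv, rep_subject, condition="measured")
        src = SourceModel(kind="flat_cleaved", position_mm=(12.0, 12.0, 12.0))
        with pytest.raises(ValueError, match="1000"):
            simulate_fluence(ov, src, n_packets=10, seed=0)

    def test_unknown_source_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            SourceModel(kind="laser_pointer", position_mm=(0, 0, 0))
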