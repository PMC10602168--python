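"""Phantom generator: geometry, transport physics, imaging forward models."""

import numpy as np
import pytest

from tracerflow.core import MS_PER_MIN, AcquisitionError, GeometryError
from tracerflow.dti import DEFAULT_DIRECTIONS
from tracerflow.phantom import (PhantomSpec, build_phantom, concentration_to_t1,
                                simulate_dwi, simulate_tracer)


# ---------------------------------------------------------------------------
# build_phantom
# ---------------------------------------------------------------------------

class TestBuildPhantom:
    def test_striatum_mask_matches_bruteforce_containment(self, small_spec):
        _, _, masks = build_phantom(small_spec)
        cx, cy, cz = small_spec.striatum_center_mm
        r2 = small_spec.striatum_radius_mm ** 2
        dx, dy, dz = small_spec.spacing
        expected = np.zeros(small_spec.grid_shape, bool)
        for i in range(small_spec.grid_shape[0]):
            for j in range(small_spec.grid_shape[1]):
                for k in range(small_spec.grid_shape[2]):
                    d2 = ((i * dx - cx) ** 2 + (j * dy - cy) ** 2
                          + (k * dz - cz) ** 2)
                    expected[i, j, k] = d2 <= r2
        assert np.array_equal(masks["striatum"], expected)

    def test_degenerate_slab_anisotropy_gives_zero_fa(self, small_spec):
        spec = PhantomSpec.from_dict({
            **small_spec.to_dict(),
            "tensor_field_params": dict(slab_axial=7e-7, slab_radial=7e-7)})
        tensor_map, _, masks = build_phantom(spec)
        assert np.allclose(tensor_map.fa[masks["callosum"]], 0.0, atol=1e-12)

    def test_slab_tensors_are_cigar_shaped(self, small_spec):
        tensor_map, _, masks = build_phantom(small_spec)
        sl = masks["callosum"]
        assert np.all(tensor_map.daxi[sl] >= tensor_map.drad[sl])
        p = small_spec.tensor_field_params
        assert np.allclose(tensor_map.daxi[sl], p.slab_axial)
        assert np.allclose(tensor_map.drad[sl], p.slab_radial)

    def test_zero_velocity_field_is_identically_zero(self, small_spec):
        _, velocity, _ = build_phantom(small_spec)
        assert velocity.shape == small_spec.grid_shape + (3,)
        assert not np.any(velocity)

    def test_region_outside_grid_raises(self, small_spec):
        with pytest.raises(GeometryError):
            PhantomSpec.from_dict({**small_spec.to_dict(),
                                   "striatum_center_mm": (0.2, 4.0, 2.5)})


# ---------------------------------------------------------------------------
# simulate_tracer
# ---------------------------------------------------------------------------

class TestSimulateTracer:
    def test_point_source_diffusion_matches_gaussian_spread_law(self, small_spec):
        """Per-axis variance of a diffusing point bolus grows as 2 D t."""
        spec = PhantomSpec.from_dict({
            **small_spec.to_dict(), "grid_shape": (48, 48, 48),
            "spacing": (0.125, 0.125, 0.125),
            "striatum_center_mm": (3.0, 3.0, 3.0),
            "callosum_slab_mm": (1.0, 5.0, 1.0, 5.0, 4.5, 5.5),
            "source": dict(center_mm=(3.0, 3.0, 3.0), rate=0.0)})
        init = np.zeros(spec.grid_shape)
        init[24, 24, 24] = 1.0
        # default max step 0.25 min -> >= 120 steps by 30 min
        (vol,) = simulate_tracer(spec, [30.0], initial=init)
        d_mm2_min = spec.tracer_diffusivity * MS_PER_MIN
        coords = np.arange(48) * 0.125
        mass = vol.values.sum()
        for axis in range(3):
            proj = vol.values.sum(axis=tuple(a for a in range(3) if a != axis))
            mu = (proj * coords).sum() / mass
            var = (proj * (coords - mu) ** 2).sum() / mass
            assert var == pytest.approx(2 * d_mm2_min * 30.0, rel=0.05)

    def test_advection_only_translates_center_of_mass(self, small_spec):
        v = (0.05, 0.0, 0.0)
        spec = PhantomSpec.from_dict({
            **small_spec.to_dict(), "tracer_diffusivity": 0.0,
            "velocity_mm_per_min": v,
            "source": dict(center_mm=(4.0, 4.0, 2.5), rate=0.0)})
        init = np.zeros(spec.grid_shape)
        init[8, 16, 10] = 1.0
        (vol,) = simulate_tracer(spec, [20.0], initial=init)
        com = np.array([
            (vol.values.sum(axis=tuple(a for a in range(3) if a != ax))
             * np.arange(spec.grid_shape[ax]) * spec.spacing[ax]).sum()
            / vol.values.sum() for ax in range(3)])
        start = np.array([8, 16, 10]) * np.array(spec.spacing)
        expected = start + np.array(v) * 20.0
        assert np.all(np.abs(com - expected) <= np.array(spec.spacing))

    def test_mass_conserved_with_source_off(self, small_spec):
        rng = np.random.default_rng(0)
        init = rng.random(small_spec.grid_shape)
        spec = PhantomSpec.from_dict({**small_spec.to_dict(),
                                      "source": dict(rate=0.0,
                                                     center_mm=(4.0, 4.0, 2.5)),
                                      "velocity_mm_per_min": (0.02, -0.01, 0.03)})
        vols = simulate_tracer(spec, [0.0, 25.0], initial=init)
        m0, m1 = vols[0].values.sum(), vols[1].values.sum()
        assert abs(m1 - m0) / m0 <= 1e-6

    def test_concentration_nonnegative_and_times_attached(self, small_spec):
        vols = simulate_tracer(small_spec, [4.5, 24.0])
        assert [v.time_min for v in vols] == [4.5, 24.0]
        for v in vols:
            assert np.all(v.values >= 0)
            assert v.kind == "concentration"

    def test_negative_timepoint_rejected(self, small_spec):
        with pytest.raises(ValueError):
            simulate_tracer(small_spec, [-1.0, 5.0])

    def test_identical_spec_and_seed_bit_identical(self, small_spec):
        a = simulate_tracer(small_spec, [4.5, 24.0])
        b = simulate_tracer(small_spec, [4.5, 24.0])
        for x, y in zip(a, b):
            assert np.array_equal(x.values, y.values)

    def test_stronger_advection_moves_half_max_contour_centroid_farther(
            self, small_spec):
        """The displacement of the 50%-max contour centroid between
        successive timepoints grows strictly with advection speed."""
        displacements = []
        for vz in (0.0, 0.05, 0.1):
            spec = PhantomSpec.from_dict({**small_spec.to_dict(),
                                          "velocity_mm_per_min": (0.0, 0.0, vz)})
            vols = simulate_tracer(spec, [4.5, 24.0])
            cents = []
            for v in vols:
                m = v.values > 0.5 * v.values.max()
                idx = np.argwhere(m)
                cents.append((idx * np.array(spec.spacing)).mean(axis=0))
            displacements.append(np.linalg.norm(cents[1] - cents[0]))
        assert displacements[0] < displacements[1] < displacements[2]


# ---------------------------------------------------------------------------
# concentration_to_t1
# ---------------------------------------------------------------------------

class TestConcentrationToT1:
    def test_zero_concentration_gives_uniform_baseline(self, small_spec):
        conc = simulate_tracer(PhantomSpec.from_dict(
            {**small_spec.to_dict(),
             "source": dict(rate=0.0, center_mm=(4.0, 4.0, 2.5))}), [1.0])[0]
        t1 = concentration_to_t1(conc, gain=2.0, baseline=5.0, noise_sigma=0.0)
        assert np.all(t1.values == 5.0)

    def test_affine_map(self, small_spec):
        conc = simulate_tracer(small_spec, [4.5])[0]
        conc.values[3, 3, 3] = 3.0
        t1 = concentration_to_t1(conc, gain=2.0, baseline=1.0, noise_sigma=0.0)
        assert t1.values[3, 3, 3] == pytest.approx(7.0)
        assert t1.time_min == conc.time_min

    def test_fixed_seed_reproducible_noise(self, small_spec):
        conc = simulate_tracer(small_spec, [4.5])[0]
        a = concentration_to_t1(conc, 1.0, 10.0, 0.7, seed=42)
        b = concentration_to_t1(conc, 1.0, 10.0, 0.7, seed=42)
        c = concentration_to_t1(conc, 1.0, 10.0, 0.7, seed=43)
        assert np.array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)


# ---------------------------------------------------------------------------
# simulate_dwi
# ---------------------------------------------------------------------------

class TestSimulateDwi:
    spacing = (0.25, 0.25, 0.25)

    def _uniform_field(self, tensor):
        return np.broadcast_to(tensor, (4, 4, 4, 3, 3)).copy()

    def test_zero_tensor_gives_s0_everywhere(self):
        dwi = simulate_dwi(self._uniform_field(np.zeros((3, 3))), 900.0,
                           s0=500.0, spacing=self.spacing)
        for vol in dwi.dw_volumes:
            assert np.allclose(vol.values, 500.0)

    def test_isotropic_attenuation_is_direction_independent(self):
        d = 1e-3
        dwi = simulate_dwi(self._uniform_field(d * np.eye(3)), 900.0, s0=1000.0,
                           spacing=self.spacing)
        for vol in dwi.dw_volumes:
            assert np.allclose(vol.values, 1000.0 * np.exp(-900.0 * d))

    def test_diagonal_tensor_hand_value(self):
        tensor = np.diag([2e-3, 1e-3, 1e-3])
        dwi = simulate_dwi(self._uniform_field(tensor), 900.0,
                           directions=[[1.0, 0.0, 0.0]] + DEFAULT_DIRECTIONS.tolist(),
                           s0=1000.0, spacing=self.spacing)
        assert np.allclose(dwi.dw_volumes[0].values, 1000.0 * np.exp(-1.8))

    def test_non_unit_direction_rejected(self):
        with pytest.raises(AcquisitionError):
            simulate_dwi(self._uniform_field(np.eye(3) * 1e-3), 900.0,
                         directions=[[1, 1, 0]] * 6, spacing=self.spacing)

    def test_rician_noise_reproducible_and_nonnegative(self):
        field = self._uniform_field(1e-3 * np.eye(3))
        a = simulate_dwi(field, 900.0, rician_sigma=5.0, seed=1, spacing=self.spacing)
        b = simulate_dwi(field, 900.0, rician_sigma=5.0, seed=1, spacing=self.spacing)
        for va, vb in zip(a.dw_volumes, b.dw_volumes):
            assert np.array_equal(va.values, vb.values)
            assert np.all(va.values >= 0)

    def test_too_few_directions_rejected(self):
        field = self._uniform_field(1e-3 * np.eye(3))
        with pytest.raises(AcquisitionError):
            simulate_dwi(field, 900.0, directions=np.eye(3), spacing=self.spacing)
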