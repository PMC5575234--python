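import numpy as np
import pytest

from conftest import dense_design_matrix, make_probe
from cryoptycho.forward import (
    ContrastTransferFunction,
    ForwardOperator,
    ObjectField,
    PotentialMap,
    ctf_image,
    far_field_intensity,
    forward_apply,
    multislice_exit_wave,
    thin_object_exit_wave,
)
from cryoptycho.geometry import (
    ComplexField2D,
    ScanPlan,
    geometry_for_pixel_size,
    interaction_constant,
)


@pytest.fixture
def obj8(rng):
    phase = 0.3 * rng.standard_normal((8, 8))
    return ObjectField(ComplexField2D(0.9 * np.exp(1j * phase), 1.0))


class TestThinObjectExitWave:
    def test_identity_object_returns_probe(self, tiny_operator):
        probe = tiny_operator.probe
        obj = ObjectField(ComplexField2D(np.ones((8, 8), dtype=complex), 1.0))
        out = thin_object_exit_wave(probe, obj, (2, 3))
        assert np.array_equal(out.values, probe.values)

    def test_passivity_bounds_exit_power(self, tiny_operator, obj8):
        out = thin_object_exit_wave(tiny_operator.probe, obj8, (1, 1))
        assert out.power() <= tiny_operator.probe.field.power() + 1e-12

    def test_matches_elementwise_product(self, tiny_operator, obj8):
        out = thin_object_exit_wave(tiny_operator.probe, obj8, (3, 2))
        expected = tiny_operator.probe.values * obj8.values[3:7, 2:6]
        np.testing.assert_allclose(out.values, expected, atol=1e-15)

    def test_out_of_bounds_rejected(self, tiny_operator, obj8):
        with pytest.raises(ValueError):
            thin_object_exit_wave(tiny_operator.probe, obj8, (6, 0))


class TestFarFieldIntensity:
    def test_parseval(self, rng):
        wave = ComplexField2D(
            rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16)), 1.0
        )
        intensity = far_field_intensity(wave)
        assert intensity.sum() == pytest.approx(wave.power(), rel=1e-10)

    def test_delta_gives_flat_pattern(self):
        v = np.zeros((8, 8), dtype=complex)
        v[3, 5] = 2.0
        intensity = far_field_intensity(ComplexField2D(v, 1.0))
        np.testing.assert_allclose(intensity, intensity[0, 0], rtol=1e-10)

    def test_translation_invariance(self, rng):
        v = rng.standard_normal((8, 8)) + 1j * rng.standard_normal((8, 8))
        a = far_field_intensity(ComplexField2D(v, 1.0))
        b = far_field_intensity(ComplexField2D(np.roll(v, (2, 3), (0, 1)), 1.0))
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestCTFImage:
    def test_unity_ctf_reproduces_intensity(self, rng):
        wave = ComplexField2D(
            rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16)), 1.0
        )
        ctf = ContrastTransferFunction(defocus=0.0, additional_phase=0.0)
        np.testing.assert_allclose(
            ctf_image(wave, ctf, 1.969), np.abs(wave.values) ** 2, atol=1e-10
        )

    def test_phase_plate_gives_linear_weak_phase_contrast(self):
        # Weak-phase object + pi/2 shift of the unscattered beam:
        # I ~ 1 + 2 phi to first order.
        rng = np.random.default_rng(5)
        phi = 0.01 * rng.standard_normal((32, 32))
        phi -= phi.mean()  # the mean is part of the unscattered beam
        wave = ComplexField2D(np.exp(1j * phi), 1.0)
        ctf = ContrastTransferFunction(defocus=0.0, additional_phase=np.pi / 2)
        image = ctf_image(wave, ctf, 1.969)
        np.testing.assert_allclose(image, 1.0 + 2.0 * phi, atol=5e-3)

    def test_envelope_bound_enforced(self, rng):
        wave = ComplexField2D(np.ones((8, 8), dtype=complex), 1.0)
        ctf = ContrastTransferFunction(
            envelope=(np.array([0.0, 1.0]), np.array([1.5, 1.5]))
        )
        with pytest.raises(ValueError):
            ctf_image(wave, ctf, 1.969)


class TestMultislice:
    @pytest.fixture
    def geom(self):
        return geometry_for_pixel_size(1.0, n_detector_pixels=32)

    @pytest.fixture
    def probe(self, geom):
        from cryoptycho.probes import make_defocused_probe

        return make_defocused_probe(geom, 50.0, 5.0, electrons=1.0)

    def test_zero_potential_conserves_intensity(self, geom, probe):
        pot = PotentialMap(
            slices=np.zeros((4, 32, 32), dtype=complex),
            voxel_size=1.0,
            slice_thickness=10.0,
        )
        out = multislice_exit_wave(probe, pot, geom)
        assert out.power() == pytest.approx(probe.field.power(), rel=1e-8)

    def test_single_thin_slice_matches_thin_object(self, geom, probe, rng):
        v = rng.standard_normal((32, 32))
        # Negligible propagation: very thin slice.
        dz = 1e-6
        pot = PotentialMap(
            slices=v[None, :, :].astype(complex), voxel_size=1.0, slice_thickness=dz
        )
        sigma = interaction_constant(geom.electron_energy)
        t_equiv = np.exp(1j * sigma * v * dz)
        obj = ObjectField(
            ComplexField2D(t_equiv, 1.0), passive=False
        )
        expected = thin_object_exit_wave(probe, obj, (0, 0))
        out = multislice_exit_wave(probe, pot, geom)
        np.testing.assert_allclose(out.values, expected.values, atol=1e-8)

    def test_slice_refinement_converges(self, geom, probe):
        # Smooth weak potential: halving the slice thickness changes the
        # exit wave less and less (Lie-splitting convergence).
        yy, xx = np.mgrid[0:32, 0:32] / 32.0
        v = 5.0 * np.sin(2 * np.pi * yy) * np.cos(2 * np.pi * xx)
        total_thickness = 100.0

        def exit_with(n_slices):
            slices = np.repeat(v[None, :, :], n_slices, axis=0).astype(complex)
            pot = PotentialMap(
                slices=slices,
                voxel_size=1.0,
                slice_thickness=total_thickness / n_slices,
            )
            return multislice_exit_wave(probe, pot, geom).values

        ref = exit_with(32)
        err_coarse = np.linalg.norm(exit_with(1) - ref)
        err_fine = np.linalg.norm(exit_with(8) - ref)
        assert err_fine < err_coarse
        assert err_fine < 0.05 * np.linalg.norm(ref)

    def test_mismatched_grid_rejected(self, geom, probe):
        pot = PotentialMap(
            slices=np.zeros((2, 16, 16), dtype=complex),
            voxel_size=1.0,
            slice_thickness=10.0,
        )
        with pytest.raises(ValueError):
            multislice_exit_wave(probe, pot, geom)


class TestForwardOperator:
    def test_adjoint_identity(self, tiny_operator, rng):
        x = rng.standard_normal((8, 8)) + 1j * rng.standard_normal((8, 8))
        w = rng.standard_normal((4, 4, 4)) + 1j * rng.standard_normal((4, 4, 4))
        lhs = np.vdot(w, tiny_operator.apply(x))
        rhs = np.vdot(tiny_operator.adjoint(w), x)
        assert abs(lhs - rhs) <= 1e-8 * abs(lhs)

    def test_linearity(self, tiny_operator, rng):
        x = rng.standard_normal((8, 8)) + 1j * rng.standard_normal((8, 8))
        y = rng.standard_normal((8, 8)) + 1j * rng.standard_normal((8, 8))
        np.testing.assert_allclose(
            tiny_operator.apply(2.0 * x + 3j * y),
            2.0 * tiny_operator.apply(x) + 3j * tiny_operator.apply(y),
            atol=1e-12,
        )

    def test_matches_dense_design_matrix(self, tiny_operator, tiny_object):
        dense = dense_design_matrix(
            tiny_operator.probe.values,
            tiny_operator.scanplan.positions,
            (8, 8),
        )
        expected = np.abs(dense @ tiny_object.ravel()) ** 2
        got = tiny_operator.intensities(tiny_object).ravel()
        np.testing.assert_allclose(got, expected, rtol=1e-10, atol=1e-12)

    def test_single_position_full_probe_of_ones(self, rng):
        n = 8
        probe = make_probe(np.ones((n, n), dtype=complex))
        scan = ScanPlan(positions=np.array([[0, 0]]), step=1)
        op = ForwardOperator(probe=probe, scanplan=scan, object_shape=(n, n))
        t = rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
        from cryoptycho.geometry import fft2

        np.testing.assert_allclose(
            op.intensities(t)[0], np.abs(fft2(t)) ** 2, atol=1e-12
        )

    def test_energy_bounded_by_probe_electrons(self, tiny_operator, obj8):
        stack = forward_apply(obj8, tiny_operator)
        assert np.all(
            stack.pattern_sums() <= tiny_operator.probe.total_electrons + 1e-9
        )

    def test_probe_power_map_sums_intensity(self, tiny_operator):
        pw = tiny_operator.probe_power_map()
        assert pw.sum() == pytest.approx(
            tiny_operator.n_positions * tiny_operator.probe.field.power(), rel=1e-12
        )


class TestObjectField:
    def test_passive_bound_enforced(self):
        with pytest.raises(ValueError):
            ObjectField(ComplexField2D(1.5 * np.ones((4, 4), dtype=complex), 1.0))

    def test_non_passive_iterates_allowed(self):
        f = ObjectField(
            ComplexField2D(1.5 * np.ones((4, 4), dtype=complex), 1.0), passive=False
        )
        assert f.amplitude.max() == pytest.approx(1.5)
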