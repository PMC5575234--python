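import logging

import numpy as np
import pytest

from conftest import dense_design_matrix, make_probe
from cryoptycho.denoise import denoise_complex, domain_color, domain_uncolor
from cryoptycho.forward import ForwardOperator
from cryoptycho.geometry import ScanPlan, raster_scan
from cryoptycho.phantom import PhantomSpec, generate_phantom
from cryoptycho.reconstruct import (
    DenoiserState,
    ReconConfig,
    _spectral_eigenvector,
    intensity_percentile_mask,
    likelihood_gradient,
    poisson_nll,
    random_initialize,
    reconstruct,
    refresh_denoiser,
    sparse_prior,
    spectral_initialize,
    tikhonov_kappa,
    tikhonov_prior,
    truncated_likelihood_gradient,
    truncation_set,
)


def dense_poisson_nll(t, y, probe_values, positions, shape):
    """Brute-force likelihood through the explicit design matrix."""
    dense = dense_design_matrix(probe_values, positions, shape)
    intens = np.abs(dense @ t.ravel()) ** 2
    floor = 1e-12 * intens[intens > 0].mean()
    yv = y.ravel()
    logs = np.where(yv > 0, np.log(np.maximum(intens, floor)), 0.0)
    return float(np.sum(intens - yv * logs))


class TestPoissonNLL:
    def test_single_measurement_closed_form(self):
        # |pT|^2 = y = 1: contribution 1 - 1 * log 1 = 1.
        probe = make_probe(np.ones((1, 1), dtype=complex))
        scan = ScanPlan(positions=np.array([[0, 0]]), step=1)
        op = ForwardOperator(probe=probe, scanplan=scan, object_shape=(1, 1))
        t = np.ones((1, 1), dtype=complex)
        y = np.ones((1, 1, 1))
        assert poisson_nll(t, y, op) == pytest.approx(1.0)

    def test_matches_dense_oracle(self, tiny_operator, tiny_object, tiny_counts):
        expected = dense_poisson_nll(
            tiny_object,
            tiny_counts,
            tiny_operator.probe.values,
            tiny_operator.scanplan.positions,
            (8, 8),
        )
        assert poisson_nll(tiny_object, tiny_counts, tiny_operator) == pytest.approx(
            expected, rel=1e-12
        )

    def test_zero_count_terms_reduce_to_intensity(self, tiny_operator, tiny_object):
        y = np.zeros(
            (tiny_operator.n_positions, 4, 4)
        )
        total_intensity = tiny_operator.intensities(tiny_object).sum()
        assert poisson_nll(tiny_object, y, tiny_operator) == pytest.approx(
            total_intensity, rel=1e-12
        )

    def test_shape_mismatch_rejected(self, tiny_operator, tiny_object):
        with pytest.raises(ValueError):
            poisson_nll(tiny_object, np.ones((2, 4, 4)), tiny_operator)


class TestLikelihoodGradient:
    def test_zero_at_exact_data(self, tiny_operator, tiny_object):
        y = tiny_operator.intensities(tiny_object)
        g = likelihood_gradient(tiny_object, y, tiny_operator)
        assert np.abs(g).max() <= 1e-10

    def test_matches_finite_differences_everywhere(
        self, tiny_operator, tiny_object, tiny_counts
    ):
        g = likelihood_gradient(tiny_object, tiny_counts, tiny_operator)
        eps = 1e-6
        for i in range(8):
            for j in range(8):
                for comp, take in ((1.0, np.real), (1j, np.imag)):
                    tp = tiny_object.copy()
                    tp[i, j] += eps * comp
                    tm = tiny_object.copy()
                    tm[i, j] -= eps * comp
                    fd = (
                        poisson_nll(tp, tiny_counts, tiny_operator)
                        - poisson_nll(tm, tiny_counts, tiny_operator)
                    ) / (2 * eps)
                    assert take(g[i, j]) == pytest.approx(fd, rel=1e-5, abs=1e-7)

    def test_homogeneous_scaling(self, tiny_operator, tiny_object, tiny_counts):
        # Scaling y -> c y scales (I - y) terms of the bracket linearly at
        # intensities scaled by c as well: grad(cT..) relation via c|pT|^2.
        c = 4.0
        g1 = likelihood_gradient(
            np.sqrt(c) * tiny_object, c * tiny_counts, tiny_operator
        )
        g0 = likelihood_gradient(tiny_object, tiny_counts, tiny_operator)
        np.testing.assert_allclose(g1, np.sqrt(c) * c * g0 / c, rtol=1e-10)


class TestTruncation:
    def test_exact_data_retains_everything(self, tiny_operator, tiny_object):
        y = tiny_operator.intensities(tiny_object)
        mask = truncation_set(tiny_object, y, tiny_operator, alpha_h=5.0)
        assert mask.all()

    def test_huge_alpha_retains_everything(
        self, tiny_operator, tiny_object, tiny_counts
    ):
        mask = truncation_set(tiny_object, tiny_counts, tiny_operator, alpha_h=1e9)
        assert mask.all()

    def test_mask_matches_direct_inequality(self, tiny_operator, tiny_object, tiny_counts):
        alpha = 5.0
        amps = tiny_operator.apply(tiny_object)
        intens = np.abs(amps) ** 2
        resid = np.abs(tiny_counts - intens)
        km = tiny_counts.size
        bound = (
            (alpha / km)
            * resid.sum()
            * np.abs(amps)
            / np.linalg.norm(tiny_object)
        )
        expected = resid <= bound
        got = truncation_set(tiny_object, tiny_counts, tiny_operator, alpha)
        assert np.array_equal(got, expected)

    def test_retained_fraction_monotone_in_alpha(
        self, tiny_operator, tiny_object, tiny_counts
    ):
        fracs = [
            truncation_set(tiny_object, tiny_counts, tiny_operator, a).mean()
            for a in (1.0, 5.0, 20.0, 100.0, 1e6)
        ]
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))

    def test_zero_object_rejected(self, tiny_operator, tiny_counts):
        with pytest.raises(ValueError):
            truncation_set(
                np.zeros((8, 8), dtype=complex), tiny_counts, tiny_operator, 5.0
            )


class TestTruncatedGradient:
    def test_full_mask_equals_plain_gradient(
        self, tiny_operator, tiny_object, tiny_counts
    ):
        g_full = likelihood_gradient(tiny_object, tiny_counts, tiny_operator)
        g_trunc, retained = truncated_likelihood_gradient(
            tiny_object, tiny_counts, tiny_operator, alpha_h=1e9
        )
        assert retained == 1.0
        np.testing.assert_allclose(g_trunc, g_full, atol=1e-12)

    def test_masked_dense_oracle(self, tiny_operator, tiny_object, tiny_counts):
        alpha = 5.0
        dense = dense_design_matrix(
            tiny_operator.probe.values,
            tiny_operator.scanplan.positions,
            (8, 8),
        )
        amps = dense @ tiny_object.ravel()
        intens = np.abs(amps) ** 2
        floor = 1e-12 * intens[intens > 0].mean()
        yv = tiny_counts.ravel()
        resid = np.abs(yv - intens)
        bound = (
            (alpha / yv.size)
            * resid.sum()
            * np.abs(amps)
            / np.linalg.norm(tiny_object)
        )
        mask = resid <= bound
        factor = (1.0 - yv / np.maximum(intens, floor)) * mask
        expected = 2.0 * (dense.conj().T @ (factor * amps)).reshape(8, 8)
        got, _ = truncated_likelihood_gradient(
            tiny_object, tiny_counts, tiny_operator, alpha
        )
        np.testing.assert_allclose(got, expected, rtol=1e-8, atol=1e-10)

    def test_empty_retained_set_yields_zero_gradient(self, tiny_operator, caplog):
        # An object wildly inconsistent with tiny counts and alpha -> 0.
        t = 100.0 * np.ones((8, 8), dtype=complex)
        y = np.zeros((tiny_operator.n_positions, 4, 4))
        y[0, 0, 0] = 1.0
        with caplog.at_level(logging.WARNING):
            g, retained = truncated_likelihood_gradient(
                t, y, tiny_operator, alpha_h=1e-12
            )
        assert retained == 0.0
        assert np.all(g == 0)


class TestTikhonovPrior:
    def test_constant_object_has_zero_penalty_and_gradient(self):
        t = (0.5 + 0.5j) * np.ones((8, 8), dtype=complex)
        penalty, grad = tikhonov_prior(t, mu0=1e-2, kappa=1.0)
        assert penalty == 0.0
        assert np.abs(grad).max() == 0.0

    def test_gradient_matches_finite_differences(self, rng):
        t = rng.standard_normal((8, 8)) + 1j * rng.standard_normal((8, 8))
        mu0, kappa = 1e-2, 0.37
        _, grad = tikhonov_prior(t, mu0, kappa)
        eps = 1e-7
        for idx in [(0, 0), (3, 4), (7, 7), (5, 0)]:
            for comp, take in ((1.0, np.real), (1j, np.imag)):
                tp = t.copy()
                tp[idx] += eps * comp
                tm = t.copy()
                tm[idx] -= eps * comp
                fd = (
                    tikhonov_prior(tp, mu0, kappa)[0]
                    - tikhonov_prior(tm, mu0, kappa)[0]
                ) / (2 * eps)
                assert take(grad[idx]) == pytest.approx(fd, rel=1e-6, abs=1e-10)

    def test_kappa_closed_form(self):
        # N_pix = 128, K = 4 patterns, ||I||_1 = 8540 * 4.
        n_pix = 128
        n_m = n_pix**2 * 4
        i_l1 = 8540.0 * 4
        expected = 8.0 * n_pix**2 / (n_m * i_l1)
        assert tikhonov_kappa(n_pix, n_m, i_l1) == pytest.approx(expected, rel=1e-12)


class TestSparsePrior:
    def test_zero_at_reference(self, rng):
        t = rng.standard_normal((4, 4)) + 1j * rng.standard_normal((4, 4))
        state = DenoiserState(t_sparse=t.copy(), denoiser_id="identity")
        penalty, grad = sparse_prior(t, state, mu1=8e-2)
        assert penalty == 0.0
        assert np.abs(grad).max() == 0.0

    def test_linear_in_weight(self, rng):
        t = rng.standard_normal((4, 4)) + 1j * rng.standard_normal((4, 4))
        state = DenoiserState(
            t_sparse=np.zeros((4, 4), dtype=complex), denoiser_id="identity"
        )
        p1, g1 = sparse_prior(t, state, mu1=8e-2)
        p2, g2 = sparse_prior(t, state, mu1=16e-2)
        assert p2 == pytest.approx(2 * p1)
        np.testing.assert_allclose(g2, 2 * g1)

    def test_matches_hand_computation(self, rng):
        t = rng.standard_normal((8, 8)) + 1j * rng.standard_normal((8, 8))
        ref = rng.standard_normal((8, 8)) + 1j * rng.standard_normal((8, 8))
        state = DenoiserState(t_sparse=ref, denoiser_id="identity")
        mu1 = 8e-2
        penalty, grad = sparse_prior(t, state, mu1)
        assert penalty == pytest.approx(mu1 * np.sum(np.abs(t - ref) ** 2))
        np.testing.assert_allclose(grad, 2 * mu1 * (t - ref))


class TestDenoiser:
    def test_identity_roundtrip_exact(self, rng):
        t = 0.9 * np.exp(1j * 0.3 * rng.standard_normal((16, 16)))
        out = denoise_complex(t, "identity")
        np.testing.assert_allclose(out, t, atol=1e-9)

    def test_domain_coloring_inverse(self, rng):
        t = rng.standard_normal((8, 8)) + 1j * rng.standard_normal((8, 8))
        np.testing.assert_allclose(
            domain_uncolor(*domain_color(t)), t, atol=1e-12
        )

    def test_constant_field_maps_to_constant(self):
        t = (0.8 * np.exp(0.2j)) * np.ones((16, 16), dtype=complex)
        out = denoise_complex(t, "wavelet")
        np.testing.assert_allclose(out, t, atol=1e-9)

    def test_wavelet_denoising_reduces_error(self, rng):
        truth, _ = generate_phantom(PhantomSpec(grid=(64, 64), seed=3))
        noisy = truth.values + 0.05 * (
            rng.standard_normal((64, 64)) + 1j * rng.standard_normal((64, 64))
        )
        denoised = denoise_complex(noisy, "wavelet")
        err_before = np.linalg.norm(noisy - truth.values)
        err_after = np.linalg.norm(denoised - truth.values)
        assert err_after < err_before

    def test_unknown_denoiser_rejected(self, rng):
        with pytest.raises(ValueError):
            refresh_denoiser(np.ones((4, 4), dtype=complex), "no-such-filter")


class TestInitialization:
    def test_random_unit_amplitude_and_determinism(self):
        a = random_initialize((64, 64), seed=3)
        b = random_initialize((64, 64), seed=3)
        np.testing.assert_array_equal(a.values, b.values)
        np.testing.assert_allclose(np.abs(a.values), 1.0, atol=1e-15)

    def test_random_phase_moments(self):
        obj = random_initialize((256, 256), seed=8)
        phase = np.angle(obj.values)
        n = phase.size
        se_mean = np.sqrt(0.1 / n)
        assert abs(phase.mean() - 0.1) < 3 * se_mean
        # variance of the sample variance ~ 2 sigma^4 / n
        se_var = np.sqrt(2 * 0.1**2 / n)
        assert abs(phase.var() - 0.1) < 3 * se_var

    def test_percentile_rule_retains_exact_count(self, rng):
        y = rng.uniform(0, 10, size=(5, 8, 8))
        mask = intensity_percentile_mask(y, 80.0)
        assert mask.sum() == int(np.ceil(0.2 * y.size))

    def test_dense_eigensolver_oracle(self, rng):
        # 2x2 probe, 4x4 object (N = 16), dense H = D^-1 P+ M P.
        psi = rng.standard_normal((2, 2)) + 1j * rng.standard_normal((2, 2))
        probe = make_probe(psi)
        scan = raster_scan((4, 4), (2, 2), step=1)
        op = ForwardOperator(probe=probe, scanplan=scan, object_shape=(4, 4))
        t = rng.standard_normal((4, 4)) + 1j * rng.standard_normal((4, 4))
        y = op.intensities(t)
        config = ReconConfig(power_iters=200, seed=2)

        dense = dense_design_matrix(psi, scan.positions, (4, 4))
        mask = intensity_percentile_mask(y, config.spectral_percentile).ravel()
        power = op.probe_power_map().ravel()
        inv_power = 1.0 / np.maximum(power, 1e-6 * power.max())
        h = np.diag(inv_power) @ dense.conj().T @ np.diag(mask.astype(float)) @ dense
        evals, evecs = np.linalg.eig(h)
        v_dense = evecs[:, np.argmax(np.abs(evals))]
        v_dense /= np.linalg.norm(v_dense)

        v_power = _spectral_eigenvector(y, op, config).ravel()
        overlap = abs(np.vdot(v_dense, v_power))
        assert overlap >= 0.999

    def test_spectral_phase_correlates_with_truth(self):
        # Noiseless high-count data, 32^2 pure-phase phantom, dense scan;
        # median Pearson correlation of the initial phase with the truth
        # over probe realizations.
        from cryoptycho.probes import make_random_probe
        from cryoptycho.workflows import small_geometry
        from cryoptycho.forward import forward_apply
        from cryoptycho.metrics import align_global_scale

        geom = small_geometry(16)
        truth, _ = generate_phantom(
            PhantomSpec(
                grid=(32, 32), pixel_size=1.7, n_pseudo_atoms=12,
                imfp_protein=3200.0, seed=0,
            )
        )
        corrs = []
        for probe_seed in (1, 2, 3):
            probe = make_random_probe(geom, 1.5, probe_seed, 1.0)
            scan = raster_scan(truth.shape, probe.field.shape, step=1)
            op = ForwardOperator(
                probe=probe, scanplan=scan, object_shape=truth.shape
            )
            y = forward_apply(truth, op).data * 1e4
            init = spectral_initialize(
                y, op, ReconConfig(power_iters=200, seed=5)
            )
            aligned = align_global_scale(truth.values, init.values)
            power = op.probe_power_map()
            core = power > 0.3 * power.max()
            corrs.append(
                np.corrcoef(
                    np.angle(truth.values)[core], np.angle(aligned)[core]
                )[0, 1]
            )
        assert np.median(corrs) >= 0.9

    def test_all_zero_counts_rejected(self, tiny_operator):
        with pytest.raises(ValueError):
            spectral_initialize(
                np.zeros((4, 4, 4)), tiny_operator, ReconConfig()
            )


class TestReconstruct:
    def test_plain_ml_reduction_objective_is_nll(
        self, tiny_operator, tiny_counts
    ):
        config = ReconConfig(
            prior="none", alpha_h=np.inf, max_iters=5, seed=0
        )
        state = reconstruct(tiny_counts, tiny_operator, config)
        final_nll = poisson_nll(state.current.values, tiny_counts, tiny_operator)
        assert state.objective_trace[-1] == pytest.approx(final_nll, rel=1e-10)

    def test_objective_trace_non_increasing(self, tiny_operator, tiny_counts):
        config = ReconConfig(prior="none", alpha_h=np.inf, max_iters=30, seed=0)
        state = reconstruct(tiny_counts, tiny_operator, config)
        trace = np.asarray(state.objective_trace)
        assert np.all(np.diff(trace) <= 1e-9 * np.abs(trace[:-1]) + 1e-9)

    def test_recovers_small_phantom_at_high_counts(self):
        from cryoptycho.metrics import nrmse
        from cryoptycho.workflows import small_geometry, build_probe
        from cryoptycho.forward import forward_apply
        from cryoptycho.geometry import ComplexField2D

        geom = small_geometry(16)
        truth, _ = generate_phantom(
            PhantomSpec(grid=(32, 32), pixel_size=1.7, n_pseudo_atoms=12, seed=1)
        )
        probe = build_probe("random", geom, seed=2)
        scan = raster_scan(truth.shape, probe.field.shape, step=4)
        op = ForwardOperator(probe=probe, scanplan=scan, object_shape=truth.shape)
        rng = np.random.default_rng(3)
        y = rng.poisson(1e4 * op.intensities(truth.values)).astype(float)
        state = reconstruct(
            y, op, ReconConfig(prior="none", alpha_h=np.inf, max_iters=150, seed=4)
        )
        px = truth.pixel_size
        sl = np.s_[8:24, 8:24]
        err = nrmse(
            ComplexField2D(truth.values[sl], px),
            ComplexField2D(state.current.values[sl], px),
        )
        assert err <= 0.1
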