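import numpy as np
import pytest

from tomodl import (DenoiserParams, ForwardModel, Geometry, UnrolledConfig,
                    build_sampling, cg_solve, count_parameters,
                    data_consistency, denoiser_forward, inscribed_circle_mask,
                    load_checkpoint, normal_operator, save_checkpoint,
                    tomodl_reconstruct)
from tomodl.unrolled import _normalize_image

from .conftest import dense_matrix


class TestNormalOperator:
    def test_zero_input(self, model16):
        assert np.all(normal_operator(np.zeros((16, 16)), model16, 0.0) == 0.0)

    def test_symmetry(self, model16_sub, rng):
        for _ in range(10):
            x = rng.normal(size=(16, 16))
            y = rng.normal(size=(16, 16))
            lhs = float(np.vdot(normal_operator(x, model16_sub, 0.3), y))
            rhs = float(np.vdot(x, normal_operator(y, model16_sub, 0.3)))
            assert abs(lhs - rhs) / (np.linalg.norm(x) * np.linalg.norm(y)) < 1e-5

    def test_empty_sampling_reduces_to_scaled_identity(self, geom16, rng):
        from tomodl.radon import SamplingScheme
        empty = SamplingScheme(24, 24, 0, ())
        A = ForwardModel(geom16, empty)
        x = rng.normal(size=(16, 16))
        assert np.allclose(normal_operator(x, A, 0.7), 0.7 * x)


class TestCGSolve:
    def test_recovers_constructed_solution(self, model16_sub, rng):
        x_star = rng.normal(size=(16, 16))
        lam = 0.2
        rhs = normal_operator(x_star, model16_sub, lam)
        x = cg_solve(rhs, model16_sub, lam, tol=1e-10, max_iter=500)
        assert np.linalg.norm(x - x_star) / np.linalg.norm(x_star) < 1e-4

    def test_matches_dense_direct_solve(self, model16_sub, rng):
        R = dense_matrix(model16_sub)
        lam = 0.15
        M = R.T @ R + lam * np.eye(R.shape[1])
        rhs = rng.normal(size=(16, 16))
        dense = np.linalg.solve(M, rhs.ravel()).reshape(16, 16)
        x = cg_solve(rhs, model16_sub, lam, tol=1e-10, max_iter=500)
        assert np.linalg.norm(x - dense) / np.linalg.norm(dense) < 1e-4

    def test_identity_dominated_limit(self, model16_sub, rng):
        rhs = rng.normal(size=(16, 16))
        lam = 1e6
        x = cg_solve(rhs, model16_sub, lam, tol=1e-10, max_iter=200)
        assert np.linalg.norm(x - rhs / lam) / np.linalg.norm(rhs / lam) < 1e-3

    def test_nonpositive_lambda_rejected(self, model16_sub):
        with pytest.raises(ValueError):
            cg_solve(np.zeros((16, 16)), model16_sub, 0.0)


class TestDataConsistency:
    def test_large_lambda_returns_normalised_prior(self, model16_sub, rng):
        cfg = UnrolledConfig(K=1, N_L=2, n_filters=4, cg_tol=1e-12, cg_max_iter=500)
        z = rng.random((16, 16))
        atb = rng.random((16, 16))
        mask = inscribed_circle_mask(16)
        out = data_consistency(z, atb, model16_sub, 1e8, cfg)
        assert np.abs(out - _normalize_image(z, mask)).max() < 1e-3

    def test_small_lambda_approaches_pseudoinverse(self, model16, rng):
        """With z=0 and lambda -> 0+ the update tends to the least-norm
        least-squares solution (dense SVD oracle).  The fully sampled model
        keeps the nonzero singular values bounded away from sqrt(lambda)."""
        x_true = rng.random((16, 16))
        x_true[~inscribed_circle_mask(16)] = 0.0
        b = model16.project(x_true)
        R = dense_matrix(model16)
        x_pinv = (np.linalg.pinv(R, rcond=1e-8) @ b.ravel()).reshape(16, 16)
        errs = []
        for lam, iters in ((1e-3, 2000), (1e-5, 4000), (1e-7, 8000)):
            x = cg_solve(model16.backproject(b), model16, lam,
                         tol=1e-14, max_iter=iters)
            errs.append(np.linalg.norm(x - x_pinv) / np.linalg.norm(x_pinv))
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 1e-2

    def test_fixed_point_on_consistent_data(self, shepp64):
        """Fully sampled noiseless data with z = truth: the update returns
        (up to normalisation) the truth for small lambda."""
        geom = Geometry.uniform(64, 120)
        A = ForwardModel(geom)
        b = A.project(shepp64)
        lam = 1e-3
        x = cg_solve(A.backproject(b) + lam * shepp64, A, lam,
                     tol=1e-12, max_iter=2000)
        mask = inscribed_circle_mask(64)
        rel = np.linalg.norm((x - shepp64)[mask]) / np.linalg.norm(shepp64[mask])
        assert rel < 1e-2


class TestDenoiser:
    def test_zero_weights_give_identity(self, rng):
        cfg = UnrolledConfig(K=1, N_L=4, n_filters=8)
        theta = DenoiserParams(cfg, seed=0)
        for w in theta.weights:
            w.data[:] = 0.0
        x = rng.random((20, 20))
        assert np.allclose(denoiser_forward(x, theta), x)

    @pytest.mark.parametrize("size", [64, 100])
    def test_fully_convolutional_shapes(self, size, rng):
        theta = DenoiserParams(UnrolledConfig(K=1, N_L=3, n_filters=4), seed=0)
        out = denoiser_forward(rng.random((size, size)), theta)
        assert out.shape == (size, size)

    def test_last_layer_can_increase_values(self, rng):
        """No ReLU on the final layer: a negative noise estimate must be able
        to push the output above the input."""
        cfg = UnrolledConfig(K=1, N_L=2, n_filters=1, use_batchnorm=False)
        theta = DenoiserParams(cfg, seed=0)
        theta.weights[0].data[:] = 0.0
        theta.biases[0].data[:] = 1.0   # positive feature everywhere
        theta.weights[1].data[:] = 0.0
        theta.weights[1].data[1, 1, 0, 0] = -1.0  # centre tap: noise = -1
        x = rng.random((12, 12))
        out = denoiser_forward(x, theta)
        assert np.all(out > x)


class TestUnrolledReconstruction:
    def test_identity_denoiser_reduces_to_data_consistency(self, model16, rng):
        """Zero noise-learner weights, K=1, small lambda: the output is the
        (normalised) pseudo-inverse solution."""
        x_true = rng.random((16, 16))
        mask = inscribed_circle_mask(16)
        x_true[~mask] = 0.0
        b = model16.project(x_true)
        cfg = UnrolledConfig(K=1, N_L=2, n_filters=2, lambda_init=1e-7,
                             cg_tol=1e-14, cg_max_iter=8000)
        theta = DenoiserParams(cfg, seed=0)
        for w in theta.weights:
            w.data[:] = 0.0
        out = tomodl_reconstruct(b, model16, theta, cfg)
        R = dense_matrix(model16)
        x_pinv = (np.linalg.pinv(R, rcond=1e-8) @ b.ravel()).reshape(16, 16)
        expected = _normalize_image(x_pinv, mask)
        assert np.abs(out - expected).max() < 1e-2

    def test_k0_returns_normalised_backprojection(self, model16_sub, rng):
        b = rng.random((model16_sub.n_angles, 16))
        cfg = UnrolledConfig(K=0, N_L=2, n_filters=2)
        theta = DenoiserParams(cfg, seed=0)
        out = tomodl_reconstruct(b, model16_sub, theta, cfg)
        mask = inscribed_circle_mask(16)
        expected = _normalize_image(model16_sub.backproject(b), mask)
        assert np.abs(out - expected).max() < 1e-5

    def test_zero_denoiser_iteration_contracts_to_fixed_point(self, model16_sub, rng):
        """With D = identity the unroll is a fixed-point iteration of the
        normalised data-consistency map: successive iterates approach each
        other, so the output becomes independent of K."""
        x_true = rng.random((16, 16))
        x_true[~inscribed_circle_mask(16)] = 0.0
        b = model16_sub.project(x_true)

        def run(K):
            cfg = UnrolledConfig(K=K, N_L=2, n_filters=2, lambda_init=0.05,
                                 cg_tol=1e-12, cg_max_iter=1000)
            theta = DenoiserParams(cfg, seed=0, dtype=np.float64)
            for w in theta.weights:
                w.data[:] = 0.0
            return tomodl_reconstruct(b, model16_sub, theta, cfg)

        x1, x2, x16, x17 = run(1), run(2), run(16), run(17)
        early = np.abs(x2 - x1).max()
        late = np.abs(x17 - x16).max()
        assert late < 0.05 * early
        assert late < 5e-4

    def test_accepts_zero_padded_full_sinogram(self, model16_sub, rng):
        from tomodl import apply_zero_pad_mask
        b_full = rng.random((24, 16))
        masked = apply_zero_pad_mask(b_full, model16_sub.scheme)
        cfg = UnrolledConfig(K=1, N_L=2, n_filters=2)
        theta = DenoiserParams(cfg, seed=0)
        a = tomodl_reconstruct(masked, model16_sub, theta, cfg)
        bsub = b_full[sorted(model16_sub.scheme.retained_indices)]
        bb = tomodl_reconstruct(bsub, model16_sub, theta, cfg)
        assert np.allclose(a, bb)


class TestParameterCount:
    def test_default_is_about_two_hundred_thousand(self):
        theta = DenoiserParams(UnrolledConfig())  # N_L=8, 64 filters
        count = count_parameters(theta)
        # rounds to 2e5 at one significant figure
        assert round(count, -int(np.floor(np.log10(count)))) == 200_000

    def test_tiny_hand_count(self):
        cfg = UnrolledConfig(K=1, N_L=2, n_filters=1, use_batchnorm=False,
                             lambda_learnable=False)
        assert count_parameters(DenoiserParams(cfg)) == 20
        cfg2 = UnrolledConfig(K=1, N_L=2, n_filters=1, use_batchnorm=False,
                              lambda_learnable=True)
        assert count_parameters(DenoiserParams(cfg2)) == 21

    def test_closed_form_and_filter_scaling(self):
        def closed_form(nl, f, bn=True, lam=True):
            total = 9 * f + f                    # first layer 1 -> f
            total += (nl - 2) * (9 * f * f + f)  # middle convs
            if bn:
                total += (nl - 2) * 2 * f        # batch-norm affine
            total += 9 * f + 1                   # last layer f -> 1
            return total + (1 if lam else 0)

        for nl, f in [(4, 32), (8, 64), (8, 128)]:
            cfg = UnrolledConfig(K=1, N_L=nl, n_filters=f)
            assert count_parameters(DenoiserParams(cfg)) == closed_form(nl, f)
        mid64 = 6 * (9 * 64 * 64 + 64)
        mid128 = 6 * (9 * 128 * 128 + 128)
        assert 3.9 < mid128 / mid64 < 4.1


def test_checkpoint_roundtrip(tmp_path, model16_sub, rng):
    cfg = UnrolledConfig(K=2, N_L=3, n_filters=4, lambda_init=0.07)
    theta = DenoiserParams(cfg, seed=5)
    b = rng.random((model16_sub.n_angles, 16))
    before = tomodl_reconstruct(b, model16_sub, theta, cfg)
    path = tmp_path / "model.ckpt"
    save_checkpoint(path, theta, extra={"R": 3})
    theta2 = load_checkpoint(path)
    assert theta2.cfg == cfg
    after = tomodl_reconstruct(b, model16_sub, theta2, cfg)
    assert np.array_equal(before, after)
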