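"""Graph-guided decoding: solvers, residual refinement, decoding objective."""

import numpy as np
import pytest

import autograd.numpy as anp
from lcen.data import PhenotypeGraph, project_adjacency
from lcen.decoder import (
    DecoderSpec,
    adjacency_from_triu,
    constrain_adjacency,
    decode,
    decode_loss,
    init_decoder,
    residual_refine,
    structural_gaussian_nll,
)
from lcen.nn import fit_adam


def identity_decoder_params(rng, d_z, d_y, spec, W_d=None):
    """Params whose base map is exactly W_d (pre layer = identity)."""
    params = init_decoder(rng, d_z, d_y, spec)
    params["pre"]["W"] = np.eye(d_z, spec.hidden_widths[0])
    params["pre"]["b"][:] = 0
    if W_d is not None:
        params["out"]["W"] = np.asarray(W_d, dtype=float).T
    params["out"]["b"][:] = 0
    return params


SPEC22 = DecoderSpec(hidden_widths=(2, 4), residual_block=False)


class TestDecode:
    def test_no_graph_message_passing_is_linear_map(self, rng):
        spec = DecoderSpec(hidden_widths=(2, 4), residual_block=False)
        W_d = rng.normal(size=(3, 2))
        params = identity_decoder_params(rng, 2, 3, spec, W_d)
        z = rng.normal(size=(5, 2))
        y = decode(z, PhenotypeGraph(np.zeros((3, 3))), spec, params)
        assert np.allclose(y, z @ W_d.T, atol=1e-12)

    def test_two_by_two_closed_form(self, rng):
        params = identity_decoder_params(rng, 2, 2, SPEC22, W_d=np.eye(2))
        g = PhenotypeGraph(np.array([[0.0, 0.5], [0.5, 0.0]]))
        y = decode(np.array([[1.0, 0.0]]), g, SPEC22, params)
        assert np.allclose(y, [[4 / 3, 2 / 3]], atol=1e-12)

    def test_unrolled_matches_closed_form(self, rng):
        spec_u = DecoderSpec(hidden_widths=(3, 4), residual_block=False,
                             solver="unrolled", unroll_steps=50)
        spec_c = DecoderSpec(hidden_widths=(3, 4), residual_block=False)
        for _ in range(20):
            d_y = 4
            # radius 0.7: the 50-term truncation error rho^51/(1-rho) < 1e-6
            A = project_adjacency(rng.normal(size=(d_y, d_y)), delta=0.1).adjacency
            A *= 0.7 / max(np.abs(np.linalg.eigvalsh(A)).max(), 1e-9)
            g = PhenotypeGraph(A)
            params = identity_decoder_params(rng, 3, d_y, spec_c, rng.normal(size=(d_y, 3)))
            z = rng.normal(size=(6, 3))
            assert np.allclose(
                decode(z, g, spec_u, params), decode(z, g, spec_c, params), atol=1e-6
            )

    def test_refuses_unit_spectral_radius(self, rng):
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        params = identity_decoder_params(rng, 2, 2, SPEC22, np.eye(2))
        with pytest.raises(ValueError, match="project"):
            decode(np.ones((1, 2)), PhenotypeGraph(A), SPEC22, params)

    def test_linear_in_z_without_residual(self, rng):
        spec = DecoderSpec(hidden_widths=(3, 4), residual_block=False)
        params = init_decoder(rng, 3, 4, spec)
        g = project_adjacency(rng.normal(size=(4, 4)))
        params["pre"]["b"][:] = 0
        params["out"]["b"][:] = 0
        z1, z2 = rng.normal(size=(2, 5, 3))
        a, b = 0.7, -1.3
        lhs = decode(a * z1 + b * z2, g, spec, params)
        rhs = a * decode(z1, g, spec, params) + b * decode(z2, g, spec, params)
        assert np.allclose(lhs, rhs, atol=1e-8)


class TestResidualRefine:
    def test_zero_initialized_block_is_identity(self, rng):
        spec = DecoderSpec(hidden_widths=(2, 8))
        params = init_decoder(rng, 2, 3, spec)
        y = rng.normal(size=(4, 3))
        assert np.allclose(residual_refine(y, spec, params), y, atol=1e-12)

    def test_linear_activation_known_weights(self, rng):
        spec = DecoderSpec(hidden_widths=(2, 2), activation="linear")
        params = init_decoder(rng, 2, 2, spec)
        params["res1"]["W"] = np.array([[1.0, 0.0], [0.0, 2.0]])
        params["res1"]["b"] = np.array([0.5, -0.5])
        params["res2"]["W"] = np.array([[1.0, 1.0], [0.0, 1.0]])
        params["res2"]["b"] = np.array([0.0, 1.0])
        y = np.array([[1.0, 2.0]])
        h = y @ params["res1"]["W"] + params["res1"]["b"]  # (1.5, 3.5)
        expected = y + h @ params["res2"]["W"] + params["res2"]["b"]
        assert np.allclose(residual_refine(y, spec, params), expected)

    def test_difference_is_exactly_residual_branch(self, rng):
        spec = DecoderSpec(hidden_widths=(2, 6))
        params = init_decoder(rng, 2, 3, spec)
        params["res2"]["W"] = rng.normal(size=(6, 3))
        y = rng.normal(size=(5, 3))
        from lcen.nn import apply_linear, gelu

        branch = apply_linear(params["res2"], gelu(apply_linear(params["res1"], y)))
        assert np.allclose(residual_refine(y, spec, params) - y, branch, atol=1e-12)


class TestDecodeLoss:
    def test_perfect_predictions_zero(self, rng):
        y = rng.normal(size=(3, 2))
        total, comps = decode_loss(y, y, PhenotypeGraph(np.zeros((2, 2))))
        assert total == pytest.approx(0.0)

    def test_all_ones_error_batch_mean_dim_sum(self):
        y_true = np.zeros((2, 3))
        y_pred = np.ones((2, 3))
        total, _ = decode_loss(y_true, y_pred, np.zeros((3, 3)))
        assert total == pytest.approx(3.0)

    def test_components_sum_to_total(self, rng):
        d = 4
        g = project_adjacency(rng.normal(size=(d, d)))
        y_t, y_p = rng.normal(size=(2, 6, d))
        total, comps = decode_loss(
            y_t, y_p, g, lambdas={"graph": 0.3, "sparsity": 0.1, "symmetry": 0.2}
        )
        assert total == pytest.approx(sum(comps.values()), abs=1e-12)

    def test_negative_weight_rejected(self, rng):
        y = rng.normal(size=(2, 2))
        with pytest.raises(ValueError):
            decode_loss(y, y, np.zeros((2, 2)), lambdas={"graph": -1.0})

    def test_loss_decreases_over_first_50_steps(self, rng):
        # noiseless linear instance: y = (I - A)^{-1} W z
        d_z, d_y, n = 3, 4, 64
        A = project_adjacency(np.random.default_rng(0).normal(size=(d_y, d_y))).adjacency * 0.5
        W = np.random.default_rng(1).normal(size=(d_y, d_z))
        z = np.random.default_rng(2).normal(size=(n, d_z))
        y = np.linalg.solve(np.eye(d_y) - A, (z @ W.T).T).T
        spec = DecoderSpec(hidden_widths=(d_z, 4), residual_block=False)
        g = PhenotypeGraph(A)
        params = init_decoder(np.random.default_rng(3), d_z, d_y, spec)

        def loss(p):
            total, _ = decode_loss(y, decode(z, g, spec, p), g)
            return total

        # plain gradient descent with a small step is monotone on this
        # smooth instance; Adam's adaptive steps may overshoot early on
        from autograd import value_and_grad
        from autograd.misc import flatten

        flat, unflatten = flatten(params)
        vg = value_and_grad(lambda f: loss(unflatten(f)))
        losses = []
        for _ in range(50):
            val, grad = vg(flat)
            losses.append(float(val))
            flat = flat - 1e-3 * grad
        assert all(b <= a + 1e-9 for a, b in zip(losses, losses[1:]))


class TestLearnableAdjacency:
    def test_triu_parameterization_symmetric_zero_diagonal(self, rng):
        t = rng.normal(size=10)  # d_y = 5
        A = np.asarray(adjacency_from_triu(t, 5))
        assert np.allclose(A, A.T)
        assert np.all(np.diag(A) == 0)

    def test_constraint_caps_spectral_radius(self, rng):
        A = np.asarray(constrain_adjacency(adjacency_from_triu(rng.normal(size=45) * 5, 10)))
        assert np.abs(np.linalg.eigvalsh(A)).max() <= 0.95 + 1e-9

    def test_structural_nll_prefers_true_adjacency(self, rng):
        # at the generating parameters the NLL beats the A=0 reparameterization
        d_y, d_z, n = 4, 2, 2000
        local = np.random.default_rng(5)
        A = np.zeros((d_y, d_y))
        A[0, 1] = A[1, 0] = 0.6
        A[2, 3] = A[3, 2] = -0.5
        W = local.normal(size=(d_y, d_z))
        z = local.normal(size=(n, d_z))
        eps = 0.3 * local.normal(size=(n, d_y))
        y = np.linalg.solve(np.eye(d_y) - A, (z @ W.T + eps).T).T
        spec = DecoderSpec(hidden_widths=(d_z, 4), residual_block=False)
        p_true = identity_decoder_params(rng, d_z, d_y, spec, W)
        p_null = identity_decoder_params(rng, d_z, d_y, spec, np.linalg.solve(np.eye(d_y) - A, W))
        lv = float(np.log(0.3**2))
        nll_true = structural_gaussian_nll(y, z, spec, p_true, log_var_obs=lv, graph=PhenotypeGraph(A))
        nll_null = structural_gaussian_nll(y, z, spec, p_null, log_var_obs=lv, graph=PhenotypeGraph(np.zeros((d_y, d_y))))
        assert float(nll_true) < float(nll_null)
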