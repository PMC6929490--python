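"""Capsule primitives (squash, routing, margin loss) and the evolutionary model.

The miniature forward-pass test compares the model against a straight-line
NumPy reimplementation written with explicit loops.
"""

import numpy as np
import pytest

from memtype.capsule_model import (EvoModelSpec, MarginLossParams,
                                   build_evolutionary_model,
                                   conv_pool_output_shape, dynamic_routing,
                                   margin_loss, margin_loss_batch,
                                   predict_proba_caps, squash)
from memtype.nn.autograd import Tensor


class TestGeometry:
    def test_evolutionary_stack_reaches_372_by_2(self):
        s1 = conv_pool_output_shape((1500, 20), 5, pool=2)
        s2 = conv_pool_output_shape(s1, 5, pool=2)
        assert s2 == (372, 2)

    def test_same_padding_strided(self):
        assert conv_pool_output_shape((1500,), 15, stride=10,
                                      padding="same") == (150,)

    def test_exact_fit_valid(self):
        assert conv_pool_output_shape((5,), 5) == (1,)

    def test_kernel_too_large(self):
        with pytest.raises(ValueError, match="kernel"):
            conv_pool_output_shape((3,), 5)

    def test_default_spec_capsule_counts(self):
        spec = EvoModelSpec()
        assert spec.spatial_shape == (372, 2)
        assert spec.primary_capsule_count == 2976
        assert spec.caps_dim == 16 and spec.n_classes == 8
        assert spec.routing_iterations == 3 and spec.lr == 1e-4


class TestSquash:
    def test_zero_maps_to_zero(self):
        np.testing.assert_allclose(squash(np.zeros(5)), 0.0)

    def test_unit_norm_halves(self):
        v = squash(np.array([0.0, 1.0, 0.0]))
        assert np.linalg.norm(v) == pytest.approx(0.5, abs=1e-6)

    def test_norm_three_gives_nine_tenths(self):
        v = squash(np.array([3.0, 0.0]))
        assert np.linalg.norm(v) == pytest.approx(0.9, abs=1e-6)

    def test_output_parallel_to_input(self):
        s = np.array([1.0, 2.0, -2.0])
        v = squash(s)
        cos = v @ s / (np.linalg.norm(v) * np.linalg.norm(s))
        assert cos == pytest.approx(1.0)

    def test_monotone_and_bounded_on_norm_grid(self):
        norms = np.linspace(0.01, 50, 200)
        out = np.array([np.linalg.norm(squash(np.array([n, 0.0])))
                        for n in norms])
        assert (np.diff(out) > 0).all() and (out < 1.0).all()

    def test_as_printed_mode_peaks_at_half(self):
        # the non-monotone variant: norm n/(1+n^2), maximal at n=1
        out = [np.linalg.norm(squash(np.array([n, 0.0]), mode="as_printed"))
               for n in (0.5, 1.0, 3.0)]
        assert out[1] == pytest.approx(0.5, abs=1e-6)
        assert out[1] > out[0] and out[1] > out[2]

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            squash(np.ones(2), mode="bogus")


class TestRouting:
    def test_initial_couplings_uniform_over_eight(self):
        u_hat = np.random.default_rng(0).normal(size=(3, 5, 8, 4))
        _, c = dynamic_routing(u_hat, iterations=1)
        np.testing.assert_allclose(c, 1.0 / 8.0)

    def test_coupling_conservation_every_round(self):
        rng = np.random.default_rng(1)
        u_hat = rng.normal(size=(2, 7, 4, 3))
        for iterations in (1, 2, 3, 5):
            _, c = dynamic_routing(u_hat, iterations)
            np.testing.assert_allclose(c.sum(axis=2), 1.0, atol=1e-12)
            assert (c >= 0).all()

    def test_zero_predictions_fixed_point(self):
        v, _ = dynamic_routing(np.zeros((2, 4, 3, 6)), iterations=4)
        np.testing.assert_allclose(v, 0.0, atol=1e-9)

    def test_matches_hand_iterated_oracle(self):
        # I=2 input capsules, J=2 output capsules, 2 dims, 3 rounds
        u_hat = np.array([[[[1.0, 0.0], [0.0, 2.0]],
                           [[0.5, 0.5], [-1.0, 0.0]]]])   # (1, 2, 2, 2)

        def squash_np(s):
            n2 = (s ** 2).sum()
            return s * np.sqrt(n2 + 1e-12) / (1 + n2)

        b = np.zeros((2, 2))
        for _ in range(3):
            e = np.exp(b - b.max(axis=1, keepdims=True))
            c_exp = e / e.sum(axis=1, keepdims=True)
            s = np.einsum("ij,ijd->jd", c_exp, u_hat[0])
            v_exp = np.stack([squash_np(s[j]) for j in range(2)])
            b = b + np.einsum("ijd,jd->ij", u_hat[0], v_exp)
        v, c = dynamic_routing(u_hat, iterations=3)
        np.testing.assert_allclose(v[0], v_exp, atol=1e-10)
        np.testing.assert_allclose(c[0], c_exp, atol=1e-10)

    def test_invalid_iterations(self):
        with pytest.raises(ValueError):
            dynamic_routing(np.zeros((1, 2, 2, 2)), iterations=0)


class TestMarginLoss:
    def test_zero_when_margins_satisfied(self):
        norms = np.array([0.05, 0.95, 0.05, 0.05])
        assert margin_loss(norms, label=2) == 0.0

    def test_all_zero_norms_gives_081(self):
        assert margin_loss(np.zeros(8), label=5) == pytest.approx(0.81)

    def test_all_high_norms_approach_2835(self):
        # every wrong capsule contributes lambda*(1-0.1)^2 -> 7*0.5*0.81
        norms = np.full(8, 1.0 - 1e-9)
        assert margin_loss(norms, label=1) == pytest.approx(2.835, abs=1e-6)

    def test_zero_iff_margins_met(self):
        assert margin_loss(np.array([0.9, 0.1]), label=1) == 0.0
        assert margin_loss(np.array([0.89, 0.1]), label=1) > 0.0
        assert margin_loss(np.array([0.9, 0.11]), label=1) > 0.0

    def test_invalid_norms_and_labels(self):
        with pytest.raises(ValueError, match="norms"):
            margin_loss(np.array([1.2, 0.0]), label=1)
        with pytest.raises(ValueError, match="label"):
            margin_loss(np.zeros(4), label=5)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            MarginLossParams(m_plus=0.1, m_minus=0.9)

    def test_gradient_matches_finite_difference_away_from_kinks(self):
        rng = np.random.default_rng(2)
        norms_val = rng.uniform(0.2, 0.8, size=(3, 4))
        onehot = np.eye(4)[[0, 2, 1]]
        norms = Tensor(norms_val, requires_grad=True)
        margin_loss_batch(norms, onehot).backward()
        eps = 1e-6
        for i in range(3):
            for j in range(4):
                plus, minus = norms_val.copy(), norms_val.copy()
                plus[i, j] += eps
                minus[i, j] -= eps
                numeric = (margin_loss_batch(Tensor(plus), onehot).data
                           - margin_loss_batch(Tensor(minus), onehot).data) / (2 * eps)
                assert abs(numeric - norms.grad[i, j]) < 1e-4


# -- miniature model vs straight-line oracle ---------------------------------

def _oracle_forward(model, x):
    """Loop-based reimplementation of the full evolutionary forward pass."""
    spec = model.spec

    def conv2d(inp, w, b):
        n, h, wd, c = inp.shape
        kh, kw, _, f = w.shape
        out = np.zeros((n, h - kh + 1, wd - kw + 1, f))
        for ni in range(n):
            for i in range(out.shape[1]):
                for j in range(out.shape[2]):
                    for fi in range(f):
                        acc = b[fi]
                        for ki in range(kh):
                            for kj in range(kw):
                                for ci in range(c):
                                    acc += inp[ni, i + ki, j + kj, ci] * w[ki, kj, ci, fi]
                        out[ni, i, j, fi] = acc
        return out

    def pool(inp, p):
        n, h, wd, c = inp.shape
        out = np.zeros((n, h // p, wd // p, c))
        for ni in range(n):
            for i in range(h // p):
                for j in range(wd // p):
                    out[ni, i, j] = inp[ni, i * p:(i + 1) * p,
                                        j * p:(j + 1) * p].mean(axis=(0, 1))
        return out

    def squash_np(s):
        n2 = (s ** 2).sum()
        return s * np.sqrt(n2 + 1e-12) / (1 + n2)

    h = x[..., None]
    h = np.maximum(conv2d(h, model.conv1.w.data, model.conv1.b.data), 0.0)
    h = pool(h, spec.pool)
    h = np.maximum(conv2d(h, model.conv2.w.data, model.conv2.b.data), 0.0)
    h = pool(h, spec.pool)
    h = conv2d(h, model.primary.w.data, model.primary.b.data)
    n = x.shape[0]
    u = h.reshape(n, spec.primary_capsule_count, spec.caps_dim)
    u = np.stack([[squash_np(u[ni, i]) for i in range(u.shape[1])]
                  for ni in range(n)])
    w = model.routing_w.data
    norms = np.zeros((n, spec.n_classes))
    for ni in range(n):
        u_hat = np.einsum("ijod,id->ijo", w, u[ni])
        b = np.zeros((u.shape[1], spec.n_classes))
        for _ in range(spec.routing_iterations):
            e = np.exp(b - b.max(axis=1, keepdims=True))
            c = e / e.sum(axis=1, keepdims=True)
            s = np.einsum("ij,ijo->jo", c, u_hat)
            v = np.stack([squash_np(s[j]) for j in range(spec.n_classes)])
            b = b + np.einsum("ijo,jo->ij", u_hat, v)
        norms[ni] = np.sqrt((v ** 2).sum(axis=1) + 1e-12)
    return norms


@pytest.fixture(scope="module")
def mini_model():
    spec = EvoModelSpec(T=26, width=16, n_classes=2, conv1_filters=2,
                        conv2_filters=3, caps_channels=1, caps_dim=2,
                        out_caps_dim=2, dropout=0.0, seed=4)
    return build_evolutionary_model(spec)


class TestModelForward:
    def test_miniature_forward_matches_oracle(self, mini_model):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(3, 26, 16))
        norms = mini_model.forward(Tensor(x)).data
        np.testing.assert_allclose(norms, _oracle_forward(mini_model, x),
                                   atol=1e-8)

    def test_scores_in_squash_range(self, mini_model):
        rng = np.random.default_rng(9)
        scores = predict_proba_caps(mini_model, rng.normal(size=(4, 26, 16)))
        assert (scores >= 0).all() and (scores < 1).all()

    def test_normalized_mode_preserves_argmax(self, mini_model):
        rng = np.random.default_rng(10)
        x = rng.normal(size=(5, 26, 16))
        raw = predict_proba_caps(mini_model, x)
        normed = predict_proba_caps(mini_model, x, normalize=True)
        np.testing.assert_allclose(normed.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_array_equal(raw.argmax(axis=1), normed.argmax(axis=1))

    def test_input_shape_mismatch(self, mini_model):
        with pytest.raises(ValueError, match="shape"):
            mini_model.forward(Tensor(np.zeros((1, 30, 16))))

    def test_full_scale_primary_capsule_geometry(self):
        # build the full 1500x20 model and push one profile through it
        model = build_evolutionary_model(EvoModelSpec(seed=0))
        x = np.random.default_rng(0).normal(size=(1, 1500, 20))
        norms, v, c = model.forward(Tensor(x), return_couplings=True)
        assert c.shape == (1, 2976, 8)
        assert v.shape == (1, 8, 16)
        assert (norms.data >= 0).all() and (norms.data < 1).all()
        np.testing.assert_allclose(c.data.sum(axis=2), 1.0, atol=1e-10)
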