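"""Architecture tests against independent scalar-loop oracles.

The oracles evaluate the gate/attention equations literally, element by
element, sharing nothing with the vectorized implementations they check.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from laidrivers.autodiff import Tensor
from laidrivers.networks import ANNNet, IMVNet, LSTMNet


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------- oracles
def lstm_step_oracle(p, h_prev, c_prev, x):
    """Literal per-element LSTM recurrence on 1-D state vectors."""
    d = h_prev.size
    hx = np.concatenate([h_prev, x])
    h_new, c_new = np.zeros(d), np.zeros(d)
    for k in range(d):
        i = sigmoid(sum(hx[m] * p["Wi"].data[m, k] for m in range(hx.size)) + p["bi"].data[k])
        f = sigmoid(sum(hx[m] * p["Wf"].data[m, k] for m in range(hx.size)) + p["bf"].data[k])
        o = sigmoid(sum(hx[m] * p["Wo"].data[m, k] for m in range(hx.size)) + p["bo"].data[k])
        cand = np.tanh(sum(hx[m] * p["Wc"].data[m, k] for m in range(hx.size)) + p["bc"].data[k])
        c_new[k] = f * c_prev[k] + i * cand
        h_new[k] = o * np.tanh(c_new[k])
    return h_new, c_new


def imv_step_oracle(p, h_prev, c_prev, x):
    """Literal per-variable tensorized recurrence; h_prev, c_prev: (N, d)."""
    N, d = h_prev.shape
    h_new, c_new = np.zeros((N, d)), np.zeros((N, d))
    for n in range(N):
        for k in range(d):
            wh = sum(h_prev[n, m] * p["Wj"].data[n, m, k] for m in range(d))
            j = np.tanh(wh + x[n] * p["Uj"].data[n, 0, k] + p["bj"].data[n, 0, k])
            gates = {}
            for gate in ("i", "f", "o"):
                wh = sum(h_prev[n, m] * p[f"W{gate}"].data[n, m, k] for m in range(d))
                gates[gate] = sigmoid(wh + x[n] * p[f"U{gate}"].data[n, 0, k]
                                      + p[f"b{gate}"].data[n, 0, k])
            c_new[n, k] = gates["f"] * c_prev[n, k] + gates["i"] * j
            h_new[n, k] = gates["o"] * np.tanh(c_new[n, k])
    return h_new, c_new


def attention_oracle(scores):
    """Direct softmax over time followed by the weighted-sum contract."""
    e = np.exp(scores - scores.max())
    return e / e.sum()


# ---------------------------------------------------------------- ANN
class TestANN:
    def test_zero_parameters_give_zero_output(self):
        net = ANNNet(7, 2, hidden=(4, 4))
        for v in net.params.values():
            v.data[:] = 0.0
        out = net.forward(np.random.default_rng(0).uniform(size=(5, 7, 2)))
        assert np.allclose(out.data, 0.0)

    def test_matches_hand_evaluated_tanh_chain(self):
        """Single-unit layers, hand-set weights, hand-evaluated chain."""
        net = ANNNet(1, 2, hidden=(1, 1))
        w0 = np.array([[0.3], [-0.2]])
        net.params["W0"].data = w0
        net.params["b0"].data = np.array([0.1])
        net.params["W1"].data = np.array([[0.5]])
        net.params["b1"].data = np.array([-0.4])
        net.params["W2"].data = np.array([[2.0]])
        net.params["b2"].data = np.array([0.25])
        x = np.array([[[0.7, 0.9]]])
        h1 = np.tanh(0.3 * 0.7 - 0.2 * 0.9 + 0.1)
        h2 = np.tanh(0.5 * h1 - 0.4)
        assert np.allclose(net.forward(x).data, 2.0 * h2 + 0.25)

    def test_batch_order_invariance(self, rng):
        net = ANNNet(7, 2, hidden=(8, 8), rng=rng)
        X = rng.uniform(size=(10, 7, 2))
        perm = rng.permutation(10)
        assert np.allclose(net.forward(X).data[perm], net.forward(X[perm]).data)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            ANNNet(7, 2, hidden=(4,)).forward(np.zeros((3, 6, 2)))


# ---------------------------------------------------------------- LSTM
class TestLSTM:
    def test_zero_parameters_zero_state(self):
        net = LSTMNet(2, hidden=4)
        for v in net.params.values():
            v.data[:] = 0.0
        h, c = net.step(Tensor(np.zeros((1, 4))), Tensor(np.zeros((1, 4))),
                        Tensor(np.ones((1, 2))))
        assert np.allclose(h.data, 0.0) and np.allclose(c.data, 0.0)

    def test_step_matches_scalar_loop_oracle(self, rng):
        for _ in range(25):
            net = LSTMNet(2, hidden=3, rng=rng)
            h0, c0 = rng.normal(size=3), rng.normal(size=3)
            x = rng.normal(size=2)
            h, c = net.step(Tensor(h0[None]), Tensor(c0[None]), Tensor(x[None]))
            h_ref, c_ref = lstm_step_oracle(net.params, h0, c0, x)
            assert np.allclose(h.data[0], h_ref, atol=1e-10)
            assert np.allclose(c.data[0], c_ref, atol=1e-10)

    def test_saturated_gates_pass_memory_through(self, rng):
        """f ~ 1 and i ~ 0 (large biases) leave the cell state unchanged."""
        net = LSTMNet(2, hidden=3, rng=rng)
        net.params["bf"].data[:] = 50.0
        net.params["bi"].data[:] = -50.0
        c0 = rng.normal(size=(1, 3))
        _, c = net.step(Tensor(np.zeros((1, 3))), Tensor(c0), Tensor(rng.normal(size=(1, 2))))
        assert np.allclose(c.data, c0, atol=1e-12)

    def test_forward_equals_iterated_oracle(self, rng):
        net = LSTMNet(2, hidden=3, rng=rng)
        X = rng.uniform(size=(1, 7, 2))
        h, c = np.zeros(3), np.zeros(3)
        for t in range(7):
            h, c = lstm_step_oracle(net.params, h, c, X[0, t])
        expected = h @ net.params["Wy"].data[:, 0] + net.params["by"].data[0]
        assert np.allclose(net.forward(X).data[0, 0], expected, atol=1e-10)

    def test_length_one_sequence_reduces_to_single_step(self, rng):
        net = LSTMNet(2, hidden=4, rng=rng)
        x = rng.uniform(size=(2, 1, 2))
        h, _ = net.step(Tensor(np.zeros((2, 4))), Tensor(np.zeros((2, 4))),
                        Tensor(x[:, 0, :]))
        head = h.data @ net.params["Wy"].data + net.params["by"].data
        assert np.allclose(net.forward(x).data, head, atol=1e-12)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            LSTMNet(2, hidden=2).forward(np.zeros((1, 0, 2)))


# ---------------------------------------------------------------- IMV
class TestIMV:
    def test_zero_parameters_zero_state(self):
        net = IMVNet(2, hidden=3)
        for k, v in net.params.items():
            v.data[:] = 0.0
        h, c = net.step(Tensor(np.zeros((2, 1, 3))), Tensor(np.zeros((2, 1, 3))),
                        Tensor(np.ones((2, 1, 1))))
        assert np.allclose(h.data, 0.0)

    def test_step_matches_scalar_loop_oracle(self, rng):
        for _ in range(25):
            net = IMVNet(2, hidden=2, rng=rng)
            h0, c0 = rng.normal(size=(2, 2)), rng.normal(size=(2, 2))
            x = rng.normal(size=2)
            h, c = net.step(Tensor(h0[:, None, :]), Tensor(c0[:, None, :]),
                            Tensor(x[:, None, None]))
            h_ref, c_ref = imv_step_oracle(net.params, h0, c0, x)
            assert np.allclose(h.data[:, 0, :], h_ref, atol=1e-10)
            assert np.allclose(c.data[:, 0, :], c_ref, atol=1e-10)

    def test_variables_stay_separate_before_attention(self, rng):
        """Perturbing variable 0's input leaves variable 1's state unchanged."""
        net = IMVNet(2, hidden=4, rng=rng)
        X = rng.uniform(size=(3, 5, 2))
        X2 = X.copy()
        X2[:, :, 0] += 0.5

        def hidden_after(Xin):
            h = Tensor(np.zeros((2, 3, 4)))
            c = Tensor(np.zeros((2, 3, 4)))
            for t in range(Xin.shape[1]):
                h, c = net.step(h, c, Tensor(np.ascontiguousarray(Xin[:, t, :].T)[:, :, None]))
            return h.data

        a, b = hidden_after(X), hidden_after(X2)
        assert not np.allclose(a[0], b[0])
        assert np.array_equal(a[1], b[1])

    def test_temporal_attention_matches_softmax_oracle(self, rng):
        net = IMVNet(2, hidden=3, rng=rng)
        h_seq = [Tensor(rng.normal(size=(2, 1, 3))) for _ in range(6)]
        alpha, g = net.temporal_attention(h_seq)
        for n in range(2):
            scores = np.array([
                np.tanh(h.data[n, 0] @ net.params["Wa"].data[n] + net.params["ba"].data[n, 0])
                @ net.params["wa"].data[n][:, 0] + net.params["ca"].data[n, 0, 0]
                for h in h_seq])
            ref = attention_oracle(scores)
            assert np.allclose(alpha.data[n, 0], ref, atol=1e-12)
            g_ref = sum(ref[t] * h_seq[t].data[n, 0] for t in range(6))
            assert np.allclose(g.data[n, 0], g_ref, atol=1e-12)

    def test_uniform_attention_for_constant_scores(self):
        net = IMVNet(2, hidden=3)
        for key in ("Wa", "wa"):
            net.params[key].data[:] = 0.0
        h_seq = [Tensor(np.random.default_rng(t).normal(size=(2, 4, 3))) for t in range(5)]
        alpha, _ = net.temporal_attention(h_seq)
        assert np.allclose(alpha.data, 1.0 / 5.0)

    def test_symmetric_variables_get_equal_weights(self, rng):
        """Identical inputs + identical per-variable parameters => Pr = 1/2."""
        net = IMVNet(2, hidden=3, rng=rng)
        for key, v in net.params.items():
            if v.data.ndim == 3 and v.data.shape[0] == 2:
                v.data[1] = v.data[0]
        X = rng.uniform(size=(4, 7, 1)).repeat(2, axis=2)
        _, record = net.forward(X, return_attention=True)
        assert np.allclose(record.variable_weights, 0.5, atol=1e-12)

    def test_forward_equals_composed_oracles(self, rng):
        """Full forward against step + attention + mixture oracles."""
        net = IMVNet(2, hidden=2, rng=rng)
        X = rng.uniform(size=(1, 4, 2))
        h = np.zeros((2, 2))
        c = np.zeros((2, 2))
        hist = []
        for t in range(4):
            h, c = imv_step_oracle(net.params, h, c, X[0, t])
            hist.append(h.copy())
        feats, prs = [], []
        for n in range(2):
            scores = np.array([
                np.tanh(ht[n] @ net.params["Wa"].data[n] + net.params["ba"].data[n, 0])
                @ net.params["wa"].data[n][:, 0] + net.params["ca"].data[n, 0, 0]
                for ht in hist])
            alpha = attention_oracle(scores)
            g = sum(alpha[t] * hist[t][n] for t in range(4))
            feats.append(np.concatenate([hist[-1][n], g]))
        logits = np.array([f @ net.params["Wv"].data[:, 0] + net.params["bv"].data[0]
                           for f in feats])
        pr = attention_oracle(logits)
        mus = np.array([feats[n] @ net.params["Wmu"].data[n][:, 0]
                        + net.params["bmu"].data[n, 0, 0] for n in range(2)])
        expected = float((pr * mus).sum())
        pred, record = net.forward(X, return_attention=True)
        assert np.allclose(pred.data[0, 0], expected, atol=1e-8)
        assert np.allclose(record.variable_weights[0], pr, atol=1e-8)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(seed=st.integers(0, 10_000), batch=st.integers(1, 5), steps=st.integers(1, 9))
def test_attention_record_simplex_invariants(seed, batch, steps):
    """Temporal and variable weights are nonnegative and sum to one for
    arbitrary parameters and inputs."""
    rng = np.random.default_rng(seed)
    net = IMVNet(2, hidden=3, rng=rng)
    X = rng.normal(size=(batch, steps, 2))
    _, record = net.forward(X, return_attention=True)
    assert record.temporal_weights.shape == (batch, steps, 2)
    assert (record.temporal_weights >= 0).all()
    assert np.allclose(record.temporal_weights.sum(axis=1), 1.0, atol=1e-6)
    assert (record.variable_weights >= 0).all()
    assert np.allclose(record.variable_weights.sum(axis=1), 1.0, atol=1e-6)
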