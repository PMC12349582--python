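"""Network architectures: feed-forward ANN, LSTM, and the interpretable
multivariable LSTM (IMV-LSTM).

All three regress a scalar (normalized LAI) on a window of ``T`` time steps of
``N = 2`` forcing variables (soil moisture, air temperature).  The IMV-LSTM
keeps a separate hidden-state block per input variable: variable ``n``'s
update and gates read only its own hidden state ``h^n`` and its own scalar
input ``x^n``, so the blocks stay disjoint until the attention stage.  A
temporal-attention module then summarises each variable's hidden-state
sequence, and a variable-attention module produces a mixture weight
``Pr(z = n)`` per variable — the importance score the interpretation stage
consumes.  The prediction is the mixture mean of per-variable affine heads.

Parameters are plain dicts of :class:`~laidrivers.autodiff.Tensor` so the
training loop can snapshot, copy and serialize them as arrays.
"""

from __future__ import annotations

from typing import Dict, NamedTuple

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

VARIABLE_NAMES = ("soil_moisture", "temperature")


class AttentionRecord(NamedTuple):
    """Attention output of one IMV-LSTM forward pass.

    temporal_weights : (batch, T, N) — per-variable softmax over time steps,
        each (batch, :, n) row sums to 1.
    variable_weights : (batch, N) — mixture weights Pr(z = n), rows sum to 1.
    context : (batch, N, d) — attention-weighted sums g_n of hidden states.
    """

    temporal_weights: np.ndarray
    variable_weights: np.ndarray
    context: np.ndarray


def _uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


def _param(rng, shape, fan_in) -> Tensor:
    return Tensor(_uniform(rng, shape, fan_in), requires_grad=True)


class Network:
    """Base class: a parameter dict plus a forward map."""

    params: Dict[str, Tensor]

    def get_state(self) -> Dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def set_state(self, state: Dict[str, np.ndarray]) -> None:
        for k, v in self.params.items():
            v.data = np.asarray(state[k], dtype=np.float64).copy()

    def forward(self, X: np.ndarray) -> Tensor:  # pragma: no cover - interface
        raise NotImplementedError


class ANNNet(Network):
    """Fully connected regressor on the flattened input window.

    Hidden layers use tanh; the output layer is affine.  The default widths
    (32, 256, 256, 32) match the reference configuration; tests use a small
    profile.
    """

    def __init__(self, n_steps: int = 7, n_vars: int = 2,
                 hidden: tuple = (32, 256, 256, 32), rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.n_steps, self.n_vars, self.hidden = n_steps, n_vars, tuple(hidden)
        sizes = [n_steps * n_vars, *hidden, 1]
        self.params = {}
        for l in range(len(sizes) - 1):
            self.params[f"W{l}"] = _param(rng, (sizes[l], sizes[l + 1]), sizes[l])
            self.params[f"b{l}"] = _param(rng, (sizes[l + 1],), sizes[l])

    def forward(self, X: np.ndarray) -> Tensor:
        if X.ndim != 3 or X.shape[1:] != (self.n_steps, self.n_vars):
            raise ValueError(
                f"expected input of shape (batch, {self.n_steps}, {self.n_vars}), got {X.shape}")
        h = Tensor(X.reshape(X.shape[0], -1))
        n_layers = len(self.hidden)
        for l in range(n_layers):
            h = ad.tanh(h @ self.params[f"W{l}"] + self.params[f"b{l}"])
        return h @ self.params[f"W{n_layers}"] + self.params[f"b{n_layers}"]


class LSTMNet(Network):
    """Single-layer LSTM; the scalar head reads the final hidden state.

    Gates follow the standard formulation: input/forget/output gates and the
    candidate cell are affine maps of [h_{t-1}, x_t] squashed by sigma / tanh;
    C_t = f*C_{t-1} + i*C~_t and h_t = o*tanh(C_t).
    """

    def __init__(self, n_vars: int = 2, hidden: int = 256, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.n_vars, self.hidden = n_vars, hidden
        fan = hidden + n_vars
        self.params = {}
        for gate in ("i", "f", "o", "c"):
            self.params[f"W{gate}"] = _param(rng, (fan, hidden), fan)
            self.params[f"b{gate}"] = _param(rng, (hidden,), fan)
        self.params["Wy"] = _param(rng, (hidden, 1), hidden)
        self.params["by"] = _param(rng, (1,), hidden)

    def step(self, h: Tensor, c: Tensor, x: Tensor):
        """One recurrence step; ``x`` is (batch, n_vars)."""
        hx = ad.concat([h, x], axis=1)
        p = self.params
        i = ad.sigmoid(hx @ p["Wi"] + p["bi"])
        f = ad.sigmoid(hx @ p["Wf"] + p["bf"])
        o = ad.sigmoid(hx @ p["Wo"] + p["bo"])
        c_cand = ad.tanh(hx @ p["Wc"] + p["bc"])
        c_new = f * c + i * c_cand
        h_new = o * ad.tanh(c_new)
        return h_new, c_new

    def forward(self, X: np.ndarray) -> Tensor:
        if X.ndim != 3 or X.shape[2] != self.n_vars:
            raise ValueError(f"expected (batch, T, {self.n_vars}) input, got {X.shape}")
        if X.shape[1] < 1:
            raise ValueError("empty input sequence")
        B = X.shape[0]
        h = Tensor(np.zeros((B, self.hidden)))
        c = Tensor(np.zeros((B, self.hidden)))
        for t in range(X.shape[1]):
            h, c = self.step(h, c, Tensor(X[:, t, :]))
        return h @ self.params["Wy"] + self.params["by"]


class IMVNet(Network):
    """Interpretable multivariable LSTM with hybrid (temporal + variable)
    attention.

    Per variable ``n`` (input dimension d0 = 1, hidden size d):

    * update  j^n = tanh(W_j^n h^n + U_j^n x^n + b_j^n)
    * gates   i^n, f^n, o^n = sigma(W_g^n h^n + U_g^n x^n + b_g^n)
    * cell    c^n = f^n * c^n + i^n * j^n ;  h^n = o^n * tanh(c^n)

    Temporal attention: alpha_t^n = softmax_t(f_n(h_t^n)) with f_n a
    one-hidden-layer tanh scorer; context g_n = sum_t alpha_t^n h_t^n.
    Variable attention: Pr(z = n) = softmax_n(w_v . (h_T^n ++ g_n)) with a
    scorer shared across variables; per-variable affine heads mu_n on the same
    concatenation; prediction = sum_n Pr(z = n) mu_n.
    """

    def __init__(self, n_vars: int = 2, hidden: int = 256, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.n_vars, self.hidden = n_vars, hidden
        d, N = hidden, n_vars
        self.params = {}
        # per-variable blocks are stacked along a leading group axis; grouped
        # matmuls never mix groups, which is what keeps variable n's cell
        # independent of variable m's parameters before the attention stage
        for gate in ("j", "i", "f", "o"):
            self.params[f"W{gate}"] = _param(rng, (N, d, d), d + 1)
            self.params[f"U{gate}"] = _param(rng, (N, 1, d), d + 1)
            self.params[f"b{gate}"] = _param(rng, (N, 1, d), d + 1)
        # temporal scorers f_n: d -> d -> 1, separate parameters per variable
        self.params["Wa"] = _param(rng, (N, d, d), d)
        self.params["ba"] = _param(rng, (N, 1, d), d)
        self.params["wa"] = _param(rng, (N, d, 1), d)
        self.params["ca"] = _param(rng, (N, 1, 1), d)
        # per-variable output heads mu_n on h_T^n ++ g_n
        self.params["Wmu"] = _param(rng, (N, 2 * d, 1), 2 * d)
        self.params["bmu"] = _param(rng, (N, 1, 1), 2 * d)
        # shared variable-attention scorer
        self.params["Wv"] = _param(rng, (2 * d, 1), 2 * d)
        self.params["bv"] = _param(rng, (1,), 2 * d)
        # per-variable log-sd for the Gaussian-likelihood mixture variant
        # (unused by squared-error training)
        self.params["logsig"] = Tensor(np.full((N, 1, 1), -2.0), requires_grad=True)

    def step(self, h: Tensor, c: Tensor, x: Tensor):
        """One step over all variables.

        h, c: (N, batch, d) stacked per-variable states; x: (N, batch, 1).
        """
        p = self.params
        j = ad.tanh(ad.gmatmul(h, p["Wj"]) + ad.gmatmul(x, p["Uj"]) + p["bj"])
        i = ad.sigmoid(ad.gmatmul(h, p["Wi"]) + ad.gmatmul(x, p["Ui"]) + p["bi"])
        f = ad.sigmoid(ad.gmatmul(h, p["Wf"]) + ad.gmatmul(x, p["Uf"]) + p["bf"])
        o = ad.sigmoid(ad.gmatmul(h, p["Wo"]) + ad.gmatmul(x, p["Uo"]) + p["bo"])
        c_new = f * c + i * j
        h_new = o * ad.tanh(c_new)
        return h_new, c_new

    def temporal_attention(self, h_seq):
        """Per-variable softmax attention over the hidden-state sequence.

        h_seq: list of T tensors (N, batch, d).  Returns (alpha (N, batch, T),
        context g (N, batch, d)).
        """
        if len(h_seq) < 1:
            raise ValueError("empty hidden-state sequence")
        p = self.params
        scores = [ad.gmatmul(ad.tanh(ad.gmatmul(h, p["Wa"]) + p["ba"]), p["wa"]) + p["ca"]
                  for h in h_seq]                          # each (N, B, 1)
        alpha = ad.softmax(ad.concat(scores, axis=2), axis=2)
        g = None
        for t, h in enumerate(h_seq):
            term = ad.slice_last(alpha, t, t + 1) * h
            g = term if g is None else g + term
        return alpha, g

    def forward_parts(self, X: np.ndarray):
        """Forward pass exposing the mixture pieces as graph tensors.

        Returns (prediction (B, 1), per-variable means mu (N, B, 1), variable
        logits (B, N), variable weights Pr (B, N), temporal weights alpha
        (N, B, T)).
        """
        if X.ndim != 3 or X.shape[2] != self.n_vars:
            raise ValueError(f"expected (batch, T, {self.n_vars}) input, got {X.shape}")
        if X.shape[1] < 1:
            raise ValueError("empty input sequence")
        B, T, N = X.shape
        d = self.hidden
        h = Tensor(np.zeros((N, B, d)))
        c = Tensor(np.zeros((N, B, d)))
        h_hist = []
        for t in range(T):
            x_t = Tensor(np.ascontiguousarray(X[:, t, :].T)[:, :, None])  # (N, B, 1)
            h, c = self.step(h, c, x_t)
            h_hist.append(h)

        alpha, g = self.temporal_attention(h_hist)
        feats = ad.concat([h, g], axis=2)                  # (N, B, 2d): h_T^n ++ g_n
        mus = ad.gmatmul(feats, self.params["Wmu"]) + self.params["bmu"]  # (N, B, 1)
        raw = ad.gmatmul(feats, self.params["Wv"]) + self.params["bv"]
        logits = ad.concat([ad.select(raw, n) for n in range(N)], axis=1)  # (B, N)
        pr = ad.softmax(logits, axis=1)                    # (B, N)
        pred = None
        for n in range(N):
            term = ad.slice_cols(pr, n, n + 1) * ad.select(mus, n)
            pred = term if pred is None else pred + term
        self._last_context = g
        return pred, mus, logits, pr, alpha

    def forward(self, X: np.ndarray, return_attention: bool = False):
        pred, _, _, pr, alpha = self.forward_parts(X)
        if not return_attention:
            return pred
        record = AttentionRecord(
            temporal_weights=np.moveaxis(alpha.data, 0, 2).copy(),   # (B, T, N)
            variable_weights=pr.data.copy(),
            context=np.swapaxes(self._last_context.data, 0, 1).copy(),  # (B, N, d)
        )
        return pred, record
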