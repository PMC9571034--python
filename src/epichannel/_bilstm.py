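"""A small, deterministic bidirectional-LSTM classifier in NumPy.

The network mirrors the classic five-layer sequence classifier: sequence
input -> bidirectional LSTM -> fully connected -> softmax -> cross-entropy
classification.  Only the final hidden state of each direction is used
("last" output mode): the forward pass over t = 1..T and the backward
pass over t = T..1 each deliver their terminal hidden vector, the two are
concatenated and mapped linearly to class logits.

Training is full backpropagation through time with the Adam optimizer
and global gradient-norm clipping.  Everything is driven by a single
`numpy.random.Generator`, so a given (data, config, seed) triple always
produces bit-identical parameters.

Shapes: X is (B, T, D); hidden size H; C classes.  Gate order inside the
stacked weight matrices is input, forget, cell, output.
"""

from __future__ import annotations

import numpy as np


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _glorot(rng, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_params(rng: np.random.Generator, d: int, h: int, c: int) -> dict:
    """Glorot-uniform weights; forget-gate bias starts at 1."""
    params = {}
    for direction in ("f", "b"):
        params[f"Wx_{direction}"] = _glorot(rng, d, 4 * h)
        params[f"Wh_{direction}"] = _glorot(rng, h, 4 * h)
        bias = np.zeros(4 * h)
        bias[h : 2 * h] = 1.0
        params[f"b_{direction}"] = bias
    params["Wo"] = _glorot(rng, 2 * h, c)
    params["bo"] = np.zeros(c)
    return params


def _lstm_forward(X, Wx, Wh, b):
    """Run one direction; returns final hidden state and the BPTT cache."""
    B, T, D = X.shape
    H = Wh.shape[0]
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    cache = []
    for t in range(T):
        x_t = X[:, t, :]
        z = x_t @ Wx + h @ Wh + b
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H : 2 * H])
        g = np.tanh(z[:, 2 * H : 3 * H])
        o = _sigmoid(z[:, 3 * H :])
        c_prev, h_prev = c, h
        c = f * c + i * g
        tc = np.tanh(c)
        h = o * tc
        cache.append((x_t, i, f, g, o, c_prev, h_prev, tc))
    return h, cache


def _lstm_backward(dh_last, cache, Wx, Wh):
    """BPTT for one direction given the gradient on the final hidden state."""
    H = Wh.shape[0]
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(4 * H)
    dh = dh_last
    dc = np.zeros_like(dh_last)
    for x_t, i, f, g, o, c_prev, h_prev, tc in reversed(cache):
        do = dh * tc
        dc = dc + dh * o * (1.0 - tc * tc)
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dz = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g * g),
                do * o * (1.0 - o),
            ],
            axis=1,
        )
        dWx += x_t.T @ dz
        dWh += h_prev.T @ dz
        db += dz.sum(axis=0)
        dh = dz @ Wh.T
        dc = dc * f
    return dWx, dWh, db


def forward(params: dict, X: np.ndarray):
    """Class probabilities (B, C) plus the cache needed for backprop."""
    h_f, cache_f = _lstm_forward(
        X, params["Wx_f"], params["Wh_f"], params["b_f"]
    )
    X_rev = X[:, ::-1, :]
    h_b, cache_b = _lstm_forward(
        X_rev, params["Wx_b"], params["Wh_b"], params["b_b"]
    )
    feats = np.concatenate([h_f, h_b], axis=1)
    logits = feats @ params["Wo"] + params["bo"]
    logits = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    probs = e / e.sum(axis=1, keepdims=True)
    return probs, (cache_f, cache_b, feats)


def predict_proba(params: dict, X: np.ndarray) -> np.ndarray:
    return forward(params, X)[0]


def loss_and_grads(params: dict, X: np.ndarray, y: np.ndarray):
    """Mean cross-entropy over the batch and gradients for every array."""
    B = X.shape[0]
    probs, (cache_f, cache_b, feats) = forward(params, X)
    eps = 1e-12
    loss = -np.mean(np.log(probs[np.arange(B), y] + eps))

    dlogits = probs.copy()
    dlogits[np.arange(B), y] -= 1.0
    dlogits /= B
    grads = {
        "Wo": feats.T @ dlogits,
        "bo": dlogits.sum(axis=0),
    }
    dfeats = dlogits @ params["Wo"].T
    H = params["Wh_f"].shape[0]
    dWx, dWh, db = _lstm_backward(
        dfeats[:, :H], cache_f, params["Wx_f"], params["Wh_f"]
    )
    grads["Wx_f"], grads["Wh_f"], grads["b_f"] = dWx, dWh, db
    dWx, dWh, db = _lstm_backward(
        dfeats[:, H:], cache_b, params["Wx_b"], params["Wh_b"]
    )
    grads["Wx_b"], grads["Wh_b"], grads["b_b"] = dWx, dWh, db
    return loss, grads


def _clip_global_norm(grads: dict, threshold: float) -> None:
    total = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
    if total > threshold > 0:
        scale = threshold / total
        for k in grads:
            grads[k] = grads[k] * scale


def train(
    X: np.ndarray,
    y: np.ndarray,
    hidden_units: int,
    n_classes: int,
    max_epochs: int = 30,
    minibatch_size: int = 150,
    learn_rate: float = 0.01,
    gradient_threshold: float = 1.0,
    rng: np.random.Generator | None = None,
) -> dict:
    """Fit the network with Adam; returns the trained parameter dict."""
    rng = rng if rng is not None else np.random.default_rng(0)
    n, _, d = X.shape
    params = init_params(rng, d, hidden_units, n_classes)
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(v) for k, v in params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    for _ in range(max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, minibatch_size):
            idx = order[start : start + minibatch_size]
            _, grads = loss_and_grads(params, X[idx], y[idx])
            _clip_global_norm(grads, gradient_threshold)
            step += 1
            for k in params:
                m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                v[k] = beta2 * v[k] + (1 - beta2) * grads[k] ** 2
                m_hat = m[k] / (1 - beta1**step)
                v_hat = v[k] / (1 - beta2**step)
                params[k] = params[k] - learn_rate * m_hat / (
                    np.sqrt(v_hat) + eps
                )
    return params
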