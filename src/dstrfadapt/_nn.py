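"""Minimal NumPy engine for dilated 1-D convolutional ReLU networks.

Implements exactly the architecture family used by the encoding models:
stacked valid (no padding) dilated convolutions without hidden biases, ReLU
activations, and a final per-electrode linear projection with bias. Because
the network is piecewise linear, both the training gradients and the exact
input gradient (the dSTRF) are computed in closed form here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import as_strided


def conv_forward(h: np.ndarray, w: np.ndarray, dilation: int) -> np.ndarray:
    """Valid dilated convolution.

    h : (C_in, T), w : (C_out, C_in, K) -> (C_out, T - (K-1)*dilation)

    out[o, t] = sum_{i,k} w[o, i, k] * h[i, t + k*dilation]
    """
    c_in, t = h.shape
    c_out, _, k = w.shape
    t_out = t - (k - 1) * dilation
    if t_out <= 0:
        raise ValueError("input shorter than the layer's receptive field")
    s0, s1 = h.strides
    win = as_strided(h, shape=(c_in, k, t_out),
                     strides=(s0, s1 * dilation, s1))
    return np.einsum("oik,ikt->ot", w, win, optimize=True)


def conv_backward(h: np.ndarray, w: np.ndarray, dilation: int,
                  grad_out: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Gradients of a valid dilated convolution.

    Returns (grad_w, grad_h) for upstream gradient grad_out (C_out, T_out).
    """
    c_in, t = h.shape
    c_out, _, k = w.shape
    t_out = grad_out.shape[1]
    s0, s1 = h.strides
    win = as_strided(h, shape=(c_in, k, t_out),
                     strides=(s0, s1 * dilation, s1))
    grad_w = np.einsum("ot,ikt->oik", grad_out, win, optimize=True)
    grad_h = np.zeros_like(h)
    for kk in range(k):
        # tensordot over the output-channel axis
        grad_h[:, kk * dilation: kk * dilation + t_out] += np.tensordot(
            w[:, :, kk], grad_out, axes=(0, 0))
    return grad_w, grad_h


@dataclass
class CnnParams:
    """Parameters of the dilated conv trunk + per-electrode linear head."""

    conv_weights: list[np.ndarray]   # layer l: (C_out, C_in, K)
    head_weight: np.ndarray          # (n_electrodes, C_last)
    head_bias: np.ndarray            # (n_electrodes,)
    dilations: tuple[int, ...]

    def copy(self) -> "CnnParams":
        return CnnParams([w.copy() for w in self.conv_weights],
                         self.head_weight.copy(), self.head_bias.copy(),
                         tuple(self.dilations))

    def flat(self) -> list[np.ndarray]:
        return [*self.conv_weights, self.head_weight, self.head_bias]

    @property
    def receptive_field(self) -> int:
        return 1 + sum((w.shape[2] - 1) * d
                       for w, d in zip(self.conv_weights, self.dilations))


def init_params(n_freq: int, n_kernels: int, kernel_size: int,
                n_layers: int, dilations, n_electrodes: int,
                rng: np.random.Generator) -> CnnParams:
    """He-normal initialization (no hidden biases by construction)."""
    ws = []
    c_in = n_freq
    for _ in range(n_layers):
        fan_in = c_in * kernel_size
        ws.append(rng.standard_normal((n_kernels, c_in, kernel_size))
                  * np.sqrt(2.0 / fan_in))
        c_in = n_kernels
    head_w = rng.standard_normal((n_electrodes, c_in)) * np.sqrt(1.0 / c_in)
    head_b = np.zeros(n_electrodes)
    return CnnParams(ws, head_w, head_b, tuple(dilations))


def forward(params: CnnParams, x: np.ndarray, cache: bool = False):
    """Full-sequence forward pass.

    x : (n_freq, T). Output (n_electrodes, T - RF + 1); output column i
    predicts the response at sample i + RF - 1.
    """
    h = x
    hs, masks = [h], []
    for w, d in zip(params.conv_weights, params.dilations):
        z = conv_forward(h, w, d)
        m = z > 0
        h = z * m
        if cache:
            hs.append(h)
            masks.append(m)
    y = params.head_weight @ h + params.head_bias[:, None]
    if cache:
        return y, (hs, masks, h)
    return y


def backward(params: CnnParams, cache, grad_y: np.ndarray) -> list[np.ndarray]:
    """Gradients of a scalar loss wrt all parameters.

    grad_y : (n_electrodes, T_out) upstream gradient on the output.
    Returns gradients in the order of ``params.flat()``.
    """
    hs, masks, h_last = cache
    grad_head_w = grad_y @ h_last.T
    grad_head_b = grad_y.sum(axis=1)
    g = params.head_weight.T @ grad_y
    grad_ws: list[np.ndarray] = []
    for li in range(len(params.conv_weights) - 1, -1, -1):
        g = g * masks[li]
        gw, g = conv_backward(hs[li], params.conv_weights[li],
                              params.dilations[li], g)
        grad_ws.append(gw)
    grad_ws.reverse()
    return [*grad_ws, grad_head_w, grad_head_b]


# ---------------------------------------------------------------------------
# batched window passes (used for dSTRF extraction)

def _window_view(x: np.ndarray, k: int, dilation: int) -> np.ndarray:
    """(B, C, L) -> strided view (B, C, K, L_out)."""
    b, c, ln = x.shape
    l_out = ln - (k - 1) * dilation
    s0, s1, s2 = x.strides
    return as_strided(x, shape=(b, c, k, l_out),
                      strides=(s0, s1, s2 * dilation, s2))


def forward_windows(params: CnnParams, xw: np.ndarray):
    """Forward pass on a batch of input windows.

    xw : (B, n_freq, L) with L == receptive field; returns
    (y (B, n_electrodes), cache) where cache holds per-layer inputs/masks.
    """
    h = xw
    hs, masks = [h], []
    for w, d in zip(params.conv_weights, params.dilations):
        win = _window_view(h, w.shape[2], d)
        z = np.einsum("oik,bikt->bot", w, win, optimize=True)
        m = z > 0
        h = z * m
        hs.append(h)
        masks.append(m)
    # after the full stack L_out == 1 when L == RF
    y = h[:, :, 0] @ params.head_weight.T + params.head_bias
    return y, (hs, masks)


def input_gradient_windows(params: CnnParams, cache,
                           electrode: int) -> np.ndarray:
    """Exact gradient d y[:, electrode] / d window for a batch of windows.

    Returns (B, n_freq, L). For a bias-free-hidden-layer ReLU network this
    is the instantaneous equivalent linear filter (dSTRF) of each window.
    """
    hs, masks = cache
    b = hs[0].shape[0]
    g = np.broadcast_to(params.head_weight[electrode][None, :, None],
                        (b, params.head_weight.shape[1], 1)).copy()
    for li in range(len(params.conv_weights) - 1, -1, -1):
        g = g * masks[li]
        w = params.conv_weights[li]
        d = params.dilations[li]
        k = w.shape[2]
        l_in = hs[li].shape[2]
        l_out = g.shape[2]
        gh = np.zeros((b, w.shape[1], l_in))
        for kk in range(k):
            gh[:, :, kk * d: kk * d + l_out] += np.einsum(
                "oi,bot->bit", w[:, :, kk], g, optimize=True)
        g = gh
    return g


# ---------------------------------------------------------------------------
# RAdam optimizer (rectified Adam) with decoupled weight decay

class RAdam:
    """Rectified Adam with optional decoupled weight decay.

    Weight decay is applied to convolution and head weights but not to the
    head bias.
    """

    def __init__(self, shapes, lr=1e-3, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.0, decay_mask=None):
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = weight_decay
        self.t = 0
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.decay_mask = (decay_mask if decay_mask is not None
                           else [True] * len(self.m))
        self.rho_inf = 2.0 / (1.0 - self.b2) - 1.0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray],
             lr_scale: float = 1.0) -> None:
        self.t += 1
        t = self.t
        b1, b2 = self.b1, self.b2
        rho = self.rho_inf - 2.0 * t * b2 ** t / (1.0 - b2 ** t)
        lr = self.lr * lr_scale
        if rho > 4.0:
            r = np.sqrt(((rho - 4.0) * (rho - 2.0) * self.rho_inf)
                        / ((self.rho_inf - 4.0) * (self.rho_inf - 2.0) * rho))
        else:
            r = None
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1 - b1 ** t)
            if r is not None:
                v_hat = np.sqrt(self.v[i] / (1 - b2 ** t)) + self.eps
                p -= lr * r * m_hat / v_hat
            else:
                # warm-up steps have no variance normalization; cap the
                # update at unit RMS so huge target scales cannot blow up
                # the first few iterations
                rms = np.sqrt(np.mean(m_hat ** 2))
                p -= lr * m_hat / max(1.0, rms)
            if self.wd and self.decay_mask[i]:
                p -= lr * self.wd * p
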