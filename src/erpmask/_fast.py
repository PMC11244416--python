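"""Batched forward/backward pass and optimizer for the dynamic masked network.

This module mirrors the per-sample reference pipeline in :mod:`erpmask.model`
exactly, but vectorized over a batch and with the two expensive stages
optimized: the depthwise dynamic convolution runs through real FFTs (the
per-epoch spectra are computed once per dataset and reused every epoch), and
the batch-norm/dropout/linear head runs through fused numba kernels.  The
backward pass is the hand-derived adjoint of the forward and is validated
against central finite differences in the test suite.

Shapes used throughout: X (n, C, T) input epochs, D (n, K, C*T) convolution
feature maps, kernels (K, l), masks (n, K, l).
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np
from numba import njit
from scipy import fft as sfft

from .model import BN_EPS, BN_MOMENTUM, ModelConfig, ModelParams

__all__ = ["PreparedData", "prepare_data", "forward_batch", "backward_batch",
           "predict_logits", "AdamW", "SGD", "update_running_stats"]


# -- numba kernels -----------------------------------------------------------

@njit(cache=True, fastmath=True)
def _bn_stats(D):  # D: (n, K, M)
    n, K, M = D.shape
    mu = np.empty(K, D.dtype)
    var = np.empty(K, D.dtype)
    for k in range(K):
        s1 = 0.0
        s2 = 0.0
        for s in range(n):
            row = D[s, k]
            for m in range(M):
                v = row[m]
                s1 += v
                s2 += v * v
        mean = s1 / (n * M)
        mu[k] = mean
        var[k] = s2 / (n * M) - mean * mean
    return mu, var


@njit(cache=True, fastmath=True)
def _head_fwd_train(D, a, b, keep, scale, w2, bias):
    """logit[s] = sum_{k,m} (a[k]*D + b[k]) * keep * scale * w2 + bias."""
    n, K, M = D.shape
    logit = np.empty(n, D.dtype)
    for s in range(n):
        acc = 0.0
        for k in range(K):
            ak = a[k]
            bk = b[k]
            drow = D[s, k]
            krow = keep[s, k]
            wrow = w2[k]
            for m in range(M):
                if krow[m]:
                    acc += (ak * drow[m] + bk) * wrow[m]
        logit[s] = acc * scale + bias
    return logit


@njit(cache=True, fastmath=True)
def _head_bwd_pass1(D, mu, inv, gamma, keep, scale, w2, glogit):
    """Accumulate gbias, ggamma, gbeta and the two per-scale sums that the
    batch-statistics backward needs (sum gz_hat, sum gz_hat*z_hat)."""
    n, K, M = D.shape
    ggamma = np.zeros(K, D.dtype)
    gbeta = np.zeros(K, D.dtype)
    s1 = np.zeros(K, D.dtype)  # sum of gz_hat
    s2 = np.zeros(K, D.dtype)  # sum of gz_hat * z_hat
    gbias = 0.0
    for s in range(n):
        gl = glogit[s]
        gbias += gl
        for k in range(K):
            muk = mu[k]
            ik = inv[k]
            gk = gamma[k]
            drow = D[s, k]
            krow = keep[s, k]
            wrow = w2[k]
            a1 = 0.0
            a2 = 0.0
            ag = 0.0
            ab = 0.0
            for m in range(M):
                if krow[m]:
                    zh = (drow[m] - muk) * ik
                    gy = gl * wrow[m] * scale
                    gzh = gy * gk
                    a1 += gzh
                    a2 += gzh * zh
                    ag += gy * zh
                    ab += gy
            s1[k] += a1
            s2[k] += a2
            ggamma[k] += ag
            gbeta[k] += ab
    return gbias, ggamma, gbeta, s1, s2


@njit(cache=True, fastmath=True)
def _head_bwd_gw2(D, mu, inv, gamma, beta, keep, scale, glogit):
    """gw2[k, m] = sum_s glogit[s] * Z[s, k, m] (Z = dropped-out BN output)."""
    n, K, M = D.shape
    gw2 = np.zeros((K, M), D.dtype)
    for s in range(n):
        gl = glogit[s]
        for k in range(K):
            muk = mu[k]
            ik = inv[k]
            gk = gamma[k]
            bk = beta[k]
            drow = D[s, k]
            krow = keep[s, k]
            grow = gw2[k]
            for m in range(M):
                if krow[m]:
                    grow[m] += gl * (gk * (drow[m] - muk) * ik + bk) * scale
    return gw2


@njit(cache=True, fastmath=True)
def _head_bwd_gD(D, mu, inv, gamma, keep, scale, w2, glogit, s1, s2, gD):
    """Batch-norm (batch statistics) backward into gD, in place."""
    n, K, M = D.shape
    N = n * M
    for s in range(n):
        gl = glogit[s]
        for k in range(K):
            muk = mu[k]
            ik = inv[k]
            gk = gamma[k]
            c1 = s1[k] / N
            c2 = s2[k] / N
            drow = D[s, k]
            krow = keep[s, k]
            wrow = w2[k]
            grow = gD[s, k]
            for m in range(M):
                zh = (drow[m] - muk) * ik
                if krow[m]:
                    gzh = gl * wrow[m] * scale * gk
                else:
                    gzh = 0.0
                grow[m] = ik * (gzh - c1 - zh * c2)
    return gD


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# -- data preparation --------------------------------------------------------

class PreparedData:
    """Per-dataset caches: epoch spectra for the FFT convolution and the
    shifted channel-mean stacks for the width-3 feature convolution."""

    def __init__(self, X: np.ndarray, config: ModelConfig, dtype=np.float32):
        X = np.ascontiguousarray(X, dtype=dtype)
        n, C, T = X.shape
        if (C, T) != (config.n_channels, config.n_samples):
            raise ValueError(
                f"data shape {(C, T)} does not match config "
                f"({config.n_channels}, {config.n_samples})")
        l = config.kernel_len
        self.dtype = dtype
        self.n, self.C, self.T, self.l = n, C, T, l
        self.nfft = sfft.next_fast_len(T + l)
        # spectrum of each channel's zero-extended epoch (zero padding to nfft
        # subsumes the explicit l-zero tail padding of the reference pipeline)
        self.Sf = sfft.rfft(X, n=self.nfft, axis=-1)
        # stacked (t-1, t, t+1) views of the channel-mean signal, zero-padded ends
        xbar = X.mean(axis=1)
        xp = np.pad(xbar, ((0, 0), (1, 1)))
        self.shifts = np.stack([xp[:, 0:T], xp[:, 1:T + 1], xp[:, 2:T + 2]],
                               axis=1).astype(dtype)  # (n, 3, T)


def prepare_data(X: np.ndarray, config: ModelConfig, dtype=np.float32) -> PreparedData:
    return PreparedData(X, config, dtype)


# -- forward / backward ------------------------------------------------------

def forward_batch(prep: PreparedData, idx: np.ndarray, params: ModelParams,
                  config: ModelConfig, training: bool,
                  dropout_rng: Optional[np.random.Generator] = None,
                  ) -> Tuple[np.ndarray, Dict]:
    """Forward pass for the trials selected by ``idx``.

    Returns (logits, cache); the cache carries every intermediate needed by
    :func:`backward_batch` plus the batch BN statistics for running updates.
    """
    dt = prep.dtype
    K, l, T, C = config.n_scales, config.kernel_len, prep.T, prep.C
    P = config.segment_start
    n = len(idx)
    W = params.base_kernels
    cache: Dict = {"idx": idx, "n": n}

    if config.variant == "masked":
        shifts = prep.shifts[idx]                                    # (n, 3, T)
        Ep = np.einsum("ku,nut->nkt", params.feature_w, shifts)
        Ep += params.feature_b[None, :, None]
        Lseg = Ep[:, :, P:P + l]                                     # (n, K, l)
        x_cat = np.concatenate(
            [Lseg, np.broadcast_to(W, (n, K, l))], axis=2)           # (n, K, 2l)
        h = x_cat @ params.m1_w.T + params.m1_b                      # (n, K, l)
        z2 = h @ params.m2_w + params.m2_b                           # (n, K)
        if not np.all(np.isfinite(z2)):
            raise FloatingPointError("non-finite value in mask-ratio computation")
        r = _sigmoid(z2)
        j = np.arange(1, l + 1, dtype=dt)
        M = _sigmoid((config.sharpness * (r[:, :, None] * l - j)).astype(dt))
        Wv = (W[None] * M).astype(dt)                                # (n, K, l)
        cache.update(shifts=shifts, x_cat=x_cat, h=h, r=r, M=M)
    else:
        Wv = np.broadcast_to(W.astype(dt), (n, K, l))
        cache.update(M=None)
    cache["Wv"] = Wv

    Sf = prep.Sf[idx]                                                # (n, C, F)
    Wf = sfft.rfft(np.ascontiguousarray(Wv), n=prep.nfft, axis=-1)   # (n, K, F)
    D = sfft.irfft(Sf[:, None] * np.conj(Wf)[:, :, None],
                   n=prep.nfft, axis=-1)[..., :T]                    # (n, K, C, T)
    D += params.base_b.astype(dt)[None, :, None, None]
    D3 = np.ascontiguousarray(D.reshape(n, K, C * T), dtype=dt)
    cache["D3"] = D3

    if training:
        mu, var = _bn_stats(D3)
        p = config.dropout_rate
        if p > 0:
            if dropout_rng is None:
                raise ValueError("training forward needs a dropout rng")
            keep = dropout_rng.random((n, K, C * T), dtype=np.float32) >= p
        else:
            keep = np.ones((n, K, C * T), dtype=bool)
        scale = dt(1.0 / (1.0 - p)) if p > 0 else dt(1.0)
        inv = (1.0 / np.sqrt(var + BN_EPS)).astype(dt)
        a = (params.bn_gamma.astype(dt) * inv)
        b = (params.bn_beta.astype(dt) - a * mu.astype(dt))
        logits = _head_fwd_train(D3, a, b, keep, dt(scale),
                                 np.ascontiguousarray(params.clf_w.reshape(K, C * T), dtype=dt),
                                 dt(params.clf_b))
        cache.update(mu=mu.astype(dt), var=var.astype(dt), inv=inv,
                     keep=keep, scale=dt(scale))
    else:
        inv = (1.0 / np.sqrt(params.bn_var.astype(dt) + BN_EPS))
        a = params.bn_gamma.astype(dt) * inv
        b = params.bn_beta.astype(dt) - a * params.bn_mean.astype(dt)
        w2 = params.clf_w.reshape(K, C * T).astype(dt)
        wa = (w2 * a[:, None]).reshape(-1)
        const = float((w2.sum(axis=1) * b).sum() + params.clf_b)
        logits = D3.reshape(n, -1) @ wa + const
    return np.asarray(logits, dtype=np.float64), cache


def backward_batch(prep: PreparedData, cache: Dict, params: ModelParams,
                   config: ModelConfig, glogits: np.ndarray) -> Dict[str, np.ndarray]:
    """Adjoint of :func:`forward_batch` in training mode.

    Returns gradients keyed by ModelParams field name (only fields that
    participate in the active variant appear).
    """
    dt = prep.dtype
    K, l, T, C = config.n_scales, config.kernel_len, prep.T, prep.C
    P = config.segment_start
    idx = cache["idx"]
    n = cache["n"]
    D3 = cache["D3"]
    glogit = np.ascontiguousarray(glogits, dtype=dt)
    w2 = np.ascontiguousarray(params.clf_w.reshape(K, C * T), dtype=dt)

    # head
    gbias, ggamma, gbeta, s1, s2 = _head_bwd_pass1(
        D3, cache["mu"], cache["inv"], params.bn_gamma.astype(dt),
        cache["keep"], cache["scale"], w2, glogit)
    gw2 = _head_bwd_gw2(D3, cache["mu"], cache["inv"],
                        params.bn_gamma.astype(dt), params.bn_beta.astype(dt),
                        cache["keep"], cache["scale"], glogit)
    gD3 = np.empty_like(D3)
    _head_bwd_gD(D3, cache["mu"], cache["inv"], params.bn_gamma.astype(dt),
                 cache["keep"], cache["scale"], w2, glogit, s1, s2, gD3)
    gD = gD3.reshape(n, K, C, T)

    grads: Dict[str, np.ndarray] = {
        "clf_w": gw2.reshape(-1).astype(np.float64),
        "clf_b": np.asarray(float(gbias)),
        "bn_gamma": ggamma.astype(np.float64),
        "bn_beta": gbeta.astype(np.float64),
        "base_b": gD.sum(axis=(0, 2, 3)).astype(np.float64),
    }

    # convolution: gWv[s,i,tau] = sum_{c,t} gD[s,i,c,t] * S[s,c,t+tau]
    Sf = prep.Sf[idx]
    Gf = sfft.rfft(np.ascontiguousarray(gD), n=prep.nfft, axis=-1)
    gWv = sfft.irfft((Sf[:, None] * np.conj(Gf)).sum(axis=2),
                     n=prep.nfft, axis=-1)[..., :l]                  # (n, K, l)

    W = params.base_kernels
    if config.variant == "masked":
        M = cache["M"]
        r = cache["r"]
        gM = gWv * W[None]
        gW = (gWv * M).sum(axis=0)
        gli = (gM * config.sharpness * M * (1.0 - M)).sum(axis=2)    # (n, K)
        gz2 = gli * l * r * (1.0 - r)                                # (n, K)
        gh = gz2[:, :, None] * params.m2_w[None, None, :].astype(dt)
        grads["m2_w"] = (gz2[:, :, None] * cache["h"]).sum(axis=(0, 1)).astype(np.float64)
        grads["m2_b"] = np.asarray(float(gz2.sum()))
        gx = gh @ params.m1_w.astype(dt)                             # (n, K, 2l)
        grads["m1_w"] = np.einsum("nkl,nkm->lm", gh, cache["x_cat"]).astype(np.float64)
        grads["m1_b"] = gh.sum(axis=(0, 1)).astype(np.float64)
        gW += gx[:, :, l:].sum(axis=0)
        gL = gx[:, :, :l]
        gEp = np.zeros((n, K, T), dtype=dt)
        gEp[:, :, P:P + l] = gL
        grads["feature_w"] = np.einsum(
            "nkt,nut->ku", gEp, cache["shifts"]).astype(np.float64)
        grads["feature_b"] = gEp.sum(axis=(0, 2)).astype(np.float64)
    else:
        gW = gWv.sum(axis=0)

    if config.base_kernels_trainable:
        grads["base_kernels"] = gW.astype(np.float64)
    return grads


def update_running_stats(params: ModelParams, cache: Dict,
                         momentum: float = BN_MOMENTUM) -> None:
    """Exponential-moving-average update of the BN running statistics."""
    params.bn_mean = ((1 - momentum) * params.bn_mean
                      + momentum * cache["mu"].astype(np.float64))
    params.bn_var = ((1 - momentum) * params.bn_var
                     + momentum * cache["var"].astype(np.float64))


def predict_logits(X: np.ndarray, params: ModelParams,
                   config: Optional[ModelConfig] = None, batch_size: int = 64,
                   dtype=np.float32) -> np.ndarray:
    """Deterministic evaluation-mode logits for a stack of epochs."""
    cfg = config if config is not None else params.config
    if cfg is None:
        raise ValueError("a ModelConfig is required")
    X = np.asarray(X)
    if X.ndim != 3 or X.shape[1:] != (cfg.n_channels, cfg.n_samples):
        raise ValueError(
            f"input shape {X.shape} does not match config "
            f"(n, {cfg.n_channels}, {cfg.n_samples})")
    prep = PreparedData(X, cfg, dtype=dtype)
    out = np.empty(len(X))
    for start in range(0, len(X), batch_size):
        idx = np.arange(start, min(start + batch_size, len(X)))
        logits, _ = forward_batch(prep, idx, params, cfg, training=False)
        out[idx] = logits
    return out


# -- optimizers --------------------------------------------------------------

class AdamW:
    """Adaptive moment estimation with decoupled weight decay."""

    def __init__(self, lr: float, weight_decay: float = 0.0,
                 betas: Tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.lr = lr
        self.weight_decay = weight_decay
        self.betas = betas
        self.eps = eps
        self.t = 0
        self._m: Dict[str, np.ndarray] = {}
        self._v: Dict[str, np.ndarray] = {}

    def step(self, params: ModelParams, grads: Dict[str, np.ndarray]) -> None:
        b1, b2 = self.betas
        self.t += 1
        for name, g in grads.items():
            theta = np.asarray(getattr(params, name), dtype=np.float64)
            g = np.asarray(g, dtype=np.float64)
            if name not in self._m:
                self._m[name] = np.zeros_like(theta)
                self._v[name] = np.zeros_like(theta)
            m = self._m[name] = b1 * self._m[name] + (1 - b1) * g
            v = self._v[name] = b2 * self._v[name] + (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            theta = theta - self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                       + self.weight_decay * theta)
            setattr(params, name, theta)


class SGD:
    """Plain gradient descent with L2 weight decay."""

    def __init__(self, lr: float, weight_decay: float = 0.0):
        self.lr = lr
        self.weight_decay = weight_decay

    def step(self, params: ModelParams, grads: Dict[str, np.ndarray]) -> None:
        for name, g in grads.items():
            theta = np.asarray(getattr(params, name), dtype=np.float64)
            theta = theta - self.lr * (np.asarray(g, dtype=np.float64)
                                       + self.weight_decay * theta)
            setattr(params, name, theta)
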