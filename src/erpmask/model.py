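"""Dynamic multi-scale masked convolution network for ERP decoding.

The model classifies single epochs (channels x time) as self-face vs.
stranger-face.  Its distinguishing element is a *variable-length* bank of K
one-dimensional convolution kernels: a small generator network inspects a
pooled feature segment of each input epoch and emits, per kernel, a ratio
``r in (0, 1)``.  The effective kernel length ``l_i = r * l`` is imposed by a
differentiable soft mask

    m_ij = sigmoid(lambda * (l_i - j)),   j = 1..l,

which smoothly zeroes the kernel tail while keeping the length decision
trainable by gradient descent.  The masked kernels are applied depthwise
(one kernel per scale, shared across EEG channels, no cross-channel mixing)
to the zero-padded epoch, and a batch-normalized, dropout-regularized linear
layer on the flattened feature maps produces a single logit.

Pipeline per epoch ``S`` of shape (C, T)::

    feature_conv -> channel_gap -> extract_segment -> mask_ratio -> soft_mask
        -> masked_kernels -> pad_input -> dynamic_conv -> classify

The ``standard`` variant keeps the same convolution bank but fixes every mask
at 1 (full-length kernels, no generator).

The functions in this module are the reference, per-sample implementations;
training uses the numerically identical batched path in ``erpmask._fast``.
Mask indices ``j`` are 1-based (matching the soft-mask definition above);
time slices such as ``[P, P + l)`` are 0-based half-open.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "ModelConfig",
    "ModelParams",
    "MaskDiagnostics",
    "ForwardTrace",
    "feature_conv",
    "channel_gap",
    "extract_segment",
    "mask_ratio",
    "soft_mask",
    "masked_kernels",
    "pad_input",
    "dynamic_conv",
    "classify",
    "forward",
    "save_checkpoint",
    "load_checkpoint",
]

BN_EPS = 1e-5
BN_MOMENTUM = 0.1


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    x = np.asarray(x, dtype=float) if np.ndim(x) else np.asarray(x, dtype=float)
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Parameters
    ----------
    n_scales : int
        K, the number of kernels / scales.
    kernel_len : int
        l, the base (maximum) kernel length in samples.
    segment_start : int
        P, the 0-based start of the pooled-feature segment fed to the mask
        generator; the segment is ``[P, P + kernel_len)``.
    sharpness : float
        lambda, the soft-mask sharpness; larger values approach a hard cutoff.
    n_channels, n_samples : int
        C and T of the input epochs.
    variant : {"masked", "standard"}
        "standard" fixes all masks at 1 (fixed full-length kernels).
    base_kernels_trainable : bool
        Whether the Gaussian-initialized kernel bank receives gradient updates.
    init_std : float, optional
        Std of the Gaussian kernel initialization; defaults to 1/sqrt(kernel_len).
    """

    n_scales: int = 30
    kernel_len: int = 200
    segment_start: int = 400
    sharpness: float = 5.0
    n_channels: int = 30
    n_samples: int = 1000
    feature_kernel_width: int = 3
    dropout_rate: float = 0.5
    variant: str = "masked"
    base_kernels_trainable: bool = True
    init_std: Optional[float] = None

    def validate(self) -> None:
        if self.n_scales < 1:
            raise ValueError("n_scales must be >= 1")
        if not (1 <= self.kernel_len <= self.n_samples):
            raise ValueError("kernel_len must satisfy 1 <= l <= n_samples")
        if not (0 <= self.segment_start and
                self.segment_start + self.kernel_len <= self.n_samples):
            raise ValueError(
                f"segment [P, P+l) = [{self.segment_start}, "
                f"{self.segment_start + self.kernel_len}) exceeds T={self.n_samples}"
            )
        if self.sharpness <= 0:
            raise ValueError("sharpness must be positive")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.variant not in ("masked", "standard"):
            raise ValueError("variant must be 'masked' or 'standard'")
        if self.feature_kernel_width != 3:
            raise ValueError("feature_kernel_width is fixed at 3")

    @property
    def effective_init_std(self) -> float:
        return self.init_std if self.init_std is not None else 1.0 / np.sqrt(self.kernel_len)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


@dataclass
class ModelParams:
    """All learnable weights plus batch-norm running statistics.

    ``feature_w/feature_b`` are the K width-3 feature filters; ``base_kernels``
    is the Gaussian-initialized K x l kernel bank with per-scale biases
    ``base_b``; ``m1_*``/``m2_*`` are the shared mask-generator fully connected
    layers (2l -> l -> 1); ``clf_w``/``clf_b`` the linear classifier on the
    flattened K*C*T feature maps; ``bn_*`` the per-scale batch-norm parameters
    and running statistics.
    """

    feature_w: np.ndarray
    feature_b: np.ndarray
    base_kernels: np.ndarray
    base_b: np.ndarray
    m1_w: np.ndarray
    m1_b: np.ndarray
    m2_w: np.ndarray
    m2_b: np.ndarray
    clf_w: np.ndarray
    clf_b: np.ndarray
    bn_gamma: np.ndarray
    bn_beta: np.ndarray
    bn_mean: np.ndarray
    bn_var: np.ndarray
    config: Optional[ModelConfig] = None

    ARRAY_FIELDS = ("feature_w", "feature_b", "base_kernels", "base_b",
                    "m1_w", "m1_b", "m2_w", "m2_b", "clf_w", "clf_b",
                    "bn_gamma", "bn_beta", "bn_mean", "bn_var")

    TRAINABLE_FIELDS = ("feature_w", "feature_b", "base_kernels", "base_b",
                        "m1_w", "m1_b", "m2_w", "m2_b", "clf_w", "clf_b",
                        "bn_gamma", "bn_beta")

    @classmethod
    def initialize(cls, config: ModelConfig, rng: np.random.Generator,
                   dtype=np.float64) -> "ModelParams":
        config.validate()
        K, l = config.n_scales, config.kernel_len
        C, T = config.n_channels, config.n_samples
        sd = config.effective_init_std

        def g(shape, scale):
            return rng.normal(0.0, scale, size=shape).astype(dtype)

        return cls(
            feature_w=g((K, 3), 1.0 / np.sqrt(3)),
            feature_b=np.zeros(K, dtype),
            base_kernels=g((K, l), sd),
            base_b=np.zeros(K, dtype),
            m1_w=g((l, 2 * l), 1.0 / np.sqrt(2 * l)),
            m1_b=np.zeros(l, dtype),
            m2_w=g((l,), 1.0 / np.sqrt(l)),
            m2_b=np.zeros((), dtype),
            clf_w=g((K * C * T,), 1.0 / np.sqrt(K * C * T)),
            clf_b=np.zeros((), dtype),
            bn_gamma=np.ones(K, dtype),
            bn_beta=np.zeros(K, dtype),
            bn_mean=np.zeros(K, dtype),
            bn_var=np.ones(K, dtype),
            config=config,
        )

    def astype(self, dtype) -> "ModelParams":
        kw = {f: getattr(self, f).astype(dtype) for f in self.ARRAY_FIELDS}
        return ModelParams(config=self.config, **kw)


@dataclass
class MaskDiagnostics:
    """Per-sample mask internals: ratios ``r``, real lengths ``l_i = r*l``, soft masks."""

    ratios: np.ndarray      # (K,) in (0, 1)
    lengths: np.ndarray     # (K,) in (0, l)
    masks: np.ndarray       # (K, l), entries in (0, 1), non-increasing over j


@dataclass
class ForwardTrace:
    """Intermediate tensors of one forward pass (shapes for a single epoch)."""

    E: np.ndarray           # (K, C, T) feature maps
    E_pooled: np.ndarray    # (K, 1, T) channel-averaged feature maps
    L: np.ndarray           # (K, 1, l) mask-generator input segments
    W_v: np.ndarray         # (K, l) masked kernels
    S_padded: np.ndarray    # (C, T + l)
    D: np.ndarray           # (K, C, T) depthwise convolution output
    logit: float


# -- pipeline stages ---------------------------------------------------------

def feature_conv(S: np.ndarray, feature_w: np.ndarray,
                 feature_b: np.ndarray) -> np.ndarray:
    """Width-3 depthwise feature convolution with same-padding.

    Each of the K filters slides along time over every channel:
    ``E[k, c, t] = sum_u w[k, u] * S[c, t + u - 1] + b[k]`` with one zero of
    padding on each side, so the time length is preserved.
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2:
        raise ValueError(f"epoch must be 2-D (channels, samples); got {S.shape}")
    feature_w = np.asarray(feature_w, dtype=float)
    if feature_w.ndim != 2 or feature_w.shape[1] != 3:
        raise ValueError("feature filters must have shape (K, 3)")
    C, T = S.shape
    Sp = np.pad(S, ((0, 0), (1, 1)))
    windows = np.stack([Sp[:, 0:T], Sp[:, 1:T + 1], Sp[:, 2:T + 2]], axis=0)  # (3, C, T)
    E = np.einsum("ku,uct->kct", feature_w, windows)
    return E + np.asarray(feature_b, dtype=float)[:, None, None]


def channel_gap(E: np.ndarray) -> np.ndarray:
    """Global average pooling over the EEG-channel dimension: (K,C,T) -> (K,1,T)."""
    E = np.asarray(E, dtype=float)
    if E.ndim != 3:
        raise ValueError(f"feature maps must be 3-D (K, C, T); got {E.shape}")
    return E.mean(axis=1, keepdims=True)


def extract_segment(E_pooled: np.ndarray, P: int, l: int) -> np.ndarray:
    """Contiguous time slice ``[P, P + l)`` of the pooled features (0-based, half-open)."""
    E_pooled = np.asarray(E_pooled, dtype=float)
    T = E_pooled.shape[-1]
    if P < 0 or l < 1 or P + l > T:
        raise ValueError(f"segment [{P}, {P + l}) out of range for T={T}")
    return E_pooled[..., P:P + l]


def mask_ratio(L: np.ndarray, base_kernels: np.ndarray, m1_w: np.ndarray,
               m1_b: np.ndarray, m2_w: np.ndarray, m2_b: np.ndarray) -> np.ndarray:
    """Per-scale mask ratio ``r_i = sigma(W_m2 (W_m1 (L_i ++ W_i) + b_m1) + b_m2)``.

    The pooled segment ``L_i`` is concatenated with the base kernel ``W_i``
    (in that order) and pushed through the shared 2l -> l -> 1 fully connected
    pair; the final sigmoid confines the ratio strictly to (0, 1).
    """
    L = np.asarray(L, dtype=float).reshape(base_kernels.shape[0], -1)
    if L.shape != base_kernels.shape:
        raise ValueError("segment and base kernels must both be (K, l)")
    x = np.concatenate([L, base_kernels], axis=1)          # (K, 2l)
    h = x @ np.asarray(m1_w).T + np.asarray(m1_b)          # (K, l)
    z = h @ np.asarray(m2_w) + float(m2_b)                 # (K,)
    if not np.all(np.isfinite(z)):
        raise FloatingPointError("non-finite value in mask-ratio computation")
    return sigmoid(z)


def soft_mask(r: np.ndarray, l: int, sharpness: float) -> np.ndarray:
    """Differentiable soft masks ``m_ij = sigma(sharpness * (r_i * l - j))``, j = 1..l.

    Every row is strictly decreasing in j with entries in (0, 1); at an integer
    index ``j = r_i * l`` the mask value is exactly 0.5.
    """
    r = np.atleast_1d(np.asarray(r, dtype=float))
    lengths = r * l
    j = np.arange(1, l + 1, dtype=float)
    return sigmoid(sharpness * (lengths[:, None] - j[None, :]))


def masked_kernels(base_kernels: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """Elementwise product of the kernel bank with its soft masks."""
    base_kernels = np.asarray(base_kernels, dtype=float)
    masks = np.asarray(masks, dtype=float)
    if base_kernels.shape != masks.shape:
        raise ValueError(
            f"kernel/mask shape mismatch: {base_kernels.shape} vs {masks.shape}")
    return base_kernels * masks


def pad_input(S: np.ndarray, l: int) -> np.ndarray:
    """Append ``l`` zeros to the end of every channel: (C, T) -> (C, T + l)."""
    if l < 1:
        raise ValueError("pad length must be >= 1")
    S = np.asarray(S, dtype=float)
    return np.pad(S, ((0, 0), (0, l)))


def dynamic_conv(S_padded: np.ndarray, W_v: np.ndarray,
                 base_b: np.ndarray) -> np.ndarray:
    """Depthwise valid convolution of every channel with every masked kernel.

    ``D[i, c, t] = sum_tau W_v[i, tau] * S_padded[c, t + tau] + base_b[i]``,
    cropped to the first T output samples.  Per-(scale, channel) maps are kept
    separate (no cross-channel summation), so D has shape (K, C, T).
    """
    S_padded = np.asarray(S_padded, dtype=float)
    W_v = np.asarray(W_v, dtype=float)
    K, l = W_v.shape
    C, Tp = S_padded.shape
    if l > Tp:
        raise ValueError(f"kernel length {l} exceeds padded input length {Tp}")
    T = Tp - l
    from numpy.lib.stride_tricks import sliding_window_view
    windows = sliding_window_view(S_padded, l, axis=-1)[:, :T]  # (C, T, l)
    D = np.einsum("ctl,kl->kct", windows, W_v)
    return D + np.asarray(base_b, dtype=float)[:, None, None]


def classify(D: np.ndarray, params: ModelParams, training: bool = False,
             rng: Optional[np.random.Generator] = None) -> float:
    """Batch-norm -> dropout -> flatten -> linear logit.

    In evaluation mode (``training=False``) the stored running batch-norm
    statistics are used and dropout is inactive, so the output is deterministic
    and affine in D.  In training mode the statistics are computed from D itself
    and dropout (inverted, rate ``config.dropout_rate``) requires ``rng``.
    """
    D = np.asarray(D, dtype=float)
    cfg = params.config
    if training:
        mu = D.mean(axis=(1, 2))
        var = D.var(axis=(1, 2))
    else:
        mu, var = params.bn_mean, params.bn_var
    z = (D - mu[:, None, None]) / np.sqrt(var[:, None, None] + BN_EPS)
    z = params.bn_gamma[:, None, None] * z + params.bn_beta[:, None, None]
    if training and cfg is not None and cfg.dropout_rate > 0:
        if rng is None:
            raise ValueError("training-mode classify needs an rng for dropout")
        keep = rng.random(z.shape) >= cfg.dropout_rate
        z = z * keep / (1.0 - cfg.dropout_rate)
    flat = z.reshape(-1)
    if flat.shape != params.clf_w.shape:
        raise ValueError(
            f"flattened feature size {flat.shape[0]} does not match classifier "
            f"weight size {params.clf_w.shape[0]}")
    return float(flat @ params.clf_w + params.clf_b)


def forward(S: np.ndarray, params: ModelParams, config: Optional[ModelConfig] = None,
            training: bool = False, rng: Optional[np.random.Generator] = None,
            ) -> Tuple[float, ForwardTrace, Optional[MaskDiagnostics]]:
    """Full reference forward pass for a single epoch.

    Returns the logit, a :class:`ForwardTrace` of every intermediate tensor,
    and :class:`MaskDiagnostics` (None for the ``standard`` variant, whose
    masks are identically 1 and whose logit is independent of the generator).
    """
    cfg = config if config is not None else params.config
    if cfg is None:
        raise ValueError("a ModelConfig is required")
    S = np.asarray(S, dtype=float)
    if S.shape != (cfg.n_channels, cfg.n_samples):
        raise ValueError(
            f"epoch shape {S.shape} does not match config "
            f"({cfg.n_channels}, {cfg.n_samples})")

    E = feature_conv(S, params.feature_w, params.feature_b)
    E_pooled = channel_gap(E)
    L = extract_segment(E_pooled, cfg.segment_start, cfg.kernel_len)

    if cfg.variant == "masked":
        r = mask_ratio(L, params.base_kernels, params.m1_w, params.m1_b,
                       params.m2_w, params.m2_b)
        M = soft_mask(r, cfg.kernel_len, cfg.sharpness)
        diagnostics = MaskDiagnostics(ratios=r, lengths=r * cfg.kernel_len, masks=M)
    else:
        M = np.ones_like(params.base_kernels)
        diagnostics = None

    W_v = masked_kernels(params.base_kernels, M)
    S_padded = pad_input(S, cfg.kernel_len)
    D = dynamic_conv(S_padded, W_v, params.base_b)
    logit = classify(D, params, training=training, rng=rng)
    trace = ForwardTrace(E=E, E_pooled=E_pooled, L=L, W_v=W_v,
                         S_padded=S_padded, D=D, logit=logit)
    return logit, trace, diagnostics


# -- checkpointing -----------------------------------------------------------

def save_checkpoint(path: str, params: ModelParams) -> None:
    """Single-file archive of all parameter arrays plus the config as JSON."""
    if params.config is None:
        raise ValueError("params must carry a config to be checkpointed")
    arrays = {f: getattr(params, f) for f in ModelParams.ARRAY_FIELDS}
    np.savez(path, config_json=np.array(json.dumps(params.config.to_dict())),
             **arrays)


def load_checkpoint(path: str) -> ModelParams:
    """Inverse of :func:`save_checkpoint`; bit-exact for stored precision."""
    with np.load(path, allow_pickle=False) as z:
        cfg = ModelConfig.from_dict(json.loads(str(z["config_json"])))
        kw = {f: z[f] for f in ModelParams.ARRAY_FIELDS}
    return ModelParams(config=cfg, **kw)
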