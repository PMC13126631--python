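"""Asymmetric multitask transformer autoencoder for AFM height images.

The network embeds non-overlapping image patches, prepends a class token,
adds learned positional embeddings and runs a pre-norm transformer
encoder.  Two branches share this representation: a classifier (further
transformer blocks, then a linear map from the class token to K state
logits) and a decoder (a linear projection of the patch tokens to a
narrower width, more transformer blocks, and a per-token linear map back
to pixel patches).  The encoder is deliberately deeper and wider than
the decoder so that it carries the semantic burden of the task rather
than memorising pixels.

Implemented on the package's own numpy autodiff engine
(:mod:`afmstate.nn.autodiff`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import (Tensor, cat, cross_entropy_logits, gelu, layer_norm,
                       mse_loss, softmax)

__all__ = ["ModelConfig", "Prediction", "ViTAutoencoder", "build_model", "loss"]

_DTYPE = np.float32


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    Defaults follow the reference architecture (12-layer/512-dim encoder,
    8-layer/256-dim decoder on 36 px images); tests and examples use a
    smaller desk-scale configuration.
    """

    image_px: int = 36
    patch_px: int = 6
    enc_layers: int = 12
    enc_dim: int = 512
    dec_layers: int = 8
    dec_dim: int = 256
    heads: int = 8
    n_states: int = 2
    cls_layers: int = 2
    mlp_ratio: int = 4

    def __post_init__(self):
        if self.image_px % self.patch_px != 0:
            raise ValueError("image_px must be divisible by patch_px")
        if self.enc_dim % self.heads or self.dec_dim % self.heads:
            raise ValueError("embedding dims must be divisible by heads")
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")

    @property
    def n_patches(self) -> int:
        return (self.image_px // self.patch_px) ** 2


@dataclass
class Prediction:
    """Network output for one image."""

    denoised01: np.ndarray
    probs: np.ndarray
    state_hat: int
    rollout: np.ndarray | None = None


def _init(rng, *shape, std=0.02):
    return Tensor(rng.normal(0.0, std, size=shape).astype(_DTYPE), requires_grad=True)


def _zeros(*shape):
    return Tensor(np.zeros(shape, dtype=_DTYPE), requires_grad=True)


def _ones(*shape):
    return Tensor(np.ones(shape, dtype=_DTYPE), requires_grad=True)


class _Linear:
    def __init__(self, rng, d_in, d_out, prefix):
        self.w = _init(rng, d_in, d_out)
        self.b = _zeros(d_out)
        self.names = {f"{prefix}.w": self.w, f"{prefix}.b": self.b}

    def __call__(self, x: Tensor) -> Tensor:
        # collapse leading axes so the matmul is one large BLAS call
        if x.ndim > 2:
            lead = x.shape[:-1]
            flat = x.reshape(-1, x.shape[-1]) @ self.w + self.b
            return flat.reshape(*lead, self.w.shape[-1])
        return x @ self.w + self.b


class _Attention:
    def __init__(self, rng, dim, heads, prefix):
        self.heads = heads
        self.head_dim = dim // heads
        self.scale = 1.0 / np.sqrt(self.head_dim)
        self.qkv = _Linear(rng, dim, 3 * dim, f"{prefix}.qkv")
        self.proj = _Linear(rng, dim, dim, f"{prefix}.proj")
        self.names = {**self.qkv.names, **self.proj.names}
        self.last_attn = None  # (B, heads, T, T), captured on request

    def __call__(self, x: Tensor, capture: bool = False) -> Tensor:
        b, t, d = x.shape
        h, hd = self.heads, self.head_dim
        qkv = self.qkv(x).reshape(b, t, 3, h, hd).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]          # (B, h, T, hd)
        attn = softmax((q @ k.transpose(0, 1, 3, 2)) * self.scale)
        if capture:
            self.last_attn = attn.data.copy()
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(b, t, d)
        return self.proj(out)


class _Block:
    """Pre-norm transformer block: x + MHA(LN(x)); x + MLP(LN(x))."""

    def __init__(self, rng, dim, heads, mlp_ratio, prefix):
        self.ln1_g, self.ln1_b = _ones(dim), _zeros(dim)
        self.attn = _Attention(rng, dim, heads, f"{prefix}.attn")
        self.ln2_g, self.ln2_b = _ones(dim), _zeros(dim)
        self.fc1 = _Linear(rng, dim, mlp_ratio * dim, f"{prefix}.fc1")
        self.fc2 = _Linear(rng, mlp_ratio * dim, dim, f"{prefix}.fc2")
        self.names = {
            f"{prefix}.ln1.g": self.ln1_g, f"{prefix}.ln1.b": self.ln1_b,
            f"{prefix}.ln2.g": self.ln2_g, f"{prefix}.ln2.b": self.ln2_b,
            **self.attn.names, **self.fc1.names, **self.fc2.names,
        }

    def __call__(self, x: Tensor, capture: bool = False) -> Tensor:
        x = x + self.attn(layer_norm(x, self.ln1_g, self.ln1_b), capture=capture)
        return x + self.fc2(gelu(self.fc1(layer_norm(x, self.ln2_g, self.ln2_b))))


class ViTAutoencoder:
    """Multitask denoising + state-classification transformer."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        p = cfg.patch_px
        t = cfg.n_patches
        self.patch_embed = _Linear(rng, p * p, cfg.enc_dim, "patch_embed")
        self.cls_token = _init(rng, 1, 1, cfg.enc_dim)
        self.pos_embed = _init(rng, 1, t + 1, cfg.enc_dim)
        self.enc_blocks = [
            _Block(rng, cfg.enc_dim, cfg.heads, cfg.mlp_ratio, f"enc.{i}")
            for i in range(cfg.enc_layers)
        ]
        self.enc_ln_g, self.enc_ln_b = _ones(cfg.enc_dim), _zeros(cfg.enc_dim)
        self.cls_blocks = [
            _Block(rng, cfg.enc_dim, cfg.heads, cfg.mlp_ratio, f"cls.{i}")
            for i in range(cfg.cls_layers)
        ]
        self.cls_ln_g, self.cls_ln_b = _ones(cfg.enc_dim), _zeros(cfg.enc_dim)
        self.head = _Linear(rng, cfg.enc_dim, cfg.n_states, "head")
        self.dec_embed = _Linear(rng, cfg.enc_dim, cfg.dec_dim, "dec_embed")
        self.dec_pos_embed = _init(rng, 1, t, cfg.dec_dim)
        self.dec_blocks = [
            _Block(rng, cfg.dec_dim, cfg.heads, cfg.mlp_ratio, f"dec.{i}")
            for i in range(cfg.dec_layers)
        ]
        self.dec_ln_g, self.dec_ln_b = _ones(cfg.dec_dim), _zeros(cfg.dec_dim)
        self.dec_out = _Linear(rng, cfg.dec_dim, p * p, "dec_out")

        self.params = {
            **self.patch_embed.names,
            "cls_token": self.cls_token,
            "pos_embed": self.pos_embed,
            "enc.ln.g": self.enc_ln_g, "enc.ln.b": self.enc_ln_b,
            "cls.ln.g": self.cls_ln_g, "cls.ln.b": self.cls_ln_b,
            **self.head.names,
            **self.dec_embed.names,
            "dec_pos_embed": self.dec_pos_embed,
            "dec.ln.g": self.dec_ln_g, "dec.ln.b": self.dec_ln_b,
            **self.dec_out.names,
        }
        for blk in self.enc_blocks + self.cls_blocks + self.dec_blocks:
            self.params.update(blk.names)
        self.frozen: set = set()

    # -- patch bookkeeping -------------------------------------------------
    def patchify(self, images: np.ndarray) -> np.ndarray:
        """(B, H, W) -> (B, n_patches, patch_px^2), row-major patch order."""
        b = images.shape[0]
        p = self.cfg.patch_px
        g = self.cfg.image_px // p
        x = images.reshape(b, g, p, g, p).transpose(0, 1, 3, 2, 4)
        return x.reshape(b, g * g, p * p)

    def unpatchify(self, tokens: Tensor) -> Tensor:
        b = tokens.shape[0]
        p = self.cfg.patch_px
        g = self.cfg.image_px // p
        x = tokens.reshape(b, g, g, p, p).transpose(0, 1, 3, 2, 4)
        return x.reshape(b, g * p, g * p)

    # -- forward -----------------------------------------------------------
    def forward(self, images: np.ndarray, capture_attn: bool = False):
        """Run a batch of normalised images (B, H, W).

        Returns ``(denoised01, logits)`` as Tensors.  With
        ``capture_attn=True`` each attention module stores its latest
        head-resolved attention matrix for rollout.
        """
        images = np.asarray(images, dtype=_DTYPE)
        if images.ndim == 2:
            images = images[None]
        b = images.shape[0]
        x = Tensor(self.patchify(images))
        x = self.patch_embed(x)
        cls = self.cls_token.broadcast_to((b, 1, self.cfg.enc_dim))
        x = cat([cls, x], axis=1) + self.pos_embed
        for blk in self.enc_blocks:
            x = blk(x, capture=capture_attn)
        x = layer_norm(x, self.enc_ln_g, self.enc_ln_b)

        c = x
        for blk in self.cls_blocks:
            c = blk(c, capture=capture_attn)
        c = layer_norm(c, self.cls_ln_g, self.cls_ln_b)
        logits = self.head(c[:, 0, :])

        d = self.dec_embed(x[:, 1:, :]) + self.dec_pos_embed
        for blk in self.dec_blocks:
            d = blk(d)
        d = layer_norm(d, self.dec_ln_g, self.dec_ln_b)
        denoised = self.unpatchify(self.dec_out(d))
        return denoised, logits

    def predict(self, images: np.ndarray):
        """Forward pass without gradients; returns (denoised01, probs,
        states) as numpy arrays with 1-based state labels."""
        from .autodiff import no_grad

        with no_grad():
            denoised, logits = self.forward(images)
        z = logits.data - logits.data.max(axis=-1, keepdims=True)
        e = np.exp(z)
        probs = e / e.sum(axis=-1, keepdims=True)
        states = probs.argmax(axis=-1) + 1
        return denoised.data, probs, states

    # -- parameters --------------------------------------------------------
    def trainable(self):
        return {k: v for k, v in self.params.items() if k not in self.frozen}

    def n_parameters(self, prefix: str | None = None) -> int:
        return sum(v.data.size for k, v in self.params.items()
                   if prefix is None or k.startswith(prefix))

    def state_dict(self):
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state, strict: bool = True):
        for k, v in self.params.items():
            if k in state and state[k].shape == v.data.shape:
                v.data = state[k].astype(_DTYPE).copy()
            elif strict:
                raise KeyError(f"missing or mismatched parameter: {k}")

    def attention_stack(self, include_encoder: bool = True,
                        include_classifier: bool = True):
        """Captured attention matrices, in forward order."""
        blocks = []
        if include_encoder:
            blocks += self.enc_blocks
        if include_classifier:
            blocks += self.cls_blocks
        return [blk.attn.last_attn for blk in blocks]


def build_model(cfg: ModelConfig, seed: int = 0) -> ViTAutoencoder:
    """Construct a seeded :class:`ViTAutoencoder`."""
    return ViTAutoencoder(cfg, seed=seed)


def loss(denoised: Tensor, logits: Tensor, gt01: np.ndarray, y: np.ndarray,
         alpha: float = 100.0, beta: float = 1.0):
    """Weighted multitask loss ``alpha * L_d + beta * L_c``.

    ``L_d`` is the pixel MSE between the denoised output and the
    (normalised) ground truth; ``L_c`` the softmax cross-entropy against
    the 1-based state labels.  Returns ``(total, L_d, L_c)`` where the
    total is a Tensor and the components are floats.
    """
    y = np.atleast_1d(np.asarray(y, dtype=int)) - 1
    l_d = mse_loss(denoised, np.asarray(gt01, dtype=_DTYPE))
    l_c = cross_entropy_logits(logits, y)
    total = l_d * float(alpha) + l_c * float(beta)
    return total, float(l_d.data), float(l_c.data)
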