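"""Attention rollout: where did the classifier look?

Per transformer layer, head-averaged attention is blended with the
identity to account for the residual path, ``A' = 0.5 (A + I)``, rows
renormalised to sum to 1, and the layer matrices are multiplied in
forward order.  The class-token row of the product, restricted to the
patch tokens, is reshaped to the patch grid, upsampled to pixel
resolution and min-max normalised to [0, 1].
"""

from __future__ import annotations

import numpy as np

__all__ = ["rollout_from_attention", "attention_rollout"]


def rollout_from_attention(attn_layers) -> np.ndarray:
    """Multiply residual-blended, row-normalised attention matrices.

    ``attn_layers``: iterable of (T, T) or (B, heads, T, T) matrices in
    forward order; returns the (T, T) (or (B, T, T)) rollout product.
    """
    product = None
    for a in attn_layers:
        a = np.asarray(a, dtype=float)
        if a.ndim == 4:
            a = a.mean(axis=1)  # average heads -> (B, T, T)
        eye = np.eye(a.shape[-1])
        blended = 0.5 * (a + eye)
        blended = blended / blended.sum(axis=-1, keepdims=True)
        product = blended if product is None else blended @ product
    if product is None:
        raise ValueError("no attention matrices supplied")
    return product


def attention_rollout(net, img01: np.ndarray, *, include_encoder: bool = True,
                      include_classifier: bool = True) -> np.ndarray:
    """Pixel-resolution rollout map in [0, 1] for one normalised image.

    By default the rollout spans both the encoder and the classifier
    blocks; either span can be disabled.
    """
    img01 = np.asarray(img01, dtype=np.float32)
    if img01.ndim == 2:
        img01 = img01[None]
    net.forward(img01, capture_attn=True)
    layers = net.attention_stack(include_encoder=include_encoder,
                                 include_classifier=include_classifier)
    product = rollout_from_attention(layers)  # (B, T+1, T+1)
    cls_row = product[0, 0, 1:]               # class token -> patch tokens
    g = net.cfg.image_px // net.cfg.patch_px
    patch_map = cls_row.reshape(g, g)
    pixel_map = np.kron(patch_map, np.ones((net.cfg.patch_px, net.cfg.patch_px)))
    lo, hi = pixel_map.min(), pixel_map.max()
    if hi == lo:
        return np.zeros_like(pixel_map)
    return (pixel_map - lo) / (hi - lo)
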