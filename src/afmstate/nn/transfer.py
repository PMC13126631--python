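"""Transfer learning: reuse pretrained weights on a new target.

Every parameter whose name and shape match the source checkpoint is
copied; the classifier output layer is reinitialised whenever the state
count differs.  Optionally the encoder (patch embedding, positional
embeddings, encoder blocks and final norm) is frozen so that fine-tuning
touches only the classifier and decoder.
"""

from __future__ import annotations

from .vit import ModelConfig, ViTAutoencoder, build_model

__all__ = ["transfer_init"]

_ENCODER_PREFIXES = ("patch_embed", "cls_token", "pos_embed", "enc.")


def transfer_init(source, cfg_new: ModelConfig, *, freeze_encoder: bool = False,
                  seed: int = 0) -> ViTAutoencoder:
    """Build a network for ``cfg_new`` initialised from a trained source.

    ``source`` is a :class:`ViTAutoencoder` or a checkpoint path.  All
    matching-shape weights are copied; mismatched ones (e.g. the
    classifier head when K changes) keep their fresh seeded init.
    """
    if not isinstance(source, ViTAutoencoder):
        from .train import load_checkpoint

        source = load_checkpoint(source)
    net = build_model(cfg_new, seed=seed)
    src_state = source.state_dict()
    copied = {k: v for k, v in src_state.items()
              if k in net.params and net.params[k].data.shape == v.shape}
    net.load_state_dict(copied, strict=False)
    if freeze_encoder:
        net.frozen = {k for k in net.params if k.startswith(_ENCODER_PREFIXES)}
    return net
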