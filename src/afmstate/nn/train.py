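"""Training, checkpointing and inference for the multitask autoencoder.

Optimisation is AdamW (decoupled weight decay) with a linear warmup to
the peak learning rate over the first epochs followed by cosine decay to
zero.  Checkpoints are a directory holding the weights (npz) plus a JSON
sidecar recording the model/training configuration, the state count and
the normalisation convention.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from ..dataset import minmax_normalize, minmax_rescale
from ..simulate import HeightImage
from .rollout import attention_rollout
from .vit import ModelConfig, Prediction, ViTAutoencoder, build_model, loss

__all__ = ["TrainConfig", "AdamW", "lr_at", "train", "save_checkpoint",
           "load_checkpoint", "infer"]

#: How images are scaled before entering the network and how the decoder
#: output is mapped back to nm (recorded in every checkpoint).
NORMALIZATION = "minmax_of_input"


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation hyperparameters (reference values)."""

    epochs: int = 20
    batch: int = 192
    lr_max: float = 0.002
    warmup_epochs: int = 5
    weight_decay: float = 0.0001
    alpha: float = 100.0
    beta: float = 1.0
    grad_clip: float = 0.0  # global-norm clip; 0 disables
    seed: int = 0

    def __post_init__(self):
        if min(self.epochs, self.batch) < 1 or self.lr_max <= 0:
            raise ValueError("epochs, batch and lr_max must be positive")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("loss weights must be non-negative")


def lr_at(step: int, total_steps: int, warmup_steps: int, lr_max: float) -> float:
    """Learning rate at ``step`` (0-based): linear 0 -> lr_max over the
    warmup, then cosine decay to 0 at ``total_steps``."""
    if warmup_steps > 0 and step < warmup_steps:
        return lr_max * step / warmup_steps
    span = max(total_steps - warmup_steps, 1)
    frac = (step - warmup_steps) / span
    return lr_max * 0.5 * (1.0 + np.cos(np.pi * min(frac, 1.0)))


class AdamW:
    """Adam with decoupled weight decay on a named parameter dict."""

    def __init__(self, params: dict, weight_decay: float = 0.0,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}

    def step(self, lr: float) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            update = (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)
            p.data = p.data - lr * (update + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def clip_grad_norm(self, max_norm: float) -> float:
        """Scale all gradients so their global L2 norm is <= max_norm."""
        total = 0.0
        for p in self.params.values():
            if p.grad is not None:
                total += float((p.grad.astype(np.float64) ** 2).sum())
        norm = np.sqrt(total)
        if norm > max_norm > 0:
            scale = max_norm / norm
            for p in self.params.values():
                if p.grad is not None:
                    p.grad = p.grad * scale
        return norm


def _evaluate(net: ViTAutoencoder, stream, alpha: float, beta: float):
    from .autodiff import no_grad

    n = correct = 0
    sum_ld = sum_lc = 0.0
    for noisy01, gt01, states in stream:
        with no_grad():
            denoised, logits = net.forward(noisy01)
            _, l_d, l_c = loss(denoised, logits, gt01, states, alpha, beta)
        b = len(states)
        sum_ld += l_d * b
        sum_lc += l_c * b
        preds = logits.data.argmax(axis=-1) + 1
        correct += int((preds == states).sum())
        n += b
    if n == 0:
        return {"L_d": np.nan, "L_c": np.nan, "accuracy": np.nan}
    return {"L_d": sum_ld / n, "L_c": sum_lc / n, "accuracy": correct / n}


def train(net: ViTAutoencoder, train_stream, val_stream, tcfg: TrainConfig,
          steps_per_epoch: int | None = None):
    """Train the network; returns ``(net, history)``.

    ``train_stream`` and ``val_stream`` are zero-argument callables that
    return a fresh iterator of ``(noisy01, gt01, states)`` batches for
    each epoch (states 1-based).  History holds per-epoch train/val
    denoising loss, classification loss and validation exact-match
    accuracy.  If the loss turns non-finite, training aborts and the last
    finite-state weights are restored.
    """
    if steps_per_epoch is None:
        steps_per_epoch = sum(1 for _ in train_stream())
    total_steps = tcfg.epochs * steps_per_epoch
    warmup_steps = tcfg.warmup_epochs * steps_per_epoch
    opt = AdamW(net.trainable(), weight_decay=tcfg.weight_decay)
    history = []
    step = 0
    last_good = net.state_dict()
    for epoch in range(tcfg.epochs):
        sum_ld = sum_lc = 0.0
        n = 0
        for noisy01, gt01, states in train_stream():
            lr = lr_at(step, total_steps, warmup_steps, tcfg.lr_max)
            opt.zero_grad()
            denoised, logits = net.forward(noisy01)
            total, l_d, l_c = loss(denoised, logits, gt01, states,
                                   tcfg.alpha, tcfg.beta)
            if not np.isfinite(total.data):
                net.load_state_dict(last_good)
                history.append({"epoch": epoch, "aborted": True})
                return net, history
            total.backward()
            if tcfg.grad_clip > 0:
                opt.clip_grad_norm(tcfg.grad_clip)
            opt.step(lr)
            b = len(states)
            sum_ld += l_d * b
            sum_lc += l_c * b
            n += b
            step += 1
        last_good = net.state_dict()
        val = _evaluate(net, val_stream(), tcfg.alpha, tcfg.beta)
        history.append({
            "epoch": epoch,
            "lr": lr_at(step, total_steps, warmup_steps, tcfg.lr_max),
            "train_L_d": sum_ld / max(n, 1),
            "train_L_c": sum_lc / max(n, 1),
            "val_L_d": val["L_d"],
            "val_L_c": val["L_c"],
            "val_accuracy": val["accuracy"],
        })
    return net, history


def save_checkpoint(path, net: ViTAutoencoder, tcfg: TrainConfig | None = None,
                    history=None) -> None:
    """Persist weights + JSON sidecar (configs, state count, normalisation
    convention, library versions)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savez(path / "weights.npz", **net.state_dict())
    sidecar = {
        "model_config": asdict(net.cfg),
        "train_config": asdict(tcfg) if tcfg else None,
        "n_states": net.cfg.n_states,
        "normalization": NORMALIZATION,
        "versions": {"numpy": np.__version__},
    }
    (path / "checkpoint.json").write_text(json.dumps(sidecar, indent=2))
    if history is not None:
        (path / "history.json").write_text(json.dumps(history, indent=2))


def load_checkpoint(path) -> ViTAutoencoder:
    path = Path(path)
    sidecar = json.loads((path / "checkpoint.json").read_text())
    cfg = ModelConfig(**sidecar["model_config"])
    net = build_model(cfg, seed=0)
    with np.load(path / "weights.npz") as data:
        net.load_state_dict({k: data[k] for k in data.files})
    return net


def infer(net_or_path, img: HeightImage, *, with_rollout: bool = True):
    """Denoise and classify one height image (nm).

    The image is min-max normalised, passed through the network, and the
    denoised output is rescaled to nm with the *input's* recorded min and
    max.  Returns ``(Prediction, denoised_nm)``.
    """
    net = net_or_path if isinstance(net_or_path, ViTAutoencoder) \
        else load_checkpoint(net_or_path)
    img01, vmin, vmax = minmax_normalize(img)
    denoised01, probs, states = net.predict(img01[None])
    rollout = attention_rollout(net, img01) if with_rollout else None
    pred = Prediction(denoised01=denoised01[0], probs=probs[0],
                      state_hat=int(states[0]), rollout=rollout)
    denoised_nm = minmax_rescale(pred.denoised01, vmin, vmax, grid=img.grid)
    return pred, denoised_nm
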