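"""Paired-image training datasets streamed to sharded tar archives.

Each sample is a (ground-truth, scan-lag-distorted) image pair with a
conformational-state label, stored as three tar members that share a
zero-padded key: ``<key>.gt.tiff``, ``<key>.noisy.tiff`` (32-bit float
TIFF, nm) and ``<key>.json`` (label + generation parameters).  White
noise and the +/-3 px shift augmentation are applied at *load* time, so
one stored dataset serves many noise levels; the scan-lag distortion of
the noisy member is baked in at build time.

Normalisation convention: both members of a pair are min-max scaled by
the minimum and maximum of the *noisy input*, because those are the only
quantities available at inference time to map the denoised output back
to nanometres.
"""

from __future__ import annotations

import io
import json
import logging
import tarfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .bead_model import Ensemble
from .scan_noise import (ScanNoiseParams, render_with_scan_lag,
                         sample_sigma_N, shift_values)
from .simulate import (HeightImage, ImageGrid, ParamRanges, render,
                       sample_sim_params)
from .state_space import StateModel

logger = logging.getLogger(__name__)

__all__ = [
    "ShardSpec",
    "minmax_normalize",
    "minmax_rescale",
    "build_dataset",
    "iter_samples",
    "cache_samples",
    "load_batches",
]


@dataclass(frozen=True)
class ShardSpec:
    """Shard layout: pairs per archive, key format, optional gzip."""

    shard_size: int = 1000
    key_format: str = "{:010d}"
    compression: bool = False

    def __post_init__(self):
        if self.shard_size < 1:
            raise ValueError("shard_size must be >= 1")


def minmax_normalize(img: HeightImage):
    """Scale an image to [0, 1]; returns ``(img01, vmin, vmax)`` in nm.

    A constant image maps to all-zeros, with vmin = vmax recorded.
    """
    vmin = float(img.values.min())
    vmax = float(img.values.max())
    if vmax == vmin:
        return np.zeros_like(img.values), vmin, vmax
    return (img.values - vmin) / (vmax - vmin), vmin, vmax


def minmax_rescale(img01: np.ndarray, vmin: float, vmax: float,
                   grid: ImageGrid | None = None):
    """Invert min-max scaling back to nm: ``img01 * (vmax - vmin) + vmin``."""
    if vmax < vmin:
        raise ValueError("vmax must be >= vmin")
    values = np.asarray(img01, dtype=float) * (vmax - vmin) + vmin
    if grid is not None:
        return HeightImage(values, grid)
    return values


def _tiff_bytes(values: np.ndarray) -> bytes:
    import tifffile

    buf = io.BytesIO()
    tifffile.imwrite(buf, values.astype(np.float32))
    return buf.getvalue()


def _read_tiff_bytes(data: bytes) -> np.ndarray:
    import tifffile

    return np.asarray(tifffile.imread(io.BytesIO(data)), dtype=float)


def _add_member(tar: tarfile.TarFile, name: str, data: bytes) -> None:
    info = tarfile.TarInfo(name=name)
    info.size = len(data)
    info.mtime = 0  # fixed so archives are byte-reproducible
    tar.addfile(info, io.BytesIO(data))


def build_dataset(ens: Ensemble, sm: StateModel, n_pairs: int, out_dir,
                  *, ranges: ParamRanges = ParamRanges(),
                  noise: ScanNoiseParams = ScanNoiseParams(),
                  shard: ShardSpec = ShardSpec(),
                  grid: ImageGrid | None = None,
                  sigma_range: tuple = (0.0, 0.3, 0.01),
                  seed: int = 0, stage_mode: str = "surface"):
    """Generate ``n_pairs`` labelled image pairs and write them to sharded
    tar archives under ``out_dir``; returns the list of shard paths.

    Frames are drawn uniformly from the ensemble; each pair samples a
    probe and initial pose, renders the ground truth, renders the noisy
    member with per-line scan lag, and records (but does not apply) a
    white-noise sigma.  Each shard is deterministic given (seed, shard
    index), so shards may be generated in parallel.
    """
    if sm.labels is None or sm.K == 0:
        raise ValueError("state model has no clusters")
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    grid = grid or ImageGrid.centered()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    n_shards = (n_pairs + shard.shard_size - 1) // shard.shard_size
    mode = "w:gz" if shard.compression else "w"
    ext = ".tar.gz" if shard.compression else ".tar"
    paths = []
    for shard_idx in range(n_shards):
        rng = np.random.default_rng(np.random.SeedSequence([seed, shard_idx]))
        lo = shard_idx * shard.shard_size
        hi = min(lo + shard.shard_size, n_pairs)
        path = out_dir / f"shard-{shard_idx:06d}{ext}"
        with tarfile.open(path, mode) as tar:
            for i in range(lo, hi):
                key = shard.key_format.format(i)
                frame = int(rng.integers(len(ens)))
                tip, pose0 = sample_sim_params(rng, ranges)
                gt = render(ens[frame], pose0, tip, grid, stage_mode=stage_mode)
                noisy = render_with_scan_lag(ens[frame], pose0, tip, grid,
                                             noise, rng, stage_mode=stage_mode)
                sigma_n = sample_sigma_N(rng, *sigma_range)
                meta = {
                    "state": int(sm.labels[frame]),
                    "frame_id": int(ens.frame_ids[frame]),
                    "R": tip.R,
                    "Theta": tip.Theta,
                    "pose0": list(pose0.as_tuple()),
                    "sigma_N": sigma_n,
                    "seed": seed,
                    "grid": {"nx": grid.nx, "ny": grid.ny,
                             "pixel_size": grid.pixel_size,
                             "origin": list(grid.origin)},
                }
                _add_member(tar, f"{key}.gt.tiff", _tiff_bytes(gt.values))
                _add_member(tar, f"{key}.noisy.tiff", _tiff_bytes(noisy.values))
                _add_member(tar, f"{key}.json",
                            json.dumps(meta, sort_keys=True).encode())
        paths.append(path)
    return paths


def iter_samples(archives):
    """Stream ``(key, gt_values, noisy_values, meta)`` from tar shards in
    archive order.  Incomplete or corrupt sample groups are skipped with a
    logged count."""
    skipped = 0
    for archive in archives:
        with tarfile.open(archive, "r:*") as tar:
            pending = {}
            for member in tar:
                if not member.isfile():
                    continue
                key, _, role_ext = member.name.partition(".")
                try:
                    data = tar.extractfile(member).read()
                    group = pending.setdefault(key, {})
                    if role_ext == "gt.tiff":
                        group["gt"] = _read_tiff_bytes(data)
                    elif role_ext == "noisy.tiff":
                        group["noisy"] = _read_tiff_bytes(data)
                    elif role_ext == "json":
                        group["meta"] = json.loads(data)
                except Exception:  # corrupt member: drop the whole sample
                    pending.pop(key, None)
                    skipped += 1
                    continue
                group = pending.get(key)
                if group is not None and len(group) == 3:
                    del pending[key]
                    yield key, group["gt"], group["noisy"], group["meta"]
            skipped += len(pending)
    if skipped:
        logger.warning("skipped %d incomplete/corrupt samples", skipped)


def cache_samples(archives):
    """Decode all samples of the given shards into memory (float32).

    Returns a list of ``(gt, noisy, meta)`` suitable for repeated passes
    through :func:`load_batches` without re-reading the archives — useful
    when the dataset fits in RAM and many epochs are run.
    """
    return [(gt.astype(np.float32), noisy.astype(np.float32), meta)
            for _, gt, noisy, meta in iter_samples(archives)]


def load_batches(source, batch: int, rng: np.random.Generator,
                 *, augment: bool = True, max_shift: int = 3,
                 buffer_size: int = 1024):
    """Stream training batches ``(noisy01, gt01, state)``.

    ``source`` is a list of tar shard paths or a pre-decoded list from
    :func:`cache_samples`.  Per sample: optional joint +/-``max_shift``
    pixel shift of both members, white noise at the recorded sigma_N
    added to the noisy member, then min-max normalisation of both
    members by the noisy member's min/max.  Samples are shuffled through
    a bounded buffer, so memory stays O(batch + buffer) when streaming
    from disk.  States are returned 1-based.
    """
    buffer = []

    def _prepare(gt, noisy, meta):
        if augment:
            dx = int(rng.integers(-max_shift, max_shift + 1))
            dy = int(rng.integers(-max_shift, max_shift + 1))
            gt = shift_values(gt, dx, dy)
            noisy = shift_values(noisy, dx, dy)
        sigma = float(meta.get("sigma_N", 0.0))
        if sigma > 0:
            noisy = noisy + rng.normal(0.0, sigma, size=noisy.shape)
        vmin, vmax = float(noisy.min()), float(noisy.max())
        if vmax == vmin:
            return np.zeros_like(noisy), np.zeros_like(gt), meta["state"]
        return ((noisy - vmin) / (vmax - vmin),
                (gt - vmin) / (vmax - vmin),
                meta["state"])

    def _emit(items):
        noisy01 = np.stack([s[0] for s in items])
        gt01 = np.stack([s[1] for s in items])
        states = np.array([s[2] for s in items], dtype=int)
        return noisy01, gt01, states

    if source and isinstance(source[0], tuple):
        stream = iter(source)
    else:
        stream = ((gt, noisy, meta)
                  for _, gt, noisy, meta in iter_samples(source))
    for gt, noisy, meta in stream:
        buffer.append(_prepare(gt, noisy, meta))
        if len(buffer) >= buffer_size + batch:
            picks = rng.choice(len(buffer), size=batch, replace=False)
            picks = np.sort(picks)[::-1]
            items = [buffer.pop(int(i)) for i in picks]
            yield _emit(items)
    rng.shuffle(buffer)
    for start in range(0, len(buffer), batch):
        items = buffer[start:start + batch]
        if items:
            yield _emit(items)
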