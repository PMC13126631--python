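"""Preprocessing of experimental AFM height maps.

Raw images of molecules on a supporting lattice are converted to
model-ready 36 x 36 nm-unit inputs: the stage height is estimated as the
mean lattice level outside both the lattice holes and the molecule, the
holes are filled with that value, the image mean is subtracted, the
molecule is shifted to the image centre, and the frame is cropped or
zero-padded to the target size.

Masks may be supplied explicitly; otherwise they are derived by a
deterministic median +/- k*MAD threshold so the pipeline is auditable.
"""

from __future__ import annotations

import numpy as np

from .simulate import HeightImage, ImageGrid
from .scan_noise import shift_values

__all__ = [
    "auto_masks",
    "estimate_stage",
    "fill_and_level",
    "center_and_frame",
    "preprocess_image",
]


def auto_masks(img: HeightImage, k: float = 3.0):
    """Derive (hole_mask, molecule_mask) by robust thresholding.

    Pixels below ``median - k*MAD`` are holes; above ``median + k*MAD``
    the molecule.  MAD is scaled to sigma-equivalent (1.4826).
    """
    v = img.values
    med = np.median(v)
    mad = 1.4826 * np.median(np.abs(v - med))
    span = k * mad if mad > 0 else 0.0
    return v < med - span, v > med + span


def estimate_stage(img: HeightImage, hole_mask, molecule_mask) -> float:
    """Mean height of the lattice surface, excluding holes and molecule."""
    keep = ~(np.asarray(hole_mask, bool) | np.asarray(molecule_mask, bool))
    if keep.shape != img.values.shape:
        raise ValueError("masks must share the image grid")
    if not keep.any():
        raise ValueError("no lattice pixels left after masking")
    return float(img.values[keep].mean())


def fill_and_level(img: HeightImage, hole_mask, stage: float) -> HeightImage:
    """Fill holes with the stage value, then subtract the image mean."""
    values = img.values.copy()
    values[np.asarray(hole_mask, bool)] = stage
    values -= values.mean()
    return HeightImage(values, img.grid)


def center_and_frame(img: HeightImage, target: int = 36,
                     threshold: float | None = None, k: float = 3.0) -> HeightImage:
    """Centre the molecule and standardise the frame to target x target.

    The intensity-weighted centroid of above-threshold pixels is moved to
    the central pixel by an integer shift (zero-fill), then the image is
    symmetrically cropped or zero-padded.  The default threshold is
    ``median + k*MAD`` of the levelled image.
    """
    v = img.values
    if threshold is None:
        med = np.median(v)
        mad = 1.4826 * np.median(np.abs(v - med))
        threshold = med + k * mad
    mask = v > threshold
    if not mask.any():
        raise ValueError("no pixel above threshold; cannot locate molecule")
    weights = np.where(mask, v - threshold, 0.0)
    ys, xs = np.mgrid[0:v.shape[0], 0:v.shape[1]]
    cy = float((ys * weights).sum() / weights.sum())
    cx = float((xs * weights).sum() / weights.sum())
    dy = int(round(v.shape[0] // 2 - cy))
    dx = int(round(v.shape[1] // 2 - cx))
    centered = shift_values(v, dx, dy)

    out = np.zeros((target, target))
    sy = (v.shape[0] - target) // 2
    sx = (v.shape[1] - target) // 2
    src_y = slice(max(sy, 0), max(sy, 0) + min(target, v.shape[0]))
    src_x = slice(max(sx, 0), max(sx, 0) + min(target, v.shape[1]))
    dst_y = slice(max(-sy, 0), max(-sy, 0) + min(target, v.shape[0]))
    dst_x = slice(max(-sx, 0), max(-sx, 0) + min(target, v.shape[1]))
    out[dst_y, dst_x] = centered[src_y, src_x]
    grid = ImageGrid.centered(nx=target, ny=target, pixel_size=img.grid.pixel_size)
    return HeightImage(out, grid)


def preprocess_image(img: HeightImage, hole_mask=None, molecule_mask=None,
                     target: int = 36, k: float = 3.0) -> HeightImage:
    """Full pipeline: masks -> stage estimate -> fill & level -> centre &
    frame.  Idempotent for already-processed inputs with stable masks."""
    if hole_mask is None or molecule_mask is None:
        auto_hole, auto_mol = auto_masks(img, k=k)
        hole_mask = auto_hole if hole_mask is None else hole_mask
        molecule_mask = auto_mol if molecule_mask is None else molecule_mask
    stage = estimate_stage(img, hole_mask, molecule_mask)
    levelled = fill_and_level(img, hole_mask, stage)
    return center_and_frame(levelled, target=target, k=k)
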