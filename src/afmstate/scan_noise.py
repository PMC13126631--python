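"""Line-scan lag and white-noise models for realistic pseudo-AFM images.

High-speed AFM acquires an image line by line along the fast (x) axis;
a molecule diffusing on the stage moves between lines, distorting the
assembled image.  This is emulated by drawing, for every scan line, an
independent perturbation of the molecule's lateral position and
orientation *relative to its t = 0 pose* (not a cumulative walk):

``dp_i ~ N(0, s * sigma_i^2)`` for p in {x, y, phi, theta, psi},

truncated by rejection so that ``sqrt(dx^2+dy^2) <= w*dr_max`` (jointly)
and each angle stays within ``w * dmax`` of 0.  ``s`` scales all variances
and ``w`` scales the truncation window; at large ``s`` the truncated
distributions approach the uniform distribution on the allowed window.
The internal conformation is held fixed during the scan.

Additive pixel noise is plain Gaussian white noise of standard deviation
``sigma_N`` (nm), applied without clamping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import HeightImage, ImageGrid, Pose, TipModel, render

__all__ = [
    "ScanNoiseParams",
    "LinePerturbation",
    "sample_line_perturbation",
    "sample_line_perturbations",
    "render_with_scan_lag",
    "add_white_noise",
    "sample_sigma_N",
    "random_pixel_shift",
]


@dataclass(frozen=True)
class ScanNoiseParams:
    """Per-line perturbation parameters.

    Defaults are the reference set used throughout: variances 0.81 nm^2
    laterally, 6.25 deg^2 for the tilts, 25 deg^2 for the in-plane
    rotation; truncation radii 1.2 nm, 5 deg, 5 deg, 10 deg; s = w = 1.
    """

    s: float = 1.0
    w: float = 1.0
    var_x: float = 0.81
    var_y: float = 0.81
    var_phi: float = 6.25
    var_theta: float = 6.25
    var_psi: float = 25.0
    dr_max: float = 1.2
    dphi_max: float = 5.0
    dtheta_max: float = 5.0
    dpsi_max: float = 10.0

    def __post_init__(self):
        for name in ("s", "w", "var_x", "var_y", "var_phi", "var_theta",
                     "var_psi", "dr_max", "dphi_max", "dtheta_max", "dpsi_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class LinePerturbation:
    """Displacement of one scan line from the t = 0 pose."""

    dx: float = 0.0
    dy: float = 0.0
    dphi: float = 0.0
    dtheta: float = 0.0
    dpsi: float = 0.0


def _truncated_normal(rng, n, sigma, bound):
    """n i.i.d. N(0, sigma^2) draws restricted to |v| <= bound by rejection."""
    if sigma == 0.0 or bound == 0.0:
        return np.zeros(n)
    out = rng.normal(0.0, sigma, size=n)
    bad = np.abs(out) > bound
    while bad.any():
        out[bad] = rng.normal(0.0, sigma, size=int(bad.sum()))
        bad = np.abs(out) > bound
    return out


def sample_line_perturbations(rng: np.random.Generator, p: ScanNoiseParams,
                              n: int) -> np.ndarray:
    """Draw ``n`` perturbations at once; returns an (n, 5) array with
    columns (dx, dy, dphi, dtheta, dpsi).

    (dx, dy) are resampled *jointly* until the radial bound holds; the
    three angles are truncated independently.  ``s = 0`` or ``w = 0``
    short-circuits to zeros.
    """
    out = np.zeros((n, 5))
    if p.s == 0.0 or p.w == 0.0:
        return out
    sx, sy = np.sqrt(p.s * p.var_x), np.sqrt(p.s * p.var_y)
    r_bound = p.w * p.dr_max
    if (sx > 0 or sy > 0) and r_bound > 0:
        dx = rng.normal(0.0, sx, size=n) if sx > 0 else np.zeros(n)
        dy = rng.normal(0.0, sy, size=n) if sy > 0 else np.zeros(n)
        bad = np.hypot(dx, dy) > r_bound
        while bad.any():
            k = int(bad.sum())
            if sx > 0:
                dx[bad] = rng.normal(0.0, sx, size=k)
            if sy > 0:
                dy[bad] = rng.normal(0.0, sy, size=k)
            bad = np.hypot(dx, dy) > r_bound
        out[:, 0], out[:, 1] = dx, dy
    out[:, 2] = _truncated_normal(rng, n, np.sqrt(p.s * p.var_phi), p.w * p.dphi_max)
    out[:, 3] = _truncated_normal(rng, n, np.sqrt(p.s * p.var_theta), p.w * p.dtheta_max)
    out[:, 4] = _truncated_normal(rng, n, np.sqrt(p.s * p.var_psi), p.w * p.dpsi_max)
    return out


def sample_line_perturbation(rng: np.random.Generator,
                             p: ScanNoiseParams) -> LinePerturbation:
    """Draw a single per-line perturbation."""
    row = sample_line_perturbations(rng, p, 1)[0]
    return LinePerturbation(*map(float, row))


def render_with_scan_lag(model, pose0: Pose, tip: TipModel, grid: ImageGrid,
                         p: ScanNoiseParams, rng: np.random.Generator,
                         *, stage_mode: str = "surface",
                         return_log: bool = False):
    """Render an image with per-line pose perturbation.

    Lines are scanned bottom row to top row (row index 0 upward); each
    line is rendered as that row of a fresh full-pose render at
    ``pose0 + perturbation`` and the rows are assembled into one image.
    With ``return_log=True`` also returns the (ny, 5) perturbation log so
    any line can be replayed exactly.
    """
    perts = sample_line_perturbations(rng, p, grid.ny)
    values = np.zeros((grid.ny, grid.nx))
    for i in range(grid.ny):
        dx, dy, dphi, dtheta, dpsi = perts[i]
        pose_i = pose0.perturbed(dx, dy, dphi, dtheta, dpsi)
        line = render(model, pose_i, tip, grid, stage_mode=stage_mode, rows=i)
        values[i] = line.values[i]
    img = HeightImage(values, grid)
    if return_log:
        return img, perts
    return img


def add_white_noise(img: HeightImage, sigma_N: float,
                    rng: np.random.Generator) -> HeightImage:
    """Add i.i.d. Gaussian noise N(0, sigma_N^2) to every pixel (nm); no
    clamping, so negative heights may result."""
    if sigma_N < 0:
        raise ValueError("sigma_N must be non-negative")
    if sigma_N == 0:
        return img.copy()
    noise = rng.normal(0.0, sigma_N, size=img.values.shape)
    return HeightImage(img.values + noise, img.grid)


def sample_sigma_N(rng: np.random.Generator, lo: float = 0.0, hi: float = 0.3,
                   step: float = 0.01) -> float:
    """Uniform draw from the inclusive grid {lo, lo+step, ..., hi} (nm)."""
    if lo > hi:
        raise ValueError("lo must not exceed hi")
    if step <= 0:
        raise ValueError("step must be positive")
    n = int(round((hi - lo) / step)) + 1
    return float(round(lo + step * int(rng.integers(n)), 12))


def shift_values(values: np.ndarray, dx: int, dy: int) -> np.ndarray:
    """Shift an array by integer pixels (+dx -> +x columns, +dy -> +y rows),
    filling vacated pixels with 0."""
    ny, nx = values.shape
    if abs(dx) >= nx or abs(dy) >= ny:
        raise ValueError("shift exceeds image size")
    out = np.zeros_like(values)
    ys_src = slice(max(0, -dy), ny - max(0, dy))
    ys_dst = slice(max(0, dy), ny - max(0, -dy))
    xs_src = slice(max(0, -dx), nx - max(0, dx))
    xs_dst = slice(max(0, dx), nx - max(0, -dx))
    out[ys_dst, xs_dst] = values[ys_src, xs_src]
    return out


def random_pixel_shift(pair, rng: np.random.Generator, max_shift: int = 3):
    """Apply one uniformly drawn integer shift in [-max_shift, max_shift]^2
    identically to both members of a (ground-truth, noisy) image pair."""
    gt, noisy = pair
    if gt.grid != noisy.grid:
        raise ValueError("pair members must share one grid")
    dx = int(rng.integers(-max_shift, max_shift + 1))
    dy = int(rng.integers(-max_shift, max_shift + 1))
    return (
        HeightImage(shift_values(gt.values, dx, dy), gt.grid),
        HeightImage(shift_values(noisy.values, dx, dy), noisy.grid),
    )
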