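"""Exhaustive-grid rigid-body fitting by pixel correlation.

Each candidate structure (typically the K cluster centres) is rendered
over a discrete grid of orientations and probe parameters; the rendered
image is additionally translated by integer pixels within a small window
(zero-fill), and the pose maximising the Pearson correlation coefficient
(c.c.) with the reference image wins.  The search order — state, psi,
phi, theta, R, Theta, shift — and a first-maximum tie-break make results
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import HeightImage, Pose, TipModel, render_many

__all__ = ["FitGrid", "FitResult", "cc", "fit", "fit_after_denoise"]


@dataclass(frozen=True)
class FitGrid:
    """Discrete search grid.

    Defaults: psi in [-180, 180] step 5 (73 values); phi, theta in
    [-30, 30] step 5 (13 values each); probe fixed at R = 1 nm,
    Theta = 10 deg; lateral shifts within +/-3 pixels.
    """

    psi_range: tuple = (-180.0, 180.0)
    psi_step: float = 5.0
    phi_range: tuple = (-30.0, 30.0)
    phi_step: float = 5.0
    theta_range: tuple = (-30.0, 30.0)
    theta_step: float = 5.0
    R_values: tuple = (1.0,)
    Theta_values: tuple = (10.0,)
    shift_px: int = 3

    def __post_init__(self):
        if min(self.psi_step, self.phi_step, self.theta_step) <= 0:
            raise ValueError("grid steps must be positive")
        if not self.R_values or not self.Theta_values:
            raise ValueError("probe grids must be non-empty")

    def _axis(self, lo_hi, step):
        lo, hi = lo_hi
        n = int(round((hi - lo) / step)) + 1
        return lo + step * np.arange(n)

    @property
    def psi_values(self):
        return self._axis(self.psi_range, self.psi_step)

    @property
    def phi_values(self):
        return self._axis(self.phi_range, self.phi_step)

    @property
    def theta_values(self):
        return self._axis(self.theta_range, self.theta_step)

    @property
    def shifts(self):
        s = self.shift_px
        return [(dx, dy) for dx in range(-s, s + 1) for dy in range(-s, s + 1)]


@dataclass
class FitResult:
    """Best grid point: 1-based state index, pose, probe, pixel shift and
    the winning correlation coefficient."""

    state: int
    pose: Pose
    tip: TipModel
    shift: tuple
    cc: float
    table: list = field(default_factory=list)


def cc(sim: HeightImage, ref: HeightImage) -> float:
    """Pearson correlation coefficient over all pixels.

    Undefined (raises ValueError) when both images are constant.
    """
    a = sim.values if isinstance(sim, HeightImage) else np.asarray(sim)
    b = ref.values if isinstance(ref, HeightImage) else np.asarray(ref)
    if a.shape != b.shape:
        raise ValueError("images must share one grid")
    da = a - a.mean()
    db = b - b.mean()
    na = float((da * da).sum())
    nb = float((db * db).sum())
    if na == 0.0 and nb == 0.0:
        raise ValueError("c.c. undefined: both images are constant")
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float((da * db).sum() / np.sqrt(na * nb))


def _shift_batch(images: np.ndarray, dx: int, dy: int) -> np.ndarray:
    """Integer-pixel shift (zero fill) applied to a whole (n, ny, nx) stack."""
    n, ny, nx = images.shape
    out = np.zeros_like(images)
    ys_src = slice(max(0, -dy), ny - max(0, dy))
    ys_dst = slice(max(0, dy), ny - max(0, -dy))
    xs_src = slice(max(0, -dx), nx - max(0, dx))
    xs_dst = slice(max(0, dx), nx - max(0, -dx))
    out[:, ys_dst, xs_dst] = images[:, ys_src, xs_src]
    return out


def _cc_many(sims: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """c.c. of each image in ``sims`` (n, ny, nx) against ``ref``;
    constant sims score -inf."""
    flat = sims.reshape(len(sims), -1)
    da = flat - flat.mean(axis=1, keepdims=True)
    db = (ref - ref.mean()).ravel()
    na = (da * da).sum(axis=1)
    nb = float((db * db).sum())
    out = np.full(len(sims), -np.inf)
    ok = na > 0
    if nb > 0:
        out[ok] = np.clip((da[ok] @ db) / np.sqrt(na[ok] * nb), -1.0, 1.0)
    return out


def fit(image: HeightImage, candidates, grid: FitGrid = FitGrid(),
        *, stage_mode: str = "surface", keep_table: int = 0,
        chunk: int = 256) -> FitResult:
    """Exhaustively fit candidate structures to a reference image.

    Scans every (candidate, psi, phi, theta, R, Theta, shift) grid point
    in lexicographic order and returns the global c.c. argmax; ties go to
    the earliest grid point.  ``keep_table`` > 0 additionally returns the
    top-scoring entries as ``(cc, state, pose, tip, shift)`` tuples.
    """
    if not len(candidates):
        raise ValueError("need at least one candidate structure")
    poses = [Pose(phi=phi, theta=theta, psi=psi)
             for psi in grid.psi_values
             for phi in grid.phi_values
             for theta in grid.theta_values]
    tips = [TipModel(R=r, Theta=th)
            for r in grid.R_values for th in grid.Theta_values]
    shifts = grid.shifts

    best = None  # (cc, lex_index)
    table = []
    any_defined = False
    for ci, cand in enumerate(candidates):
        for ti, tip in enumerate(tips):
            images = render_many(cand, poses, tip, grid=image.grid,
                                 stage_mode=stage_mode, chunk=chunk)
            for si, (dx, dy) in enumerate(shifts):
                shifted = _shift_batch(images, dx, dy)
                scores = _cc_many(shifted, image.values)
                if np.any(np.isfinite(scores)):
                    any_defined = True
                # lexicographic rank: state > pose > tip > shift
                order = np.argmax(scores)
                score = float(scores[order])
                rank = (ci, int(order), ti, si)
                if best is None or score > best[0] or \
                        (score == best[0] and rank < best[1]):
                    best = (score, rank)
                if keep_table:
                    for k in np.argsort(scores)[::-1][:keep_table]:
                        table.append((float(scores[k]), ci + 1, poses[int(k)],
                                      tip, (dx, dy)))
    if best is None or not any_defined:
        raise ValueError("fit failed: all rendered images were constant")
    score, (ci, pi, ti, si) = best
    result = FitResult(state=ci + 1, pose=poses[pi], tip=tips[ti],
                       shift=shifts[si], cc=score)
    if keep_table:
        table.sort(key=lambda row: -row[0])
        result.table = table[:keep_table]
    return result


def fit_after_denoise(image: HeightImage, net_or_ckpt, candidates,
                      grid: FitGrid = FitGrid(), **kwargs):
    """Denoise + classify first, then fit the pose of the predicted
    state's centre structure only.

    ``candidates`` must be the per-state centre structures in state order
    (1-based).  Returns ``(FitResult, Prediction)``; the FitResult's
    state index refers to the original candidate list.
    """
    from .nn.train import infer

    pred, denoised_nm = infer(net_or_ckpt, image, with_rollout=False)
    center = candidates[pred.state_hat - 1]
    result = fit(denoised_nm, [center], grid, **kwargs)
    result.state = pred.state_hat
    return result, pred
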