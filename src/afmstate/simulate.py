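"""Noise-free pseudo-AFM rendering of bead models.

The tip is a cone of half-apex angle ``Theta`` capped by a sphere of radius
``R``.  For every pixel the tip is lowered vertically until it first touches
any bead; the recorded height is the tip-apex z at that contact.  Below the
molecule the bare stage gives height 0.

Conventions (fixed so that images are bit-comparable):

* pose angles are degrees; rotations are applied sequentially about the
  fixed z-, x- and y-axes (psi, phi, theta), i.e. extrinsic z -> x -> y,
  about the geometric centroid of the bead centres;
* after rotation and lateral translation the model is shifted along z so
  that the stage reference maps to 0 — by default the lowest *sphere
  surface* ``min(center_z - radius)``, optionally the lowest centre;
* pixel (i, j) has its centre at ``origin + ((j + 0.5), (i + 0.5)) *
  pixel_size`` and row index i increases with +y.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .bead_model import BeadModel

__all__ = [
    "TipModel",
    "Pose",
    "ImageGrid",
    "HeightImage",
    "ParamRanges",
    "transform_model",
    "contact_height",
    "render",
    "render_many",
    "sample_sim_params",
    "write_image",
    "read_image",
]


@dataclass(frozen=True)
class TipModel:
    """Sphere-capped cone probe: sphere radius ``R`` (nm), cone half-apex
    angle ``Theta`` (degrees, measured from the tip axis)."""

    R: float
    Theta: float

    def __post_init__(self):
        if not self.R > 0:
            raise ValueError("probe radius R must be positive")
        if not 0 < self.Theta < 90:
            raise ValueError("cone half-apex angle must lie in (0, 90) degrees")


@dataclass(frozen=True)
class Pose:
    """Lateral offset (nm) and orientation (degrees).

    ``psi`` rotates about z, ``phi`` about x, ``theta`` about y; applied in
    that order about fixed axes.
    """

    x: float = 0.0
    y: float = 0.0
    phi: float = 0.0
    theta: float = 0.0
    psi: float = 0.0

    def __post_init__(self):
        vals = (self.x, self.y, self.phi, self.theta, self.psi)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("pose parameters must be finite")

    def perturbed(self, dx=0.0, dy=0.0, dphi=0.0, dtheta=0.0, dpsi=0.0) -> "Pose":
        return Pose(self.x + dx, self.y + dy, self.phi + dphi,
                    self.theta + dtheta, self.psi + dpsi)

    def as_tuple(self):
        return (self.x, self.y, self.phi, self.theta, self.psi)


@dataclass(frozen=True)
class ImageGrid:
    """Pixel raster: ``nx`` columns, ``ny`` rows, square pixels (nm)."""

    nx: int = 36
    ny: int = 36
    pixel_size: float = 0.8
    origin: tuple = (0.0, 0.0)

    def __post_init__(self):
        if self.nx < 1 or self.ny < 1:
            raise ValueError("pixel counts must be >= 1")
        if not self.pixel_size > 0:
            raise ValueError("pixel size must be positive")
        object.__setattr__(self, "origin", (float(self.origin[0]), float(self.origin[1])))

    @classmethod
    def centered(cls, nx: int = 36, ny: int = 36, pixel_size: float = 0.8) -> "ImageGrid":
        """Grid whose centre coincides with the lab origin (0, 0)."""
        return cls(nx, ny, pixel_size,
                   origin=(-0.5 * nx * pixel_size, -0.5 * ny * pixel_size))

    def pixel_centers(self):
        """Return (xs, ys): x-coordinates of columns, y-coordinates of rows."""
        ox, oy = self.origin
        xs = ox + (np.arange(self.nx) + 0.5) * self.pixel_size
        ys = oy + (np.arange(self.ny) + 0.5) * self.pixel_size
        return xs, ys


@dataclass
class HeightImage:
    """2D height map in nm on a fixed pixel grid."""

    values: np.ndarray
    grid: ImageGrid

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.ny, self.grid.nx):
            raise ValueError(
                f"values shape {self.values.shape} does not match grid "
                f"({self.grid.ny}, {self.grid.nx})"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("height values must be finite")

    def copy(self) -> "HeightImage":
        return HeightImage(self.values.copy(), self.grid)


def _rotation_matrix(pose: Pose) -> np.ndarray:
    # lowercase 'zxy' = extrinsic, applied in sequence z then x then y
    return Rotation.from_euler(
        "zxy", [pose.psi, pose.phi, pose.theta], degrees=True
    ).as_matrix()


def transform_model(model: BeadModel, pose: Pose, *, stage_mode: str = "surface") -> BeadModel:
    """Apply a pose to a bead model and re-reference the stage height.

    Beads are rotated about the model centroid (z-, x-, then y-axis, fixed
    axes), translated laterally by (x, y), and finally shifted along z so
    the stage reference is 0: with ``stage_mode="surface"`` (default) the
    lowest bead *surface* touches the stage; with ``"center"`` the lowest
    bead centre defines z = 0.
    """
    if stage_mode not in ("surface", "center"):
        raise ValueError("stage_mode must be 'surface' or 'center'")
    rot = _rotation_matrix(pose)
    centroid = model.centroid()
    coords = (model.centers - centroid) @ rot.T + centroid
    coords = coords + np.array([pose.x, pose.y, 0.0])
    if stage_mode == "surface":
        z_ref = np.min(coords[:, 2] - model.radii)
    else:
        z_ref = np.min(coords[:, 2])
    coords[:, 2] -= z_ref
    return BeadModel(coords, model.radii, model.kinds, model.name)


def contact_height(bead, tip: TipModel, px) -> float:
    """Tip-apex height at first steric contact with one bead, for the tip
    axis positioned at lateral point ``px = (x, y)``.

    Sphere-sphere contact applies for lateral distance
    ``d <= (R + r) cos(Theta)``; beyond that the bead touches the cone
    flank.  The cone is treated as infinitely tall, so every bead is
    reachable.
    """
    center = np.asarray(bead.center, float) if hasattr(bead, "center") else np.asarray(bead[0])
    r = bead.radius if hasattr(bead, "radius") else bead[1]
    dx, dy = center[0] - px[0], center[1] - px[1]
    d = float(np.sqrt(dx * dx + dy * dy))
    return float(
        _contact_heights(
            np.array([d]), np.array([center[2]]), np.array([r]), tip.R, tip.Theta
        )[0]
    )


def _contact_heights(d, z, r, R, Theta_deg):
    """Vectorised contact-height kernel (all arrays broadcastable)."""
    theta = np.deg2rad(Theta_deg)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    rr = R + r
    sphere = z + np.sqrt(np.maximum(rr * rr - d * d, 0.0)) - R
    cone = z + (rr - d * cos_t) / sin_t - R
    return np.where(d <= rr * cos_t, sphere, cone)


def render(model: BeadModel, pose: Pose, tip: TipModel, grid: ImageGrid,
           *, stage_mode: str = "surface", rows=None) -> HeightImage:
    """Render the noise-free height map of a posed bead model.

    Each pixel takes the maximum contact height over all beads, floored at
    0 (bare stage).  ``rows`` optionally restricts rendering to a subset of
    row indices (other rows are 0) — used by the line-scan noise model.
    """
    posed = transform_model(model, pose, stage_mode=stage_mode)
    xs, ys = grid.pixel_centers()
    if rows is None:
        row_idx = np.arange(grid.ny)
    else:
        row_idx = np.atleast_1d(np.asarray(rows, dtype=int))
    out = np.zeros((grid.ny, grid.nx))
    out[row_idx] = _render_rows(posed.centers, posed.radii, tip, xs, ys[row_idx])
    return HeightImage(out, grid)


def _render_rows(centers, radii, tip: TipModel, xs, ys):
    """Heights for the pixel block ``ys x xs``; shape (len(ys), len(xs))."""
    dx = xs[None, :, None] - centers[None, None, :, 0]
    dy = ys[:, None, None] - centers[None, None, :, 1]
    d = np.sqrt(dx * dx + dy * dy)
    h = _contact_heights(d, centers[None, None, :, 2], radii[None, None, :],
                         tip.R, tip.Theta)
    return np.maximum(h.max(axis=-1), 0.0)


def render_many(models, poses, tip: TipModel, grid: ImageGrid,
                *, stage_mode: str = "surface", chunk: int = 256,
                dtype=np.float32) -> np.ndarray:
    """Render many (model, pose) pairs at once; returns (n, ny, nx).

    ``models`` may be a single BeadModel (shared by all poses) or a
    sequence matched to ``poses``.  Used by the exhaustive rigid-body
    fit; computed in float32 by default for throughput (per-pixel error
    ~1e-6 nm, far below any physical scale here).
    """
    single = isinstance(models, BeadModel)
    n = len(poses)
    xs = grid.pixel_centers()[0].astype(dtype)
    ys = grid.pixel_centers()[1].astype(dtype)
    theta = np.deg2rad(tip.Theta)
    cos_t, sin_t = dtype(np.cos(theta)), dtype(np.sin(theta))
    out = np.empty((n, grid.ny, grid.nx), dtype=dtype)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        cen = []
        rad = []
        for k in range(start, stop):
            m = models if single else models[k]
            posed = transform_model(m, poses[k], stage_mode=stage_mode)
            cen.append(posed.centers)
            rad.append(posed.radii)
        cen = np.stack(cen).astype(dtype)    # (b, nbeads, 3)
        rad = np.stack(rad).astype(dtype)
        cx, cy, cz = cen[:, :, 0], cen[:, :, 1], cen[:, :, 2]
        rr = tip.R + rad                     # (b, nbeads)
        dxx = xs[None, None, :, None] - cx[:, None, None, :]
        dxx *= dxx                           # (b, 1, nx, nbeads)
        dyy = ys[None, :, None, None] - cy[:, None, None, :]
        dyy *= dyy                           # (b, ny, 1, nbeads)
        d2 = dxx + dyy                       # (b, ny, nx, nbeads)
        cone_mask = d2 > ((rr * cos_t) ** 2)[:, None, None, :]
        h = (rr * rr)[:, None, None, :] - d2
        np.maximum(h, 0.0, out=h)
        np.sqrt(h, out=h)                    # sphere-contact term
        np.sqrt(d2, out=d2)                  # d
        d2 *= -cos_t / sin_t
        d2 += (rr / sin_t)[:, None, None, :] # cone-contact term
        np.copyto(h, d2, where=cone_mask)
        h += (cz - dtype(tip.R))[:, None, None, :]
        block = h.max(axis=-1)
        np.maximum(block, 0.0, out=block)
        out[start:stop] = block
    return out


def _grid_values(lo, hi, step):
    n = int(round((hi - lo) / step)) + 1
    vals = lo + step * np.arange(n)
    if not len(vals):
        raise ValueError("empty parameter grid")
    return vals


@dataclass(frozen=True)
class ParamRanges:
    """Discrete sampling grids for probe and pose parameters.

    Defaults: R on {1.0..3.0} nm step 0.1; Theta on {5..30} deg step 1;
    phi, theta on {-20..20} deg step 1; psi on {-180..180} deg step 1;
    lateral offsets fixed at 0 (lateral variability is supplied by the
    +/-3 px shift augmentation instead).
    """

    R: tuple = (1.0, 3.0, 0.1)
    Theta: tuple = (5.0, 30.0, 1.0)
    phi: tuple = (-20.0, 20.0, 1.0)
    theta: tuple = (-20.0, 20.0, 1.0)
    psi: tuple = (-180.0, 180.0, 1.0)
    x: tuple = (0.0, 0.0, 1.0)
    y: tuple = (0.0, 0.0, 1.0)

    def values(self, name: str) -> np.ndarray:
        return _grid_values(*getattr(self, name))


def sample_sim_params(rng: np.random.Generator, ranges: ParamRanges = ParamRanges()):
    """Draw one (TipModel, Pose) uniformly from the discrete grids."""
    def pick(name):
        vals = ranges.values(name)
        return float(vals[rng.integers(len(vals))])

    tip = TipModel(R=round(pick("R"), 10), Theta=pick("Theta"))
    pose = Pose(x=pick("x"), y=pick("y"), phi=pick("phi"),
                theta=pick("theta"), psi=pick("psi"))
    return tip, pose


def write_image(path, img: HeightImage) -> None:
    """Write a height image as 32-bit float TIFF (nm) or headerless CSV,
    chosen by file extension."""
    path = str(path)
    if path.endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(path, img.values.astype(np.float32))
    elif path.endswith(".csv"):
        np.savetxt(path, img.values, delimiter=",")
    else:
        raise ValueError(f"unsupported image format: {path}")


def read_image(path, grid: ImageGrid | None = None) -> HeightImage:
    """Read a TIFF or CSV height map (nm).  If ``grid`` is omitted, a
    centred grid with the default 0.8 nm pixel is assumed."""
    path = str(path)
    if path.endswith((".tif", ".tiff")):
        import tifffile

        values = np.asarray(tifffile.imread(path), dtype=float)
    elif path.endswith(".csv"):
        values = np.atleast_2d(np.loadtxt(path, delimiter=","))
    else:
        raise ValueError(f"unsupported image format: {path}")
    if grid is None:
        ny, nx = values.shape
        grid = ImageGrid.centered(nx=nx, ny=ny)
    return HeightImage(values, grid)
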