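"""Synthetic hinge-motion ensembles with planted ordered states.

The toy molecule is two rigid rods of overlapping beads joined at a
pivot, opening in the stage (xy) plane.  State k of K sets the hinge
angle to the k-th value evenly spaced across ``angle_range``, emulating a
closed -> wide-open domain transition that is resolvable at 0.8 nm/pixel;
within-state thermal motion is i.i.d. Gaussian jitter on every bead.
There is no force field and no claim of biological realism — the fixture
exists so every downstream stage (clustering, dataset building, training,
fitting) is testable end to end from code alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bead_model import BeadModel, Ensemble

__all__ = ["HingeSpec", "make_hinge_ensemble", "linear_morph", "make_reference_scene"]


@dataclass(frozen=True)
class HingeSpec:
    """Hinge-fixture parameters.

    Defaults: K = 4 states spanning 40-120 degrees, 12 beads per 6 nm arm
    of radius 0.8 nm, 0.15 nm jitter, 250 frames per state — sized so a
    36 x 36 image at 0.8 nm/pixel resolves the motion and desk-scale
    training converges in minutes.
    """

    n_beads_per_domain: int = 12
    bead_radius: float = 0.8
    arm_length: float = 6.0
    angle_range: tuple = (40.0, 120.0)
    K: int = 4
    jitter_sigma: float = 0.15
    frames_per_state: int = 250
    seed: int = 0

    def __post_init__(self):
        if self.K < 2:
            raise ValueError("need at least 2 planted states")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be non-negative")
        if self.arm_length <= 0:
            raise ValueError("arm_length must be positive")


def planted_angles(spec: HingeSpec) -> np.ndarray:
    """Hinge angle of each state: K values evenly spaced over angle_range
    (endpoints included)."""
    lo, hi = spec.angle_range
    return lo + (hi - lo) * np.arange(spec.K) / (spec.K - 1)


def _hinge_conformer(spec: HingeSpec, angle_deg: float) -> BeadModel:
    n = spec.n_beads_per_domain
    t = (np.arange(n) + 1) / n * spec.arm_length
    # arms open symmetrically about +x in the xy-plane; beads rest at z = r
    half = np.deg2rad(angle_deg) / 2.0
    arm_a = np.stack([t * np.cos(half), t * np.sin(half), np.full(n, spec.bead_radius)], axis=1)
    arm_b = np.stack([t * np.cos(half), -t * np.sin(half), np.full(n, spec.bead_radius)], axis=1)
    pivot = np.array([[0.0, 0.0, spec.bead_radius]])
    centers = np.concatenate([pivot, arm_a, arm_b])
    radii = np.full(len(centers), spec.bead_radius)
    kinds = ["ALA"] * len(centers)
    return BeadModel(centers, radii, kinds, name=f"hinge{angle_deg:.1f}")


def make_hinge_ensemble(spec: HingeSpec = HingeSpec()):
    """Build the hinge ensemble; returns ``(Ensemble, planted_labels)``.

    Frames are grouped by state (state k occupies the k-th block of
    ``frames_per_state`` frames) and labels are 1-based, ordered with the
    hinge angle.
    """
    rng = np.random.default_rng(spec.seed)
    conformers = []
    labels = []
    for k, angle in enumerate(planted_angles(spec), start=1):
        base = _hinge_conformer(spec, float(angle))
        for _ in range(spec.frames_per_state):
            jitter = rng.normal(0.0, spec.jitter_sigma, size=base.centers.shape) \
                if spec.jitter_sigma > 0 else 0.0
            conformers.append(BeadModel(base.centers + jitter, base.radii,
                                        base.kinds, base.name))
            labels.append(k)
    return Ensemble(conformers), np.asarray(labels)


def linear_morph(a: BeadModel, b: BeadModel, n_snapshots: int):
    """Cartesian linear interpolation from ``a`` to ``b``.

    Returns ``n_snapshots`` bead models; the endpoints are preserved
    exactly.  Stands in for a geometric morphing trajectory between two
    endpoint structures.
    """
    if len(a) != len(b) or a.kinds != b.kinds:
        raise ValueError("endpoint models must share bead count and kinds")
    if n_snapshots < 2:
        raise ValueError("need at least 2 snapshots")
    out = []
    for i in range(n_snapshots):
        f = i / (n_snapshots - 1)
        centers = a.centers if i == 0 else (b.centers if i == n_snapshots - 1
                                            else (1 - f) * a.centers + f * b.centers)
        out.append(BeadModel(centers, a.radii, a.kinds, name=f"morph{i}"))
    return out


def make_reference_scene(spec: HingeSpec = HingeSpec(), *, disc_radius: float = 8.0,
                         n_disc_beads: int = 40, disc_bead_radius: float = 0.235,
                         mount_height: float = 1.0):
    """A nanodisc-like scene: a flat ring of PO4-kind beads parallel to the
    stage with the hinge molecule mounted above it.

    Returns ``(disc, protein)``.  The disc plane makes the tilt limits
    (|phi|, |theta| <= 20 deg) physically meaningful: larger tilts would
    lift the disc rim off the stage.
    """
    phi = 2 * np.pi * np.arange(n_disc_beads) / n_disc_beads
    disc_centers = np.stack([
        disc_radius * np.cos(phi),
        disc_radius * np.sin(phi),
        np.full(n_disc_beads, disc_bead_radius),
    ], axis=1)
    disc = BeadModel(disc_centers, np.full(n_disc_beads, disc_bead_radius),
                     ["PO4"] * n_disc_beads, name="disc")
    mid_angle = float(np.mean(planted_angles(spec)))
    protein = _hinge_conformer(spec, mid_angle)
    protein = protein.translated([0.0, 0.0, 2 * disc_bead_radius + mount_height])
    return disc, protein


def combine(*models: BeadModel, name: str = "scene") -> BeadModel:
    """Merge several bead models into one rigid scene."""
    centers = np.concatenate([m.centers for m in models])
    radii = np.concatenate([m.radii for m in models])
    kinds = [k for m in models for k in m.kinds]
    return BeadModel(centers, radii, kinds, name=name)
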