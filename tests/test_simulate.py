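import numpy as np
import pytest

from afmstate.bead_model import BeadModel
from afmstate.simulate import (ImageGrid, ParamRanges, Pose, TipModel,
                               contact_height, read_image, render, render_many,
                               sample_sim_params, transform_model, write_image)


def brute_force_contact(zb, r, d, R, theta_deg, z_hi=100.0, iters=60):
    """Independent oracle: binary-search the lowest tip-apex height at which
    a finely discretised sphere-capped-cone surface still clears the bead.

    The tip surface profile (apex at height z) is sampled densely in the
    radial coordinate; contact occurs when any surface point comes within r
    of the bead centre.
    """
    theta = np.deg2rad(theta_deg)
    n_cap, n_flank = 8001, 100001
    rho = np.concatenate([
        np.linspace(0.0, R * np.cos(theta), n_cap),
        R * np.cos(theta) + np.linspace(0.0, 50.0, n_flank)[1:],
    ])
    # surface height above the apex
    cap = R - np.sqrt(np.maximum(R * R - rho[:n_cap] ** 2, 0.0))
    z_t = R - R * np.sin(theta)
    flank = z_t + (rho[n_cap:] - R * np.cos(theta)) / np.tan(theta)
    surf = np.concatenate([cap, flank])

    def overlaps(z):
        if zb >= z + np.interp(d, rho, surf):  # centre inside the tip solid
            return True
        dist2 = (rho - d) ** 2 + (z + surf - zb) ** 2
        return dist2.min() <= r * r

    lo, hi = 0.0, z_hi
    while not overlaps(lo):
        lo -= 5.0
        assert lo > -1e4
    assert not overlaps(hi)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if overlaps(mid):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class FakeBead:
    def __init__(self, center, radius):
        self.center = np.asarray(center, float)
        self.radius = radius


class TestContactHeight:
    def test_apex_contact_on_axis(self):
        """d = 0 forces z = z_bead + r: sphere-sphere contact on the axis."""
        b = FakeBead([0, 0, 2.0], 1.0)
        assert contact_height(b, TipModel(1.0, 10.0), (0, 0)) == pytest.approx(3.0)

    def test_branch_continuity(self):
        """Sphere and cone formulas agree at d = (R+r)cos(Theta)."""
        R, r, theta = 1.7, 0.6, 25.0
        rr = R + r
        d = rr * np.cos(np.deg2rad(theta))
        b = FakeBead([d, 0, 1.3], r)
        z_sphere = 1.3 + np.sqrt(rr ** 2 - d ** 2) - R
        z_cone = 1.3 + (rr - d * np.cos(np.deg2rad(theta))) / np.sin(np.deg2rad(theta)) - R
        assert z_sphere == pytest.approx(z_cone, abs=1e-12)
        assert contact_height(b, TipModel(R, theta), (0, 0)) == pytest.approx(z_sphere, abs=1e-12)

    def test_matches_discretised_lowering_oracle(self, rng):
        """100 random (bead, tip, pixel) triples against the brute-force
        tip-lowering oracle, within 1e-3 nm."""
        for _ in range(100):
            zb = rng.uniform(0.5, 5.0)
            r = rng.uniform(0.2, 1.5)
            R = rng.uniform(1.0, 3.0)
            theta = rng.uniform(5.0, 30.0)
            d = rng.uniform(0.0, 8.0)
            b = FakeBead([d, 0, zb], r)
            analytic = contact_height(b, TipModel(R, theta), (0, 0))
            oracle = brute_force_contact(zb, r, d, R, theta)
            assert analytic == pytest.approx(oracle, abs=1e-3)


def _manual_rotation(psi, phi, theta):
    """Independent composition: sequential extrinsic z, x, y rotations."""
    cz, sz = np.cos(np.deg2rad(psi)), np.sin(np.deg2rad(psi))
    cx, sx = np.cos(np.deg2rad(phi)), np.sin(np.deg2rad(phi))
    cy, sy = np.cos(np.deg2rad(theta)), np.sin(np.deg2rad(theta))
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-cy * 0 - sy, 0, cy]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    return ry @ rx @ rz


class TestTransformModel:
    def test_identity_pose_only_stage_shift(self):
        m = BeadModel([[0, 0, 3.0], [1, 2, 5.0]], [0.5, 0.5], ["ALA"] * 2)
        out = transform_model(m, Pose())
        # lowest sphere surface rests on the stage
        assert np.min(out.centers[:, 2] - out.radii) == pytest.approx(0.0)
        np.testing.assert_allclose(out.centers[:, :2], m.centers[:, :2])

    def test_psi_90_rotates_x_to_y(self):
        """A bead at +x relative to the centroid moves to +y under psi=90."""
        m = BeadModel([[1, 0, 1], [-1, 0, 1]], [0.5, 0.5], ["ALA"] * 2)
        out = transform_model(m, Pose(psi=90.0))
        rel = out.centers - out.centers.mean(axis=0)
        np.testing.assert_allclose(rel[0], [0, 1, 0], atol=1e-12)

    def test_matches_independent_matrix_composition(self, rng):
        """Random poses against hand-built Ry Rx Rz about the centroid."""
        m = BeadModel(rng.normal(size=(7, 3)), np.full(7, 0.4), ["ALA"] * 7)
        for _ in range(20):
            pose = Pose(x=rng.uniform(-3, 3), y=rng.uniform(-3, 3),
                        phi=rng.uniform(-180, 180), theta=rng.uniform(-180, 180),
                        psi=rng.uniform(-180, 180))
            rot = _manual_rotation(pose.psi, pose.phi, pose.theta)
            cen = m.centroid()
            expect = (m.centers - cen) @ rot.T + cen + [pose.x, pose.y, 0.0]
            expect[:, 2] -= np.min(expect[:, 2] - m.radii)
            out = transform_model(m, pose)
            np.testing.assert_allclose(out.centers, expect, atol=1e-9)

    def test_center_stage_mode(self):
        m = BeadModel([[0, 0, 3.0]], [0.5], ["ALA"])
        out = transform_model(m, Pose(), stage_mode="center")
        assert out.centers[0, 2] == pytest.approx(0.0)


class TestRender:
    def test_sphere_on_stage_apex_height(self):
        """A sphere of radius r resting on the stage images 2r at its apex."""
        grid = ImageGrid(nx=9, ny=9, pixel_size=0.8, origin=(-3.6, -3.6))
        m = BeadModel([[0, 0, 1.0]], [1.0], ["ALA"])
        # place the bead exactly on a pixel centre
        m2 = BeadModel([[grid.pixel_centers()[0][4], grid.pixel_centers()[1][4], 1.0]],
                       [1.0], ["ALA"])
        img = render(m2, Pose(), TipModel(1.0, 10.0), grid)
        assert img.values.max() == pytest.approx(2.0)

    def test_far_pixel_is_stage(self):
        grid = ImageGrid.centered()
        m = BeadModel([[0, 0, 1.0]], [1.0], ["ALA"])
        img = render(m, Pose(), TipModel(1.0, 10.0), grid)
        assert img.values[0, 0] == 0.0

    def test_equals_per_pixel_contact_loop(self, rng):
        """Full render equals an explicit double loop over pixels/beads."""
        grid = ImageGrid(nx=12, ny=10, pixel_size=0.8, origin=(-4.8, -4.0))
        m = BeadModel(rng.normal(size=(6, 3)) * 2 + [0, 0, 3],
                      rng.uniform(0.3, 1.0, 6), ["ALA"] * 6)
        tip = TipModel(1.5, 15.0)
        img = render(m, Pose(), tip, grid)
        posed = transform_model(m, Pose())
        xs, ys = grid.pixel_centers()
        for i in range(grid.ny):
            for j in range(grid.nx):
                h = max(
                    contact_height(FakeBead(c, r), tip, (xs[j], ys[i]))
                    for c, r in zip(posed.centers, posed.radii)
                )
                assert img.values[i, j] == pytest.approx(max(h, 0.0), abs=1e-12)

    def test_dilation_monotonicity(self, rng):
        """Increasing R or Theta never decreases any pixel."""
        grid = ImageGrid.centered(nx=18, ny=18)
        m = BeadModel(rng.normal(size=(8, 3)) * 2 + [0, 0, 2],
                      rng.uniform(0.3, 1.0, 8), ["ALA"] * 8)
        base = render(m, Pose(), TipModel(1.0, 10.0), grid).values
        blunter = render(m, Pose(), TipModel(2.0, 10.0), grid).values
        wider = render(m, Pose(), TipModel(1.0, 25.0), grid).values
        assert np.all(blunter >= base - 1e-12)
        assert np.all(wider >= base - 1e-12)

    def test_whole_pixel_translation_shifts_image(self):
        grid = ImageGrid.centered()
        m = BeadModel([[0, 0, 1.0], [1.6, 0, 1.0]], [1.0, 1.0], ["ALA"] * 2)
        a = render(m, Pose(), TipModel(1.0, 10.0), grid).values
        b = render(m, Pose(x=2 * grid.pixel_size), TipModel(1.0, 10.0), grid).values
        np.testing.assert_allclose(b[:, 2:], a[:, :-2], atol=1e-9)

    def test_render_many_matches_single(self, rng):
        m = BeadModel(rng.normal(size=(5, 3)) + [0, 0, 2],
                      rng.uniform(0.3, 0.8, 5), ["ALA"] * 5)
        grid = ImageGrid.centered(nx=20, ny=20)
        poses = [Pose(psi=a, phi=b) for a, b in rng.uniform(-20, 20, (5, 2))]
        many = render_many(m, poses, TipModel(1.2, 12.0), grid)
        for img, pose in zip(many, poses):
            single = render(m, pose, TipModel(1.2, 12.0), grid).values
            np.testing.assert_allclose(img, single, atol=1e-5)


class TestSampleSimParams:
    def test_draws_lie_on_grids(self, rng):
        ranges = ParamRanges()
        r_grid = ranges.values("R")
        for _ in range(2000):
            tip, pose = sample_sim_params(rng, ranges)
            assert np.isclose(r_grid, tip.R).any()
            assert 1.0 <= tip.R <= 3.0
            assert 5.0 <= tip.Theta <= 30.0
            assert -20.0 <= pose.phi <= 20.0
            assert abs(pose.phi - round(pose.phi)) < 1e-9

    def test_phi_range_is_covered(self):
        rng = np.random.default_rng(1)
        phis = [sample_sim_params(rng)[1].phi for _ in range(20000)]
        assert min(phis) == -20.0 and max(phis) == 20.0

    def test_deterministic_under_seed(self):
        a = [sample_sim_params(np.random.default_rng(5)) for _ in range(1)]
        b = [sample_sim_params(np.random.default_rng(5)) for _ in range(1)]
        assert a == b


class TestImageIO:
    @pytest.mark.parametrize("ext", ["tiff", "csv"])
    def test_round_trip(self, tmp_path, rng, ext):
        grid = ImageGrid.centered(nx=8, ny=8)
        from afmstate.simulate import HeightImage

        img = HeightImage(rng.random((8, 8)).astype(np.float32).astype(float), grid)
        path = tmp_path / f"img.{ext}"
        write_image(path, img)
        back = read_image(path, grid)
        np.testing.assert_allclose(back.values, img.values, atol=1e-7)
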