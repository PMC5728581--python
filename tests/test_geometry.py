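"""DNA axis extraction, sliding/rotation coordinates, RMSD, per-SHL series."""

import numpy as np
import pytest

from conftest import random_rigid_motion, straight_bdna
from nucleoslide import geometry, synthetic
from nucleoslide.errors import GeometryError, WindowError
from nucleoslide.geometry import (ZetaTable, analyze_sliding, build_zeta_table,
                                  compute_frame_axes, dna_axis, fit_circle_3d,
                                  loop_delta_r, rmsd_central, rotation_eta,
                                  shl_sliding, sliding_zeta, symmetry_axis,
                                  unwrap_degrees, zeta_to_bp)
from nucleoslide.structures import Bead, CGStructure, Trajectory


class TestCircleFit:
    def test_exact_on_noiseless_circle(self):
        t = np.linspace(0, 2 * np.pi, 17, endpoint=False)
        pts = np.column_stack([1 + 10 * np.cos(t), 2 + 10 * np.sin(t),
                               np.zeros_like(t)])
        center, radius, _ = fit_circle_3d(pts)
        np.testing.assert_allclose(center, (1, 2, 0), atol=1e-9)
        assert radius == pytest.approx(10.0, abs=1e-9)

    def test_exact_on_tilted_circle(self):
        rng = np.random.default_rng(1)
        rot, trans = random_rigid_motion(rng)
        t = np.linspace(0, 2 * np.pi, 10, endpoint=False)
        pts = np.column_stack([4 * np.cos(t), 4 * np.sin(t), np.zeros_like(t)])
        center, radius, _ = fit_circle_3d(pts @ rot.T + trans)
        np.testing.assert_allclose(center, trans, atol=1e-9)
        assert radius == pytest.approx(4.0, abs=1e-9)

    def test_too_few_points(self):
        with pytest.raises(GeometryError):
            fit_circle_3d(np.zeros((2, 3)))


class TestDnaAxis:
    def test_straight_bdna_axis_on_true_axis(self):
        s = straight_bdna(n_bp=60)
        axis = dna_axis(s)
        lo, hi = axis.window
        for b in range(lo, hi + 1):
            pt = axis.point(b)
            # true helical axis is the z line x=y=0
            assert np.hypot(pt[0], pt[1]) < 0.5
            np.testing.assert_allclose(axis.tangent(b), (0, 0, 1), atol=0.02)

    def test_radius_estimate_matches_phosphate_distance(self):
        s = straight_bdna(n_bp=60)
        axis = dna_axis(s)
        lo, hi = axis.window
        dists = []
        for b in range(lo, hi + 1):
            p = s.positions[s.strand1[b]["P"]]
            dists.append(np.linalg.norm(p - axis.point(b)))
        assert abs(np.mean(dists) - 9.4) / 9.4 < 0.05

    def test_rigid_rotation_equivariance(self):
        s = straight_bdna(n_bp=50)
        axis = dna_axis(s)
        rng = np.random.default_rng(2)
        rot, trans = random_rigid_motion(rng)
        axis_r = dna_axis(s, s.positions @ rot.T + trans)
        lo, hi = axis.window
        for b in range(lo, hi + 1):
            np.testing.assert_allclose(axis_r.point(b),
                                       axis.point(b) @ rot.T + trans,
                                       atol=1e-6)

    def test_too_short_dna_rejected(self):
        s = straight_bdna(n_bp=25)
        with pytest.raises(WindowError):
            dna_axis(s)

    def test_window_guard(self):
        s = straight_bdna(n_bp=60)
        axis = dna_axis(s)
        with pytest.raises(WindowError):
            axis.point(0)


class TestSymmetryAxis:
    def test_exact_line_recovered(self):
        beads = []
        for cid, off in (("U", (0, 4, 0)), ("V", (0, -4, 0))):
            for r in range(1, 6):
                beads.append(Bead(cid, r, "CA",
                                  np.array([2.0 * r, 0, 0]) + off))
        s = CGStructure(beads)
        ax = symmetry_axis(s)
        np.testing.assert_allclose(np.abs(ax.direction), (1, 0, 0), atol=1e-12)
        assert abs(ax.point[1]) < 1e-12 and abs(ax.point[2]) < 1e-12

    def test_ideal_fixture_axis_matches_construction(self, ideal):
        ax = symmetry_axis(ideal)
        # construction places the dyad axis along x
        assert np.degrees(np.arccos(abs(ax.direction @ np.array([1.0, 0, 0])))) \
            < 0.1

    def test_noise_robustness(self, ideal):
        rng = np.random.default_rng(0)
        angles = []
        for _ in range(10):
            pos = ideal.positions + rng.normal(0, 0.1, ideal.positions.shape)
            ax = symmetry_axis(ideal, pos)
            cosang = abs(ax.direction @ np.array([1.0, 0, 0]))
            angles.append(np.degrees(np.arccos(min(cosang, 1.0))))
        assert np.max(angles) < 1.0

    def test_coincident_midpoints_rejected(self):
        beads = [Bead("U", r, "CA", (1.0 * r, 1, 0)) for r in (1, 2)] + \
                [Bead("V", r, "CA", (3.0 - r, -1, 0)) for r in (1, 2)]
        s = CGStructure(beads)  # midpoints both at (1.5, 0, 0)
        with pytest.raises(GeometryError):
            symmetry_axis(s)


class TestSlidingZeta:
    def test_zero_at_dyad(self, ideal):
        assert sliding_zeta(ideal, ideal.meta["dyad_bp"]) == \
            pytest.approx(0.0, abs=1e-9)

    def test_screw_advance_gives_positive_closed_form(self, ideal):
        spec = ideal.meta["superhelix"]
        s5 = synthetic.advance_screw(ideal, 5)
        axes = compute_frame_axes(ideal, s5.positions)
        z = sliding_zeta(ideal, ideal.meta["dyad_bp"], s5.positions, axes)
        expected = 5 * 360.0 / spec.bp_per_superhelix_turn
        assert z > 0
        assert z == pytest.approx(expected, rel=0.01)

    def test_mirror_image_negates_with_transported_normal(self, ideal):
        # Reflecting the frame while carrying the reference normal along
        # as a true vector flips the sense of rotation, so zeta negates.
        # (Re-deriving the normal from the mirrored geometry would flip
        # it too and leave zeta invariant: the index direction is
        # mirror-covariant.)
        m = np.diag([1.0, -1.0, 1.0])
        s2 = synthetic.advance_screw(ideal, 2)
        axes = compute_frame_axes(ideal, s2.positions)
        z = sliding_zeta(ideal, ideal.meta["dyad_bp"], s2.positions, axes)
        mirrored = s2.positions @ m
        axes_m = compute_frame_axes(ideal, mirrored)
        axes_m.normal = m @ axes.normal      # transported, not re-derived
        axes_m.symmetry.direction = m @ axes.symmetry.direction
        zm = sliding_zeta(ideal, ideal.meta["dyad_bp"], mirrored, axes_m)
        assert zm == pytest.approx(-z, rel=1e-6)
        # with the normal re-derived from the mirrored geometry the
        # magnitude is preserved
        zr = sliding_zeta(ideal, ideal.meta["dyad_bp"], mirrored,
                          compute_frame_axes(ideal, mirrored))
        assert abs(zr) == pytest.approx(abs(z), rel=1e-6)

    def test_rigid_motion_invariance(self, ideal):
        s3 = synthetic.advance_screw(ideal, 3)
        z0 = sliding_zeta(ideal, ideal.meta["dyad_bp"], s3.positions,
                          compute_frame_axes(ideal, s3.positions))
        rng = np.random.default_rng(4)
        rot, trans = random_rigid_motion(rng)
        moved = s3.positions @ rot.T + trans
        z1 = sliding_zeta(ideal, ideal.meta["dyad_bp"], moved,
                          compute_frame_axes(ideal, moved))
        assert abs(z1 - z0) < 1e-6


class TestZetaTable:
    def test_monotone_and_exact_inverse(self, ideal):
        t = build_zeta_table(ideal, center_bp=ideal.meta["dyad_bp"])
        assert np.all(np.diff(t.zetas) > 0)
        for bp, z in zip(t.bps, t.zetas):
            assert zeta_to_bp(z, t) == pytest.approx(bp, abs=1e-9)

    def test_midpoint_interpolation(self):
        t = ZetaTable(bps=np.arange(10.0), zetas=np.arange(10.0) * 4.0)
        assert zeta_to_bp(22.0, t) == pytest.approx(5.5)

    def test_extrapolation_warns(self):
        t = ZetaTable(bps=np.arange(5.0), zetas=np.arange(5.0) * 4.0)
        with pytest.warns(UserWarning, match="extrapolat"):
            assert zeta_to_bp(-4.0, t) == pytest.approx(-1.0)
        with pytest.warns(UserWarning):
            assert zeta_to_bp(20.0, t) == pytest.approx(5.0)

    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError):
            ZetaTable(bps=np.arange(3.0), zetas=np.array([0.0, 2.0, 1.0]))


class TestRotationEta:
    def test_screw_full_turn_is_360(self, ideal):
        d = ideal.meta["dyad_bp"]
        etas = []
        for n in (0, 10):
            sn = synthetic.advance_screw(ideal, n)
            axes = compute_frame_axes(ideal, sn.positions)
            ax = dna_axis(ideal, sn.positions)
            etas.append(rotation_eta(ideal, d, sn.positions, ax,
                                     axes.centroid, wrap_normal=axes.normal))
        # one full helical twist: same angle modulo 360
        assert abs((etas[1] - etas[0] + 180) % 360 - 180) < 1.0

    def test_jump_advance_keeps_eta_constant(self, ideal):
        d = ideal.meta["dyad_bp"]
        etas = []
        for n in (-10, -5, 0, 5, 10):
            j = synthetic.advance_jump(ideal, n)
            axes = compute_frame_axes(ideal, j.positions)
            ax = dna_axis(ideal, j.positions)
            etas.append(rotation_eta(ideal, d, j.positions, ax,
                                     axes.centroid, wrap_normal=axes.normal))
        etas = unwrap_degrees(etas)
        assert etas.max() - etas.min() < 1.0

    def test_screw_slope_36_deg_per_bp(self, ideal):
        d = ideal.meta["dyad_bp"]
        table = build_zeta_table(ideal, center_bp=d)
        etas, bps = [], []
        for n in range(-10, 11):
            sn = synthetic.advance_screw(ideal, n)
            axes = compute_frame_axes(ideal, sn.positions)
            ax = dna_axis(ideal, sn.positions)
            etas.append(rotation_eta(ideal, d, sn.positions, ax,
                                     axes.centroid, wrap_normal=axes.normal))
            bps.append(zeta_to_bp(
                sliding_zeta(ideal, d, sn.positions, axes), table) - d)
        slope = np.polyfit(bps, unwrap_degrees(etas), 1)[0]
        assert slope == pytest.approx(36.0, abs=0.5)

    def test_outside_axis_window_rejected(self, ideal):
        ax = dna_axis(ideal)
        with pytest.raises(WindowError):
            rotation_eta(ideal, 2, axis=ax)


class TestRmsd:
    def test_identity_is_zero(self, ideal):
        assert rmsd_central(ideal, ideal.positions) == pytest.approx(0.0,
                                                                     abs=1e-9)

    def test_rigid_motion_removed_by_superposition(self, ideal):
        rng = np.random.default_rng(8)
        rot, trans = random_rigid_motion(rng)
        moved = ideal.positions @ rot.T + trans
        assert rmsd_central(ideal, ideal.positions, moved) < 1e-6

    def test_single_displaced_bead_follows_rule(self):
        rng = np.random.default_rng(12)
        beads = [Bead("X", i + 1, "CA", rng.uniform(0, 30, 3))
                 for i in range(10)]
        s = CGStructure(beads)
        pos = s.positions.copy()
        fit = list(range(10))
        measure = list(range(4))
        pos2 = pos.copy()
        # displace a measured bead NOT in the fit set
        measure_only = 3
        fit = [i for i in range(10) if i != measure_only]
        pos2[measure_only] += (0, 0, 2.0)
        r = rmsd_central(s, pos, pos2, fit_indices=fit,
                         measure_indices=measure)
        assert r == pytest.approx(2.0 / np.sqrt(len(measure)), rel=1e-9)

    def test_cross_check_against_mdanalysis(self, ideal):
        import MDAnalysis.analysis.rms as mda_rms
        rng = np.random.default_rng(21)
        fit = sorted(ideal.histone_core)
        noisy = ideal.positions + rng.normal(0, 0.8, ideal.positions.shape)
        ours = rmsd_central(ideal, ideal.positions, noisy,
                            fit_indices=fit, measure_indices=fit)
        theirs = mda_rms.rmsd(noisy[fit], ideal.positions[fit],
                              center=True, superposition=True)
        assert ours == pytest.approx(theirs, rel=1e-6)

    def test_too_few_fit_beads(self, ideal):
        with pytest.raises(GeometryError):
            rmsd_central(ideal, ideal.positions, fit_indices=[0, 1])


class TestTrajectoryAnalyses:
    def test_analyze_sliding_tracks_schedule(self, ideal):
        sched = [0, 1, 2, 3, 2, 1, 0, -1, -2]
        traj = synthetic.make_trajectory(
            ideal, synthetic.TrajectorySpec(mode="screw", n_frames=len(sched),
                                            schedule=sched))
        df = analyze_sliding(traj)
        np.testing.assert_allclose(df["bp_shift"], sched, atol=0.05)

    def test_screw_shl_series_move_together(self, ideal):
        traj = synthetic.make_trajectory(
            ideal, synthetic.TrajectorySpec(mode="screw", n_frames=5,
                                            schedule=[0, 2, 4, 6, 8]))
        df = shl_sliding(traj, [0, 2, 4], bp_per_turn=10.0)
        for shl in (0, 2, 4):
            np.testing.assert_allclose(df[f"shl_{shl}"], [0, 2, 4, 6, 8],
                                       atol=0.3)

    def test_jump_steps_all_shls_simultaneously(self, ideal):
        frames = [ideal.positions, synthetic.advance_jump(ideal, 5).positions]
        traj = Trajectory(topology=ideal, coords=np.stack(frames))
        df = shl_sliding(traj, [0, 2, 4], bp_per_turn=10.0)
        for shl in (0, 2, 4):
            assert df[f"shl_{shl}"].iloc[1] == pytest.approx(5.0, abs=0.3)

    def test_loop_trajectory_steps_sequentially(self, ideal):
        traj = synthetic.make_trajectory(
            ideal, synthetic.TrajectorySpec(mode="loop", n_frames=40))
        df = shl_sliding(traj, [0, 2, 4], bp_per_turn=10.0)

        def crossing(col):
            arr = df[col].to_numpy()
            return np.argmax(arr > 5.0)
        # the defect enters at the high-index end: SHL 4 shifts first
        assert crossing("shl_4") < crossing("shl_2") < crossing("shl_0")
        # and every SHL ends fully shifted by the loop size
        for shl in (0, 2, 4):
            assert df[f"shl_{shl}"].iloc[-1] == pytest.approx(10.0, abs=0.5)


class TestLoopDeltaR:
    def test_identity_zero(self, ideal):
        assert loop_delta_r(ideal, ideal.positions) == pytest.approx(0.0)

    def test_radial_displacement_reflected(self, ideal):
        d = ideal.meta["dyad_bp"]
        pos = ideal.positions.copy()
        c = ideal.core_centroid()
        idx = list(ideal.strand1[d].values()) + list(ideal.strand2[d].values())
        center = pos[idx].mean(axis=0)
        u = (center - c) / np.linalg.norm(center - c)
        pos[idx] += 3.0 * u
        assert loop_delta_r(ideal, ideal.positions, pos, d) == \
            pytest.approx(3.0, abs=1e-6)

    def test_bulge_localized_at_propagating_shl(self, ideal):
        spec = ideal.meta["superhelix"]
        d = ideal.meta["dyad_bp"]
        traj = synthetic.make_trajectory(
            ideal, synthetic.TrajectorySpec(mode="loop", n_frames=41))
        truth = traj.meta["truth"]
        shl4_bp = d + 40
        # pick the frame whose boundary is at SHL 4
        i = int((truth["loop_boundary_bp"] - shl4_bp).abs().idxmin())
        dr4 = loop_delta_r(ideal, traj.coords[0], traj.coords[i], shl4_bp)
        dr0 = loop_delta_r(ideal, traj.coords[0], traj.coords[i], d)
        assert dr4 > 1.0
        assert abs(dr0) < 0.5
        assert spec.linker_bp > 0  # bulge needs linker reserve to slide into
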