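"""Outline extraction, resampling, Procrustes and EFA."""

import numpy as np
import pytest

from complexspace import (
    Outline,
    choose_harmonics,
    efa_coefficients,
    efa_reconstruct,
    extract_outline,
    flatten_to_morphospace,
    harmonic_power,
    procrustes_align,
    resample_outline,
    synthetic_colony,
)


def circle_outline(n=200, r=1.0, center=(0.0, 0.0)):
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return Outline(
        np.column_stack(
            [center[0] + r * np.cos(theta), center[1] + r * np.sin(theta)]
        )
    )


class TestOutlineType:
    def test_enforces_ccw(self):
        sq = np.array([[0, 0], [0, 1], [1, 1], [1, 0]], float)  # clockwise
        o = Outline(sq)
        x, y = o.points[:, 0], o.points[:, 1]
        signed = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        assert signed > 0

    def test_rejects_degenerate(self):
        with pytest.raises(ValueError):
            Outline(np.array([[0, 0], [1, 1]], float))
        with pytest.raises(ValueError):
            Outline(np.array([[0, 0], [1, 0], [2, 0]], float))  # zero area
        with pytest.raises(ValueError):
            Outline(np.array([[0, 0], [0, 0], [1, 0], [0, 1]], float))


class TestExtractOutline:
    def test_rectangle_mask_geometry(self):
        mask = np.zeros((40, 60), bool)
        mask[10:30, 15:45] = True  # 20 x 30 rectangle
        o = extract_outline(mask)
        from scipy.spatial import ConvexHull

        hull = ConvexHull(o.points)
        assert hull.volume == pytest.approx(20 * 30, rel=0.12)
        # within one pixel band of the exact area
        assert abs(hull.volume - 600) <= (2 * (20 + 30) + 4)

    def test_disc_vertices_near_radius(self):
        rr, cc = np.mgrid[0:64, 0:64]
        mask = (rr - 32) ** 2 + (cc - 30) ** 2 <= 20**2
        o = extract_outline(mask)
        d = np.linalg.norm(o.points - o.points.mean(axis=0), axis=1)
        assert np.all(np.abs(d - 20) <= 1.0)

    def test_annulus_hole_ignored(self):
        rr, cc = np.mgrid[0:64, 0:64]
        r2 = (rr - 32) ** 2 + (cc - 32) ** 2
        annulus = (r2 <= 25**2) & (r2 >= 10**2)
        o = extract_outline(annulus)
        d = np.linalg.norm(o.points - o.points.mean(axis=0), axis=1)
        assert d.min() > 20  # no vertex on the inner boundary

    def test_largest_component_wins(self):
        mask = np.zeros((40, 40), bool)
        mask[2:6, 2:6] = True  # 16 px
        mask[10:30, 10:30] = True  # 400 px
        o = extract_outline(mask)
        assert o.points[:, 0].max() > 9

    def test_empty_and_ambiguous_masks_rejected(self):
        with pytest.raises(ValueError, match="no foreground"):
            extract_outline(np.zeros((10, 10), bool))
        tie = np.zeros((20, 20), bool)
        tie[2:6, 2:6] = True
        tie[10:14, 10:14] = True
        with pytest.raises(ValueError, match="ambiguous"):
            extract_outline(tie)

    def test_tiny_component_rejected(self):
        mask = np.zeros((10, 10), bool)
        mask[4:6, 4:6] = True
        with pytest.raises(ValueError, match="< 9"):
            extract_outline(mask)


class TestResample:
    def test_unit_square_to_eight_equal_gaps(self):
        sq = Outline(np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float))
        r = resample_outline(sq, 8)
        closed = np.vstack([r.points, r.points[:1]])
        gaps = np.linalg.norm(np.diff(closed, axis=0), axis=1)
        assert np.allclose(gaps, 0.5)

    def test_fixed_point_when_already_equally_spaced(self):
        c = circle_outline(100)
        r = resample_outline(c, 100)
        assert np.allclose(r.points, c.points, atol=1e-9)

    def test_triangle_inscribed_in_circle(self):
        r = resample_outline(circle_outline(3000), 3)
        closed = np.vstack([r.points, r.points[:1]])
        gaps = np.linalg.norm(np.diff(closed, axis=0), axis=1)
        assert np.allclose(gaps, gaps[0], rtol=1e-3)

    def test_perimeter_preserved(self):
        col = synthetic_colony("dimorphic", 1.0, seed=0)
        for o, _ in col:
            r = resample_outline(o, 150)
            assert r.perimeter == pytest.approx(o.perimeter, rel=0.01)


class TestProcrustes:
    def test_rotated_scaled_copy_superimposes(self):
        base = synthetic_colony("monomorphic", 1.0, seed=1)[0][0]
        ang = np.pi / 2
        rot = np.array([[np.cos(ang), np.sin(ang)], [-np.sin(ang), np.cos(ang)]])
        moved = Outline(base.points @ rot * 3.0 + [5.0, -2.0])
        aligned, _ = procrustes_align([base, moved], n_points=200)
        assert np.abs(aligned[0] - aligned[1]).max() < 1e-6

    def test_constraints_hold_for_every_shape(self):
        outs = [o for o, _ in synthetic_colony("trimorphic", 1.0, seed=2)]
        aligned, mean = procrustes_align(outs, n_points=150)
        for a in aligned:
            assert np.linalg.norm(a.mean(axis=0)) < 1e-9
            assert np.linalg.norm(a - a.mean(axis=0)) == pytest.approx(1.0, abs=1e-9)
        assert np.linalg.norm(mean) == pytest.approx(1.0, abs=1e-6)

    def test_input_order_irrelevant(self):
        outs = [o for o, _ in synthetic_colony("trimorphic", 1.0, seed=3)]
        a1, _ = procrustes_align(outs, n_points=150)
        order = [3, 1, 4, 0, 2]
        a2, _ = procrustes_align([outs[i] for i in order], n_points=150)
        for pos, orig in enumerate(order):
            assert np.abs(a1[orig] - a2[pos]).max() < 1e-6

    def test_needs_two_outlines(self):
        with pytest.raises(ValueError):
            procrustes_align([circle_outline()], n_points=50)


class TestEFA:
    def test_unit_circle_first_harmonic(self):
        c = efa_coefficients(circle_outline(400), 5)
        svals = np.linalg.svd(c.harmonics[0].reshape(2, 2), compute_uv=False)
        assert np.allclose(svals, 1.0, atol=1e-3)
        assert np.abs(c.harmonics[1:]).max() < 1e-3
        assert np.allclose(c.dc, 0.0, atol=1e-3)

    def test_ellipse_is_one_harmonic_in_angle_parameter(self):
        theta = np.linspace(0, 2 * np.pi, 400, endpoint=False)
        ell = Outline(np.column_stack([3 * np.cos(theta), 1.5 * np.sin(theta)]))
        c = efa_coefficients(ell, 1, parameterization="uniform")
        rec = efa_reconstruct(c, 400)
        from scipy.spatial import cKDTree

        d, _ = cKDTree(ell.points).query(rec.points)
        assert np.sqrt((d**2).mean()) < 1e-3 * 3.0

    def test_reconstruction_error_non_increasing_in_h(self):
        o = resample_outline(
            synthetic_colony("dimorphic", 1.5, seed=4)[3][0], 300
        )
        from scipy.spatial import cKDTree

        tree = cKDTree(o.points)
        errs = []
        for H in (1, 2, 4, 8, 16):
            rec = efa_reconstruct(efa_coefficients(o, H), 300)
            d, _ = tree.query(rec.points)
            errs.append(np.sqrt((d**2).mean()))
        assert all(b <= a + 1e-9 for a, b in zip(errs, errs[1:]))

    def test_round_trip_coefficients(self):
        """Reconstruction samples the series uniformly in its own
        parameter, so re-extraction in that same (uniform)
        parameterization recovers the coefficients."""
        o = resample_outline(synthetic_colony("monomorphic", 1.0, seed=5)[1][0], 400)
        c = efa_coefficients(o, 6)
        rec = efa_reconstruct(c, 4000)
        c2 = efa_coefficients(rec, 6, parameterization="uniform")
        assert np.abs(c.harmonics - c2.harmonics).max() < 1e-6
        assert np.allclose(c.dc, c2.dc, atol=1e-6)

    def test_linearity_in_coefficients(self):
        o = circle_outline(200)
        c = efa_coefficients(o, 3)
        from complexspace.outlines import EFACoefficients

        doubled = EFACoefficients(c.harmonics * 2, c.dc)
        rec1 = efa_reconstruct(c, 100).points
        rec2 = efa_reconstruct(doubled, 100).points
        assert np.allclose(rec2 - np.array(c.dc), 2 * (rec1 - np.array(c.dc)), atol=1e-12)

    def test_zero_harmonics_degenerate(self):
        from complexspace.outlines import EFACoefficients

        zero = EFACoefficients(np.zeros((2, 4)), (1.0, 2.0))
        with pytest.raises(ValueError, match="degenerate"):
            efa_reconstruct(zero, 50)

    def test_h_limited_by_sampling(self):
        with pytest.raises(ValueError, match="exceeds"):
            efa_coefficients(circle_outline(20), 15)

    def test_harmonic_power_cumulative(self):
        o = resample_outline(synthetic_colony("trimorphic", 1.5, seed=6)[4][0], 300)
        power = harmonic_power(efa_coefficients(o, 20))
        assert np.all(power >= 0)
        assert np.all(np.diff(np.cumsum(power)) >= 0)

    def test_choose_harmonics_reaches_threshold(self):
        outs = [o for o, _ in synthetic_colony("trimorphic", 1.5, seed=7)]
        outs = [resample_outline(o, 200) for o in outs]
        H = choose_harmonics(outs, threshold=0.99)
        for o in outs:
            power = harmonic_power(efa_coefficients(o, 50))
            assert np.cumsum(power)[H - 1] / power.sum() >= 0.99 - 1e-6

    def test_rigid_motion_invariance_after_procrustes(self):
        """Procrustes + EFA pipeline is invariant to rigid motion and
        scaling of the input polygons."""
        outs = [o for o, _ in synthetic_colony("dimorphic", 1.0, seed=8)]
        ang = 1.1
        rot = np.array([[np.cos(ang), np.sin(ang)], [-np.sin(ang), np.cos(ang)]])
        moved = [Outline(o.points @ rot * 0.4 + [3, 9]) for o in outs]
        a1, _ = procrustes_align(outs, n_points=200)
        a2, _ = procrustes_align(moved, n_points=200)
        for s1, s2 in zip(a1, a2):
            c1 = efa_coefficients(Outline(s1), 6)
            c2 = efa_coefficients(Outline(s2), 6)
            assert np.abs(c1.harmonics - c2.harmonics).max() < 1e-6


class TestFlatten:
    def test_dimensional_bookkeeping(self):
        outs = [circle_outline(100, r=1 + 0.1 * i) for i in range(5)]
        coeffs = [efa_coefficients(o, 2) for o in outs]
        pt = flatten_to_morphospace(coeffs, ["s"] * 5, [f"p{i}" for i in range(5)])
        assert pt.data.shape == (5, 2 + 8)
        assert pt.variables == ["a1", "b1", "c1", "d1", "a2", "b2", "c2", "d2"]

    def test_identical_outlines_identical_rows(self):
        o = circle_outline(100)
        coeffs = [efa_coefficients(o, 2)] * 3
        pt = flatten_to_morphospace(coeffs, ["s"] * 3, ["p1", "p2", "p3"])
        vals = pt.data[pt.variables].to_numpy()
        assert np.allclose(vals, vals[0])

    def test_mixed_h_rejected(self):
        o = circle_outline(100)
        with pytest.raises(ValueError, match="mixed"):
            flatten_to_morphospace(
                [efa_coefficients(o, 2), efa_coefficients(o, 3)],
                ["s", "s"], ["p1", "p2"],
            )

    def test_pipeline_deterministic(self):
        """Same masks in, bit-identical coefficient table out."""
        rr, cc = np.mgrid[0:48, 0:48]
        masks = [
            ((rr - 24) ** 2 / (1 + 0.2 * i) + (cc - 24) ** 2 <= 15**2)
            for i in range(3)
        ]

        def run():
            outs = [extract_outline(m, source_id=str(i)) for i, m in enumerate(masks)]
            aligned, _ = procrustes_align(outs, n_points=150)
            coeffs = [
                efa_coefficients(Outline(a, source_id=o.source_id), 4)
                for a, o in zip(aligned, outs)
            ]
            return flatten_to_morphospace(coeffs, ["s"] * 3).data

        t1, t2 = run(), run()
        assert t1.equals(t2)
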