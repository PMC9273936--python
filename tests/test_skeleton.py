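"""WTMM detection, chaining, along-chain maxima and cross-scale linking."""

import numpy as np
import pytest

from wtmm2d import chain_wtmm, cwt, detect_wtmm, detect_wtmmm, link_scales, make_scale_grid
from wtmm2d.cwt import CwtPlan, ScaleGrid
from wtmm2d.skeleton import (
    MaximaChain,
    WTMMPoints,
    compute_sheaf,
    detect_wtmmm_field,
    load_skeleton,
    save_skeleton,
    suppress_duplicates,
)


def make_chain(coords, moduli, scale=7.0):
    return MaximaChain(
        scale=scale, coords=np.asarray(coords, dtype=int), moduli=np.asarray(moduli, float)
    )


def points_at(coords, moduli, scale=7.0):
    coords = np.asarray(coords, dtype=int)
    return WTMMPoints(
        scale=scale,
        rows=coords[:, 0],
        cols=coords[:, 1],
        modulus=np.asarray(moduli, float),
        argument=np.zeros(len(coords)),
    )


class TestDetectWTMM:
    def test_constant_image_yields_nothing(self):
        w = cwt(np.full((64, 64), 5.0), 4.0)
        assert len(detect_wtmm(w)) == 0

    def test_gaussian_bump_yields_ring(self):
        n, sigma = 128, 6.0
        yy, xx = np.mgrid[0:n, 0:n].astype(float)
        f = np.exp(-((xx - n / 2) ** 2 + (yy - n / 2) ** 2) / (2 * sigma**2))
        w = cwt(f, 3.0)
        pts = detect_wtmm(w)
        assert len(pts) > 0
        r = np.hypot(pts.rows - n / 2, pts.cols - n / 2)
        # all retained points lie on a thin annulus around the center
        assert r.min() > 1.0
        assert r.max() < 4 * sigma
        assert np.std(r) < 2.0
        # oracle: exhaustive directional-maximum re-test at each point
        from scipy.ndimage import map_coordinates

        m, ang = w.modulus, w.argument
        dr, dc = np.sin(ang[pts.rows, pts.cols]), np.cos(ang[pts.rows, pts.cols])
        fwd = map_coordinates(m, [pts.rows + dr, pts.cols + dc], order=1, mode="grid-wrap")
        bwd = map_coordinates(m, [pts.rows - dr, pts.cols - dc], order=1, mode="grid-wrap")
        assert np.all(pts.modulus >= fwd) and np.all(pts.modulus >= bwd)

    def test_wtmm_mask_on_fbm_traces_chains(self, fbm_small):
        w = cwt(fbm_small, 10.0)
        pts = detect_wtmm(w)
        # edges cover a thin subset of the image, organized in chains
        assert 0.002 < len(pts) / fbm_small.size**2 < 0.2
        chains = chain_wtmm(pts, (fbm_small.size,) * 2)
        assert max(len(c) for c in chains) > 20  # long connected chains exist


class TestChaining:
    def test_adjacent_points_form_one_chain(self):
        pts = points_at([(5, 5), (5, 6)], [1.0, 2.0])
        chains = chain_wtmm(pts, (16, 16))
        assert len(chains) == 1 and len(chains[0]) == 2

    def test_distant_points_form_singletons(self):
        pts = points_at([(5, 5), (8, 9)], [1.0, 2.0])
        chains = chain_wtmm(pts, (16, 16))
        assert sorted(len(c) for c in chains) == [1, 1]

    def test_closed_ring_is_single_chain(self):
        n = 32
        theta = np.linspace(0, 2 * np.pi, 200)
        coords = np.unique(
            np.column_stack(
                [np.round(16 + 8 * np.sin(theta)), np.round(16 + 8 * np.cos(theta))]
            ).astype(int),
            axis=0,
        )
        pts = points_at(coords, np.ones(len(coords)))
        chains = chain_wtmm(pts, (n, n))
        assert len(chains) == 1
        assert len(chains[0]) == len(coords)

    def test_matches_connected_component_oracle(self, rng):
        # random sparse mask: chain partition == scipy label components
        import scipy.ndimage as ndi

        mask = rng.random((40, 40)) < 0.15
        rows, cols = np.nonzero(mask)
        pts = points_at(np.column_stack([rows, cols]), rng.random(len(rows)) + 0.1)
        chains = chain_wtmm(pts, (40, 40), periodic=False)
        lab, n = ndi.label(mask, structure=np.ones((3, 3)))
        assert len(chains) == n
        sizes = sorted(len(c) for c in chains)
        oracle = sorted(np.bincount(lab.ravel())[1:])
        assert sizes == oracle

    def test_periodic_wraparound_merges(self):
        pts = points_at([(0, 5), (39, 5)], [1.0, 2.0])
        assert len(chain_wtmm(pts, (40, 40), periodic=True)) == 1
        assert len(chain_wtmm(pts, (40, 40), periodic=False)) == 2


class TestDetectWTMMM:
    def test_interior_maximum(self):
        chain = make_chain([(5, 5), (5, 6), (5, 7)], [1, 3, 2])
        got = detect_wtmmm(chain)
        assert len(got) == 1 and (got.rows[0], got.cols[0]) == (5, 6)

    def test_plateau_yields_one_representative(self):
        # closed triangle of equal moduli
        chain = make_chain([(5, 5), (5, 6), (6, 5)], [2, 2, 2])
        assert len(detect_wtmmm(chain)) == 1

    def test_singleton_chain_kept(self):
        chain = make_chain([(3, 3)], [5.0])
        got = detect_wtmmm(chain)
        assert len(got) == 1 and got.modulus[0] == 5.0

    def test_matches_bruteforce_on_random_path_chains(self, rng):
        # straight path chain: along-chain maxima == 1D local-max scan
        for _ in range(20):
            n = int(rng.integers(5, 50))
            moduli = rng.random(n) * 10
            coords = [(7, 7 + i) for i in range(n)]
            got = detect_wtmmm(make_chain(coords, moduli))
            brute = set()
            i = 0
            while i < n:
                j = i
                while j + 1 < n and moduli[j + 1] == moduli[i]:
                    j += 1
                left = moduli[i - 1] if i > 0 else -np.inf
                right = moduli[j + 1] if j + 1 < n else -np.inf
                if moduli[i] >= left and moduli[i] >= right:
                    brute.add(i)  # first index of the plateau run
                i = j + 1
            assert set(got.cols - 7) == brute

    def test_field_version_matches_chain_version(self, fbm_small):
        # with the screening window collapsed to plain adjacency, the
        # vectorized grid path equals chain-by-chain detection
        w = cwt(fbm_small, 12.0)
        grid_pts = detect_wtmmm_field(w, window_factor=0.0)
        pts = detect_wtmm(w)
        chain_pts = set()
        for chain in chain_wtmm(pts, w.shape):
            got = detect_wtmmm(chain)
            chain_pts.update(zip(got.rows.tolist(), got.cols.tolist()))
        assert set(zip(grid_pts.rows.tolist(), grid_pts.cols.tolist())) == chain_pts


class TestSuppression:
    def test_keeps_strongest_within_radius(self):
        pts = points_at([(10, 10), (10, 12), (30, 30)], [1.0, 5.0, 2.0])
        kept = suppress_duplicates(pts, 4.0, size=64)
        assert len(kept) == 2
        assert set(kept.modulus) == {5.0, 2.0}

    def test_zero_radius_is_noop(self):
        pts = points_at([(1, 1), (1, 2)], [1.0, 2.0])
        assert len(suppress_duplicates(pts, 0.0, size=64)) == 2


def cusp_surface(n, h, centers):
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    f = np.zeros((n, n))
    for r0, c0 in centers:
        f += np.hypot(yy - r0, xx - c0) ** h
    return f


class TestLinking:
    def small_grid(self, n=256):
        return make_scale_grid(n, a0=4, voices=4)

    def build(self, f, grid, window_factor=1.0):
        plan = CwtPlan(f, precision="double")
        wt = [detect_wtmmm_field(plan(a), window_factor=window_factor) for a in grid.scales]
        return wt

    @staticmethod
    def full_lines_near(skel, center, radius=12.0):
        """Full-depth lines rooted within ``radius`` px of ``center``.

        An isotropic cusp produces a small symmetric set of maxima
        lines on the gradient-maxima ring (radius ~ 2 a0 at the
        smallest scale), all pointing to the singularity; the periodic
        seam of the non-periodic cusp surface produces its own border
        lines, excluded by the distance cut."""
        full = np.flatnonzero(skel.j_max == len(skel.grid) - 1)
        roots = skel.positions[full, 0, :]
        d = np.hypot(roots[:, 0] - center[0], roots[:, 1] - center[1])
        return full[d <= radius]

    def test_single_cusp_lines_point_to_singularity(self):
        n = 256
        grid = self.small_grid(n)
        f = cusp_surface(n, 0.5, [(n // 2, n // 2)])
        skel = link_scales(self.build(f, grid), grid, size=n)
        near = self.full_lines_near(skel, (n // 2, n // 2))
        assert 1 <= len(near) <= 8
        # no other full-depth lines exist away from the cusp and seam
        full = np.flatnonzero(skel.j_max == len(grid) - 1)
        roots = skel.positions[full, 0, :]
        seam = (np.min(roots, axis=1) < 16) | (np.max(roots, axis=1) > n - 16)
        d = np.hypot(roots[:, 0] - n // 2, roots[:, 1] - n // 2)
        assert np.all(seam | (d <= 12.0))

    def test_two_distant_cusps_tracked_by_disjoint_lines(self):
        # each singularity is tracked by its own line over the scales
        # where the two gradient-maxima rings stay resolved (the rings
        # grow like ~2a and eventually meet at the midpoint saddle)
        n = 256
        grid = self.small_grid(n)
        f = cusp_surface(n, 0.5, [(64, 64), (192, 192)])
        skel = link_scales(self.build(f, grid), grid, size=n)
        found = []
        for center in ((64, 64), (192, 192)):
            roots = skel.positions[:, 0, :]
            d = np.hypot(roots[:, 0] - center[0], roots[:, 1] - center[1])
            near = np.flatnonzero(d <= 12.0)
            assert len(near) >= 1
            deepest = near[np.argmax(skel.j_max[near])]
            assert grid.scales[skel.j_max[deepest]] >= 10.0
            found.append(int(deepest))
        assert found[0] != found[1]

    def test_far_targets_terminate_lines(self):
        grid = ScaleGrid(a0=2, voices_per_octave=1, scales=np.array([2.0, 4.0]))
        p0 = points_at([(10, 10)], [1.0], scale=2.0)
        p1 = points_at([(40, 40)], [1.0], scale=4.0)  # farther than 1.5*4 px
        skel = link_scales([p0, p1], grid, size=64)
        assert skel.n_lines == 1 and skel.j_max[0] == 0

    def test_no_midscale_births(self):
        grid = ScaleGrid(a0=2, voices_per_octave=1, scales=np.array([2.0, 4.0]))
        p0 = points_at([(10, 10)], [1.0], scale=2.0)
        p1 = points_at([(10, 10), (50, 50)], [1.0, 9.0], scale=4.0)
        skel = link_scales([p0, p1], grid, size=64)
        assert skel.n_lines == 1  # the orphan at (50, 50) seeds nothing

    def test_line_count_nonincreasing_and_records_match(self, fbm_small):
        from wtmm2d import build_skeleton

        skel = build_skeleton(fbm_small)
        counts = skel.counts()
        assert np.all(np.diff(counts) <= 0)
        assert counts[0] == skel.n_lines
        # every line record is a real WTMMM of its scale
        plan = CwtPlan(fbm_small.heights, precision="single")
        j = min(4, len(skel.grid) - 1)
        pts = detect_wtmmm_field(plan(skel.grid.scales[j]))
        locs = set(zip(pts.rows.tolist(), pts.cols.tolist()))
        for i in range(skel.n_lines):
            if skel.j_max[i] >= j:
                r, c = skel.positions[i, j]
                assert (int(r), int(c)) in locs


class TestSheafAndHolder:
    def test_exact_power_law_line_gives_straight_curve(self):
        from wtmm2d import LineFamily, make_fixture_skeleton

        grid = make_scale_grid(512)
        skel = make_fixture_skeleton([LineFamily(n=1, holder=0.7, amplitude=3.0)], grid)
        sheaf = compute_sheaf(skel)
        y = sheaf.log2_moduli[0]
        slope = np.polyfit(sheaf.log2_scales, y, 1)
        assert slope[0] == pytest.approx(0.7, abs=1e-9)

    def test_empty_skeleton_empty_sheaf(self):
        grid = make_scale_grid(512)
        skel = link_scales(
            [points_at(np.empty((0, 2)), []) for _ in grid.scales], grid, size=512
        )
        assert compute_sheaf(skel).n_lines == 0

    @pytest.mark.parametrize("h", [0.3, 0.5, 0.7])
    def test_cusp_holder_recovered_from_sheaf_slope(self, h):
        # |x - x0|^h: the full-length line's sheaf slope estimates h
        n = 256
        grid = make_scale_grid(n, a0=4, voices=4)
        f = cusp_surface(n, h, [(n // 2, n // 2)])
        plan = CwtPlan(f, precision="double")
        wt = [detect_wtmmm_field(plan(a)) for a in grid.scales]
        skel = link_scales(wt, grid, size=n)
        i = int(TestLinking.full_lines_near(skel, (n // 2, n // 2))[0])
        sheaf = compute_sheaf(skel)
        y = sheaf.log2_moduli[i]
        ok = np.isfinite(y)
        slope = np.polyfit(sheaf.log2_scales[ok], y[ok], 1)[0]
        assert slope == pytest.approx(h, abs=0.05)


class TestPersistence:
    def test_hdf5_roundtrip(self, tmp_path, fbm_small):
        from wtmm2d import build_skeleton

        skel = build_skeleton(fbm_small)
        save_skeleton(tmp_path / "s.h5", skel)
        back = load_skeleton(tmp_path / "s.h5")
        assert back.n_lines == skel.n_lines
        assert np.allclose(back.grid.scales, skel.grid.scales)
        assert np.array_equal(back.j_max, skel.j_max)
        assert np.allclose(back.moduli, skel.moduli, equal_nan=True)
        assert back.meta.get("hurst") == 0.7

    def test_summary_table(self, fbm_small):
        from wtmm2d import build_skeleton
        from wtmm2d.skeleton import skeleton_summary

        skel = build_skeleton(fbm_small)
        df = skeleton_summary(skel)
        assert list(df.columns) == ["line_id", "n_scales", "m_first", "m_last", "a_max", "m_adj"]
        assert len(df) == skel.n_lines
        assert (df.n_scales >= 1).all()
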