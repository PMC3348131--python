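"""Grid-probe pocket detection, properties and druggability scores."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ensemblepockets import pocket_detect as pdet
from ensemblepockets.fixtures import CARBON_VDW, make_shell_cavity
from ensemblepockets.pocket_detect import (
    PocketConfig,
    ScoreCoefficients,
    cluster_site_points,
    d_score,
    detect_pockets,
    grid_sites,
    site_score,
)
from ensemblepockets.structure_io import AtomRecord, MolecularStructure


def _single_atom():
    return MolecularStructure([
        AtomRecord(1, "CB", "ALA", "A", 1, "", "C", (0.0, 0.0, 0.0))
    ])


class TestGridSites:
    def test_isolated_atom_has_no_site_points(self):
        assert grid_sites(_single_atom()) == []

    def test_slab_has_no_candidates(self, slab):
        assert grid_sites(slab) == []

    def test_coarser_grid_gives_fewer_points(self, shell):
        fine = grid_sites(shell[0], spacing=1.0)
        coarse = grid_sites(shell[0], spacing=2.0)
        assert 0 < len(coarse) < len(fine)

    def test_site_points_outside_vdw_spheres(self, shell):
        coords = shell[0].coordinates()
        pts = np.array([sp.position for sp in grid_sites(shell[0])])
        from scipy.spatial import cKDTree

        d, _ = cKDTree(coords).query(pts)
        assert (d > CARBON_VDW - 1e-9).all()

    def test_closed_shell_count_matches_flood_fill_oracle(self, closed_shell):
        """The detected cavity equals an independent interior flood fill.

        Oracle: start from the cavity centre and flood-fill grid cells that
        lie outside every vdW sphere, moving between 26-neighbours.  In a
        closed shell the fill cannot escape, so it enumerates the cavity.
        The fill runs on the same canonical-frame grid the detector declares,
        but selects and connects cells by its own independent logic.
        """
        s, _ = closed_shell
        cfg = PocketConfig()
        pockets = detect_pockets(s, cfg)
        assert len(pockets) == 1

        c0, frame = pdet._canonical_frame(s.coordinates())
        coords = (s.coordinates() - c0) @ frame
        lo = coords.min(axis=0) - cfg.margin
        hi = coords.max(axis=0) + cfg.margin
        grids = [np.arange(lo[d], hi[d] + 1e-9, cfg.spacing) for d in range(3)]
        shape = tuple(len(g) for g in grids)
        from scipy.spatial import cKDTree

        tree = cKDTree(coords)
        start = tuple(int(np.argmin(np.abs(g))) for g in grids)

        def outside(idx):
            p = np.array([grids[d][idx[d]] for d in range(3)])
            return tree.query(p)[0] > CARBON_VDW

        assert outside(start)
        seen = {start}
        stack = [start]
        while stack:
            cur = stack.pop()
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dz in (-1, 0, 1):
                        nxt = (cur[0] + dx, cur[1] + dy, cur[2] + dz)
                        if nxt in seen:
                            continue
                        if any(n < 0 or n >= shape[d]
                               for d, n in enumerate(nxt)):
                            continue
                        if outside(nxt):
                            seen.add(nxt)
                            stack.append(nxt)
        assert pockets[0].n == len(seen)


class TestScores:
    def test_zero_case(self):
        c = ScoreCoefficients(1.0, 1.0, 1.0)
        assert site_score(0, 0.0, 0.0, c) == 0.0
        assert d_score(0, 0.0, 0.0, c) == 0.0

    def test_default_coefficients_hand_arithmetic(self):
        # 0.0733·√100 + 0.6688·0.76 − 0.20·1.0
        assert site_score(100, 0.76, 1.0) == pytest.approx(
            0.733 + 0.508288 - 0.200, abs=1e-9
        )

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_hand_formula_on_random_tuples(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(0, 300))
        e = float(rng.uniform(0, 1))
        p = float(rng.uniform(0, 3))
        cs = ScoreCoefficients(*rng.uniform(0.05, 1.0, 3))
        expected_ss = cs.a_n * math.sqrt(min(n, 100)) + cs.a_e * e \
            - cs.a_p * min(p, 1.0)
        expected_ds = cs.a_n * math.sqrt(min(n, 100)) + cs.a_e * e - cs.a_p * p
        assert site_score(n, e, p, cs) == pytest.approx(expected_ss, rel=1e-12)
        assert d_score(n, e, p, cs) == pytest.approx(expected_ds, rel=1e-12)

    def test_sitescore_hydrophilicity_cap(self):
        assert site_score(50, 0.8, 2.5) == site_score(50, 0.8, 1.0)

    def test_dscore_uncapped_and_strictly_decreasing_in_p(self):
        assert d_score(50, 0.8, 2.5) < d_score(50, 0.8, 1.0)
        c = pdet.DSCORE_DEFAULT
        assert d_score(50, 0.8, 2.0) - d_score(50, 0.8, 3.0) == pytest.approx(
            c.a_p
        )

    def test_scores_increase_with_enclosure(self):
        assert site_score(50, 0.9, 0.5) > site_score(50, 0.5, 0.5)
        assert d_score(50, 0.9, 0.5) > d_score(50, 0.5, 0.5)


class TestClusterSitePoints:
    def _points_at(self, offsets):
        return [
            pdet.SitePoint(position=tuple(map(float, o)),
                           character="philic-neutral")
            for o in offsets
        ]

    def _dummy_structure(self):
        return MolecularStructure([
            AtomRecord(1, "CB", "ALA", "A", 1, "", "C", (50.0, 50.0, 50.0))
        ])

    def test_fourteen_points_filtered(self):
        pts = self._points_at([(i % 3, (i // 3) % 3, i // 9) for i in range(14)])
        assert cluster_site_points(pts, self._dummy_structure()) == []

    def test_fifteen_points_make_one_pocket(self):
        pts = self._points_at([(i % 3, (i // 3) % 3, i // 9) for i in range(15)])
        pockets = cluster_site_points(pts, self._dummy_structure())
        assert len(pockets) == 1
        assert pockets[0].n == 15

    def test_distant_clusters_stay_separate(self):
        near = [(i % 3, (i // 3) % 3, i // 9) for i in range(20)]
        far = [(x + 30.0, y, z) for x, y, z in near]
        pockets = cluster_site_points(
            self._points_at(near + far), self._dummy_structure()
        )
        assert len(pockets) == 2


class TestDetectPockets:
    def test_shell_cavity_single_pocket(self, shell, shell_pockets):
        _, analytic = shell
        assert len(shell_pockets) == 1
        p = shell_pockets[0]
        assert p.enclosure >= 0.8
        assert abs(p.volume - analytic) / analytic <= 0.15
        assert p.druggable

    def test_center_of_closed_shell_highly_enclosed(self, closed_shell):
        pockets = detect_pockets(closed_shell[0])
        center_sp = min(
            pockets[0].site_points,
            key=lambda sp: float(np.linalg.norm(sp.position)),
        )
        assert center_sp.enclosure >= 0.95

    def test_far_point_nearly_open(self, shell):
        s, _ = shell
        coords = s.coordinates()
        radii = np.full(len(coords), CARBON_VDW)
        axes = pdet._ray_axes(33)
        point = coords.mean(axis=0) + np.array([0.0, 0.0, 30.0])
        enc, _ = pdet._blocked_rays(point[None, :], coords, radii, axes, 12.0)
        assert enc[0] <= 0.05

    def test_slab_yields_no_pockets(self, slab):
        assert detect_pockets(slab) == []

    def test_two_cavities_found_and_ranked(self, two_cavity):
        pockets = detect_pockets(two_cavity[0])
        assert len(pockets) == 2
        assert pockets[0].site_score >= pockets[1].site_score

    def test_volume_converges_with_finer_grid(self, shell):
        s, analytic = shell
        coarse = detect_pockets(s)[0]
        fine = detect_pockets(s, PocketConfig(spacing=0.5))[0]
        assert abs(fine.volume - coarse.volume) / coarse.volume <= 0.25
        assert abs(fine.volume - analytic) <= abs(coarse.volume - analytic)

    def test_rigid_motion_invariance(self, shell, shell_pockets):
        """Pocket count, volume, enclosure and scores survive rotation+translation."""
        s, _ = shell
        R = Rotation.from_euler("xyz", [30, -45, 60], degrees=True).as_matrix()
        t = np.array([11.0, -7.0, 23.0])
        # rotate the grid with the structure so detection sees identical geometry
        moved = s.with_coordinates(s.coordinates() @ R.T + t)
        pockets = detect_pockets(moved)
        assert len(pockets) == len(shell_pockets)
        ref = shell_pockets[0]
        got = pockets[0]
        assert got.n == pytest.approx(ref.n, rel=0.03)
        assert got.enclosure == pytest.approx(ref.enclosure, abs=0.02)
        assert got.site_score == pytest.approx(ref.site_score, abs=0.02)

    def test_determinism(self, shell, shell_pockets):
        again = detect_pockets(shell[0])
        assert pdet.pockets_to_table(again).equals(
            pdet.pockets_to_table(shell_pockets)
        )

    def test_center_is_mean_of_site_points(self, shell_pockets):
        p = shell_pockets[0]
        np.testing.assert_allclose(
            p.center, p.positions().mean(axis=0), atol=1e-9
        )

    def test_sphere_pdb_round_trip(self, shell_pockets):
        from ensemblepockets.structure_io import read_sphere_pdb

        text = pdet.pockets_to_sphere_pdb(shell_pockets)
        spheres = read_sphere_pdb(text)
        assert len(spheres) == shell_pockets[0].n

    def test_all_hydrophobic_pocket_hits_balance_cap(self, shell_pockets):
        """A cavity lined only by apolar carbons saturates h/p at the cap."""
        p = shell_pockets[0]
        wall_points = [
            sp for sp in p.site_points
            if np.linalg.norm(sp.position) > 4.0  # close enough to type apolar
        ]
        assert all(sp.character == "hydrophobic" for sp in wall_points)
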