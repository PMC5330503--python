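"""Geometric descriptors on constructed shapes with known answers."""

import itertools

import numpy as np
import pytest

from confdiv.descriptors import (
    assign_secondary_structure,
    count_hinges,
    detect_pockets,
    detect_tunnels,
    ligand_stats,
    pocket_variation_with_idrs,
    protein_volume,
    radius_of_gyration_normalized,
    residue_network_degree,
    sasa,
    ss_fractions,
    tunnel_variation,
)
from confdiv.io import AtomRecord, LigandRecord, build_ensemble
from confdiv.superpose import max_rmsd_pair
from confdiv.synth import _rotation_matrix

from conftest import (
    conf_from_ca,
    cubic_cavity_conformer,
    slab_channel_conformer,
    solid_ball_conformer,
)


class TestSecondaryStructure:
    def test_ideal_helix_mostly_h(self):
        i = np.arange(40)
        ang = np.deg2rad(100.0) * i
        helix = np.stack([2.3 * np.cos(ang), 2.3 * np.sin(ang), 1.5 * i], 1)
        ss = assign_secondary_structure(conf_from_ca(helix))
        interior = [ss[p] for p in range(5, 36)]
        assert interior.count("H") / len(interior) >= 0.9

    def test_ideal_strand_mostly_e(self):
        i = np.arange(40)
        strand = np.stack([3.35 * i, 0.9 * (-1.0) ** i, np.zeros(40)], 1)
        ss = assign_secondary_structure(conf_from_ca(strand))
        interior = [ss[p] for p in range(5, 36)]
        assert interior.count("E") / len(interior) >= 0.8

    def test_random_walk_mostly_coil(self):
        rng = np.random.default_rng(3)
        pts = [np.zeros(3)]
        for _ in range(39):
            v = rng.normal(size=3)
            v *= 3.8 / np.linalg.norm(v)
            pts.append(pts[-1] + v)
        ss = assign_secondary_structure(conf_from_ca(np.array(pts)))
        vals = list(ss.values())
        assert vals.count("C") / len(vals) > 0.5

    def test_tiny_chain_all_coil_and_fraction_sum(self):
        ss = assign_secondary_structure(conf_from_ca(np.eye(3) * 3.8))
        assert set(ss.values()) == {"C"}
        assert sum(ss_fractions(ss)) == pytest.approx(1.0)


class TestRadiusOfGyration:
    def test_uniform_ball_ratio_near_one(self):
        conf = solid_ball_conformer(radius=20.0, n=5000, seed=1)
        assert radius_of_gyration_normalized(conf) == pytest.approx(1.0, abs=0.1)

    def test_elongation_increases_ratio(self):
        conf = solid_ball_conformer(radius=10.0, n=1500, seed=2)
        pts = np.array([r.ca_xyz for r in conf.residues])
        stretched = conf_from_ca(pts * np.array([3.0, 1.0, 1.0]))
        assert radius_of_gyration_normalized(stretched) > radius_of_gyration_normalized(conf)

    def test_single_atom_raises(self):
        with pytest.raises(ValueError):
            radius_of_gyration_normalized(conf_from_ca(np.zeros((1, 3))))

    def test_volume_positive_and_motion_invariant(self):
        conf = solid_ball_conformer(radius=8.0, n=300, seed=3)
        v1 = protein_volume(conf)
        pts = np.array([r.ca_xyz for r in conf.residues])
        rot = _rotation_matrix(np.array([1.0, 2.0, 3.0]), 1.1)
        v2 = protein_volume(conf_from_ca(pts @ rot.T + 40.0))
        assert v1 > 0
        assert v2 == pytest.approx(v1, rel=0.05)  # grid re-anchored to the structure


class TestResidueNetwork:
    def test_far_apart_residues_degree_zero(self):
        pts = np.arange(10)[:, None] * np.array([20.0, 0.0, 0.0])
        _, deg = residue_network_degree(conf_from_ca(pts))
        assert deg == 0.0

    def test_clique_degree(self):
        # 6 residues pairwise within cutoff; |i-j| >= 2 never holds for
        # adjacent pairs, so they are excluded from the clique edges
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(6, 3)) * 0.5
        g, deg = residue_network_degree(conf_from_ca(pts), cutoff=5.0, min_seq_sep=1)
        assert deg == pytest.approx(5.0)
        assert all(d == 5 for _, d in g.degree())

    def test_avg_degree_identity_on_random_geometry(self, rng):
        pts = rng.uniform(0, 25, size=(60, 3))
        g, deg = residue_network_degree(conf_from_ca(pts), cutoff=6.0)
        # independent recount of qualifying edges
        e = sum(
            1
            for i, j in itertools.combinations(range(60), 2)
            if abs(i - j) >= 2 and np.linalg.norm(pts[i] - pts[j]) <= 6.0
        )
        assert g.number_of_edges() == e
        assert deg == pytest.approx(2 * e / 60)


class TestPockets:
    def test_enclosed_cavity_volume(self):
        pockets = detect_pockets(cubic_cavity_conformer())
        assert pockets, "cavity not found"
        assert pockets[0].volume == pytest.approx(125.0, rel=0.20)

    def test_convex_cluster_has_no_real_pocket(self):
        pockets = detect_pockets(solid_ball_conformer(radius=7.0, n=300, seed=0))
        largest = pockets[0].volume if pockets else 0.0
        assert largest <= 30.0  # noise floor

    def test_filling_the_cavity_shrinks_the_pocket(self):
        conf = cubic_cavity_conformer()
        v_before = detect_pockets(conf)[0].volume
        pts = np.array([r.ca_xyz for r in conf.residues])
        filler = np.array(
            [(x, y, z) for x in (-1.5, 0, 1.5) for y in (-1.5, 0, 1.5) for z in (-1.5, 0, 1.5)]
        )
        filled = conf_from_ca(np.vstack([pts, filler]))
        pockets = detect_pockets(filled)
        v_after = pockets[0].volume if pockets else 0.0
        assert v_after < v_before

    def test_variation_formula(self):
        assert pocket_variation_with_idrs(100, 50, 100, 40) == 0.0
        assert pocket_variation_with_idrs(100, 20, 50, 10) == pytest.approx(0.5)
        # symmetric under swapping the conformers
        a = pocket_variation_with_idrs(80, 30, 60, 20)
        b = pocket_variation_with_idrs(30, 80, 20, 60)
        assert a == pytest.approx(b)
        with pytest.raises(ValueError):
            pocket_variation_with_idrs(0, 0, 0, 0)

    def test_variation_bounded(self, rng):
        for _ in range(200):
            v = rng.uniform(0, 500, size=4)
            out = pocket_variation_with_idrs(*v)
            assert 0.0 <= out <= 1.0


class TestTunnels:
    def test_open_channel_recovered(self):
        tunnels = detect_tunnels(slab_channel_conformer(channel_radius=2.0, thickness=20.0))
        assert len(tunnels) >= 1
        assert tunnels[0].length == pytest.approx(20.0, rel=0.15)
        assert tunnels[0].bottleneck_radius >= 1.25

    def test_channel_below_interior_threshold_disappears(self):
        tunnels = detect_tunnels(slab_channel_conformer(channel_radius=1.0, thickness=20.0))
        assert tunnels == []

    def test_solid_geometry_has_no_tunnels(self):
        assert detect_tunnels(solid_ball_conformer(radius=8.0, n=400, seed=0)) == []

    def test_lining_residues_near_path(self):
        conf = slab_channel_conformer(channel_radius=2.0, thickness=20.0)
        t = detect_tunnels(conf)[0]
        pts = np.array([r.ca_xyz for r in conf.residues])
        for pos in t.lining_positions:
            d = np.linalg.norm(pts[pos - 1] - t.path, axis=1).min()
            assert d <= t.bottleneck_radius + 3.0 + 1e-6

    def test_variation_formula(self):
        assert tunnel_variation(10.0, 10.0) == 0.0
        assert tunnel_variation(10.0, 5.0) == pytest.approx(0.5)
        assert tunnel_variation(7.0, 0.0) == 1.0
        assert tunnel_variation(5.0, 10.0) == tunnel_variation(10.0, 5.0)
        with pytest.raises(ValueError):
            tunnel_variation(0.0, 0.0)


def _hinge_pair(breaks, angle=30.0, n=100):
    """Two conformers differing by rigid rotations at the given breakpoints."""
    base = np.zeros((n, 3))
    base[:, 0] = np.arange(n) * 3.8
    base[:, 1] = np.sin(np.arange(n)) * 1.0
    other = base.copy()
    axes = [np.array([0, 0, 1.0]), np.array([0, 1.0, 0]), np.array([1.0, 1.0, 0])]
    for k, brk in enumerate(breaks):
        rot = _rotation_matrix(axes[k % 3], np.deg2rad(angle))
        pivot = other[brk - 1]
        other[brk:] = (other[brk:] - pivot) @ rot.T + pivot
    ens = build_ensemble([conf_from_ca(base, "AAAA"), conf_from_ca(other, "BBBB")], "h")
    return ens, max_rmsd_pair(ens)


def _exhaustive_min_breakpoints(ens, pair, threshold=1.5, min_seg=15, max_breaks=2):
    """Oracle: enumerate every breakpoint placement up to ``max_breaks``."""
    from confdiv.descriptors import _segment_rmsd, _segment_rmsd_tables

    a, b = pair.pair
    common = ens.common_observed_positions(a, b)
    xa, xb = ens.conformer(a).ca_coords(common), ens.conformer(b).ca_coords(common)
    tables = _segment_rmsd_tables(xa, xb)
    n = len(common)

    def feasible(bounds):
        edges = [0, *bounds, n]
        for i, j in zip(edges, edges[1:]):
            if j - i < min_seg or _segment_rmsd(tables, i, j - 1) > threshold:
                return False
        return True

    for k in range(0, max_breaks + 1):
        for bounds in itertools.combinations(range(1, n), k):
            if feasible(bounds):
                return k
    return None


class TestHinges:
    def test_identical_conformers_zero_hinges(self):
        ens, mp = _hinge_pair([], angle=0.0)
        n, bounds, flagged = count_hinges(ens, mp)
        assert (n, bounds, flagged) == (0, [], False)

    def test_single_hinge_found_at_junction(self):
        ens, mp = _hinge_pair([50])
        n, bounds, flagged = count_hinges(ens, mp)
        assert n == 1 and not flagged
        assert abs(bounds[0] - 50) <= 2

    def test_two_hinges(self):
        ens, mp = _hinge_pair([33, 66], angle=25.0)
        n, bounds, flagged = count_hinges(ens, mp)
        assert n == 2 and not flagged
        assert abs(bounds[0] - 33) <= 2 and abs(bounds[1] - 66) <= 2

    @pytest.mark.parametrize("breaks", [[], [25], [30], [20, 40]])
    def test_dp_matches_exhaustive_enumeration(self, breaks):
        """DP count equals brute-force enumeration for short chains."""
        ens, mp = _hinge_pair(breaks, angle=35.0, n=60)
        expected = _exhaustive_min_breakpoints(ens, mp)
        n, _, flagged = count_hinges(ens, mp)
        assert expected is not None and not flagged
        assert n == expected == len(breaks)


class TestSasa:
    def test_isolated_atom_analytic_area(self):
        conf = conf_from_ca(np.array([[100.0, 100.0, 100.0]]))
        area = sasa(conf)[0]
        exact = 4.0 * np.pi * (1.7 + 1.4) ** 2
        assert area == pytest.approx(exact, rel=0.01)

    def test_fully_enclosed_atom_near_zero(self):
        shell = []
        for t in np.linspace(0, np.pi, 12):
            for p in np.linspace(0, 2 * np.pi, 24, endpoint=False):
                shell.append(
                    3.0 * np.array([np.sin(t) * np.cos(p), np.sin(t) * np.sin(p), np.cos(t)])
                )
        pts = np.vstack([[0.0, 0.0, 0.0], shell])
        areas = sasa(conf_from_ca(pts))
        assert areas[0] == pytest.approx(0.0, abs=1.0)

    def test_two_atom_system_matches_high_density_oracle(self):
        pts = np.array([[0.0, 0.0, 0.0], [2.5, 0.0, 0.0]])
        coarse = sasa(conf_from_ca(pts), n_points=960)
        fine = sasa(conf_from_ca(pts), n_points=10000)
        np.testing.assert_allclose(coarse, fine, rtol=0.02)

    def test_total_area_decreases_as_context_grows(self, rng):
        pts = rng.uniform(0, 10, size=(12, 3))
        totals = [sasa(conf_from_ca(pts[: k + 3])).sum() / (k + 3) for k in range(8)]
        conf_full = conf_from_ca(pts)
        # adding context atoms can only bury the first three atoms further
        first3_alone = sasa(conf_from_ca(pts[:3]))[:3].sum()
        first3_crowded = sasa(conf_full)[:3].sum()
        assert first3_crowded <= first3_alone + 1e-9


class TestLigands:
    def _ens(self, ligand_lists):
        ca = np.random.default_rng(0).normal(size=(30, 3)) * 5
        confs = [
            conf_from_ca(ca, name=f"C{i:03d}", ligands=l)
            for i, l in enumerate(ligand_lists)
        ]
        return build_ensemble(confs, "p")

    def test_no_hetatms_all_apo(self):
        stats = ligand_stats(self._ens([[], [], []]))
        assert stats["n_distinct_ligands"] == 0
        assert len(stats["apo_ids"]) == 3 and stats["holo_ids"] == []

    def test_shared_het_code_counted_once(self):
        atp = LigandRecord("ATP", 31, 507.18)
        stats = ligand_stats(self._ens([[atp], [atp], []]))
        assert stats["n_distinct_ligands"] == 1
        assert stats["mean_ligand_mw"] == pytest.approx(507.18)
        assert len(stats["holo_ids"]) == 2

    def test_small_het_groups_do_not_make_holo(self):
        ion = LigandRecord("MG", 1, 24.3)
        stats = ligand_stats(self._ens([[ion], [ion], []]))
        assert stats["n_distinct_ligands"] == 0
        assert stats["holo_ids"] == []
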