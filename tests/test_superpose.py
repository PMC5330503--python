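"""Superposition and RMSD: oracle agreement, invariances, max-pair logic."""

import numpy as np
import pytest

from confdiv.disorder import IDRAnnotation
from confdiv.superpose import (
    compare_pair,
    kabsch_rmsd,
    max_rmsd_pair,
    pairwise_matrix,
    per_position_profile,
    rmsd_excluding_union_idrs,
)

from conftest import conf_from_ca, ensemble_from_traces, quaternion_rmsd, random_rigid_motion


class TestKabsch:
    def test_identical_sets_zero(self, rng):
        a = rng.normal(size=(20, 3)) * 10
        rmsd, rot, trans = kabsch_rmsd(a, a.copy())
        assert rmsd == pytest.approx(0.0, abs=1e-7)
        np.testing.assert_allclose(rot @ rot.T, np.eye(3), atol=1e-12)

    def test_rigid_motion_invariance(self, rng):
        a = rng.normal(size=(15, 3)) * 8
        rz = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])  # 90 deg about z
        b = a @ rz.T + np.array([5.0, 0.0, 0.0])
        rmsd, _, _ = kabsch_rmsd(a, b)
        assert rmsd == pytest.approx(0.0, abs=1e-8)

    def test_displaced_tetrahedron_matches_quaternion_oracle(self):
        a = np.array([[0, 0, 0], [1, 1, 0], [1, 0, 1], [0, 1, 1]], dtype=float)
        b = a.copy()
        b[3] += np.array([1.0, 0.0, 0.0]) / np.sqrt(1.0)  # displace one vertex by 1 A
        rmsd, _, _ = kabsch_rmsd(a, b)
        assert rmsd == pytest.approx(quaternion_rmsd(a, b), abs=1e-8)

    def test_agrees_with_quaternion_oracle_on_random_instances(self):
        """SVD implementation vs Horn quaternion oracle: 1,000 random pairs."""
        rng = np.random.default_rng(7)
        worst = 0.0
        for _ in range(1000):
            n = int(rng.integers(3, 201))
            a = rng.normal(size=(n, 3)) * rng.uniform(1, 20)
            rot, trans = random_rigid_motion(rng)
            b = a @ rot.T + trans + rng.normal(size=(n, 3)) * rng.uniform(0, 2)
            r1, _, _ = kabsch_rmsd(a, b)
            worst = max(worst, abs(r1 - quaternion_rmsd(a, b)))
        assert worst < 1e-8

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            kabsch_rmsd(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_rotation_always_proper(self, rng):
        for _ in range(50):
            a = rng.normal(size=(10, 3))
            b = rng.normal(size=(10, 3))
            _, rot, _ = kabsch_rmsd(a, b)
            assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)


class TestComparePair:
    def _ensemble(self, rng, missing_in_b=()):
        ca = rng.normal(size=(60, 3)) * 6
        mask = np.ones(60, bool)
        for p in missing_in_b:
            mask[p - 1] = False
        rot, trans = random_rigid_motion(rng)
        return ensemble_from_traces(
            {"AAAA": ca, "BBBB": ca @ rot.T + trans},
            observed_masks={"BBBB": mask},
        )

    def test_self_comparison_zero(self, rng):
        ens = self._ensemble(rng)
        comp = compare_pair(ens, "AAAA_A", "AAAA_A")
        assert comp.rmsd == pytest.approx(0.0, abs=1e-6)
        assert comp.n_common == 60

    def test_missing_positions_excluded_from_common_set(self, rng):
        ens = self._ensemble(rng, missing_in_b=range(45, 53))
        comp = compare_pair(ens, "AAAA_A", "BBBB_A")
        assert comp.n_common == 52
        assert not set(range(45, 53)) & set(comp.per_position_dev)

    def test_position_restriction_and_monotone_n_common(self, rng):
        ens = self._ensemble(rng)
        full = compare_pair(ens, "AAAA_A", "BBBB_A")
        loops = set(range(10, 31))
        restricted = compare_pair(ens, "AAAA_A", "BBBB_A", positions=loops)
        assert restricted.n_common == 21 <= full.n_common
        assert set(restricted.per_position_dev) <= loops

    def test_symmetry(self, rng):
        ca = rng.normal(size=(30, 3)) * 6
        cb = ca + rng.normal(size=(30, 3)) * 0.5
        ens = ensemble_from_traces({"AAAA": ca, "BBBB": cb})
        r_ab = compare_pair(ens, "AAAA_A", "BBBB_A").rmsd
        r_ba = compare_pair(ens, "BBBB_A", "AAAA_A").rmsd
        assert r_ab == pytest.approx(r_ba, abs=1e-12)

    def test_rmsd_squared_is_mean_squared_deviation(self, rng):
        ca = rng.normal(size=(30, 3)) * 6
        cb = ca + rng.normal(size=(30, 3)) * 0.5
        ens = ensemble_from_traces({"AAAA": ca, "BBBB": cb})
        comp = compare_pair(ens, "AAAA_A", "BBBB_A")
        devs = np.array(list(comp.per_position_dev.values()))
        assert comp.rmsd**2 == pytest.approx(np.mean(devs**2), rel=1e-10)


class TestPairwiseAndMaxPair:
    def test_pair_count(self, rng):
        ca = rng.normal(size=(25, 3)) * 5
        traces = {f"C{i:03d}": ca + rng.normal(size=(25, 3)) * 0.1 for i in range(5)}
        ens = ensemble_from_traces(traces)
        assert len(pairwise_matrix(ens)) == 10

    def test_identical_conformers_all_zero_and_tie_rule(self, rng):
        ca = rng.normal(size=(25, 3)) * 5
        ens = ensemble_from_traces({f"C{i:03d}": ca for i in range(4)})
        comps = pairwise_matrix(ens)
        assert all(c.rmsd < 1e-6 for c in comps)
        mp = max_rmsd_pair(ens)
        assert mp.pair == ("C000_A", "C001_A")  # lexicographically smallest

    def test_perturbed_conformer_is_in_max_pair(self, rng):
        ca = rng.normal(size=(40, 3)) * 6
        traces = {f"C{i:03d}": ca + rng.normal(size=(40, 3)) * 0.05 for i in range(5)}
        traces["C002"] = traces["C002"].copy()
        traces["C002"][15:25] += 3.0  # one conformer carries a perturbed loop
        ens = ensemble_from_traces(traces)
        mp = max_rmsd_pair(ens)
        assert "C002_A" in mp.pair
        # exhaustive check: it really is the argmax
        assert mp.rmsd == pytest.approx(max(c.rmsd for c in pairwise_matrix(ens)))

    def test_max_is_upper_bound_of_all_pairs(self, rng):
        ca = rng.normal(size=(30, 3)) * 6
        traces = {f"C{i:03d}": ca + rng.normal(size=(30, 3)) * 0.3 for i in range(6)}
        ens = ensemble_from_traces(traces)
        mp = max_rmsd_pair(ens)
        assert all(mp.rmsd >= c.rmsd for c in pairwise_matrix(ens))

    def test_singleton_ensemble_raises(self, rng):
        ens = ensemble_from_traces({"AAAA": rng.normal(size=(20, 3))})
        with pytest.raises(ValueError):
            pairwise_matrix(ens)


class TestIdrExclusionAndProfile:
    def test_no_idrs_identical_to_max_pair(self, rng):
        ca = rng.normal(size=(50, 3)) * 6
        traces = {f"C{i:03d}": ca + rng.normal(size=(50, 3)) * 0.2 for i in range(5)}
        ens = ensemble_from_traces(traces)
        idrs = [IDRAnnotation(c.conformer_id, [], 0.0, 50) for c in ens.conformers]
        assert rmsd_excluding_union_idrs(ens, idrs) == max_rmsd_pair(ens)

    def test_displacement_confined_to_idr_drops_to_baseline(self, rng):
        base = rng.normal(size=(100, 3)) * 7
        noise = 0.05
        traces = {f"C{i:03d}": base + rng.normal(size=(100, 3)) * noise for i in range(5)}
        traces["C004"] = traces["C004"].copy()
        traces["C004"][49:70] += 4.0  # displacement confined to positions 50-70
        ens = ensemble_from_traces(traces)
        before = max_rmsd_pair(ens).rmsd
        idrs = [IDRAnnotation(c.conformer_id, [(50, 70)], 21 / 100, 100) for c in ens.conformers]
        after = rmsd_excluding_union_idrs(ens, idrs).rmsd
        assert before > 1.0
        assert after < 5 * noise  # baseline thermal noise

    def test_union_covering_almost_everything_raises(self, rng):
        ca = rng.normal(size=(30, 3)) * 5
        ens = ensemble_from_traces({"AAAA": ca, "BBBB": ca + 0.1})
        idrs = [IDRAnnotation(c.conformer_id, [(1, 28)], 28 / 30, 30) for c in ens.conformers]
        with pytest.raises(ValueError):
            rmsd_excluding_union_idrs(ens, idrs)

    def test_profile_zero_for_identical_and_peak_at_displaced_position(self, rng):
        ca = rng.normal(size=(40, 3)) * 6
        ens_same = ensemble_from_traces({f"C{i:03d}": ca for i in range(3)})
        prof = per_position_profile(ens_same)
        assert max(prof.values()) == pytest.approx(0.0, abs=1e-6)

        traces = {f"C{i:03d}": ca.copy() for i in range(4)}
        for i in (2, 3):  # displaced in half the conformers
            traces[f"C{i:03d}"][19] = traces[f"C{i:03d}"][19] + np.array([2.0, 0, 0])
        ens = ensemble_from_traces(traces)
        prof = per_position_profile(ens)
        peak = prof[20]
        assert all(peak > v for p, v in prof.items() if p != 20)

    def test_single_pair_profile_equals_pair_deviations(self, rng):
        ca = rng.normal(size=(25, 3)) * 6
        cb = ca + rng.normal(size=(25, 3)) * 0.4
        ens = ensemble_from_traces({"AAAA": ca, "BBBB": cb})
        prof = per_position_profile(ens)
        comp = compare_pair(ens, "AAAA_A", "BBBB_A")
        for pos, dev in comp.per_position_dev.items():
            assert prof[pos] == pytest.approx(dev, rel=1e-10)
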