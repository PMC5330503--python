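"""IDR detection from missing density and composition profiles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from confdiv.disorder import (
    composition_profile,
    detect_idrs,
    ensemble_disorder_summary,
    idr_residue_counts,
)
from confdiv.io import build_ensemble

from conftest import conf_from_ca


def _conf_with_missing(length, missing, name="MISS"):
    ca = np.cumsum(np.random.default_rng(0).normal(size=(length, 3)), axis=0) + 50
    mask = np.ones(length, bool)
    for p in missing:
        mask[p - 1] = False
    return conf_from_ca(ca, name=name, observed_mask=mask)


class TestDetectIdrs:
    @pytest.mark.parametrize(
        "missing, expected",
        [
            (range(45, 53), [(45, 52)]),  # run of 8, interior
            (range(45, 49), []),  # run of 4: below the >=5 threshold
            (range(10, 31), [(21, 30)]),  # overlaps N-terminal window: truncated
            (range(81, 101), []),  # entirely inside the C-terminal window
            (list(range(30, 36)) + list(range(60, 66)), [(30, 35), (60, 65)]),
        ],
    )
    def test_rule_on_l100(self, missing, expected):
        ann = detect_idrs(_conf_with_missing(100, missing))
        assert ann.segments == expected

    def test_discard_policy_drops_terminal_straddling_runs(self):
        conf = _conf_with_missing(100, range(10, 31))
        assert detect_idrs(conf, terminal_run_policy="truncate").segments == [(21, 30)]
        assert detect_idrs(conf, terminal_run_policy="discard").segments == []

    def test_short_sequence_flagged_empty(self):
        ann = detect_idrs(_conf_with_missing(40, range(15, 25)))
        assert ann.segments == [] and "sequence_too_short" in ann.flags

    def test_disorder_fraction_denominator(self):
        conf = _conf_with_missing(100, range(45, 55))
        full = detect_idrs(conf)
        assert full.disorder_fraction == pytest.approx(10 / 100)
        obs = detect_idrs(conf, fraction_denominator="observed")
        assert obs.disorder_fraction == pytest.approx(10 / 90)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=1, max_value=120), max_size=60), st.integers(60, 120))
    def test_segments_always_interior_and_long_enough(self, missing, length):
        missing = [m for m in missing if m <= length]
        ann = detect_idrs(_conf_with_missing(length, set(missing)))
        for s, e in ann.segments:
            assert e - s + 1 >= 5
            assert s >= 21 and e <= length - 20
        assert 0.0 <= ann.disorder_fraction <= 1.0
        assert (ann.disorder_fraction == 0) == (ann.segments == [])

    def test_depends_only_on_observed_flags(self):
        missing = range(45, 53)
        a = detect_idrs(_conf_with_missing(100, missing))
        b_conf = _conf_with_missing(100, missing)
        for r in b_conf.residues:  # move every coordinate: annotation unchanged
            if r.observed:
                r.ca_xyz = r.ca_xyz + 100.0
        b = detect_idrs(b_conf)
        assert a.segments == b.segments


class TestEnsembleSummary:
    def _ensemble(self, missing_per_conf):
        confs = [
            _conf_with_missing(100, missing, name=f"C{i:03d}")
            for i, missing in enumerate(missing_per_conf)
        ]
        return build_ensemble(confs, "p")

    def test_percent_disordered(self):
        ens = self._ensemble([range(40, 50), range(40, 50)] + [()] * 6)
        idrs = [detect_idrs(c) for c in ens.conformers]
        s = ensemble_disorder_summary(ens, idrs)
        assert s["percent_disordered_conformers"] == pytest.approx(25.0)
        assert s["longest_idr_length"] == 10

    def test_no_idrs(self):
        ens = self._ensemble([()] * 5)
        s = ensemble_disorder_summary(ens, [detect_idrs(c) for c in ens.conformers])
        assert s["percent_disordered_conformers"] == 0.0
        assert s["max_disorder_fraction"] == 0.0

    def test_position_missing_everywhere_is_not_a_transition(self):
        ens = self._ensemble([range(40, 50)] * 5)  # missing in every conformer
        s = ensemble_disorder_summary(ens, [detect_idrs(c) for c in ens.conformers])
        assert s["n_transition_positions"] == 0
        ens2 = self._ensemble([range(40, 50)] * 4 + [()])
        s2 = ensemble_disorder_summary(ens2, [detect_idrs(c) for c in ens2.conformers])
        assert s2["n_transition_positions"] == 10


class TestCompositionProfile:
    REF = {aa: 0.05 for aa in "ACDEFGHIKLMNPQRSTVWY"}

    def test_query_equal_to_reference_gives_zero_enrichment(self):
        counts = {aa: 50 for aa in self.REF}
        prof = composition_profile(counts, self.REF, n_boot=200, seed=1)
        np.testing.assert_allclose(prof.table["enrichment"], 0.0, atol=1e-12)

    def test_doubled_frequency_gives_enrichment_one(self):
        counts = {aa: 100 for aa in self.REF}
        counts["P"] = 2000  # f_P = 2000/3900, ref 0.05
        prof = composition_profile(counts, self.REF, n_boot=200, seed=1)
        fq = 2000 / 3900
        assert prof.enrichment("P") == pytest.approx((fq - 0.05) / 0.05)
        # the normalization identity: sum f_ref * (enrichment + 1) = 1
        t = prof.table
        assert float((t["f_ref"] * (t["enrichment"] + 1)).sum()) == pytest.approx(1.0)

    def test_ci_brackets_enrichment_and_is_reproducible(self):
        rng = np.random.default_rng(5)
        counts = dict(zip(self.REF, rng.multinomial(2000, list(self.REF.values()))))
        p1 = composition_profile(counts, self.REF, n_boot=500, seed=42)
        p2 = composition_profile(counts, self.REF, n_boot=500, seed=42)
        assert (p1.table["ci_low"] <= p1.table["enrichment"]).all()
        assert (p1.table["enrichment"] <= p1.table["ci_high"]).all()
        assert p1.table.equals(p2.table)

    def test_null_coverage_of_zero(self):
        """CIs from queries sampled under the reference contain 0 >= 93% of
        the time at the 95% level."""
        rng = np.random.default_rng(11)
        ref_f = np.array(list(self.REF.values()))
        hits = total = 0
        for rep in range(20):
            counts = dict(zip(self.REF, rng.multinomial(3000, ref_f)))
            prof = composition_profile(counts, self.REF, n_boot=2000, seed=1000 + rep)
            t = prof.table.dropna()
            hits += int(((t["ci_low"] <= 0) & (0 <= t["ci_high"])).sum())
            total += len(t)
        assert hits / total >= 0.93

    def test_zero_reference_frequency_flagged(self):
        ref = dict(self.REF)
        ref["W"] = 0.0
        ref["A"] = 0.10
        prof = composition_profile({aa: 10 for aa in ref}, ref, n_boot=100, seed=0)
        assert any("zero_reference_frequency" in f for f in prof.flags)
        assert np.isnan(prof.table.loc["W", "enrichment"])

    def test_empty_query_raises(self):
        with pytest.raises(ValueError):
            composition_profile({}, self.REF, n_boot=10, seed=0)

    def test_idr_residue_counts(self):
        confs = [
            _conf_with_missing(100, range(41, 51), name="C000"),
            _conf_with_missing(100, (), name="C001"),
        ]
        ens = build_ensemble(confs, "p")
        idrs = [detect_idrs(c) for c in ens.conformers]
        counts = idr_residue_counts(ens, idrs)
        assert sum(counts.values()) == 10  # the 10 IDR residues of conformer 0
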