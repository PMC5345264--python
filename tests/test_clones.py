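"""Bisulfite clone calling: conversion, alignment, QC, genotype tests."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shoremeth import clones as cl
from shoremeth.config import SimulationConfig
from shoremeth.errors import LowIdentityError
from shoremeth.simulate import (ReferenceRegion, SubjectRecord,
                                default_reference, simulate_clones)


@pytest.fixture
def tiny_ref():
    # CpGs at 1 and 6; non-CpG Cs at 4 and 9
    return ReferenceRegion("tiny", "ACGTCACGTCA", cpg_sites=(1, 6))


class TestBisulfiteConvert:
    def test_unmethylated_image(self):
        ref = ReferenceRegion("r", "ACGTC", cpg_sites=(1,))
        assert cl.bisulfite_convert_reference(ref, [False]) == "ATGTT"

    def test_methylated_cpg_retained(self):
        ref = ReferenceRegion("r", "ACGTC", cpg_sites=(1,))
        assert cl.bisulfite_convert_reference(ref, [True]) == "ACGTT"

    def test_sequence_without_c_unchanged(self):
        ref = ReferenceRegion("r", "ACGTAGGTA", cpg_sites=(1,))
        out = cl.bisulfite_convert_reference(ref, [True])
        assert out[2:] == "GTAGGTA"  # nothing besides cytosines changes

    def test_state_length_mismatch(self, tiny_ref):
        with pytest.raises(ValueError):
            cl.bisulfite_convert_reference(tiny_ref, [True])


class TestAlignClone:
    def test_converted_image_identity_one(self, reference):
        img = cl.bisulfite_convert_reference(reference, [False] * reference.n_sites)
        aln = cl.align_clone(img, reference)
        assert aln.identity == pytest.approx(1.0)
        assert aln.orientation == "forward"
        assert aln.n_columns == len(reference.sequence)

    def test_internal_deletion_single_gap(self, reference):
        img = cl.bisulfite_convert_reference(reference, [True] * reference.n_sites)
        mutated = img[:50] + img[55:]  # one internal 5-bp deletion
        aln = cl.align_clone(mutated, reference)
        uncovered = [p for p in range(len(reference.sequence))
                     if aln.ref_to_read.get(p) is None]
        assert len(uncovered) == 5
        assert max(uncovered) - min(uncovered) == 4  # contiguous: one gap

    def test_random_sequence_rejected(self, reference):
        rng = np.random.default_rng(0)
        for _ in range(5):
            rand = "".join(rng.choice(list("ACGT"), len(reference.sequence)))
            with pytest.raises(LowIdentityError):
                cl.align_clone(rand, reference)

    def test_reverse_complement_detected(self, reference):
        from Bio.Seq import Seq
        img = cl.bisulfite_convert_reference(reference, [True] * reference.n_sites)
        aln = cl.align_clone(str(Seq(img).reverse_complement()), reference)
        assert aln.orientation == "reverse"
        assert aln.identity == pytest.approx(1.0)

    def test_empty_sequence_errors(self, reference):
        with pytest.raises(ValueError):
            cl.align_clone("", reference)


class TestCallCpgs:
    @pytest.mark.parametrize("base,expected", [
        ("C", cl.MET), ("T", cl.UNMET), ("A", cl.MISSING), (None, cl.MISSING)])
    def test_decision_rule(self, tiny_ref, base, expected):
        aln = cl.CloneAlignment("c", {1: base, 6: "T"}, 1.0, 11, "forward")
        assert cl.call_cpgs(aln, tiny_ref)[0] == expected


class TestConversionEfficiency:
    def test_all_converted(self, tiny_ref):
        aln = cl.CloneAlignment("c", {4: "T", 9: "T"}, 1.0, 11, "forward")
        assert cl.conversion_efficiency(aln, tiny_ref) == 1.0

    def test_half_converted(self, tiny_ref):
        aln = cl.CloneAlignment("c", {4: "T", 9: "C"}, 1.0, 11, "forward")
        assert cl.conversion_efficiency(aln, tiny_ref) == 0.5

    def test_none_covered_is_undefined(self, tiny_ref):
        aln = cl.CloneAlignment("c", {1: "C"}, 1.0, 11, "forward")
        assert cl.conversion_efficiency(aln, tiny_ref) is None


class TestBuildMatrix:
    def _call(self, cid, calls, eff=1.0, qc=True):
        return cl.CloneCall(cid, calls, eff, 1.0, qc)

    def test_site_percent(self):
        calls = [self._call(f"c{i}", (cl.MET if i < 9 else cl.UNMET, cl.UNMET))
                 for i in range(15)]
        m = cl.build_matrix(calls, "s", "tumour", "GG", 2)
        assert m.percent_methylated()[0] == pytest.approx(60.0)
        assert m.percent_methylated()[1] == 0.0

    def test_failing_clone_excluded(self):
        calls = [self._call("a", (cl.MET,)), self._call("b", (cl.MET,), 0.5, False)]
        m = cl.build_matrix(calls, "s", "tumour", "GG", 1)
        assert m.clone_ids == ["a"]

    def test_all_missing_site_is_nan(self):
        calls = [self._call("a", (cl.MET, cl.MISSING)),
                 self._call("b", (cl.UNMET, cl.MISSING))]
        m = cl.build_matrix(calls, "s", "tumour", "GG", 2)
        assert np.isnan(m.percent_methylated()[1])

    def test_zero_passing_names_thresholds(self):
        calls = [self._call("a", (cl.MET,), 0.5, False)]
        with pytest.raises(ValueError, match="threshold"):
            cl.build_matrix(calls, "s", "tumour", "GG", 1)


def _matrix(genotype, meth_counts, n_clones=20, n_sites=2):
    """Matrix with a given number of methylated clones per site."""
    rows = []
    for i in range(n_clones):
        rows.append([cl.MET if i < meth_counts[s] else cl.UNMET
                     for s in range(n_sites)])
    return cl.MethylationMatrix("s" + genotype, "normal_colon", genotype,
                                [f"c{i}" for i in range(n_clones)],
                                np.array(rows, dtype="<U1"))


class TestCompareSitesByGenotype:
    def test_identical_proportions_statistic_zero(self):
        mats = [_matrix("GG", [10, 10]), _matrix("GA", [10, 10])]
        for t in cl.compare_sites_by_genotype(mats):
            assert t.statistic == pytest.approx(0.0)
            assert t.p_value == pytest.approx(1.0)

    def test_perfect_separation_hand_value(self):
        """[[10,0],[0,10]] gives chi-square 20 with df 1."""
        mats = [_matrix("GG", [10, 10], n_clones=10),
                _matrix("GA", [0, 0], n_clones=10)]
        t = cl.compare_sites_by_genotype(mats)[0]
        assert t.statistic == pytest.approx(20.0)
        assert t.df == 1

    def test_degenerate_table_not_computable(self):
        mats = [_matrix("GG", [20, 10]), _matrix("GA", [20, 5])]
        tests = cl.compare_sites_by_genotype(mats)
        assert not tests[0].computable  # unmethylated row all zero
        assert tests[1].computable

    def test_clone_order_permutation_invariant(self, rng):
        mats = [_matrix("GG", [12, 5]), _matrix("GA", [3, 9])]
        base = cl.compare_sites_by_genotype(mats)
        for m in mats:
            perm = rng.permutation(len(m.clone_ids))
            m.calls = m.calls[perm]
            m.clone_ids = [m.clone_ids[i] for i in perm]
        after = cl.compare_sites_by_genotype(mats)
        for a, b in zip(base, after):
            assert a.statistic == pytest.approx(b.statistic)

    def test_genotype_dependent_probabilities_detected(self, reference):
        """Simulated p = 0.9/0.5/0.1 at n=200 clones: p < 0.01 at every site."""
        cfg = SimulationConfig(seed=21)
        cfg.clone_params.conversion_failure_rate = 0.0
        cfg.clone_params.sequencing_error_rate = 0.0
        cfg.clone_params.n_clones_min = cfg.clone_params.n_clones_max = 200
        cfg.clone_params.methylation_prob = {
            ("normal_colon", "GG"): 0.9, ("normal_colon", "GA"): 0.5,
            ("normal_colon", "AA"): 0.1}
        rng = np.random.default_rng(2)
        mats = []
        for g in ("GG", "GA", "AA"):
            subj = SubjectRecord(f"{g}1", g, 60.0, "male", 2, "MSS/MSI-L",
                                 False, False,
                                 {"PBMC": 30.0, "normal_colon": 30.0,
                                  "tumour": 30.0})
            cs = simulate_clones(subj, "normal_colon", reference, cfg, rng=rng)
            mats.append(cl.MethylationMatrix(
                cs.sample_id, "normal_colon", g, cs.names,
                np.where(cs.truth, cl.MET, cl.UNMET).astype("<U1")))
        for t in cl.compare_sites_by_genotype(mats):
            assert t.computable and t.p_value < 0.01


@settings(deadline=None, derandomize=True, max_examples=200)
@given(st.lists(st.integers(0, 30), min_size=6, max_size=6))
def test_chi_square_matches_brute_force_oracle(cells):
    """Sampled 2x3 tables with cells <= 30 agree with a hand Sum((O-E)^2/E)."""
    table = np.array(cells, dtype=float).reshape(2, 3)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return
    stat, df, p = cl._chi_square(table)
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    oracle = float(((table - expected) ** 2 / expected).sum())
    assert stat == pytest.approx(oracle, abs=1e-10)
    assert df == 2


def test_qc_threshold_monotone(reference):
    """Lowering the conversion threshold never loses retained clones."""
    cfg = SimulationConfig(seed=13)
    cfg.clone_params.conversion_failure_rate = 0.08  # stress QC
    subj = SubjectRecord("s1", "GG", 60.0, "male", 2, "MSS/MSI-L", False, False,
                         {"PBMC": 30.0, "normal_colon": 30.0, "tumour": 30.0})
    cs = simulate_clones(subj, "tumour", reference, cfg,
                         rng=np.random.default_rng(3))
    records = list(zip(cs.names, cs.sequences))
    retained = []
    for thresh in (0.99, 0.95, 0.90, 0.50, 0.0):
        calls = cl.process_clones(records, reference, min_conversion=thresh)
        retained.append(sum(c.qc_pass for c in calls))
    assert retained == sorted(retained)


def test_error_free_round_trip(reference, clean_config):
    """Error-free clones reproduce the generating states exactly."""
    subj = SubjectRecord("s1", "GA", 60.0, "male", 2, "MSS/MSI-L", False, False,
                         {"PBMC": 30.0, "normal_colon": 30.0, "tumour": 30.0})
    cs = simulate_clones(subj, "normal_colon", reference, clean_config,
                         rng=np.random.default_rng(5))
    calls = cl.process_clones(list(zip(cs.names, cs.sequences)), reference)
    assert all(c.qc_pass for c in calls)
    assert all(c.conversion_efficiency == 1.0 for c in calls)
    called = np.array([[x == cl.MET for x in c.calls] for c in calls])
    assert (called == cs.truth).all()
    assert not any(cl.MISSING in c.calls for c in calls)


def test_clone_sum_contingency_counts():
    mats = [_matrix("GG", [20, 20]), _matrix("GA", [0, 0])]
    table, labels, res = cl.clone_sum_contingency(mats)
    # GG clones all have sum 2, GA clones sum 0
    assert labels == ["0", "2"]
    assert table[labels.index("2"), 0] == 20
    assert table[labels.index("0"), 1] == 20
    assert res.computable


def test_lollipop_rendering():
    m = _matrix("GG", [1, 0], n_clones=2)
    art = cl.lollipop(m)
    assert "●○" in art and "○○" in art
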