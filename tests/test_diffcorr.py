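"""Differential-correlation stage: Pearson matrices, ΔCC, pair selection."""

import logging
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from corrshift import (
    CorrelationMatrixPair, ExpressionMatrix, PathwaySet, SampleGroups,
    compute_pathway_correlations, correlation_matrix, delta_cc_matrix,
    make_record, pathway_gene_subset, select_shifted_pairs,
)

from _reference import WNT_DEGS


def hand_pearson(x, y):
    """Textbook product-moment formula, written independently of numpy.corrcoef."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def _matrix(values, genes, samples):
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


class TestPathwayGeneSubset:
    def test_triple_intersection_sorted(self, tiny_matrix):
        ps = PathwaySet("p", "x", frozenset({"GA", "GB", "GZ"}))
        assert pathway_gene_subset(ps, {"GB", "GA", "GQ"}, tiny_matrix) == ["GA", "GB"]

    def test_empty_intersection_warns(self, tiny_matrix, caplog):
        ps = PathwaySet("p", "x", frozenset({"GX"}))
        with caplog.at_level(logging.WARNING, logger="corrshift"):
            subset = pathway_gene_subset(ps, {"GX"}, tiny_matrix)
        assert subset == []
        assert any("skipped" in rec.message for rec in caplog.records)

    def test_reference_wnt_gene_list(self):
        """A pathway carrying the reference cohort's 17 Wnt-pathway DEGs
        yields the full 17-gene subset when all are measured DEGs."""
        samples = [f"s{i}" for i in range(4)]
        data = pd.DataFrame(1.0, index=sorted(WNT_DEGS), columns=samples)
        matrix = ExpressionMatrix(data)
        ps = PathwaySet("Wnt signaling pathway", "kegg", frozenset(WNT_DEGS))
        subset = pathway_gene_subset(ps, set(WNT_DEGS), matrix)
        assert subset == sorted(WNT_DEGS)
        assert len(subset) == 17


class TestCorrelationMatrix:
    def test_unit_diagonal(self, tiny_matrix):
        C, mask = correlation_matrix(tiny_matrix, ["GA", "GB", "GC"], tiny_matrix.sample_ids)
        assert np.array_equal(np.diag(C), [1.0, 1.0, 1.0])
        assert mask.all()

    def test_perfect_anticorrelation(self):
        m = _matrix([[1, 2, 3, 4], [8, 6, 4, 2]], ["a", "b"], list("wxyz"))
        C, _ = correlation_matrix(m, ["a", "b"], list("wxyz"))
        assert C[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_hand_formula_on_three_by_six_fixture(self, tiny_matrix):
        genes, samples = ["GA", "GB", "GC"], tiny_matrix.sample_ids
        C, _ = correlation_matrix(tiny_matrix, genes, samples)
        X = tiny_matrix.values_for(genes, samples)
        for i in range(3):
            for j in range(3):
                assert C[i, j] == pytest.approx(hand_pearson(X[i], X[j]), abs=1e-12)

    def test_zero_variance_gene_masked(self):
        m = _matrix([[1, 1, 1, 1], [1, 2, 3, 4]], ["flat", "var"], list("wxyz"))
        C, mask = correlation_matrix(m, ["flat", "var"], list("wxyz"))
        assert not mask[0, 1] and not mask[0, 0]
        assert np.isnan(C[0, 1]) and np.isnan(C[0, 0])
        assert C[1, 1] == 1.0

    def test_too_few_samples_rejected(self, tiny_matrix):
        with pytest.raises(ValueError):
            correlation_matrix(tiny_matrix, ["GA", "GB"], ["S0", "S1"])

    def test_spearman_matches_scipy(self):
        rng = np.random.default_rng(4)
        values = rng.gamma(2.0, 10.0, size=(3, 12))
        m = _matrix(values, ["a", "b", "c"], [f"s{i}" for i in range(12)])
        C, _ = correlation_matrix(m, ["a", "b", "c"], m.sample_ids, method="spearman")
        expected = stats.spearmanr(values.T).statistic
        assert np.allclose(C, expected, atol=1e-12)

    def test_log2_space_flag(self):
        rng = np.random.default_rng(9)
        values = rng.gamma(2.0, 10.0, size=(2, 8))
        m = _matrix(values, ["a", "b"], [f"s{i}" for i in range(8)])
        C, _ = correlation_matrix(m, ["a", "b"], m.sample_ids, space="log2")
        expected = np.corrcoef(np.log2(values + 1.0))
        assert C[0, 1] == pytest.approx(expected[0, 1], abs=1e-12)

    def test_invariant_to_sample_order(self, tiny_matrix):
        genes = ["GA", "GB", "GC"]
        C1, _ = correlation_matrix(tiny_matrix, genes, ["S0", "S1", "S2", "S3", "S4", "S5"])
        C2, _ = correlation_matrix(tiny_matrix, genes, ["S5", "S2", "S4", "S0", "S1", "S3"])
        assert np.allclose(C1, C2, atol=1e-12)


def _pair_from(cc_control, cc_cancer, genes, pathway="pw"):
    cc_control = np.asarray(cc_control, dtype=float)
    cc_cancer = np.asarray(cc_cancer, dtype=float)
    valid = np.ones(cc_control.shape, dtype=bool)
    return CorrelationMatrixPair(pathway, list(genes), cc_control, cc_cancer, valid, valid)


class TestDeltaCC:
    def test_identical_matrices_give_zero(self):
        C = np.array([[1.0, 0.4], [0.4, 1.0]])
        delta, mask = delta_cc_matrix(_pair_from(C, C.copy(), ["a", "b"]))
        assert np.allclose(delta, 0.0) and mask.all()

    def test_elementwise_arithmetic(self):
        c0 = np.array([[1.0, 0.5], [0.5, 1.0]])
        c1 = np.array([[1.0, -0.2], [-0.2, 1.0]])
        delta, _ = delta_cc_matrix(_pair_from(c0, c1, ["a", "b"]))
        assert delta[0, 1] == pytest.approx(-0.7)

    def test_shape_mismatch_rejected(self):
        pair = _pair_from(np.eye(2), np.eye(2), ["a", "b"])
        pair.cc_cancer = np.eye(3)
        with pytest.raises(ValueError):
            delta_cc_matrix(pair)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_delta_bounded_on_random_data(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.gamma(2.0, 20.0, size=(4, 10))
        m = _matrix(values, list("abcd"), [f"s{i}" for i in range(10)])
        groups = SampleGroups({f"s{i}": ("control" if i < 5 else "cancer") for i in range(10)})
        pair = compute_pathway_correlations(m, groups, "pw", list("abcd"))
        delta, mask = delta_cc_matrix(pair)
        assert np.all(np.abs(delta[mask]) <= 2.0 + 1e-12)


class TestSelectShiftedPairs:
    @pytest.mark.parametrize("delta,selected", [(0.70, True), (-0.70, True), (0.69, False), (-0.69, False)])
    def test_boundary_inclusive(self, delta, selected):
        c0 = np.array([[1.0, 0.0], [0.0, 1.0]])
        c1 = np.array([[1.0, delta], [delta, 1.0]])
        records = select_shifted_pairs(_pair_from(c0, c1, ["a", "b"]))
        assert bool(records) is selected
        if records:
            assert records[0].delta_cc == pytest.approx(delta)
            assert records[0].pathways == {"pw"}

    def test_matches_brute_force_scan_on_six_genes(self):
        rng = np.random.default_rng(12)
        genes = [f"g{i}" for i in range(6)]
        c0 = np.clip((lambda A: (A + A.T) / 2)(rng.uniform(-1, 1, (6, 6))), -1, 1)
        c1 = np.clip((lambda A: (A + A.T) / 2)(rng.uniform(-1, 1, (6, 6))), -1, 1)
        np.fill_diagonal(c0, 1.0)
        np.fill_diagonal(c1, 1.0)
        pair = _pair_from(c0, c1, genes)
        got = {r.key for r in select_shifted_pairs(pair, cutoff=0.7)}
        expected = {
            tuple(sorted((genes[i], genes[j])))
            for i in range(6) for j in range(i + 1, 6)
            if abs(c1[i, j] - c0[i, j]) >= 0.7
        }
        assert got == expected
        assert len(list(expected)) > 0  # the random fixture does exercise selection

    def test_lowering_cutoff_never_removes_pairs(self):
        rng = np.random.default_rng(3)
        c0 = np.eye(5)
        c1 = np.eye(5)
        idx = np.triu_indices(5, 1)
        vals = rng.uniform(-1, 1, len(idx[0]))
        c1[idx] = vals
        c1[(idx[1], idx[0])] = vals
        pair = _pair_from(c0, c1, [f"g{i}" for i in range(5)])
        strict = {r.key for r in select_shifted_pairs(pair, cutoff=0.8)}
        loose = {r.key for r in select_shifted_pairs(pair, cutoff=0.4)}
        assert strict <= loose

    def test_selection_invariant_to_gene_order(self, small_cohort):
        matrix, groups, sets, _ = small_cohort
        genes = sorted(sets[0].genes)
        fwd = compute_pathway_correlations(matrix, groups, "pw", genes)
        rev = compute_pathway_correlations(matrix, groups, "pw", list(reversed(genes)))
        assert {r.key for r in select_shifted_pairs(fwd, 0.5)} == \
            {r.key for r in select_shifted_pairs(rev, 0.5)}


def test_make_record_normalizes_member_order():
    rec = make_record("ZZZ", "AAA", 0.5, -0.3, ["pw"])
    assert (rec.gene_a, rec.gene_b) == ("AAA", "ZZZ")
    assert rec.delta_cc == pytest.approx(-0.8)
    with pytest.raises(ValueError):
        make_record("AAA", "AAA", 0.1, 0.2)
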