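"""Scoring criteria, their algebraic identities, and the greedy search."""

import numpy as np
import pytest

from groupjmi.criteria import (
    CriterionSpec,
    encode_labelset,
    forward_select,
    score_group_jmi,
    score_group_jmi_decomposed,
    score_joint_jmi,
    score_mim_br,
    score_single_jmi,
)
from groupjmi.mi_core import DataError, DiscretizedMatrix, entropy, mutual_information
from groupjmi.quantization import GroupingConfig, quantize_output_space
from groupjmi.synthetic import gen_multilabel, make_spec

from conftest import naive_forward_select, naive_joint_pair_mi


def xor_fixture(seed, n=2000, n_noise=10):
    """Single XOR-driven target, one complementary pair, noise features."""
    spec = make_spec(n, 2 + n_noise, 1, n_xor_pairs=1, label_noise=0.05,
                     seed=seed)
    data = gen_multilabel(spec)
    disc = DiscretizedMatrix.from_data(data.X, n_bins=5)
    return disc, data.Y


class TestMimBR:
    def test_feature_equal_to_target_scores_its_entropy(self, rng):
        y = rng.integers(0, 3, 100)
        assert score_mim_br(y, y[:, None]) == pytest.approx(entropy(y), abs=1e-12)

    def test_independent_noise_scores_zero(self):
        xk = np.array([0, 0, 1, 1])
        Y = np.array([[0], [1], [0], [1]])
        assert score_mim_br(xk, Y) == 0.0

    def test_xor_member_blind_spot(self):
        # the imbalanced pair member is marginally invisible to MIM-BR
        disc, Y = xor_fixture(seed=1)
        partner = score_mim_br(disc.column(1), Y)
        visible = score_mim_br(disc.column(0), Y)
        assert partner < 0.01
        assert visible > 10 * partner


class TestSingleJMI:
    def test_duplicate_feature_adds_nothing(self, rng):
        xj = rng.integers(0, 3, 200)
        Y = rng.integers(0, 2, (200, 3))
        dup = score_single_jmi(xj, [xj], Y)
        base = sum(mutual_information(xj, Y[:, i]) for i in range(3))
        assert dup == pytest.approx(base, abs=1e-12)

    def test_chain_rule_reduction_for_independent_selected(self, rng):
        # I(Xj Xk; Y) = I(Xj; Y) + I(Xk; Y | Xj)
        xj = rng.integers(0, 2, 150)
        xk = rng.integers(0, 2, 150)
        y = rng.integers(0, 2, 150)
        from groupjmi.mi_core import conditional_mi
        assert score_single_jmi(xk, [xj], y[:, None]) == pytest.approx(
            mutual_information(xj, y) + conditional_mi(xk, y, xj), abs=1e-10)

    def test_xor_partner_beats_noise_once_mate_selected(self):
        disc, Y = xor_fixture(seed=2)
        sel = [disc.column(0)]
        partner_score = score_single_jmi(disc.column(1), sel, Y)
        noise_scores = [score_single_jmi(disc.column(j), sel, Y)
                        for j in range(2, disc.n_features)]
        assert partner_score > max(noise_scores)


class TestLabelset:
    def test_basic_encoding(self):
        Y = np.array([[0, 0], [0, 1], [0, 0]])
        np.testing.assert_array_equal(encode_labelset(Y), [0, 1, 0])

    def test_full_alphabet(self):
        Y = np.array(list(np.ndindex(2, 2, 2)))
        assert len(np.unique(encode_labelset(Y))) == 8

    def test_all_rows_distinct(self, rng):
        Y = np.eye(20, dtype=int)
        assert len(np.unique(encode_labelset(Y))) == 20

    def test_continuous_targets_rejected(self):
        with pytest.raises(DataError, match="categorical"):
            encode_labelset(np.array([[0.5], [1.2]]))


class TestJointJMI:
    def test_single_target_equals_single_jmi(self, rng):
        xj, xk = rng.integers(0, 3, 100), rng.integers(0, 3, 100)
        Y = rng.integers(0, 2, (100, 1))
        assert score_joint_jmi(xk, [xj], Y) == pytest.approx(
            score_single_jmi(xk, [xj], Y), abs=1e-12)

    def test_duplicated_label_column_is_invisible(self, rng):
        xj, xk = rng.integers(0, 2, 120), rng.integers(0, 2, 120)
        y = rng.integers(0, 2, 120)
        Y2 = np.column_stack([y, y])
        assert score_joint_jmi(xk, [xj], Y2) == pytest.approx(
            score_joint_jmi(xk, [xj], y[:, None]), abs=1e-12)

    def test_matches_naive_oracle(self, rng):
        for _ in range(20):
            xj = rng.integers(0, 2, 40)
            xk = rng.integers(0, 3, 40)
            Y = rng.integers(0, 2, (40, 2))
            expected = naive_joint_pair_mi(xj, xk, encode_labelset(Y))
            assert score_joint_jmi(xk, [xj], Y) == pytest.approx(
                expected, abs=1e-12)


class TestGroupJMIEquivalences:
    def test_bijective_singleton_groups_reduce_to_single_jmi(self, rng):
        # pseudo-targets that relabel each target bijectively
        xj, xk = rng.integers(0, 3, 150), rng.integers(0, 3, 150)
        Y = rng.integers(0, 2, (150, 3))
        relabeled = (1 - Y) * 7 + 1  # bijection per column
        assert score_group_jmi(xk, [xj], relabeled) == pytest.approx(
            score_single_jmi(xk, [xj], Y), abs=1e-10)

    def test_pipeline_singleton_identity_quantization(self, rng):
        y = rng.integers(0, 3, 100)[:, None]
        qt = quantize_output_space(y, GroupingConfig(pot=1.0, noc=3, seed=0))
        xj, xk = rng.integers(0, 2, 100), rng.integers(0, 2, 100)
        assert score_group_jmi(xk, [xj], qt) == pytest.approx(
            score_single_jmi(xk, [xj], y), abs=1e-10)

    def test_all_targets_group_with_full_noc_reduces_to_joint_jmi(self, rng):
        Y = rng.integers(0, 2, (120, 3))
        n_labelsets = len(np.unique(Y, axis=0))
        qt = quantize_output_space(
            Y, GroupingConfig(pot=1.0, noc=n_labelsets, seed=0, n_groups=1))
        xj, xk = rng.integers(0, 3, 120), rng.integers(0, 3, 120)
        assert score_group_jmi(xk, [xj], qt) == pytest.approx(
            score_joint_jmi(xk, [xj], Y), abs=1e-10)


class TestDecomposition:
    def test_constant_candidate_has_zero_terms(self, rng):
        xj = rng.integers(0, 2, 80)
        qt = rng.integers(1, 4, (80, 2))
        xk = np.zeros(80, dtype=int)
        score, rel, red, comp = score_group_jmi_decomposed(xk, [xj], qt)
        assert rel == red == comp == 0.0 == score

    def test_redundancy_of_duplicate_is_source_entropy(self, rng):
        xj = rng.integers(0, 3, 100)
        qt = rng.integers(1, 3, (100, 4))
        _, _, red, _ = score_group_jmi_decomposed(xj.copy(), [xj], qt)
        # one selected feature, 4 pseudo-targets: red = 4 * I(Xk;Xj) / 1
        assert red == pytest.approx(4 * entropy(xj), abs=1e-10)

    def test_greedy_argmax_matches_plain_group_jmi(self, rng):
        # ranking equivalence of the sum form and the decomposed form
        for trial in range(20):
            n = int(rng.integers(30, 200))
            d = int(rng.integers(3, 9))
            m = int(rng.integers(1, 5))
            X = rng.integers(0, 3, (n, d))
            Y = rng.integers(0, 2, (n, m))
            qt = quantize_output_space(
                Y, GroupingConfig(pot=0.6, noc=3, seed=trial))
            selected: list[int] = []
            for _ in range(d):
                s3 = np.full(d, -np.inf)
                s8 = np.full(d, -np.inf)
                sel_cols = [X[:, s] for s in selected]
                for j in range(d):
                    if j in selected:
                        continue
                    if selected:
                        s3[j] = score_group_jmi(X[:, j], sel_cols, qt)
                    s8[j], *_ = score_group_jmi_decomposed(
                        X[:, j], sel_cols, qt)
                    if not selected:
                        s3[j] = s8[j]  # both use the relevancy-only first step
                assert int(np.argmax(s3)) == int(np.argmax(s8))
                selected.append(int(np.argmax(s3)))


class TestForwardSelect:
    def test_single_feature_any_criterion(self, rng):
        X = rng.integers(0, 2, (50, 1))
        Y = rng.integers(0, 2, (50, 2))
        for name in ("mim-br", "single-jmi", "joint-jmi"):
            state = forward_select(X, Y, 1, CriterionSpec(name))
            assert state.selected == [0]

    def test_k_bounds(self, rng):
        X = rng.integers(0, 2, (30, 3))
        Y = rng.integers(0, 2, (30, 2))
        with pytest.raises(ValueError):
            forward_select(X, Y, 4, CriterionSpec("mim-br"))
        state = forward_select(X, Y, 0, CriterionSpec("mim-br"))
        assert state.selected == [] and state.trace == []

    def test_mim_br_is_descending_relevancy_order(self, rng):
        X = rng.integers(0, 3, (200, 6))
        Y = rng.integers(0, 2, (200, 2))
        state = forward_select(X, Y, 6, CriterionSpec("mim-br"))
        rel = [sum(mutual_information(X[:, j], Y[:, i]) for i in range(2))
               for j in range(6)]
        assert state.selected == sorted(range(6), key=lambda j: (-rel[j], j))

    def test_noc_one_collapses_to_tiebreak_order(self, rng):
        X = rng.integers(0, 3, (80, 5))
        Y = rng.integers(0, 2, (80, 3))
        spec = CriterionSpec("group-jmi", GroupingConfig(pot=0.5, noc=1, seed=0))
        state = forward_select(X, Y, 5, spec)
        assert state.selected == [0, 1, 2, 3, 4]
        assert all(rec.score == 0.0 for rec in state.trace)

    def test_trace_invariants(self, rng):
        X = rng.integers(0, 3, (100, 7))
        Y = rng.integers(0, 2, (100, 3))
        spec = CriterionSpec("group-jmi", GroupingConfig(seed=4))
        state = forward_select(X, Y, 4, spec)
        assert len(state.trace) == 4
        assert len(set(state.selected)) == 4
        assert sorted(state.selected + state.candidates) == list(range(7))
        for rec in state.trace:
            assert np.isfinite(rec.score)
            assert all(np.isfinite(v) for v in rec.candidate_scores.values())
            assert rec.relevancy is not None  # group criteria decompose

    @pytest.mark.parametrize("criterion", ["mim-br", "single-jmi", "joint-jmi",
                                           "group-jmi"])
    def test_matches_naive_rescoring_oracle(self, criterion, rng):
        for trial in range(5):
            n = int(rng.integers(30, 120))
            d = int(rng.integers(2, 7))
            X = rng.integers(0, 3, (n, d))
            Y = rng.integers(0, 2, (n, 3))
            if criterion == "group-jmi":
                qt = quantize_output_space(
                    Y, GroupingConfig(pot=0.7, noc=3, seed=trial))
                spec = CriterionSpec("group-jmi",
                                     GroupingConfig(pot=0.7, noc=3, seed=trial))
                state = forward_select(X, qt, d, spec)
                expected, scores = naive_forward_select(
                    X, Y, d, "group-jmi", quantized_codes=qt.codes)
            else:
                state = forward_select(X, Y, d, CriterionSpec(criterion))
                expected, scores = naive_forward_select(X, Y, d, criterion)
            assert state.selected == expected
            for rec, naive in zip(state.trace, scores):
                assert rec.score == pytest.approx(naive[rec.chosen], abs=1e-10)

    def test_xor_fixture_pair_found_first_and_second(self):
        disc, Y = xor_fixture(seed=3)
        spec = CriterionSpec("group-jmi-rand",
                             GroupingConfig.randomized(seed=0))
        state = forward_select(disc, Y, 2, spec)
        assert state.selected[0] in (0, 1)
        assert set(state.selected) == {0, 1}

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            CriterionSpec("group-jmi")  # grouping required
        with pytest.raises(ValueError):
            CriterionSpec("single-jmi", GroupingConfig())
        with pytest.raises(ValueError):
            CriterionSpec("cmi")
        # group-jmi-rand defaults to the randomized ranges
        spec = CriterionSpec("group-jmi-rand")
        assert spec.grouping.pot == (0.25, 0.75)
        assert spec.grouping.noc == (4, 16)

    def test_continuous_targets_rejected_outside_group_family(self, rng):
        X = rng.integers(0, 2, (40, 3))
        Y = rng.normal(size=(40, 2))
        for name in ("mim-br", "single-jmi", "joint-jmi"):
            with pytest.raises(DataError):
                forward_select(X, Y, 2, CriterionSpec(name))
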