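import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import rankdata, wilcoxon as scipy_wilcoxon

from targetfish import (
    DataError,
    LabelSpace,
    example_based_metrics,
    mcnemar_test,
    paired_rank_comparison,
    per_class_metrics,
    rank_positions,
    top1_restrict,
    wilcoxon_signed_rank,
)
from targetfish.classifiers import predict_smm, train_smm


class TestExampleBasedMetrics:
    def test_worked_two_instance_example(self):
        rep = example_based_metrics([{"A", "B"}, {"A"}], [{"B", "C"}, {"A"}])
        assert rep.precision == pytest.approx(0.75)
        assert rep.recall == pytest.approx(0.75)

    def test_perfect_prediction(self):
        truth = [{"A"}, {"B", "C"}, {"A", "C"}]
        rep = example_based_metrics(truth, truth)
        assert rep.precision == 1.0 and rep.recall == 1.0

    def test_fully_disjoint_prediction(self):
        rep = example_based_metrics([{"A"}, {"B"}], [{"B"}, {"A"}])
        assert rep.precision == 0.0 and rep.recall == 0.0

    def test_empty_prediction_contributes_zero_precision(self):
        rep = example_based_metrics([{"A"}, {"A"}], [set(), {"A"}])
        assert rep.precision == pytest.approx(0.5)
        assert rep.n_empty_predictions == 1
        assert rep.n_instances == 2  # |T| unchanged

    def test_empty_truth_fatal(self):
        with pytest.raises(DataError):
            example_based_metrics([set()], [{"A"}])

    def test_reduces_to_accuracy_for_singletons(self):
        truth = [{"A"}, {"B"}, {"A"}, {"C"}]
        pred = [{"A"}, {"A"}, {"A"}, {"C"}]
        rep = example_based_metrics(truth, pred)
        assert rep.precision == rep.recall == pytest.approx(0.75)

    @given(
        st.lists(
            st.tuples(
                st.sets(st.sampled_from("ABCDE"), min_size=1, max_size=3),
                st.sets(st.sampled_from("ABCDE"), max_size=3),
            ),
            min_size=1,
            max_size=30,
        ),
        st.randoms(use_true_random=False),
    )
    def test_bounded_and_order_invariant(self, pairs, rnd):
        truth = [t for t, _ in pairs]
        pred = [z for _, z in pairs]
        rep = example_based_metrics(truth, pred)
        assert 0.0 <= rep.precision <= 1.0 and 0.0 <= rep.recall <= 1.0
        shuffled = pairs[:]
        rnd.shuffle(shuffled)
        rep2 = example_based_metrics([t for t, _ in shuffled], [z for _, z in shuffled])
        assert rep2.precision == pytest.approx(rep.precision)
        assert rep2.recall == pytest.approx(rep.recall)


class TestPerClassMetrics:
    SPACE = LabelSpace(("A", "B"))

    def test_confusion_arithmetic(self):
        # 8 A->A, 2 A->B, 2 B->A: label A has TP=8, FP=2, FN=2
        truth = [{"A"}] * 10 + [{"B"}] * 2
        pred = ["A"] * 8 + ["B"] * 2 + ["A"] * 2
        rep = per_class_metrics(truth, pred, self.SPACE)
        assert rep.per_label["A"]["precision"] == pytest.approx(0.8)
        assert rep.per_label["A"]["recall"] == pytest.approx(0.8)

    def test_perfect_assignment(self):
        truth = [{"A"}, {"B"}, {"A"}]
        rep = per_class_metrics(truth, ["A", "B", "A"], self.SPACE)
        assert all(v["precision"] == 1.0 and v["recall"] == 1.0 for v in rep.per_label.values())

    def test_never_predicted_label_flagged_not_averaged(self):
        truth = [{"A"}, {"B"}]
        rep = per_class_metrics(truth, ["A", "A"], self.SPACE)
        assert rep.per_label["B"]["precision"] is None
        assert rep.undefined_precision_labels == ("B",)
        assert rep.per_label["B"]["recall"] == 0.0
        assert rep.precision == pytest.approx(0.5)  # mean over defined labels only

    def test_counts_partition_the_test_set(self):
        truth = [{"A"}] * 7 + [{"B"}] * 5
        pred = ["A", "B"] * 6
        rep = per_class_metrics(truth, pred, self.SPACE)
        tp = sum(v["TP"] for v in rep.per_label.values())
        tp_fn = sum(v["TP"] + v["FN"] for v in rep.per_label.values())
        assert tp_fn == len(truth)
        assert tp == sum(t == {p} for t, p in zip(truth, pred))

    def test_micro_average_equals_accuracy_on_single_label_truth(self):
        truth = [{"A"}] * 6 + [{"B"}] * 6
        pred = ["A"] * 5 + ["B"] * 7
        rep = per_class_metrics(truth, pred, self.SPACE, average="micro")
        assert rep.precision == rep.recall == pytest.approx(11 / 12)

    def test_non_singleton_truth_fatal(self):
        with pytest.raises(DataError):
            per_class_metrics([{"A", "B"}], ["A"], self.SPACE)

    def test_prediction_outside_space_fatal(self):
        with pytest.raises(DataError):
            per_class_metrics([{"A"}], ["Z"], self.SPACE)


class TestRanksAndTop1:
    SPACE = LabelSpace(("A", "B", "C"))

    def test_positions_by_descending_posterior(self):
        assert rank_positions([0.7, 0.2, 0.1], self.SPACE, {"B"}) == [2]

    def test_full_coverage_is_all_positions(self):
        positions = rank_positions([0.1, 0.5, 0.4], self.SPACE, {"A", "B", "C"})
        assert set(positions) == {1, 2, 3}

    def test_tie_gives_later_label_position_two(self):
        assert rank_positions([0.5, 0.5, 0.0], self.SPACE, {"B"}) == [2]

    def test_unknown_true_label_fatal(self):
        with pytest.raises(DataError):
            rank_positions([0.5, 0.3, 0.2], self.SPACE, {"Z"})

    def test_top1_ignores_threshold_and_Z(self, toy_dataset):
        model = train_smm(toy_dataset)
        pred = predict_smm(model, np.array([1, 0]))
        assert top1_restrict(pred) == frozenset({"A"})


class TestMcNemar:
    def test_continuity_corrected_closed_form(self):
        res = mcnemar_test(10, 20)
        assert res.statistic == pytest.approx(2.7)
        assert res.direction == "a"  # A has fewer exclusive errors

    def test_symmetric_counts(self):
        res = mcnemar_test(5, 5)
        assert res.statistic == pytest.approx(0.1)
        assert res.direction == "none"

    def test_no_discordant_pairs_fatal(self):
        with pytest.raises(DataError, match="discordant"):
            mcnemar_test(0, 0)

    def test_statistic_symmetric_direction_flips(self):
        a = mcnemar_test(7, 19)
        b = mcnemar_test(19, 7)
        assert a.statistic == b.statistic and a.p_value == b.p_value
        assert (a.direction, b.direction) == ("a", "b")

    def test_exact_variant_matches_binomial(self):
        res = mcnemar_test(2, 10, variant="exact")
        from scipy.stats import binomtest

        assert res.p_value == pytest.approx(binomtest(2, 12, 0.5).pvalue)


def _wilcoxon_brute_force(diffs, alternative):
    """Full 2^n enumeration of the signed-rank null; ties via average ranks."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    stats = [
        np.array(signs) @ ranks
        for signs in itertools.product([0, 1], repeat=len(d))
    ]
    stats = np.array(stats)
    p_ge = np.mean(stats >= w_obs - 1e-12)
    p_le = np.mean(stats <= w_obs + 1e-12)
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2 * min(p_ge, p_le))


class TestWilcoxon:
    def test_all_positive_run_of_five(self):
        res = wilcoxon_signed_rank([1, 2, 3, 4, 5], alternative="greater")
        assert res.p_value == pytest.approx(1 / 32)
        assert res.statistic == 15.0

    def test_symmetric_pair_two_sided(self):
        res = wilcoxon_signed_rank([3.0, -3.0])
        assert res.p_value == pytest.approx(1.0)
        assert res.direction == "none"

    def test_all_zeros_degenerate_not_error(self):
        res = wilcoxon_signed_rank([0.0, 0.0, 0.0])
        assert res.p_value == 1.0 and res.extras["degenerate"]

    @given(
        st.lists(st.integers(-5, 5), min_size=1, max_size=10).filter(
            lambda d: any(x != 0 for x in d)
        ),
        st.sampled_from(["two-sided", "greater", "less"]),
    )
    def test_exact_matches_full_enumeration(self, diffs, alternative):
        res = wilcoxon_signed_rank(diffs, alternative=alternative, mode="exact")
        assert res.p_value == pytest.approx(_wilcoxon_brute_force(diffs, alternative))

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(5)
        d = rng.permutation(np.arange(1, 13)) * rng.choice([-1, 1], 12)
        res = wilcoxon_signed_rank(d, mode="exact")
        ref = scipy_wilcoxon(d, method="exact")
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_normal_approx_matches_scipy(self):
        rng = np.random.default_rng(6)
        d = rng.normal(0.2, 1.0, 300)
        d = d[d != 0]
        res = wilcoxon_signed_rank(d, mode="normal_approx")
        ref = scipy_wilcoxon(d, method="approx", correction=False)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_large_sample_direction_consistent_with_exact_subsamples(self):
        rng = np.random.default_rng(7)
        d = rng.normal(0.3, 1.0, 10000)
        big = wilcoxon_signed_rank(d, alternative="greater")
        assert big.extras["method"] == "normal_approx"
        assert big.p_value < 0.01 and big.direction == "a"
        sub = wilcoxon_signed_rank(rng.choice(d, 20, replace=False), alternative="greater")
        assert sub.extras["method"] == "exact"
        assert sub.p_value < 0.5  # same direction at far lower power

    def test_pratt_policy_keeps_zero_ranks_out_of_statistic(self):
        res = wilcoxon_signed_rank([0, 0, 1, 2, -3], zero_policy="pratt", mode="exact")
        # |d| ranking with zeros: zeros take ranks 1-2; nonzeros 3,4,5
        assert res.statistic == pytest.approx(3 + 4)
        assert res.n_effective == 3


class TestPairedRankComparison:
    def test_identical_models_are_degenerate(self, tiny_dataset):
        idx = np.flatnonzero(tiny_dataset.multi_label_mask())
        sub = tiny_dataset.subset(idx)
        post = np.random.default_rng(0).random((sub.n, sub.n_labels))
        records, res = paired_rank_comparison(post, post, sub)
        assert res.extras["degenerate"] and res.p_value == 1.0
        assert res.extras["ties"] == len(records) == sub.n_pairs

    def test_breakdown_partitions_M(self, tiny_dataset):
        idx = np.flatnonzero(tiny_dataset.multi_label_mask())
        sub = tiny_dataset.subset(idx)
        rng = np.random.default_rng(1)
        a, b = rng.random((2, sub.n, sub.n_labels))
        records, res = paired_rank_comparison(a, b, sub)
        e = res.extras
        assert e["ties"] + e["a_better"] + e["b_better"] == e["M"] == len(records)
        assert e["M"] == sub.n_pairs

    def test_shifted_ranks_favor_better_model(self, tiny_dataset):
        """Give model B the truth as its posterior: it must win decisively."""
        idx = np.flatnonzero(tiny_dataset.multi_label_mask())
        sub = tiny_dataset.subset(idx)
        rng = np.random.default_rng(2)
        noise = rng.random((sub.n, sub.n_labels))
        truthful = sub.Y.astype(float) + 0.01 * noise
        _, res = paired_rank_comparison(noise, truthful, sub)
        assert res.direction == "b"
        assert res.p_value < 1e-6
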