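import numpy as np
import pytest

from fusionsearch.evaluation import (Qrels, average_precision, bpref,
                                     evaluate, judged_only_filter, ndcg_at,
                                     precision_at)
from fusionsearch.ranking import RankedEntry, RankedList

from oracles import (ap_oracle, bpref_enumeration_oracle, ndcg_oracle,
                     precision_oracle)


def make_ranked(topic_id, doc_ids):
    return RankedList(topic_id, [
        RankedEntry(d, float(len(doc_ids) - i), i + 1)
        for i, d in enumerate(doc_ids)
    ])


def make_qrels(topic_id, grades: dict[str, int]) -> Qrels:
    q = Qrels()
    for d, g in grades.items():
        q.add(topic_id, d, g)
    return q


def random_case(seed, n_docs=200, judged_frac=0.3):
    """A random (ranked list, grades) pair for oracle equivalence checks."""
    rng = np.random.default_rng(seed)
    docs = [f"d{i:03d}" for i in range(n_docs)]
    ranked = list(rng.permutation(docs))[: rng.integers(20, n_docs)]
    judged = rng.choice(docs, size=int(judged_frac * n_docs), replace=False)
    grades = {str(d): int(rng.integers(0, 3)) for d in judged}
    return ranked, grades


class TestPrecisionAt:
    def test_all_relevant(self):
        run = make_ranked(1, ["a", "b", "c", "d", "e"])
        qrels = make_qrels(1, {d: 2 for d in "abcde"})
        assert precision_at(run, qrels, 5) == 1.0

    def test_three_of_ten(self):
        run = make_ranked(1, [f"d{i}" for i in range(10)])
        qrels = make_qrels(1, {"d0": 1, "d4": 2, "d9": 1, "other": 2})
        assert precision_at(run, qrels, 10) == pytest.approx(0.3)

    def test_unjudged_counts_as_nonrelevant(self):
        run = make_ranked(1, [f"u{i}" for i in range(10)])
        qrels = make_qrels(1, {"elsewhere": 2})
        assert precision_at(run, qrels, 10) == 0.0


class TestNdcgAt:
    def test_ideal_ordering_scores_one(self):
        run = make_ranked(1, ["a", "b", "c"])
        qrels = make_qrels(1, {"a": 2, "b": 1, "c": 0})
        assert ndcg_at(run, qrels, 3) == pytest.approx(1.0)

    def test_no_relevant_judged_gives_zero(self):
        run = make_ranked(1, ["a"])
        qrels = make_qrels(1, {"a": 0})
        assert ndcg_at(run, qrels, 10) == 0.0

    def test_hand_derived_value(self):
        # retrieved grades [1, 0, 2] against judged {2, 1, 0}:
        # DCG = 1 + 0 + 2/log2(3), IDCG = 2 + 1 + 0 = 3
        run = make_ranked(1, ["partial", "junk", "best"])
        qrels = make_qrels(1, {"best": 2, "partial": 1, "junk": 0})
        dcg = 1 + 0 + 2 / np.log2(3)
        assert dcg == pytest.approx(2.26186, abs=1e-5)
        assert ndcg_at(run, qrels, 3) == pytest.approx(dcg / 3)
        assert ndcg_at(run, qrels, 3) == pytest.approx(0.75395, abs=1e-5)

    def test_trec_variant_discounts_rank_two(self):
        run = make_ranked(1, ["a", "b"])
        qrels = make_qrels(1, {"a": 0, "b": 2, "c": 2})
        classic = ndcg_at(run, qrels, 2, variant="as_printed")
        trec = ndcg_at(run, qrels, 2, variant="trec")
        # classic: DCG = 2/1, IDCG = 2 + 2 -> 0.5
        assert classic == pytest.approx(0.5)
        # trec: DCG = 2/log2(3), IDCG = 2 + 2/log2(3)
        assert trec == pytest.approx((2 / np.log2(3)) / (2 + 2 / np.log2(3)))


class TestAveragePrecision:
    def test_perfect_front_loading(self):
        run = make_ranked(1, ["a", "b"])
        qrels = make_qrels(1, {"a": 1, "b": 2})
        assert average_precision(run, qrels) == 1.0

    def test_no_relevant_retrieved(self):
        run = make_ranked(1, ["x", "y"])
        qrels = make_qrels(1, {"a": 1})
        assert average_precision(run, qrels) == 0.0

    def test_hand_derived_value(self):
        # relevant at ranks 1 and 3, two relevant total: (1 + 2/3)/2
        run = make_ranked(1, ["rel1", "junk", "rel2"])
        qrels = make_qrels(1, {"rel1": 2, "rel2": 1, "junk": 0})
        assert average_precision(run, qrels) == pytest.approx(5 / 6)
        assert average_precision(run, qrels) == pytest.approx(0.83333, abs=1e-5)

    def test_missed_relevant_counts_in_denominator(self):
        run = make_ranked(1, ["rel1"])
        qrels = make_qrels(1, {"rel1": 2, "missed": 2})
        assert average_precision(run, qrels) == 0.5


class TestBpref:
    def test_all_relevant_before_nonrelevant(self):
        run = make_ranked(1, ["r1", "r2", "n1"])
        qrels = make_qrels(1, {"r1": 2, "r2": 1, "n1": 0})
        assert bpref(run, qrels) == 1.0

    def test_relevant_buried_below_r_nonrelevant(self):
        run = make_ranked(1, ["n1", "n2", "r1", "r2"])
        qrels = make_qrels(1, {"n1": 0, "n2": 0, "r1": 1, "r2": 1})
        assert bpref(run, qrels) == 0.0

    def test_hand_derived_value(self):
        # R=2, order [rel, judged-nonrel, rel] -> (1 + 1/2)/2
        run = make_ranked(1, ["r1", "n1", "r2"])
        qrels = make_qrels(1, {"r1": 2, "n1": 0, "r2": 1})
        assert bpref(run, qrels) == pytest.approx(0.75)

    def test_unjudged_documents_invisible(self):
        base = make_ranked(1, ["r1", "n1", "r2"])
        qrels = make_qrels(1, {"r1": 2, "n1": 0, "r2": 1})
        padded = make_ranked(1, ["u1", "r1", "u2", "u3", "n1", "u4", "r2", "u5"])
        assert bpref(padded, qrels) == bpref(base, qrels)

    def test_no_relevant_is_undefined(self):
        run = make_ranked(1, ["n1"])
        qrels = make_qrels(1, {"n1": 0})
        assert bpref(run, qrels) is None

    def test_only_first_r_nonrelevant_counted(self):
        # R=1: only the first judged-nonrelevant doc can hurt; n2/n3 beyond R
        run = make_ranked(1, ["n1", "n2", "n3", "r1"])
        qrels = make_qrels(1, {"n1": 0, "n2": 0, "n3": 0, "r1": 2})
        assert bpref(run, qrels) == 0.0
        run2 = make_ranked(1, ["r1", "n1", "n2", "n3"])
        assert bpref(run2, qrels) == 1.0

    def test_trec_variant_denominator(self):
        # R=3 relevant, 1 judged nonrelevant: trec denominator min(3,1)=1
        run = make_ranked(1, ["n1", "r1", "r2", "r3"])
        qrels = make_qrels(1, {"n1": 0, "r1": 1, "r2": 1, "r3": 2})
        as_printed = bpref(run, qrels, variant="as_printed")
        trec = bpref(run, qrels, variant="trec")
        assert as_printed == pytest.approx((1 - 1 / 3) * 3 / 3)
        assert trec == pytest.approx(0.0)


class TestJudgedOnlyFilter:
    def test_no_judged_docs_gives_empty_list(self):
        run = {1: make_ranked(1, ["x", "y"])}
        out = judged_only_filter(run, make_qrels(1, {"z": 1}))
        assert len(out[1]) == 0

    def test_fully_judged_run_unchanged(self):
        run = {1: make_ranked(1, ["a", "b"])}
        out = judged_only_filter(run, make_qrels(1, {"a": 1, "b": 0}))
        assert out[1].doc_ids() == ["a", "b"]
        assert [e.rank for e in out[1]] == [1, 2]

    def test_survivors_match_intersection(self):
        rng = np.random.default_rng(0)
        ranked, grades = random_case(5)
        run = {1: make_ranked(1, ranked)}
        out = judged_only_filter(run, make_qrels(1, grades))
        assert len(out[1]) == len(set(ranked) & set(grades))
        out[1].validate()
        # order and scores of survivors preserved
        kept = [d for d in ranked if d in grades]
        assert out[1].doc_ids() == kept


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(20))
    def test_metrics_match_independent_oracles(self, seed):
        """P@5/P@10, nDCG@10 (trec semantics), MAP agree with the
        independent straight-line oracle to 1e-6; Bpref agrees with the
        direct enumeration oracle to 1e-9."""
        ranked, grades = random_case(seed)
        run_topic = make_ranked(1, ranked)
        qrels = make_qrels(1, grades)
        for n in (5, 10):
            assert precision_at(run_topic, qrels, n) == pytest.approx(
                precision_oracle(ranked, grades, n), abs=1e-6)
        assert ndcg_at(run_topic, qrels, 10, variant="trec") == pytest.approx(
            ndcg_oracle(ranked, grades, 10, variant="trec"), abs=1e-6)
        assert ndcg_at(run_topic, qrels, 10) == pytest.approx(
            ndcg_oracle(ranked, grades, 10, variant="classic"), abs=1e-6)
        assert average_precision(run_topic, qrels) == pytest.approx(
            ap_oracle(ranked, grades), abs=1e-6)
        got = bpref(run_topic, qrels)
        want = bpref_enumeration_oracle(ranked, grades)
        if want is None:
            assert got is None
        else:
            assert got == pytest.approx(want, abs=1e-9)


class TestEvaluate:
    def test_perfect_single_topic(self):
        run = {1: make_ranked(1, [f"r{i}" for i in range(10)])}
        qrels = make_qrels(1, {f"r{i}": 2 for i in range(10)})
        report = evaluate(run, qrels)
        for metric in ("Bpref", "MAP", "P@5", "P@10", "nDCG@10"):
            assert report[metric] == pytest.approx(1.0)

    def test_empty_run_scores_zero(self):
        run = {1: make_ranked(1, [])}
        qrels = make_qrels(1, {"a": 2, "b": 0})
        report = evaluate(run, qrels)
        assert report["MAP"] == 0.0
        assert report["P@10"] == 0.0
        assert report["Bpref"] == 0.0  # defined (R>=1) but nothing retrieved

    def test_disjoint_topics_rejected(self):
        run = {1: make_ranked(1, ["a"])}
        qrels = make_qrels(2, {"a": 1})
        with pytest.raises(ValueError):
            evaluate(run, qrels)

    def test_judged_only_flag_rescoring(self):
        # unjudged docs above the judged ones hurt P@N unless filtered
        run = {1: make_ranked(1, ["u1", "u2", "u3", "u4", "u5", "r1", "n1"])}
        qrels = make_qrels(1, {"r1": 2, "n1": 0})
        full = evaluate(run, qrels, p_cutoffs=(5,))
        judged = evaluate(run, qrels, p_cutoffs=(5,), judged_only=True)
        assert full["P@5"] == 0.0
        assert judged["P@5"] == pytest.approx(0.2)
        assert judged.judged_only

    def test_mean_over_qrels_topics(self):
        run = {1: make_ranked(1, ["a"]), 2: make_ranked(2, ["zzz"])}
        qrels = Qrels()
        qrels.add(1, "a", 2)
        qrels.add(2, "b", 2)
        report = evaluate(run, qrels)
        assert report["MAP"] == pytest.approx(0.5)


class TestQrelsIO:
    def test_round_trip(self, tmp_path):
        qrels = make_qrels(3, {"a": 2, "b": 0, "c": 1})
        path = tmp_path / "qrels.txt"
        qrels.save(path)
        assert Qrels.load(path).grades == qrels.grades

    def test_bad_grade_rejected(self):
        with pytest.raises(ValueError):
            make_qrels(1, {"a": 3})
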