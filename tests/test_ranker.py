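"""Candidate collection, the six features, classifiers and N selection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meshsuggest import (
    AnnotatedDocument,
    LabelFeatureVector,
    RankedPrediction,
    SelectionParams,
    build_index,
    build_training_set,
    collect_candidates,
    compute_features,
    discretize_features,
    feature_information_gain,
    score_labels,
    select_labels,
    train_ranker,
    tokenize_document,
)
from meshsuggest.preprocess import Descriptor, Thesaurus
from meshsuggest.ranker import apply_bins
from meshsuggest.vsm import NeighborSet, retrieve_neighbors


def _index_from(label_map, texts=None):
    docs = [
        AnnotatedDocument(doc_id, texts.get(doc_id, doc_id) if texts else "x",
                          "", frozenset(labels))
        for doc_id, labels in label_map.items()
    ]
    return build_index(docs)


class TestCollectCandidates:
    def test_union(self):
        idx = _index_from({"1": {"A", "B"}, "2": {"B", "C"}})
        ns = NeighborSet("q", (("1", 0.9), ("2", 0.8)), 2)
        assert collect_candidates(ns, idx) == ["A", "B", "C"]

    def test_single_neighbor(self):
        idx = _index_from({"1": {"A"}})
        ns = NeighborSet("q", (("1", 0.5),), 1)
        assert collect_candidates(ns, idx) == ["A"]

    def test_size_bounded_by_sum(self, small_synthetic, small_index):
        corpus, _, _ = small_synthetic
        for doc in corpus[:10]:
            ns = retrieve_neighbors(small_index, tokenize_document(doc), 10)
            cands = collect_candidates(ns, small_index)
            total = sum(
                len(small_index.labels_of[d]) for d, _ in ns.neighbors
            )
            assert len(cands) <= total


TABLE6_TITLE = (
    "An observational study of the frequency, severity, and etiology of "
    "failures in postoperative care after major elective general surgery"
)


class TestComputeFeatures:
    def _doc(self, title, abstract=""):
        return tokenize_document(
            AnnotatedDocument("q", title, abstract, frozenset())
        )

    def test_f1_all_neighbors(self):
        idx = _index_from({str(i): {"A"} for i in range(4)})
        ns = NeighborSet(
            "q", tuple((str(i), 0.5) for i in range(4)), 4
        )
        th = Thesaurus({"A": Descriptor("alpha", ("alpha",))})
        fv = compute_features("A", self._doc("unrelated"), ns, idx, th, k=4)
        assert fv.f1 == 1.0

    def test_f2_single_neighbor_k25(self):
        idx = _index_from({"1": {"A"}, "2": set()})
        ns = NeighborSet("q", (("1", 0.3), ("2", 0.9)), 25)
        th = Thesaurus({"A": Descriptor("alpha", ("alpha",))})
        fv = compute_features("A", self._doc("unrelated"), ns, idx, th, k=25)
        assert fv.f2 == pytest.approx(0.3 / 25)
        assert fv.f1 == pytest.approx(1 / 25)

    def test_f6_entry_term_in_title(self):
        idx = _index_from({"1": {"A"}})
        ns = NeighborSet("q", (("1", 0.5),), 1)
        th = Thesaurus(
            {"A": Descriptor("Postoperative care", ("Postoperative care",))}
        )
        fv = compute_features("A", self._doc(TABLE6_TITLE), ns, idx, th, k=1)
        assert fv.f6 == 1
        assert fv.f4 == 1 and fv.f5 >= 1

    def test_f3_disjoint_tokens_in_title(self):
        idx = _index_from({"1": {"A"}})
        ns = NeighborSet("q", (("1", 0.5),), 1)
        th = Thesaurus({"A": Descriptor("General surgery",
                                        ("General surgery",))})
        fv = compute_features("A", self._doc(TABLE6_TITLE), ns, idx, th, k=1)
        assert fv.f3 == 1

    def test_f3_without_contiguity(self):
        # tokens present but never adjacent: f3 = 1, f4 = f5 = f6 = 0
        idx = _index_from({"1": {"A"}})
        ns = NeighborSet("q", (("1", 0.5),), 1)
        th = Thesaurus({"A": Descriptor("alpha gamma", ("alpha gamma",))})
        fv = compute_features(
            "A", self._doc("alpha beta gamma"), ns, idx, th, k=1
        )
        assert (fv.f3, fv.f4, fv.f5, fv.f6) == (1, 0, 0, 0)

    def test_f5_counts_occurrences(self):
        idx = _index_from({"1": {"A"}})
        ns = NeighborSet("q", (("1", 0.5),), 1)
        th = Thesaurus({"A": Descriptor("alpha", ("alpha", "beta"))})
        fv = compute_features(
            "A", self._doc("alpha beta", "alpha delta beta"), ns, idx, th, k=1
        )
        assert fv.f5 == 4  # alpha x2 + beta x2
        assert fv.f4 == 1

    def test_label_missing_from_thesaurus_uses_id_text(self, caplog):
        idx = _index_from({"1": {"alpha"}})
        ns = NeighborSet("q", (("1", 0.5),), 1)
        th = Thesaurus({})
        with caplog.at_level("WARNING"):
            fv = compute_features(
                "alpha", self._doc("alpha beta"), ns, idx, th, k=1
            )
        assert fv.f3 == 1 and fv.f4 == 1
        assert "absent from thesaurus" in caplog.text

    def test_f2_never_exceeds_f1(self, small_synthetic, small_index):
        corpus, thesaurus, _ = small_synthetic
        for doc in corpus[:15]:
            tok = tokenize_document(doc)
            ns = retrieve_neighbors(small_index, tok, 25)
            for label in collect_candidates(ns, small_index):
                fv = compute_features(
                    label, tok, ns, small_index, thesaurus, 25
                )
                assert fv.f2 <= fv.f1 + 1e-12
                assert (fv.f5 > 0) == (fv.f4 == 1)


class TestBuildTrainingSet:
    def test_instance_count_and_classes(self, small_synthetic, small_index):
        corpus, thesaurus, _ = small_synthetic
        docs = corpus[:25]
        instances = build_training_set(docs, small_index, thesaurus, k=10)
        expected = 0
        for doc in docs:
            ns = retrieve_neighbors(
                small_index, tokenize_document(doc), 10
            )
            expected += len(collect_candidates(ns, small_index))
        assert len(instances) == expected
        for inst in instances:
            assert inst.cls in (0, 1)
        # planted corpus: true labels should be common among candidates
        pos_rate = sum(i.cls for i in instances) / len(instances)
        assert 0.0 < pos_rate < 1.0


def _make_instances(values, classes=None):
    return [
        LabelFeatureVector("d", f"L{i}", v, v / 2, 0, 0, int(v * 10), 0,
                           None if classes is None else classes[i])
        for i, v in enumerate(values)
    ]


class TestDiscretize:
    def test_constant_feature_single_bin(self):
        X, bins = discretize_features(_make_instances([0.5] * 20))
        assert len(bins["f1"]) == 0
        assert (X[:, 0] == 0).all()

    def test_equal_frequency_populations(self):
        values = [i / 100 for i in range(100)]
        X, _ = discretize_features(_make_instances(values), n_bins=10)
        _, counts = np.unique(X[:, 0], return_counts=True)
        assert counts.max() - counts.min() <= 1

    def test_stored_edges_reproduce_training_bins(self):
        rng = np.random.default_rng(3)
        instances = _make_instances(rng.random(57))
        X, bins = discretize_features(instances, n_bins=10)
        raw = np.array([i.values() for i in instances])
        assert (apply_bins(raw, bins) == X).all()


class TestTrainRanker:
    def _separable(self, n=40):
        insts = []
        for i in range(n):
            cls = i % 2
            insts.append(
                LabelFeatureVector("d", f"L{i}", 0.9 if cls else 0.1,
                                   0.5 if cls else 0.05, cls, cls,
                                   3 if cls else 0, cls, cls)
            )
        return insts

    @pytest.mark.parametrize("algo", ["nb", "dt", "rf"])
    def test_separable_data_ranks_positives_first(self, algo):
        insts = self._separable()
        model = train_ranker(insts, algo, seed=0)
        pred = score_labels(model, insts)
        scores = dict(pred.ranked)
        pos = [scores[i.label_id] for i in insts if i.cls == 1]
        neg = [scores[i.label_id] for i in insts if i.cls == 0]
        assert min(pos) > max(neg)

    def test_deterministic_given_seed(self):
        insts = self._separable(60)
        m1 = train_ranker(insts, "rf", seed=42)
        m2 = train_ranker(insts, "rf", seed=42)
        p1 = score_labels(m1, insts)
        p2 = score_labels(m2, insts)
        assert p1.ranked == p2.ranked

    def test_single_class_prior_model(self, caplog):
        insts = _make_instances([0.1, 0.2, 0.3], classes=[1, 1, 1])
        with caplog.at_level("WARNING"):
            model = train_ranker(insts, "rf", seed=0)
        assert model.prior == 1.0
        pred = score_labels(model, insts)
        assert all(s == 1.0 for _, s in pred.ranked)

    def test_scores_are_probabilities(self):
        insts = self._separable()
        model = train_ranker(insts, "rf", seed=0)
        pred = score_labels(model, insts)
        assert all(0.0 <= s <= 1.0 for _, s in pred.ranked)

    def test_duplicate_feature_vectors_get_identical_scores(self):
        insts = self._separable()
        model = train_ranker(insts, "rf", seed=0)
        a = LabelFeatureVector("d", "X", 0.9, 0.5, 1, 1, 3, 1)
        b = LabelFeatureVector("d", "Y", 0.9, 0.5, 1, 1, 3, 1)
        pred = score_labels(model, [a, b])
        assert pred.ranked[0][1] == pred.ranked[1][1]


TABLE5_SCORES = [0.99, 0.75, 0.60, 0.60, 0.32, 0.32, 0.32, 0.32, 0.32,
                 0.26, 0.26, 0.25, 0.21, 0.21, 0.20, 0.20]


def _prediction(scores):
    return RankedPrediction("d", [(f"l{i:02d}", s)
                                  for i, s in enumerate(scores)])


class TestSelectLabels:
    def test_threshold_inclusive(self):
        pred = _prediction([0.6, 0.5, 0.4])
        sel = select_labels(pred, SelectionParams("threshold", threshold=0.5))
        assert len(sel) == 2

    def test_threshold_keeps_at_least_one(self):
        pred = _prediction([0.2, 0.1])
        sel = select_labels(pred, SelectionParams("threshold", threshold=0.5))
        assert sel == ["l00"]

    def test_average_size_rounds_mean(self):
        idx = _index_from({
            "1": {f"A{i}" for i in range(10)},
            "2": {f"B{i}" for i in range(12)},
            "3": {f"C{i}" for i in range(14)},
        })
        ns = NeighborSet("q", (("1", 0.9), ("2", 0.8), ("3", 0.7)), 3)
        pred = _prediction([0.9] * 20)
        sel = select_labels(pred, SelectionParams("average_size"), ns, idx)
        assert len(sel) == 12

    def test_cutoff_on_printed_score_list(self):
        # first ratio violation at i = 4: 0.32/0.60 < 4/6.6
        pred = _prediction(TABLE5_SCORES)
        sel = select_labels(pred, SelectionParams("cutoff", alpha=1.6))
        assert sel == ["l00", "l01", "l02", "l03"]

    def test_cutoff_always_keeps_rank_one(self):
        pred = _prediction([0.9, 0.01])
        sel = select_labels(pred, SelectionParams("cutoff", alpha=1.6))
        assert sel == ["l00"]

    def test_cutoff_ignores_zero_scores_after_cut(self):
        base = _prediction(TABLE5_SCORES)
        select_labels(base, SelectionParams("cutoff", alpha=1.6))
        extended = _prediction(TABLE5_SCORES + [0.0, 0.0, 0.0])
        select_labels(extended, SelectionParams("cutoff", alpha=1.6))
        assert base.selected_n == extended.selected_n

    @settings(max_examples=100, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                 max_size=30),
        st.floats(min_value=0.1, max_value=5.0),
        st.floats(min_value=0.05, max_value=3.0),
    )
    def test_cutoff_monotone_in_alpha(self, scores, alpha, delta):
        scores = sorted(scores, reverse=True)
        pred1 = _prediction(scores)
        pred2 = _prediction(scores)
        select_labels(pred1, SelectionParams("cutoff", alpha=alpha))
        select_labels(pred2, SelectionParams("cutoff", alpha=alpha + delta))
        assert pred2.selected_n >= pred1.selected_n


class TestInformationGain:
    def test_independent_feature_zero_gain(self):
        X = np.array([[0], [1], [0], [1]])
        y = np.array([0, 0, 1, 1])
        gains = feature_information_gain(X, y, names=["f"])
        assert gains["f"] == pytest.approx(0.0, abs=1e-12)

    def test_identical_feature_equals_class_entropy(self):
        y = np.array([0, 0, 0, 1])
        X = y.reshape(-1, 1)
        gains = feature_information_gain(X, y, names=["f"])
        h = -(0.75 * math.log2(0.75) + 0.25 * math.log2(0.25))
        assert gains["f"] == pytest.approx(h, abs=1e-12)

    def test_hand_built_table(self):
        # f=1 -> class 1 twice; f=0 -> classes {0, 1} once each
        X = np.array([[1], [1], [0], [0]])
        y = np.array([1, 1, 1, 0])
        gains = feature_information_gain(X, y, names=["f"])
        h_y = -(0.75 * math.log2(0.75) + 0.25 * math.log2(0.25))
        h_cond = 0.5 * 0.0 + 0.5 * 1.0
        assert gains["f"] == pytest.approx(h_y - h_cond, abs=1e-12)

    def test_on_planted_training_set(self, small_synthetic, small_index):
        corpus, thesaurus, _ = small_synthetic
        instances = build_training_set(
            corpus[:40], small_index, thesaurus, k=10
        )
        X, _ = discretize_features(instances)
        y = np.array([i.cls for i in instances])
        gains = feature_information_gain(X, y)
        assert all(g >= -1e-12 for g in gains.values())
        # neighbour-vote features carry signal on the planted corpus
        assert gains["f1"] > 0.01
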