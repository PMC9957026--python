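import math

import numpy as np
import pytest

from msit.corpus_io import ClinicalDocument
from msit.ml_classifier import (
    MLConfig,
    TrainedModel,
    TrainingError,
    aggregate_patients,
    fit_tfidf,
    postprocess,
    predict_documents,
    train,
)
from msit.preprocess import TokenStream, preprocess_corpus
from msit.rule_classifier import DocumentDecision
from msit.synthdata import SimConfig, generate

UNIGRAMS = MLConfig(ngram_range=(1, 1))


def _streams(token_lists):
    return [TokenStream(doc_id=f"d{i}", tokens=tuple(t))
            for i, t in enumerate(token_lists)]


class TestTfidf:
    def test_rows_l2_normalized(self):
        fm, _ = fit_tfidf(_streams([["a", "b"], ["c", "d"], ["a", "c"]]), UNIGRAMS)
        norms = np.sqrt(np.asarray(fm.values.multiply(fm.values).sum(axis=1))).ravel()
        assert np.allclose(norms, 1.0)

    def test_disjoint_documents_block_structure(self):
        fm, _ = fit_tfidf(_streams([["a", "b"], ["c", "d"]]), UNIGRAMS)
        dense = fm.values.toarray()
        vocab = list(fm.vocabulary)
        for term in ("a", "b"):
            assert dense[1, vocab.index(term)] == 0
        for term in ("c", "d"):
            assert dense[0, vocab.index(term)] == 0

    def test_matches_hand_computed_values(self):
        """TF-IDF on a 5-document toy corpus against the closed formula
        idf(t) = ln((1+N)/(1+df)) + 1 with L2 row normalization."""
        token_lists = [
            ["army", "note"],
            ["note", "note", "clinic"],
            ["clinic", "army", "note"],
            ["mood"],
            ["mood", "clinic"],
        ]
        fm, _ = fit_tfidf(_streams(token_lists), UNIGRAMS)
        N = 5
        dfs = {"army": 2, "note": 3, "clinic": 3, "mood": 2}
        idf = {t: math.log((1 + N) / (1 + df)) + 1 for t, df in dfs.items()}
        dense = fm.values.toarray()
        vocab = list(fm.vocabulary)
        for row, tokens in enumerate(token_lists):
            raw = {t: tokens.count(t) * idf[t] for t in set(tokens)}
            norm = math.sqrt(sum(v * v for v in raw.values()))
            for t, v in raw.items():
                assert dense[row, vocab.index(t)] == pytest.approx(v / norm)

    def test_empty_corpus_rejected(self):
        with pytest.raises(TrainingError):
            fit_tfidf(_streams([[]]), UNIGRAMS)
        with pytest.raises(TrainingError):
            fit_tfidf(_streams([[], []]), UNIGRAMS)

    def test_default_config_includes_bigrams(self):
        fm, _ = fit_tfidf(_streams([["a", "b"], ["a", "c"]]), MLConfig())
        assert "a b" in fm.vocabulary


def _separable_training_data(n=60):
    pos = [["veteran", "served", "forces"], ["army", "veteran"],
           ["navy", "service", "history"]]
    neg = [["clinic", "review", "mood"], ["sleep", "poor", "review"],
           ["appointment", "missed"]]
    streams, labels = [], []
    for i in range(n):
        src = pos[i % 3] if i % 2 == 0 else neg[i % 3]
        streams.append(TokenStream(doc_id=f"t{i}", tokens=tuple(src)))
        labels.append(1 if i % 2 == 0 else 0)
    return streams, labels


class TestTrain:
    def test_separable_corpus_high_training_accuracy(self):
        streams, labels = _separable_training_data()
        model = train(streams, labels, seed=42)
        decisions = predict_documents(model, streams)
        acc = np.mean([d.label == y for d, y in zip(decisions, labels)])
        assert acc >= 0.99

    def test_single_class_rejected(self):
        streams, _ = _separable_training_data(20)
        with pytest.raises(TrainingError, match="single class"):
            train(streams, [1] * 20, seed=42)

    def test_too_few_documents_rejected(self):
        streams, labels = _separable_training_data(6)
        with pytest.raises(TrainingError, match="at least"):
            train(streams, labels, seed=42)

    def test_retraining_is_deterministic(self):
        streams, labels = _separable_training_data()
        held_out = _streams([["veteran", "review"], ["clinic", "mood"],
                             ["army"], []])
        runs = []
        for _ in range(2):
            model = train(streams, labels, seed=42)
            runs.append([d.label for d in predict_documents(model, held_out)])
        assert runs[0] == runs[1]

    def test_labels_as_mapping(self):
        streams, labels = _separable_training_data()
        mapping = {s.doc_id: y for s, y in zip(streams, labels)}
        model = train(streams, mapping, seed=42)
        assert predict_documents(model, streams[:1])[0].label == labels[0]


class TestPredict:
    def test_empty_stream_predicts_negative(self):
        streams, labels = _separable_training_data()
        model = train(streams, labels, seed=42)
        dec = predict_documents(model, _streams([[]]))[0]
        assert dec.label == 0

    def test_prediction_count_equals_input_count(self, small_corpus,
                                                 preprocess_config, military,
                                                 relations):
        streams = preprocess_corpus(small_corpus.documents, preprocess_config,
                                    military, relations)
        model = train(streams, small_corpus.doc_labels(), seed=42)
        assert len(predict_documents(model, streams)) == len(streams)

    def test_unfitted_model_rejected(self):
        from sklearn.feature_extraction.text import TfidfVectorizer
        from sklearn.linear_model import LogisticRegression

        model = TrainedModel(vectorizer=TfidfVectorizer(),
                             classifier=LogisticRegression(),
                             config=MLConfig(), training_seed=0)
        with pytest.raises(TrainingError, match="not fitted"):
            predict_documents(model, _streams([["a"]]))

    def test_model_round_trip_preserves_predictions(self, tmp_path):
        streams, labels = _separable_training_data()
        model = train(streams, labels, seed=42)
        path = tmp_path / "model.joblib"
        model.save(path)
        reloaded = TrainedModel.load(path)
        before = [d.label for d in predict_documents(model, streams)]
        after = [d.label for d in predict_documents(reloaded, streams)]
        assert before == after


class TestPostprocess:
    def test_false_positive_without_evidence_flipped(self, military, confounders):
        docs = [ClinicalDocument("d0", "p", "supported by the salvation army")]
        decisions = [DocumentDecision(doc_id="d0", label=1, source="ml")]
        out = postprocess(decisions, docs, military, confounders)
        assert out[0].label == 0
        assert out[0].source == "ml_postprocessed"

    def test_negatives_never_promoted(self, military, confounders):
        docs = [ClinicalDocument("d0", "p", "patient is a veteran")]
        decisions = [DocumentDecision(doc_id="d0", label=0, source="ml")]
        out = postprocess(decisions, docs, military, confounders)
        assert out[0].label == 0

    def test_true_positive_keeps_evidence(self, military, confounders):
        docs = [ClinicalDocument("d0", "p", "patient served in the forces")]
        decisions = [DocumentDecision(doc_id="d0", label=1, source="ml")]
        out = postprocess(decisions, docs, military, confounders)
        assert out[0].label == 1
        assert out[0].evidence

    def test_doc_id_mismatch_rejected(self, military, confounders):
        docs = [ClinicalDocument("other", "p", "text")]
        decisions = [DocumentDecision(doc_id="d0", label=0, source="ml")]
        with pytest.raises(ValueError, match="align"):
            postprocess(decisions, docs, military, confounders)

    def test_monotonicity_on_synthetic_corpus(self, default_corpus, military,
                                              confounders, relations,
                                              preprocess_config):
        """Postprocessed positives are a subset of ML positives, and every
        surviving positive carries uncontained military evidence."""
        corpus = default_corpus
        streams = preprocess_corpus(corpus.documents, preprocess_config,
                                    military, relations)
        model = train(streams, corpus.doc_labels(), seed=42)
        ml = predict_documents(model, streams)
        post = postprocess(ml, corpus.documents, military, confounders)
        ml_pos = {d.doc_id for d in ml if d.label == 1}
        post_pos = {d.doc_id for d in post if d.label == 1}
        assert post_pos <= ml_pos
        for d in post:
            if d.label == 1:
                assert d.evidence


class TestAggregate:
    def test_any_positive_document_flags_patient(self):
        decisions = [DocumentDecision(doc_id=f"d{i}", label=lab, source="ml")
                     for i, lab in enumerate([0, 1, 0])]
        out = aggregate_patients(decisions, {f"d{i}": "p1" for i in range(3)})
        assert len(out) == 1
        assert out[0].label == 1
        assert out[0].n_documents == 3
        assert out[0].n_positive_documents == 1

    def test_all_negative_patient(self):
        decisions = [DocumentDecision(doc_id=f"d{i}", label=0, source="ml")
                     for i in range(2)]
        out = aggregate_patients(decisions, {f"d{i}": "p1" for i in range(2)})
        assert out[0].label == 0

    def test_unmapped_doc_rejected(self):
        with pytest.raises(KeyError):
            aggregate_patients([DocumentDecision(doc_id="d0", label=0,
                                                 source="ml")], {})

    def test_order_invariance(self):
        rng = np.random.default_rng(17)
        decisions = [
            DocumentDecision(doc_id=f"d{i}", label=int(rng.integers(2)),
                             source="ml")
            for i in range(40)
        ]
        mapping = {f"d{i}": f"p{i % 7}" for i in range(40)}
        baseline = aggregate_patients(decisions, mapping)
        for _ in range(10):
            perm = list(rng.permutation(len(decisions)))
            shuffled = [decisions[i] for i in perm]
            assert aggregate_patients(shuffled, mapping) == baseline
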