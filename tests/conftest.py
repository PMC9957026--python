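import pytest

from msit.corpus_io import PatientRecord
from msit.gazetteer import default_lexicons
from msit.ml_classifier import PatientDecision
from msit.preprocess import PreprocessConfig
from msit.synthdata import SimConfig, generate


@pytest.fixture(scope="session")
def lexicons():
    return default_lexicons()


@pytest.fixture(scope="session")
def military(lexicons):
    return lexicons["military"]


@pytest.fixture(scope="session")
def confounders(lexicons):
    return lexicons["confounder"]


@pytest.fixture(scope="session")
def relations(lexicons):
    return lexicons["relation"]


@pytest.fixture(scope="session")
def preprocess_config(lexicons):
    return PreprocessConfig(
        stopwords=lexicons["stopword"].entries,
        confusion_terms=lexicons["confounder"],
    )


@pytest.fixture(scope="session")
def default_corpus():
    """The default synthetic corpus (seed 42, 400 patients, ~2000 docs)."""
    return generate(SimConfig())


@pytest.fixture(scope="session")
def small_corpus():
    return generate(SimConfig(n_patients=60, seed=7))


def survey_table(a: int = 111, b: int = 1, c: int = 23, d: int = 11):
    """Reconstruct patient-level predictions and truth realizing a 2x2 table.

    Cell convention: a=(pred 0, true 0), b=(pred 0, true 1),
    c=(pred 1, true 0), d=(pred 1, true 1).
    """
    preds, truth = [], []
    i = 0
    for count, pred, true in ((a, 0, 0), (b, 0, 1), (c, 1, 0), (d, 1, 1)):
        for _ in range(count):
            pid = f"S{i:03d}"
            preds.append(PatientDecision(patient_id=pid, label=pred,
                                         n_documents=1, n_positive_documents=pred))
            truth.append(PatientRecord(patient_id=pid, self_report=true))
            i += 1
    return preds, truth
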