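"""Template-based synthetic corpus of psychiatric secondary-care notes.

The generator emulates the statistical structure the two-stage pipeline
assumes: a minority of patients are veterans (default prevalence 0.233, the
proportion the validation survey classified as veterans), veterans disclose
their own service in some of their notes, and non-veteran notes may carry
the documented confounders — a family member's military service, support
from the Salvation Army, or military-flavoured metaphors. Notes are
assembled from plain-text sentence templates (auditable data files, not
code); per-note and per-patient truth is recorded alongside the text.

Randomness: one seed drives everything. Each patient gets an independent
sub-stream derived by stable hashing of (seed, patient_id), so editing one
patient's parameters never perturbs another's notes.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np

from .corpus_io import ClinicalDocument, PatientMetadata, PatientRecord


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for corpus generation.

    veteran_prevalence defaults to 0.233 (34/146 in the validation survey).
    p_disclosure is the per-note probability that a true veteran's note
    mentions their own service. The three confounder probabilities apply
    per note to non-veteran patients (confounders caused false positives in
    validation, so they are injected on the negative class by default;
    set confounders_on_veterans to extend them to everyone).
    """

    n_patients: int = 400
    docs_per_patient: tuple[int, int] = (3, 7)
    veteran_prevalence: float = 0.233
    p_family_confounder: float = 0.15
    p_charity_confounder: float = 0.10
    p_metaphor: float = 0.10
    p_disclosure: float = 0.6
    confounders_on_veterans: bool = False
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ConfigError("n_patients must be >= 2")
        lo, hi = self.docs_per_patient
        if not (1 <= lo <= hi):
            raise ConfigError("docs_per_patient must satisfy 1 <= min <= max")
        for name in ("veteran_prevalence", "p_family_confounder",
                     "p_charity_confounder", "p_metaphor", "p_disclosure"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class NoteAnnotation:
    """Generator truth for one note."""

    doc_id: str
    patient_id: str
    contains_self_service: bool
    contains_other_service: bool
    contains_confounder: bool  # charity mention and/or metaphor


@dataclass(frozen=True)
class SyntheticCorpus:
    documents: tuple[ClinicalDocument, ...]
    patients: tuple[PatientRecord, ...]
    note_annotations: tuple[NoteAnnotation, ...]

    def doc_to_patient(self) -> dict[str, str]:
        return {d.doc_id: d.patient_id for d in self.documents}

    def doc_labels(self) -> dict[str, int]:
        """Gold document labels: 1 iff the note discloses the patient's own service."""
        return {a.doc_id: int(a.contains_self_service) for a in self.note_annotations}

    def patient_truth(self) -> dict[str, int]:
        return {p.patient_id: p.self_report for p in self.patients}


def _load_templates(name: str) -> list[str]:
    ref = resources.files("msit").joinpath("data", "templates", f"{name}.txt")
    return [
        line.strip() for line in ref.read_text(encoding="utf-8").splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    ]


# Branch phrases used to fill {branch} slots; all are military-lexicon entries.
_BRANCHES = ("army", "navy", "royal air force", "royal marines", "armed forces")
_RELATIONS = ("father", "husband", "brother", "grandfather", "uncle", "son",
              "mother", "wife", "sister", "partner")


def _substream(seed: int, patient_id: str) -> np.random.Generator:
    """Independent per-patient RNG via stable hashing of (seed, patient_id)."""
    digest = hashlib.sha256(f"{seed}:{patient_id}".encode()).digest()
    entropy = int.from_bytes(digest[:8], "big") % (2**31)
    return np.random.default_rng(np.random.SeedSequence([seed % (2**31), entropy]))


@dataclass
class _Templates:
    filler: list[str] = field(default_factory=lambda: _load_templates("filler"))
    self_service: list[str] = field(default_factory=lambda: _load_templates("self_service"))
    other_service: list[str] = field(default_factory=lambda: _load_templates("other_service"))
    charity: list[str] = field(default_factory=lambda: _load_templates("charity"))
    metaphor: list[str] = field(default_factory=lambda: _load_templates("metaphor"))


def _pick(rng: np.random.Generator, items: list[str]) -> str:
    return items[int(rng.integers(len(items)))]


def generate(config: SimConfig) -> SyntheticCorpus:
    """Generate a labeled corpus. Deterministic (byte-identical) given seed."""
    tpl = _Templates()
    documents: list[ClinicalDocument] = []
    patients: list[PatientRecord] = []
    annotations: list[NoteAnnotation] = []

    width = len(str(config.n_patients))
    for i in range(config.n_patients):
        patient_id = f"P{i:0{width}d}"
        rng = _substream(config.seed, patient_id)
        is_veteran = bool(rng.random() < config.veteran_prevalence)
        lo, hi = config.docs_per_patient
        n_docs = int(rng.integers(lo, hi + 1))

        # Guarantee at least one disclosing note when disclosure is certain.
        disclose_flags = [
            bool(rng.random() < config.p_disclosure) if is_veteran else False
            for _ in range(n_docs)
        ]
        if is_veteran and config.p_disclosure >= 1.0 and not any(disclose_flags):
            disclose_flags[0] = True

        for j in range(n_docs):
            doc_id = f"{patient_id}-D{j}"
            sentences = [
                _pick(rng, tpl.filler)
                for _ in range(2 + int(rng.integers(0, 3)))
            ]
            self_service = disclose_flags[j]
            other_service = False
            confounder = False

            if self_service:
                sent = _pick(rng, tpl.self_service).format(branch=_pick(rng, list(_BRANCHES)))
                sentences.insert(int(rng.integers(len(sentences) + 1)), sent)

            if (not is_veteran) or config.confounders_on_veterans:
                if rng.random() < config.p_family_confounder:
                    other_service = True
                    sent = _pick(rng, tpl.other_service).format(
                        relation=_pick(rng, list(_RELATIONS)),
                        branch=_pick(rng, list(_BRANCHES)),
                    )
                    sentences.insert(int(rng.integers(len(sentences) + 1)), sent)
                if rng.random() < config.p_charity_confounder:
                    confounder = True
                    sentences.insert(int(rng.integers(len(sentences) + 1)),
                                     _pick(rng, tpl.charity))
                if rng.random() < config.p_metaphor:
                    confounder = True
                    sentences.insert(int(rng.integers(len(sentences) + 1)),
                                     _pick(rng, tpl.metaphor))

            documents.append(
                ClinicalDocument(doc_id=doc_id, patient_id=patient_id,
                                 text=" ".join(sentences))
            )
            annotations.append(
                NoteAnnotation(
                    doc_id=doc_id,
                    patient_id=patient_id,
                    contains_self_service=self_service,
                    contains_other_service=other_service,
                    contains_confounder=confounder,
                )
            )
        patients.append(PatientRecord(patient_id=patient_id,
                                      self_report=int(is_veteran)))

    return SyntheticCorpus(
        documents=tuple(documents),
        patients=tuple(patients),
        note_annotations=tuple(annotations),
    )


# Eligibility-metadata generation ------------------------------------------

DEFAULT_EXCLUSION_RATES: dict[str, float] = {
    # Per-criterion probability that a patient FAILS the criterion,
    # sampled independently.
    "alive": 0.02,
    "age_18_or_older": 0.05,
    "consent_given": 0.40,
    "no_dementia_or_psychosis": 0.15,
    "has_email_or_phone": 0.10,
    "english_without_interpreter": 0.05,
    "coordinator_approved_if_active": 0.10,
}


def generate_metadata(
    config: SimConfig,
    exclusion_rates: dict[str, float] | None = None,
) -> list[PatientRecord]:
    """Sample eligibility metadata for config.n_patients patients.

    Each criterion fails independently at its exclusion rate; deterministic
    given the config seed. Patients keep their veteran status draw from
    :func:`generate` (same sub-streams are NOT shared; metadata uses its own
    stream so corpus and metadata can be generated in either order).
    """
    rates = dict(DEFAULT_EXCLUSION_RATES)
    if exclusion_rates:
        unknown = set(exclusion_rates) - set(rates)
        if unknown:
            raise ConfigError(f"unknown exclusion-rate keys: {sorted(unknown)}")
        rates.update(exclusion_rates)
    for k, v in rates.items():
        if not (0.0 <= v <= 1.0):
            raise ConfigError(f"exclusion rate {k} must be in [0, 1]")

    records: list[PatientRecord] = []
    width = len(str(config.n_patients))
    for i in range(config.n_patients):
        patient_id = f"P{i:0{width}d}"
        rng = _substream(config.seed, f"meta:{patient_id}")
        fails = {k: bool(rng.random() < v) for k, v in rates.items()}
        active = bool(rng.random() < 0.5)
        meta = PatientMetadata(
            alive=not fails["alive"],
            age=17.0 if fails["age_18_or_older"] else float(18 + int(rng.integers(0, 63))),
            consent=not fails["consent_given"],
            dementia_or_psychosis=fails["no_dementia_or_psychosis"],
            has_contact=not fails["has_email_or_phone"],
            english_ok=not fails["english_without_interpreter"],
            active=active if not fails["coordinator_approved_if_active"] else True,
            coordinator_approved=not fails["coordinator_approved_if_active"],
        )
        records.append(PatientRecord(patient_id=patient_id, metadata=meta))
    return records


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    return replace(config, seed=seed)
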