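"""Stage-1 keyword rule classifier.

Historically this stage ran as SQL LIKE-pattern queries over a records
database; the semantics are reproduced here as in-memory phrase matching —
a document is flagged as evidence of the patient's own military service when,
after punctuation stripping and other-person attribution removal, at least
one military phrase survives confounder suppression. The same decision rule
doubles as the postprocessing gate for the learned classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .corpus_io import ClinicalDocument
from .gazetteer import Lexicon, PhraseMatch, surviving_military_matches
from .preprocess import remove_other_person_service, strip_punctuation


@dataclass(frozen=True)
class DocumentDecision:
    """A per-document service/no-service call with its supporting matches.

    source: ``rule`` (stage-1 keyword), ``ml`` (raw learned classifier), or
    ``ml_postprocessed`` (learned classifier gated by the keyword rule).
    A positive decision from rule or ml_postprocessed always carries
    non-empty evidence.
    """

    doc_id: str
    label: int
    evidence: tuple[PhraseMatch, ...] = field(default_factory=tuple)
    source: str = "rule"

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        if self.label == 1 and self.source in ("rule", "ml_postprocessed") and not self.evidence:
            raise ValueError(f"positive {self.source} decision requires evidence")


def rule_classify(
    doc: ClinicalDocument,
    military: Lexicon,
    confounders: Lexicon,
    relations: Lexicon,
    window: int = 5,
    raw_keywords: bool = False,
) -> DocumentDecision:
    """Classify one document with the keyword rule.

    With ``raw_keywords=True`` the other-person attribution step is skipped
    and any surviving military phrase counts — the behaviour of a plain
    keyword query, kept selectable because it is the degraded mode whose
    false positives (family members' service) motivated attribution removal.
    """
    cleaned = strip_punctuation(doc.text)
    if not raw_keywords:
        cleaned = remove_other_person_service(cleaned, military, relations, window=window)
    evidence = tuple(surviving_military_matches(cleaned, military, confounders))
    return DocumentDecision(
        doc_id=doc.doc_id,
        label=1 if evidence else 0,
        evidence=evidence,
        source="rule",
    )


def rule_classify_corpus(docs, military, confounders, relations, window: int = 5,
                         raw_keywords: bool = False) -> list[DocumentDecision]:
    return [
        rule_classify(d, military, confounders, relations, window=window,
                      raw_keywords=raw_keywords)
        for d in docs
    ]
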