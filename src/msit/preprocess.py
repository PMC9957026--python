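"""The four-step note-cleaning pipeline applied before feature extraction.

Steps, in fixed order:

1. strip punctuation (regex), lowercase, collapse whitespace;
2. delete mentions of another person's military service (a military phrase
   with a relation word — "father", "husband" ... — within a token window on
   either side is removed together with the relation word);
3. drop stop words and corpus-frequent terms, except tokens that occur in a
   military lexicon entry, which are always retained;
4. delete confusion phrases ("salvation army") as whole units.

Step 2 operates on text, steps 3–4 on token streams; step 3 needs corpus
document frequencies, so the corpus-level entry point is
:func:`preprocess_corpus`.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

from ._normalize import normalize, tokenize_with_offsets
from .corpus_io import ClinicalDocument
from .gazetteer import Lexicon, find_matches, make_lexicon


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunables for the cleaning pipeline.

    frequent_term_threshold is a document-frequency proportion in (0, 1];
    non-military tokens whose df exceeds it are dropped. relation_window is
    the symmetric token distance within which a relation word attributes a
    military mention to another person.
    """

    stopwords: frozenset[str] = frozenset()
    frequent_term_threshold: float = 0.85
    relation_window: int = 5
    confusion_terms: Lexicon = field(
        default_factory=lambda: make_lexicon("empty-confounders", "confounder", [])
    )

    def __post_init__(self) -> None:
        if not (0 < self.frequent_term_threshold <= 1):
            raise ValueError("frequent_term_threshold must be in (0, 1]")
        if self.relation_window < 1:
            raise ValueError("relation_window must be >= 1")


@dataclass(frozen=True)
class TokenStream:
    """Ordered normalized tokens of one document."""

    doc_id: str
    tokens: tuple[str, ...]


def strip_punctuation(text: str) -> str:
    """Step 1: lowercase, punctuation to spaces, whitespace collapsed."""
    return normalize(text)


def _token_spans_for_matches(normalized: str, matches) -> list[tuple[int, int]]:
    """Convert character-span matches into [first_token, last_token] index spans."""
    tokens = tokenize_with_offsets(normalized)
    starts = {start: i for i, (_, start, _) in enumerate(tokens)}
    ends = {end: i for i, (_, _, end) in enumerate(tokens)}
    spans = []
    for m in matches:
        if m.start in starts and m.end in ends:
            spans.append((starts[m.start], ends[m.end]))
    return spans


def remove_other_person_service(
    text: str, military: Lexicon, relations: Lexicon, window: int = 5
) -> str:
    """Step 2: delete military mentions attributed to another person.

    *text* must already be punctuation-stripped. A military match is deleted,
    together with the relation word that attributes it, when a relation match
    lies within *window* tokens on either side (fewer than *window* tokens
    separate the two spans). Everything else is left untouched.
    """
    normalized = text
    mil_spans = _token_spans_for_matches(normalized, find_matches(normalized, military))
    if not mil_spans:
        return normalized
    rel_spans = _token_spans_for_matches(normalized, find_matches(normalized, relations))
    if not rel_spans:
        return normalized

    def token_gap(ms: int, me: int, rs: int, re: int) -> int:
        # number of tokens strictly between the two inclusive spans
        if re < ms:
            return ms - re - 1
        if me < rs:
            return rs - me - 1
        return 0  # overlapping spans

    to_delete: set[int] = set()
    for ms, me in mil_spans:
        attributed_by = [
            (rs, re) for rs, re in rel_spans if token_gap(ms, me, rs, re) < window
        ]
        if attributed_by:
            to_delete.update(range(ms, me + 1))
            for rs, re in attributed_by:
                to_delete.update(range(rs, re + 1))

    tokens = [t for t, _, _ in tokenize_with_offsets(normalized)]
    kept = [tok for i, tok in enumerate(tokens) if i not in to_delete]
    return " ".join(kept)


def document_frequencies(streams: Sequence[TokenStream]) -> dict[str, float]:
    """Proportion of documents containing each token."""
    n = len(streams)
    if n == 0:
        return {}
    counts = Counter(tok for s in streams for tok in set(s.tokens))
    return {tok: c / n for tok, c in counts.items()}


def remove_stop_and_frequent(
    streams: Sequence[TokenStream], config: PreprocessConfig, military: Lexicon
) -> list[TokenStream]:
    """Step 3: drop stop words and corpus-frequent tokens, sparing military tokens.

    Any token that occurs inside a military lexicon entry is always retained,
    whatever its document frequency — the military vocabulary is the signal
    the downstream classifier exists to find.
    """
    df = document_frequencies(streams)
    protected = military.token_set
    thr = config.frequent_term_threshold

    def keep(tok: str) -> bool:
        if tok in protected:
            return True
        if tok in config.stopwords:
            return False
        return df.get(tok, 0.0) <= thr

    return [
        TokenStream(doc_id=s.doc_id, tokens=tuple(t for t in s.tokens if keep(t)))
        for s in streams
    ]


def remove_confusion_terms(stream: TokenStream, confusion_terms: Lexicon) -> TokenStream:
    """Step 4: delete token subsequences equal to a confusion entry, as units."""
    if not confusion_terms.entries:
        return stream
    entry_tuples = sorted(confusion_terms.entry_token_tuples(), key=len, reverse=True)
    tokens = stream.tokens
    out: list[str] = []
    i = 0
    n = len(tokens)
    while i < n:
        matched = 0
        for tup in entry_tuples:
            k = len(tup)
            if i + k <= n and tokens[i:i + k] == tup:
                matched = k
                break
        if matched:
            i += matched
        else:
            out.append(tokens[i])
            i += 1
    return TokenStream(doc_id=stream.doc_id, tokens=tuple(out))


def preprocess_corpus(
    docs: Sequence[ClinicalDocument],
    config: PreprocessConfig,
    military: Lexicon,
    relations: Lexicon,
) -> list[TokenStream]:
    """Apply steps 1→2→3→4 in order; one (possibly empty) stream per document."""
    streams = []
    for doc in docs:
        cleaned = strip_punctuation(doc.text)
        cleaned = remove_other_person_service(
            cleaned, military, relations, window=config.relation_window
        )
        streams.append(TokenStream(doc_id=doc.doc_id, tokens=tuple(cleaned.split())))
    streams = remove_stop_and_frequent(streams, config, military)
    return [remove_confusion_terms(s, config.confusion_terms) for s in streams]
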