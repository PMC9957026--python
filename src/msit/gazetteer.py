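"""Lexicons of military, confounder and relation phrases, and normalized
phrase matching over note text.

Matching is case-insensitive, token-boundary aligned, and performed on the
normal form of the text (lowercased, punctuation stripped, whitespace
collapsed). Offsets are 0-based half-open character positions in the normal
form. When several entries match at the same start, the longest wins;
matches starting at different positions may overlap — this is what lets a
confounder phrase ("salvation army") strictly contain a military term
("army") so the military hit can be suppressed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal

from ._normalize import normalize, tokenize_with_offsets

Role = Literal["military", "confounder", "relation", "stopword"]


class LexiconError(ValueError):
    """Raised when a lexicon is unusable (e.g. an empty military lexicon)."""


@dataclass(frozen=True)
class PhraseMatch:
    """One lexicon hit in the normalized text (half-open character span)."""

    entry: str
    start: int
    end: int
    role: str

    def contains(self, other: "PhraseMatch") -> bool:
        return self.start <= other.start and other.end <= self.end


@dataclass(frozen=True)
class Lexicon:
    """A named set of normalized phrases sharing one role."""

    name: str
    role: str
    entries: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if any(e == "" for e in self.entries):
            raise LexiconError(f"lexicon {self.name!r} contains an empty entry")
        if self.role == "military" and not self.entries:
            raise LexiconError(f"military lexicon {self.name!r} has no entries")

    @property
    def token_set(self) -> frozenset[str]:
        """Every individual token occurring in any entry."""
        return frozenset(tok for e in self.entries for tok in e.split(" "))

    def entry_token_tuples(self) -> list[tuple[str, ...]]:
        return [tuple(e.split(" ")) for e in self.entries]


def make_lexicon(name: str, role: str, phrases: Iterable[str]) -> Lexicon:
    """Build a lexicon from raw phrases, normalizing and deduplicating."""
    entries = frozenset(filter(None, (normalize(p) for p in phrases)))
    return Lexicon(name=name, role=role, entries=entries)


def load_lexicon(path: str | Path, role: str) -> Lexicon:
    """Load a plain-text lexicon: one phrase per line, '#' comments allowed."""
    path = Path(path)
    phrases = [
        line for line in path.read_text(encoding="utf-8").splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    ]
    return make_lexicon(name=path.stem, role=role, phrases=phrases)


_DEFAULT_FILES = {
    "military": "military.txt",
    "confounder": "confounders.txt",
    "relation": "relations.txt",
    "stopword": "stopwords.txt",
}


def default_lexicon(role: str) -> Lexicon:
    """Load one of the packaged default lexicons by role."""
    fname = _DEFAULT_FILES[role]
    ref = resources.files("msit").joinpath("data", "lexicons", fname)
    phrases = [
        line for line in ref.read_text(encoding="utf-8").splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    ]
    return make_lexicon(name=fname.removesuffix(".txt"), role=role, phrases=phrases)


def default_lexicons() -> dict[str, Lexicon]:
    """All packaged lexicons keyed by role (military/confounder/relation/stopword)."""
    return {role: default_lexicon(role) for role in _DEFAULT_FILES}


def find_matches(text: str, lexicon: Lexicon) -> list[PhraseMatch]:
    """All token-boundary occurrences of lexicon entries in normalize(text).

    Returned sorted by start offset. At each starting token the longest
    matching entry is kept; matches at distinct starts may overlap.
    """
    normalized = normalize(text)
    tokens = tokenize_with_offsets(normalized)
    if not tokens or not lexicon.entries:
        return []
    token_words = [t[0] for t in tokens]
    # Index entries by first token for a linear scan.
    by_first: dict[str, list[tuple[str, ...]]] = {}
    for tup in lexicon.entry_token_tuples():
        by_first.setdefault(tup[0], []).append(tup)
    for tups in by_first.values():
        tups.sort(key=len, reverse=True)  # longest entry wins at a given start

    matches: list[PhraseMatch] = []
    n = len(tokens)
    for i, word in enumerate(token_words):
        for tup in by_first.get(word, ()):
            k = len(tup)
            if i + k <= n and tuple(token_words[i:i + k]) == tup:
                matches.append(
                    PhraseMatch(
                        entry=" ".join(tup),
                        start=tokens[i][1],
                        end=tokens[i + k - 1][2],
                        role=lexicon.role,
                    )
                )
                break  # longest-first: first hit at this start wins
    return matches


def surviving_military_matches(
    text: str, military: Lexicon, confounders: Lexicon
) -> list[PhraseMatch]:
    """Military matches not contained within any confounder match span.

    Containment suppression is the mechanism behind the "Salvation Army"
    failure mode: "army" matches the military lexicon but lies inside the
    confounder span, so it carries no evidence of service.
    """
    mil = find_matches(text, military)
    if not mil:
        return []
    conf = find_matches(text, confounders)
    return [m for m in mil if not any(c.contains(m) for c in conf)]


def has_military_evidence(text: str, military: Lexicon, confounders: Lexicon) -> bool:
    """True iff at least one military match survives confounder suppression."""
    return bool(surviving_military_matches(text, military, confounders))
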