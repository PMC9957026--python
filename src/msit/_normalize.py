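"""Shared text normalization: one rule used by lexicons, matching and preprocessing.

Normal form: lowercase, every character that is not a letter, digit or
whitespace replaced by a space, whitespace runs collapsed to single spaces,
leading/trailing space stripped. Tokens are the space-separated pieces of the
normal form; all offsets in this package are 0-based half-open character
offsets into the normal form.
"""

from __future__ import annotations

import re

# \w includes the underscore, which is punctuation for our purposes.
_NON_WORD = re.compile(r"[^\w\s]|_", flags=re.UNICODE)
_WS = re.compile(r"\s+")


def normalize(text: str) -> str:
    """Lowercase *text*, strip punctuation to spaces and collapse whitespace."""
    cleaned = _NON_WORD.sub(" ", text)
    return _WS.sub(" ", cleaned).strip().lower()


_TOKEN = re.compile(r"\S+")


def tokenize_with_offsets(normalized: str) -> list[tuple[str, int, int]]:
    """Split an already-normalized string into (token, start, end) triples."""
    return [(m.group(), m.start(), m.end()) for m in _TOKEN.finditer(normalized)]
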