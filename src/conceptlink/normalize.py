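"""Shared text normalization for vocabulary building and topic matching.

The vocabulary and the phrase matcher must agree on tokenization exactly,
otherwise a term added from one source can silently fail to match in
another.  All text — seed terms, author keywords, titles, abstracts —
passes through the same rules:

* Unicode NFKC normalization, lowercasing
* tokens are runs of alphanumerics; internal hyphens are kept
  ("cross-modal" is one token), all other punctuation is a separator
* whitespace collapses; tokenization is idempotent
"""

from __future__ import annotations

import re
import unicodedata
from typing import NamedTuple

# alnum runs joined by single internal hyphens ("long-term" stays whole)
_TOKEN_RE = re.compile(r"[^\W_]+(?:-[^\W_]+)*", re.UNICODE)


class Token(NamedTuple):
    """A normalized token with its character span in the original text."""

    text: str
    start: int
    end: int


# NFKC may expand a word character into a string containing punctuation
# ("½" -> "1⁄2"); anything that is not a word character or internal hyphen
# is dropped so normalization stays a fixed point.
_STRIP_RE = re.compile(r"[^\w-]|_", re.UNICODE)


def _norm(s: str) -> str:
    return _STRIP_RE.sub("", unicodedata.normalize("NFKC", s).lower())


def normalize_text(text: str) -> list[Token]:
    """Tokenize ``text``, returning normalized tokens with source offsets.

    Offsets index into the original (un-normalized) string so matches can
    be mapped back to the raw record fields.
    """
    out = []
    for m in _TOKEN_RE.finditer(text):
        norm = _norm(m.group(0))
        if norm:
            out.append(Token(norm, m.start(), m.end()))
    return out


def normalize_phrase(phrase: str) -> str:
    """Canonical single-space form of a phrase (vocabulary surface form)."""
    return " ".join(tok.text for tok in normalize_text(phrase))


def phrase_tokens(phrase: str) -> tuple[str, ...]:
    """Normalized token tuple of a phrase."""
    return tuple(tok.text for tok in normalize_text(phrase))
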