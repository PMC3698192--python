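"""Tokenization and normalization shared by the lexicon, annotator and extractors.

Text chunks and lexical variants are compared as *bags of words*: repeated
tokens count with multiplicity. The normalization policy (case folding,
punctuation stripping, optional light stemming) must be identical on both
sides of the comparison, so it is a small value object carried by the lexicon.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass

# word = letters/digits optionally joined by internal apostrophes or hyphens
_TOKEN_RE = re.compile(r"[A-Za-z0-9][A-Za-z0-9'\-]*")

#: Minimal English stopword list. Used only to delimit noun-phrase candidate
#: chunks; it deliberately errs on the small side so that domain terms are
#: never swallowed.
STOPWORDS = frozenset(
    """a an the this that these those it its they them their he she his her
    and or but nor so yet of in on at by to for with from into onto over
    under between within without about against during before after above
    below up down out off than as is are was were be been being am do does
    did doing have has had having will would shall should may might must can
    could not no nor if then else when while where which who whom whose what
    how why there here also very such each any all some most more other
    own same s t just don now""".split()
)

#: Pronouns recognized as the elided-subject form of a facet pattern.
PRONOUNS = frozenset({"it", "they", "this", "these"})


@dataclass(frozen=True)
class TokenPolicy:
    """Normalization policy applied to every string before comparison.

    Parameters
    ----------
    fold_case:
        Lower-case all tokens (default True).
    stem:
        Strip simple English plural suffixes (``-ies``→``y``, ``-es``, ``-s``).
        Off by default: surface bags of words, no morphology.
    """

    fold_case: bool = True
    stem: bool = False

    def normalize_token(self, token: str) -> str:
        if self.fold_case:
            token = token.lower()
        if self.stem:
            token = _light_stem(token)
        return token

    def tokenize(self, text: str) -> list[str]:
        """Normalized tokens of ``text`` in order (punctuation discarded)."""
        return [self.normalize_token(m.group()) for m in _TOKEN_RE.finditer(text)]

    def bag(self, text: str) -> Counter:
        """Normalized bag of words of ``text``."""
        return Counter(self.tokenize(text))

    def bag_key(self, text: str) -> tuple[str, ...]:
        """Canonical hashable key of a bag of words (sorted, with multiplicity)."""
        return tuple(sorted(self.tokenize(text)))


def _light_stem(token: str) -> str:
    if len(token) > 4 and token.endswith("ies"):
        return token[:-3] + "y"
    if len(token) > 3 and token.endswith("es"):
        return token[:-2]
    if len(token) > 3 and token.endswith("s") and not token.endswith("ss"):
        return token[:-1]
    return token


def token_spans(text: str) -> list[tuple[int, int, str]]:
    """Raw (start, end, token) triples, 0-based half-open character offsets."""
    return [(m.start(), m.end(), m.group()) for m in _TOKEN_RE.finditer(text)]


DEFAULT_POLICY = TokenPolicy()
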