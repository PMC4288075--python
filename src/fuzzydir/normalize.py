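"""Query and directory-name normalization.

Raw search strings arrive in mixed case, with punctuation, and often
decorated with honorifics and clinical credentials ("Dr. Smith, MD").
Everything downstream — the edit-distance scorer, the phonetic encoder,
the nickname lookup — operates on bare lowercase a–z tokens, so this
module is the single funnel every name passes through.

Rules, in order:

1. lowercase;
2. transliterate non-ASCII letters to their closest ASCII base letter
   (``é`` → ``e``) via Unicode NFKD decomposition;
3. delete periods, commas, apostrophes (``o'brien`` → ``obrien``);
4. split on whitespace and hyphens (hyphenated surnames become two
   tokens, so either component can match);
5. drop any character still outside a–z;
6. drop tokens exactly equal to a stop term (credential/honorific).

Stop-term removal is exact-token only: "dr" removes the token "dr",
never truncates "drake".
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "DEFAULT_STOPTERMS",
    "NormalizedName",
    "load_stopterms",
    "normalize",
]

_PUNCT_DELETE = re.compile(r"[.,'’]")
_SPLIT = re.compile(r"[\s\-_/]+")
_NON_ALPHA = re.compile(r"[^a-z]")
_TOKEN = re.compile(r"^[a-z]+$")


def _default_stopterms() -> tuple[str, ...]:
    text = resources.files("fuzzydir.data").joinpath("stopterms.txt").read_text()
    return tuple(line.strip() for line in text.splitlines() if line.strip())


#: Credentials and honorifics stripped by default (dr, md, phd, ...).
DEFAULT_STOPTERMS: tuple[str, ...] = _default_stopterms()


@dataclass(frozen=True)
class NormalizedName:
    """A name reduced to ordered lowercase a–z tokens.

    ``tokens`` may be empty only for degenerate input (empty string,
    punctuation-only, or all tokens removed as stop terms); callers
    decide whether that is an error.
    """

    tokens: tuple[str, ...]
    source: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        for tok in self.tokens:
            if not _TOKEN.match(tok):
                raise ValueError(f"token {tok!r} is not a lowercase a-z word")

    def render(self) -> str:
        """Canonical single-string rendering (tokens joined by spaces)."""
        return " ".join(self.tokens)

    def __iter__(self):
        return iter(self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)


def load_stopterms(path: str | Path) -> tuple[str, ...]:
    """Read a one-term-per-line stop-term file (lowercased, blanks skipped)."""
    lines = Path(path).read_text().splitlines()
    return tuple(t.strip().lower() for t in lines if t.strip())


def normalize(
    raw: str | NormalizedName,
    stopterms: Iterable[str] | None = None,
) -> NormalizedName:
    """Normalize a raw query or directory name to comparable tokens.

    Parameters
    ----------
    raw
        Free-form string as typed by a user, or an already-normalized
        name (returned unchanged up to stop-term filtering, making the
        function idempotent).
    stopterms
        Lowercase credential/honorific tokens to drop; defaults to
        :data:`DEFAULT_STOPTERMS`.
    """
    if isinstance(raw, NormalizedName):
        raw = raw.render()
    stops = frozenset(DEFAULT_STOPTERMS if stopterms is None else stopterms)

    text = raw.lower()
    # NFKD pulls accented letters apart into base letter + combining mark;
    # dropping non-ASCII bytes then keeps only the base letter.
    text = unicodedata.normalize("NFKD", text).encode("ascii", "ignore").decode("ascii")
    text = _PUNCT_DELETE.sub("", text)
    tokens = []
    for piece in _SPLIT.split(text):
        tok = _NON_ALPHA.sub("", piece)
        if tok and tok not in stops:
            tokens.append(tok)
    return NormalizedName(tokens=tuple(tokens), source=raw)


def normalize_tokens(raw: str, stopterms: Iterable[str] | None = None) -> tuple[str, ...]:
    """Shorthand for ``normalize(raw, stopterms).tokens``."""
    return normalize(raw, stopterms).tokens
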