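"""American Soundex and the keyboard-adjacency typo model.

Two letter-level relations feed the weighted edit distance:

* *same sound* — letters sharing an American Soundex digit group
  (b f p v → 1; c g j k q s x z → 2; d t → 3; l → 4; m n → 5; r → 6);
  a phonetic misspelling tends to substitute within a group ("Smith"
  vs "Smyth").
* *keyboard adjacency* — the up-to-eight keys physically surrounding a
  key on a QWERTY layout; a fat-finger typo substitutes a neighbor
  ("Smith" vs "Smitj", j sits next to h).

Full Soundex codes (``S530``) also power the Soundex baseline search
engine.  Both the sound-group table and the adjacency table ship as CSV
files under :mod:`fuzzydir.data` so the model is auditable and editable.
"""

from __future__ import annotations

import csv
import re
from functools import lru_cache
from importlib import resources
from pathlib import Path

__all__ = [
    "SOUND_GROUPS",
    "VOWELS",
    "keyboard_neighbors",
    "load_keyboard_adjacency",
    "same_sound",
    "soundex",
]

VOWELS = frozenset("aeiou")

_SOUNDEX_RE = re.compile(r"^[A-Z][0-9]{3}$")
_TOKEN_RE = re.compile(r"^[a-z]+$")


def _load_sound_groups() -> dict[str, str]:
    groups: dict[str, str] = {}
    with resources.files("fuzzydir.data").joinpath("sound_groups.csv").open() as fh:
        for row in csv.DictReader(fh):
            groups[row["letter"]] = row["group"]
    return groups


#: Letter -> Soundex digit ('1'..'6'); vowels and h, w, y are uncoded (absent).
SOUND_GROUPS: dict[str, str] = _load_sound_groups()


def load_keyboard_adjacency(path: str | Path | None = None) -> dict[str, frozenset[str]]:
    """Load a letter -> neighboring-letters table from CSV.

    The bundled default uses a grid-aligned QWERTY layout
    (``qwertyuiop`` / ``asdfghjkl`` / ``zxcvbnm`` at equal column
    indices) so every interior key has exactly eight letter neighbors;
    edge and corner keys have fewer.  Non-letter keys are excluded.
    """
    if path is None:
        fh = resources.files("fuzzydir.data").joinpath("keyboard_qwerty.csv").open()
    else:
        fh = open(path)
    with fh:
        table = {
            row["letter"]: frozenset(row["neighbors"])
            for row in csv.DictReader(fh)
        }
    for letter, nbrs in table.items():
        for n in nbrs:
            if letter not in table.get(n, frozenset()):
                raise ValueError(f"adjacency not symmetric: {letter!r} -> {n!r}")
    return table


_QWERTY: dict[str, frozenset[str]] = load_keyboard_adjacency()


def keyboard_neighbors(c: str) -> frozenset[str]:
    """Letters on the keys surrounding ``c`` on a QWERTY keyboard."""
    if len(c) != 1 or not c.isascii() or not c.islower():
        raise ValueError(f"expected a single lowercase letter, got {c!r}")
    return _QWERTY[c]


def same_sound(a: str, b: str) -> bool:
    """Whether two letters are phonetically interchangeable.

    True for identical letters, for any vowel pair (Soundex drops all
    vowels identically, and vowel swaps dominate phonetic misspellings),
    and for letters sharing a Soundex digit group.  Uncoded consonant
    pairs (h/w/y with anything else) are not considered sound-alike.
    """
    if a == b:
        return True
    if a in VOWELS and b in VOWELS:
        return True
    ga, gb = SOUND_GROUPS.get(a), SOUND_GROUPS.get(b)
    return ga is not None and ga == gb


@lru_cache(maxsize=65536)
def soundex(token: str) -> str:
    """American Soundex code of a lowercase token, e.g. ``smith -> S530``.

    Standard rules: keep the first letter; encode the rest by digit
    group; h and w are transparent (they do not separate equal digits);
    vowels and y separate; collapse adjacent equal digits; pad with
    zeros / truncate to letter + three digits.
    """
    if not _TOKEN_RE.match(token):
        raise ValueError(f"soundex requires a nonempty lowercase a-z token, got {token!r}")
    out = [token[0].upper()]
    prev = SOUND_GROUPS.get(token[0])
    for ch in token[1:]:
        if ch in "hw":
            continue  # transparent: a repeated digit across h/w still collapses
        digit = SOUND_GROUPS.get(ch)
        if digit is None:  # vowel or y: uncoded, but breaks a run
            prev = None
            continue
        if digit != prev:
            out.append(digit)
            if len(out) == 4:
                break
        prev = digit
    code = "".join(out).ljust(4, "0")
    assert _SOUNDEX_RE.match(code)
    return code
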