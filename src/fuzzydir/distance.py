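"""Weighted Levenshtein distance with letter-aware operation costs.

The classic Levenshtein distance charges every edit the same, so the
one-key slip ``smith -> smitj`` costs as much as the wild substitution
``smith -> smizq``.  This module's cost model charges less for the
edits people actually make when typing names:

=====================================  ====
operation                              cost
=====================================  ====
delete a vowel (a e i o u)             4
delete a letter equal to its
predecessor (repeated letter)          4
delete any other letter                5
substitute sound-alike letters
(same Soundex group, e.g. d/t)         3
substitute keyboard-adjacent letters
(e.g. h/j on QWERTY)                   3
substitute any other pair              4
substitute a letter for itself         0
=====================================  ====

Insertions mirror deletions: inserting a letter costs what deleting it
would, with the repeated-letter rule read against its predecessor in
the target string.  This keeps the distance symmetric.

All costs are parameters of :class:`CostModel`; the defaults above are
the model of record.  :func:`unit_distance` provides the classic
all-ops-cost-1 distance used by the "simple LD" baseline engine.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Literal, NamedTuple

import edlib

from .phonetics import VOWELS, keyboard_neighbors, same_sound

__all__ = [
    "CostModel",
    "EditOp",
    "WeightedLevenshtein",
    "deletion_cost",
    "insertion_cost",
    "substitution_cost",
    "unit_distance",
    "weighted_distance",
]


@dataclass(frozen=True)
class CostModel:
    """Per-operation edit costs; defaults are the customized model."""

    vowel_deletion: float = 4.0
    repeat_deletion: float = 4.0
    default_deletion: float = 5.0
    samesound_substitution: float = 3.0
    adjacent_substitution: float = 3.0
    default_substitution: float = 4.0

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if value < 0:
                raise ValueError(f"{name} must be nonnegative, got {value}")
        if self.samesound_substitution > self.default_substitution:
            raise ValueError("samesound_substitution must not exceed default_substitution")
        if self.vowel_deletion > self.default_deletion:
            raise ValueError("vowel_deletion must not exceed default_deletion")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CostModel":
        return cls(**json.loads(text))


def deletion_cost(c: str, prev: str | None, model: CostModel | None = None) -> float:
    """Cost of deleting ``c``, whose predecessor in the string is ``prev``.

    Vowels and repeated letters are cheap to drop (people elide them);
    anything else costs the full deletion penalty.
    """
    m = model or _DEFAULT_MODEL
    if c in VOWELS:
        return m.vowel_deletion
    if prev is not None and c == prev:
        return m.repeat_deletion
    return m.default_deletion


def insertion_cost(c: str, prev: str | None, model: CostModel | None = None) -> float:
    """Cost of inserting ``c`` after ``prev``; mirrors :func:`deletion_cost`."""
    return deletion_cost(c, prev, model)


def substitution_cost(a: str, b: str, model: CostModel | None = None) -> float:
    """Cost of substituting ``a`` with ``b``.

    0 for identical letters; discounted when the letters sound alike
    (same Soundex group, vowel pairs) or sit on adjacent QWERTY keys.
    """
    m = model or _DEFAULT_MODEL
    if a == b:
        return 0.0
    if same_sound(a, b):
        return m.samesound_substitution
    if b in keyboard_neighbors(a):
        return m.adjacent_substitution
    return m.default_substitution


class EditOp(NamedTuple):
    """One step of an edit script transforming a source into a target."""

    kind: Literal["match", "substitute", "delete", "insert"]
    source_char: str | None
    target_char: str | None
    cost: float


class WeightedLevenshtein:
    """Dynamic-programming weighted edit distance under a :class:`CostModel`.

    Substitution costs are precomputed into a 26x26 table and pairwise
    distances are memoized, so repeated scoring of a query against a
    directory's token vocabulary stays cheap.
    """

    def __init__(self, model: CostModel | None = None):
        self.model = model or _DEFAULT_MODEL
        m = self.model
        letters = "abcdefghijklmnopqrstuvwxyz"
        self._sub = [
            [substitution_cost(a, b, m) for b in letters] for a in letters
        ]
        self._is_vowel = [ch in VOWELS for ch in letters]
        self._cache: dict[tuple[str, str], float] = {}

    def distance(self, s: str, t: str) -> float:
        """Minimum total edit cost transforming ``s`` into ``t``."""
        if s == t:
            return 0.0
        key = (s, t)
        cached = self._cache.get(key)
        if cached is not None:
            return cached
        result = self._dp(s, t)[-1][-1]
        self._cache[key] = result
        return result

    __call__ = distance

    def _op_costs(self, s: str, t: str):
        a = ord("a")
        si = [ord(c) - a for c in s]
        ti = [ord(c) - a for c in t]
        for i in si + ti:
            if not 0 <= i < 26:
                raise ValueError("weighted distance is defined over lowercase a-z tokens")
        m = self.model

        def indel(idx: list[int]) -> list[float]:
            # rule order matches deletion_cost: vowel, then repeat, then default
            return [
                m.vowel_deletion
                if self._is_vowel[c]
                else m.repeat_deletion
                if k > 0 and c == idx[k - 1]
                else m.default_deletion
                for k, c in enumerate(idx)
            ]

        return si, ti, indel(si), indel(ti)

    def _dp(self, s: str, t: str) -> list[list[float]]:
        si, ti, dels, inss = self._op_costs(s, t)
        sub = self._sub
        n = len(ti)
        rows = [[0.0] * (n + 1) for _ in range(len(si) + 1)]
        row0 = rows[0]
        for j in range(n):
            row0[j + 1] = row0[j] + inss[j]
        for i, sc in enumerate(si):
            prev_row, cur_row = rows[i], rows[i + 1]
            cur_row[0] = prev_row[0] + dels[i]
            sub_sc = sub[sc]
            for j in range(n):
                best = prev_row[j] + sub_sc[ti[j]]
                up = prev_row[j + 1] + dels[i]
                if up < best:
                    best = up
                left = cur_row[j] + inss[j]
                if left < best:
                    best = left
                cur_row[j + 1] = best
        return rows

    def explain(self, s: str, t: str) -> list[EditOp]:
        """An optimal edit script from ``s`` to ``t`` (backtrace of the DP).

        The script's summed cost equals :meth:`distance`; applying it to
        ``s`` reproduces ``t``.  Ties are broken substitution-first.
        """
        si, ti, dels, inss = self._op_costs(s, t)
        rows = self._dp(s, t)
        ops: list[EditOp] = []
        i, j = len(si), len(ti)
        while i > 0 or j > 0:
            here = rows[i][j]
            if i > 0 and j > 0 and rows[i - 1][j - 1] + self._sub[si[i - 1]][ti[j - 1]] == here:
                cost = self._sub[si[i - 1]][ti[j - 1]]
                kind = "match" if s[i - 1] == t[j - 1] else "substitute"
                ops.append(EditOp(kind, s[i - 1], t[j - 1], cost))
                i, j = i - 1, j - 1
            elif i > 0 and rows[i - 1][j] + dels[i - 1] == here:
                ops.append(EditOp("delete", s[i - 1], None, dels[i - 1]))
                i -= 1
            else:
                ops.append(EditOp("insert", None, t[j - 1], inss[j - 1]))
                j -= 1
        ops.reverse()
        return ops


_DEFAULT_MODEL = CostModel()
_DEFAULT_WL = WeightedLevenshtein(_DEFAULT_MODEL)


def weighted_distance(s: str, t: str, model: CostModel | None = None) -> float:
    """Weighted edit distance between two lowercase tokens.

    Convenience wrapper; reuses a shared calculator for the default
    model, builds a fresh one otherwise.
    """
    if model is None or model == _DEFAULT_MODEL:
        return _DEFAULT_WL.distance(s, t)
    return WeightedLevenshtein(model).distance(s, t)


def unit_distance(s: str, t: str) -> int:
    """Classic Levenshtein distance (every operation costs 1)."""
    if s == t:
        return 0
    if not s or not t:
        return max(len(s), len(t))
    return edlib.align(s, t)["editDistance"]
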