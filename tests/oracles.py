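"""Independent reference computations used to check the package.

Each oracle deliberately takes a different route than the implementation
it validates: edit distances by exhaustive script enumeration instead of
dynamic programming, Soundex by whole-string digit mapping instead of a
streaming encoder, K-S statistics by direct ECDF-gap enumeration.
"""

from itertools import groupby
from math import inf

from fuzzydir.distance import (
    CostModel,
    deletion_cost,
    insertion_cost,
    substitution_cost,
)

_GROUPS = {
    **dict.fromkeys("bfpv", "1"),
    **dict.fromkeys("cgjkqsxz", "2"),
    **dict.fromkeys("dt", "3"),
    "l": "4",
    **dict.fromkeys("mn", "5"),
    "r": "6",
}


def enumerated_weighted_distance(s: str, t: str, model: CostModel | None = None) -> float:
    """Minimum edit-script cost by plain recursive enumeration (no DP table).

    Explores every interleaving of delete/insert/substitute steps;
    exponential, intended for tokens of length <= 6.
    """
    model = model or CostModel()

    def rec(i: int, j: int) -> float:
        if i == len(s) and j == len(t):
            return 0.0
        best = inf
        if i < len(s):
            prev = s[i - 1] if i > 0 else None
            best = min(best, deletion_cost(s[i], prev, model) + rec(i + 1, j))
        if j < len(t):
            prev = t[j - 1] if j > 0 else None
            best = min(best, insertion_cost(t[j], prev, model) + rec(i, j + 1))
        if i < len(s) and j < len(t):
            step = substitution_cost(s[i], t[j], model)
            best = min(best, step + rec(i + 1, j + 1))
        return best

    return rec(0, 0)


def dp_unit_distance(s: str, t: str) -> int:
    """Classic Levenshtein by an explicit pure-Python DP table."""
    prev = list(range(len(t) + 1))
    for i, a in enumerate(s, 1):
        cur = [i]
        for j, b in enumerate(t, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (a != b)))
        prev = cur
    return prev[-1]


def whole_string_soundex(token: str) -> str:
    """American Soundex via map-then-collapse over the whole string.

    Remove h/w (transparent), map every remaining letter to its digit
    with vowels and y as '0', collapse adjacent equal symbols, drop the
    leading symbol (the first letter's own code) and the '0' separators,
    pad/truncate to three digits behind the uppercased first letter.
    """
    seq = [_GROUPS.get(token[0], "0")]
    seq += [_GROUPS.get(c, "0") for c in token[1:] if c not in "hw"]
    collapsed = [k for k, _ in groupby(seq)]
    digits = [d for d in collapsed[1:] if d != "0"]
    return (token[0].upper() + "".join(digits) + "000")[:4]


def ecdf_gap(x, y) -> float:
    """Supremum |ECDF_x(v) - ECDF_y(v)| by enumeration over all sample points."""
    xs, ys = sorted(x), sorted(y)

    def cdf(sample, v):
        return sum(1 for s in sample if s <= v) / len(sample)

    points = set(xs) | set(ys)
    return max(abs(cdf(xs, v) - cdf(ys, v)) for v in points)
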