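"""Nickname lookup with per-pair matching likelihoods.

"Bill" is neither spelled nor pronounced like "William", so no edit
distance or phonetic code will connect a nickname query to the formal
name a directory stores.  A lookup table of (canonical, nickname)
pairs, each carrying the probability that the canonical name is
rendered as that nickname (William -> Bill 0.9, William -> Will 0.45),
closes the gap: the search engine folds the likelihood into the match
score so a common nickname ranks nearly as well as an exact match.

The table is symmetric in direction — the probability that a query
"bill" refers to directory entry "william" is taken equal to the
forward likelihood, since one number is stored per pair.  A small
fixture table of common US nickname pairs ships with the package;
production use supplies a full census-derived CSV.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

__all__ = ["NicknameEntry", "NicknameTable", "load_nicknames", "bundled_nicknames"]


@dataclass(frozen=True)
class NicknameEntry:
    canonical: str
    nickname: str
    likelihood: float

    def __post_init__(self) -> None:
        if not (0 < self.likelihood <= 1):
            raise ValueError(
                f"likelihood must be in (0, 1], got {self.likelihood} "
                f"for {self.canonical!r}/{self.nickname!r}"
            )
        if self.canonical == self.nickname:
            raise ValueError(f"canonical and nickname are identical: {self.canonical!r}")


@dataclass
class NicknameTable:
    """Bidirectional (canonical, nickname, likelihood) lookup."""

    entries: tuple[NicknameEntry, ...] = ()
    _by_canonical: dict[str, list[NicknameEntry]] = field(init=False, repr=False)
    _by_nickname: dict[str, list[NicknameEntry]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        self._by_canonical = {}
        self._by_nickname = {}
        for e in self.entries:
            pair = (e.canonical, e.nickname)
            if pair in seen:
                raise ValueError(f"duplicate nickname pair {pair}")
            seen.add(pair)
            self._by_canonical.setdefault(e.canonical, []).append(e)
            self._by_nickname.setdefault(e.nickname, []).append(e)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, name: str) -> bool:
        return name in self._by_canonical or name in self._by_nickname

    def likelihood(self, canonical: str, nickname: str) -> float | None:
        """Stored likelihood for the ordered pair, or ``None`` if absent.

        By convention ``likelihood(x, x) == 1.0``: a name trivially
        "matches" itself.
        """
        if canonical == nickname:
            return 1.0
        for e in self._by_canonical.get(canonical, ()):
            if e.nickname == nickname:
                return e.likelihood
        return None

    def variants(self, name: str) -> list[tuple[str, float]]:
        """All table neighbors of ``name``, in both directions.

        Nicknames of ``name`` (treating it as canonical) plus canonical
        forms of ``name`` (treating it as a nickname), each with its
        likelihood.  Empty list for a name absent from the table.
        """
        out = [(e.nickname, e.likelihood) for e in self._by_canonical.get(name, ())]
        out += [(e.canonical, e.likelihood) for e in self._by_nickname.get(name, ())]
        return out


def _build(rows: Iterable[tuple[str, str, str]], origin: str) -> NicknameTable:
    entries = []
    for lineno, (canonical, nickname, likelihood) in rows:
        try:
            entries.append(
                NicknameEntry(canonical.strip().lower(), nickname.strip().lower(), float(likelihood))
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{origin}, line {lineno}: {exc}") from exc
    return NicknameTable(tuple(entries))


def load_nicknames(path: str | Path) -> NicknameTable:
    """Load a ``canonical,nickname,likelihood`` CSV into a table.

    Rows with a likelihood outside (0, 1], identical canonical/nickname,
    or a missing field are rejected with an error naming the line; so
    are duplicate pairs.
    """
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"canonical", "nickname", "likelihood"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"{path}: header must contain {sorted(required)}")
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if any(row.get(k) in (None, "") for k in required):
                raise ValueError(f"{path}, line {lineno}: malformed row {row}")
            rows.append((lineno, (row["canonical"], row["nickname"], row["likelihood"])))
    return _build(rows, str(path))


def bundled_nicknames() -> NicknameTable:
    """The fixture table of common US nickname pairs shipped in-package."""
    with resources.as_file(resources.files("fuzzydir.data").joinpath("nicknames.csv")) as p:
        return load_nicknames(p)
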