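"""Top-k fuzzy retrieval over a name directory, plus baseline engines.

The customized engine (``fuzzy_custom``) scores a query against every
directory entry with the weighted Levenshtein distance, expanding
given names through the nickname table: a nickname branch scores
``distance(query, variant) + alpha * (1 - likelihood)``, so a
high-likelihood nickname (William/Bill, 0.9) costs almost nothing
extra while a weak one approaches the price of a cheap substitution.
Lower scores are better; results are ranked by (score, surname, id)
and truncated to ``k``.

Three reference engines share the pipeline for comparison:

* ``exact`` — normalized full-name equality, the behavior of a
  conventional directory search box;
* ``soundex`` — surname (and, when present, given-name) Soundex code
  equality;
* ``simple_ld`` — the same top-k retrieval with the classic unit-cost
  Levenshtein distance and no nickname expansion.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .distance import CostModel, WeightedLevenshtein, unit_distance
from .nicknames import NicknameTable
from .normalize import DEFAULT_STOPTERMS, NormalizedName, normalize
from .phonetics import soundex

__all__ = [
    "DirectoryEntry",
    "EngineConfig",
    "MatchResult",
    "SearchEngine",
    "load_directory",
    "save_directory",
    "token_score",
    "entry_score",
]

EngineVariant = Literal["exact", "soundex", "simple_ld", "fuzzy_custom"]


@lru_cache(maxsize=65536)
def _name_tokens(text: str) -> tuple[str, ...]:
    # entry-name normalization never strips credentials: a physician
    # legitimately surnamed "Doctor" must stay searchable
    return normalize(text, stopterms=()).tokens


@dataclass(frozen=True)
class DirectoryEntry:
    """One searchable record: a person with a given name and a surname."""

    id: str
    given_name: str
    surname: str
    display_name: str = ""
    metadata: dict = field(default_factory=dict, compare=False)

    @property
    def given_tokens(self) -> tuple[str, ...]:
        return _name_tokens(self.given_name)

    @property
    def surname_tokens(self) -> tuple[str, ...]:
        return _name_tokens(self.surname)


@dataclass(frozen=True)
class EngineConfig:
    """Tunable knobs of the retrieval pipeline.

    ``nickname_penalty_weight`` (alpha) converts a nickname's match
    likelihood p into an additive score penalty ``alpha * (1 - p)``.
    """

    k: int = 10
    cost_model: CostModel = field(default_factory=CostModel)
    nickname_penalty_weight: float = 2.0
    engine_variant: EngineVariant = "fuzzy_custom"
    stopterms: tuple[str, ...] = DEFAULT_STOPTERMS

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.nickname_penalty_weight < 0:
            raise ValueError("nickname_penalty_weight must be nonnegative")
        if self.engine_variant not in ("exact", "soundex", "simple_ld", "fuzzy_custom"):
            raise ValueError(f"unknown engine variant {self.engine_variant!r}")

    def to_json(self) -> str:
        payload = {
            "k": self.k,
            "cost_model": json.loads(self.cost_model.to_json()),
            "nickname_penalty_weight": self.nickname_penalty_weight,
            "engine_variant": self.engine_variant,
            "stopterms": list(self.stopterms),
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "EngineConfig":
        payload = json.loads(text)
        if "cost_model" in payload:
            payload["cost_model"] = CostModel(**payload["cost_model"])
        if "stopterms" in payload:
            payload["stopterms"] = tuple(payload["stopterms"])
        return cls(**payload)


@dataclass(frozen=True)
class MatchResult:
    entry_id: str
    score: float
    rank: int
    display_name: str = ""


_EMPTY_TABLE = NicknameTable()


def token_score(
    q: str,
    t: str,
    dist,
    table: NicknameTable | None = None,
    alpha: float = 2.0,
) -> float:
    """Score one query token against one directory token.

    Minimum over the direct distance and, when a nickname table is
    supplied, every nickname branch: replace either side by a table
    variant and pay ``alpha * (1 - likelihood)`` on top of the distance
    to the variant.
    """
    best = dist(q, t)
    if table is not None and best > 0:
        for v, p in table.variants(t):
            cand = dist(q, v) + alpha * (1.0 - p)
            if cand < best:
                best = cand
        for v, p in table.variants(q):
            cand = dist(v, t) + alpha * (1.0 - p)
            if cand < best:
                best = cand
    return best


def entry_score(
    query_tokens: Sequence[str],
    entry: DirectoryEntry,
    config: EngineConfig | None = None,
    table: NicknameTable | None = None,
    dist=None,
) -> float:
    """Score a whole query against one directory entry.

    One token is compared against both the given name and the surname
    (surname-only queries are common) and the better side wins.  Two
    tokens are assigned to (given, surname) in whichever order scores
    lower.  Extra tokens beyond two are dropped at the default-deletion
    cost each, over the best two-token sub-assignment.

    Nickname branches apply to given-name comparisons only: census
    nicknames are first names.
    """
    config = config or EngineConfig()
    if dist is None:
        dist = WeightedLevenshtein(config.cost_model)
    if not query_tokens:
        raise ValueError("cannot score an empty query")
    alpha = config.nickname_penalty_weight

    def vs_given(tok: str) -> float:
        return min(token_score(tok, g, dist, table, alpha) for g in entry.given_tokens)

    def vs_surname(tok: str) -> float:
        return min(token_score(tok, s, dist, None, alpha) for s in entry.surname_tokens)

    if len(query_tokens) == 1:
        tok = query_tokens[0]
        return min(vs_given(tok), vs_surname(tok))

    def pair_score(a: str, b: str) -> float:
        return min(vs_given(a) + vs_surname(b), vs_given(b) + vs_surname(a))

    if len(query_tokens) == 2:
        return pair_score(*query_tokens)

    drop_cost = config.cost_model.default_deletion
    n = len(query_tokens)
    best = min(
        pair_score(query_tokens[i], query_tokens[j])
        for i in range(n)
        for j in range(i + 1, n)
    )
    return best + drop_cost * (n - 2)


class SearchEngine:
    """A directory plus a config, answering top-k ranked name queries.

    Directory names are normalized once at construction; weighted
    distances are memoized per unique token pair, so repeated queries
    over the same directory amortize well.
    """

    def __init__(
        self,
        directory: Sequence[DirectoryEntry],
        config: EngineConfig | None = None,
        nicknames: NicknameTable | None = None,
    ):
        if not directory:
            raise ValueError("directory must contain at least one entry")
        ids = [e.id for e in directory]
        if len(set(ids)) != len(ids):
            raise ValueError("directory entry ids must be unique")
        self.config = config or EngineConfig()
        self.table = nicknames if nicknames is not None else _EMPTY_TABLE
        self.directory = list(directory)
        self._wl = WeightedLevenshtein(self.config.cost_model)
        # sort key used everywhere: (score, surname, id)
        self._sort_names = {
            e.id: (" ".join(e.surname_tokens), e.id) for e in self.directory
        }

    # -- scoring engines ------------------------------------------------

    def search(self, raw: str | NormalizedName) -> list[MatchResult]:
        """Rank the directory for a raw query under the configured variant."""
        variant = self.config.engine_variant
        if variant == "exact":
            return self.baseline_exact(raw)
        if variant == "soundex":
            return self.baseline_soundex(raw)
        if variant == "simple_ld":
            return self.baseline_simple_ld(raw)
        return self._ranked(raw, self._wl, self.table)

    def baseline_exact(self, raw: str | NormalizedName) -> list[MatchResult]:
        """Entries whose normalized full name equals the normalized query."""
        tokens = self._query_tokens(raw)
        hits = []
        for e in self.directory:
            full = e.given_tokens + e.surname_tokens
            flipped = e.surname_tokens + e.given_tokens
            if tokens == full or tokens == flipped:
                hits.append(e)
        hits.sort(key=lambda e: self._sort_names[e.id])
        return [
            MatchResult(e.id, 0.0, rank, e.display_name)
            for rank, e in enumerate(hits, start=1)
        ]

    def baseline_soundex(self, raw: str | NormalizedName) -> list[MatchResult]:
        """Surname Soundex-code retrieval, given-name code as a tiebreaker."""
        tokens = self._query_tokens(raw)
        codes = [soundex(t) for t in tokens]
        scored = []
        for e in self.directory:
            sur_codes = {soundex(t) for t in e.surname_tokens}
            matched = [i for i, c in enumerate(codes) if c in sur_codes]
            if not matched:
                continue
            n_match = 1
            if len(tokens) >= 2:
                given_codes = {soundex(t) for t in e.given_tokens}
                others = [c for i, c in enumerate(codes) if i != matched[0]]
                if any(c in given_codes for c in others):
                    n_match += 1
            scored.append((len(tokens) - n_match, e))
        scored.sort(key=lambda se: (se[0],) + self._sort_names[se[1].id])
        return [
            MatchResult(e.id, float(s), rank, e.display_name)
            for rank, (s, e) in enumerate(scored[: self.config.k], start=1)
        ]

    def baseline_simple_ld(self, raw: str | NormalizedName) -> list[MatchResult]:
        """Top-k with classic unit-cost Levenshtein, no nickname expansion."""
        return self._ranked(raw, unit_distance, table=None)

    # -- internals -------------------------------------------------------

    def _query_tokens(self, raw: str | NormalizedName) -> tuple[str, ...]:
        name = raw if isinstance(raw, NormalizedName) else normalize(raw, self.config.stopterms)
        if not name.tokens:
            raise ValueError(f"query {name.source!r} normalizes to no tokens")
        return name.tokens

    def _ranked(self, raw, dist, table) -> list[MatchResult]:
        tokens = self._query_tokens(raw)
        scored = [
            (entry_score(tokens, e, self.config, table, dist), e)
            for e in self.directory
        ]
        scored.sort(key=lambda se: (se[0],) + self._sort_names[se[1].id])
        return [
            MatchResult(e.id, float(s), rank, e.display_name)
            for rank, (s, e) in enumerate(scored[: self.config.k], start=1)
        ]

    def with_variant(self, variant: EngineVariant) -> "SearchEngine":
        """A sibling engine over the same directory and nickname table."""
        eng = SearchEngine.__new__(SearchEngine)
        eng.config = replace(self.config, engine_variant=variant)
        eng.table = self.table
        eng.directory = self.directory
        eng._wl = self._wl  # share the distance cache
        eng._sort_names = self._sort_names
        return eng


def load_directory(path: str | Path) -> list[DirectoryEntry]:
    """Read a directory CSV: ``id,given_name,surname,display_name[,...]``.

    Extra columns land in ``metadata``.  A missing display name is
    synthesized as "Given Surname".
    """
    core = ("id", "given_name", "surname", "display_name")
    entries = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not set(core[:3]).issubset(reader.fieldnames):
            raise ValueError(f"{path}: header must contain id,given_name,surname")
        for row in reader:
            display = (row.get("display_name") or "").strip()
            if not display:
                display = f"{row['given_name'].strip()} {row['surname'].strip()}".strip()
            entries.append(
                DirectoryEntry(
                    id=row["id"].strip(),
                    given_name=row["given_name"].strip(),
                    surname=row["surname"].strip(),
                    display_name=display,
                    metadata={k: v for k, v in row.items() if k not in core},
                )
            )
    if not entries:
        raise ValueError(f"{path}: directory is empty")
    return entries


def save_directory(entries: Iterable[DirectoryEntry], path: str | Path) -> None:
    """Write entries as the directory CSV format read by :func:`load_directory`."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "given_name", "surname", "display_name"])
        for e in entries:
            writer.writerow([e.id, e.given_name, e.surname, e.display_name])
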