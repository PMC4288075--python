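"""Accuracy@k evaluation and a seeded synthetic benchmark generator.

Evaluation runs a gold *challenge set* — pairs of a realistic
misspelled/variant query and the true directory name — through an
engine and counts how often the true entry lands at rank 1 and within
the top k.

Because real challenge sets (search logs matched to a directory by
hand) are rarely shareable, the module also generates them: it samples
synthetic directories from bundled name-frequency pools and corrupts
entry names with the three mismatch mechanisms the engine is built to
absorb — keyboard-adjacent typos, phonetic substitutions (same
Soundex group, vowel drops, doubled letters), and nickname swaps.
Every generator is deterministic under its seed.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .engine import DirectoryEntry, EngineConfig, SearchEngine
from .nicknames import NicknameTable
from .normalize import NormalizedName, normalize
from .phonetics import SOUND_GROUPS, VOWELS, keyboard_neighbors

__all__ = [
    "ChallengeCase",
    "EvalReport",
    "PerturbationSpec",
    "PERTURBATION_KINDS",
    "evaluate",
    "generate_directory",
    "load_challenge",
    "bundled_challenge",
    "make_challenge",
    "perturb",
]

PERTURBATION_KINDS = (
    "adjacent_typo",
    "vowel_drop",
    "letter_double",
    "samesound_swap",
    "nickname_swap",
)


@dataclass(frozen=True)
class ChallengeCase:
    """A gold pair: what the user typed, and who they meant."""

    query: str
    expected_display_name: str


@dataclass(frozen=True)
class PerturbationSpec:
    """How to corrupt a name: which mechanism, how many edits, which seed."""

    kind: str
    n_edits: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in PERTURBATION_KINDS:
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.n_edits < 0:
            raise ValueError("n_edits must be nonnegative")


@dataclass
class EvalReport:
    """Aggregate and per-case retrieval outcome for one engine variant."""

    engine_variant: str
    k: int
    n_cases: int
    hits_at_1: int
    hits_at_k: int
    per_case: list[dict] = field(default_factory=list)

    @property
    def accuracy_at_1(self) -> float:
        return self.hits_at_1 / self.n_cases

    @property
    def accuracy_at_k(self) -> float:
        return self.hits_at_k / self.n_cases

    def to_json(self) -> str:
        return json.dumps(
            {
                "engine_variant": self.engine_variant,
                "k": self.k,
                "n_cases": self.n_cases,
                "hits_at_1": self.hits_at_1,
                "hits_at_k": self.hits_at_k,
                "accuracy_at_1": self.accuracy_at_1,
                "accuracy_at_k": self.accuracy_at_k,
                "per_case": self.per_case,
            },
            indent=2,
        )

    def summary(self) -> str:
        return (
            f"{self.engine_variant}: {self.hits_at_1}/{self.n_cases} at rank 1 "
            f"({100 * self.accuracy_at_1:.0f}%), {self.hits_at_k}/{self.n_cases} "
            f"in top {self.k} ({100 * self.accuracy_at_k:.0f}%)"
        )


def _resolve(display_name: str, directory: Sequence[DirectoryEntry]) -> DirectoryEntry:
    """Match an expected display name to exactly one entry by normalized equality."""
    want = normalize(display_name, stopterms=()).tokens
    hits = [
        e
        for e in directory
        if e.given_tokens + e.surname_tokens == want
        or e.surname_tokens + e.given_tokens == want
    ]
    if len(hits) != 1:
        raise ValueError(
            f"expected name {display_name!r} resolves to {len(hits)} directory entries"
        )
    return hits[0]


def evaluate(
    engine: SearchEngine,
    cases: Sequence[ChallengeCase],
) -> EvalReport:
    """Run every challenge case through the engine and score hits@1/@k.

    A hit@k means the expected entry appears at rank <= k after the
    engine's deterministic tie-breaking.  Every expected name must
    resolve to exactly one directory entry.
    """
    if not cases:
        raise ValueError("challenge set is empty")
    k = engine.config.k
    hits1 = hitsk = 0
    per_case = []
    for case in cases:
        gold = _resolve(case.expected_display_name, engine.directory)
        results = engine.search(case.query)
        rank = next((r.rank for r in results if r.entry_id == gold.id), None)
        if rank is not None and rank <= k:
            hitsk += 1
            if rank == 1:
                hits1 += 1
        per_case.append(
            {"query": case.query, "expected": case.expected_display_name, "rank": rank}
        )
    return EvalReport(
        engine_variant=engine.config.engine_variant,
        k=k,
        n_cases=len(cases),
        hits_at_1=hits1,
        hits_at_k=hitsk,
        per_case=per_case,
    )


def _load_pool(filename: str) -> tuple[list[str], np.ndarray]:
    names, counts = [], []
    with resources.files("fuzzydir.data").joinpath(filename).open() as fh:
        for row in csv.DictReader(fh):
            names.append(row["name"])
            counts.append(float(row["count"]))
    weights = np.asarray(counts)
    return names, weights / weights.sum()


def generate_directory(
    n: int,
    seed: int,
    given_pool: tuple[list[str], np.ndarray] | None = None,
    surname_pool: tuple[list[str], np.ndarray] | None = None,
) -> list[DirectoryEntry]:
    """Sample ``n`` synthetic directory entries from the bundled name pools.

    Given names and surnames are drawn independently, weighted by their
    pool frequencies; duplicate full names are rejected and redrawn, so
    every entry has a distinct (given, surname) pair — as a staff
    directory listing would.  Ids run ``dir0001`` upward.  Deterministic
    under ``seed``.
    """
    if n < 1:
        raise ValueError(f"directory size must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    givens, gw = given_pool or _load_pool("given_names.csv")
    surnames, sw = surname_pool or _load_pool("surnames.csv")
    if n > len(givens) * len(surnames):
        raise ValueError(f"cannot draw {n} distinct full names from the pools")
    entries = []
    seen: set[tuple[str, str]] = set()
    while len(entries) < n:
        g = givens[int(rng.choice(len(givens), p=gw))]
        s = surnames[int(rng.choice(len(surnames), p=sw))]
        if (g, s) in seen:
            continue
        seen.add((g, s))
        entries.append(
            DirectoryEntry(
                id=f"dir{len(entries) + 1:04d}",
                given_name=g,
                surname=s,
                display_name=f"{g.capitalize()} {s.capitalize()}",
            )
        )
    return entries


class PerturbationError(ValueError):
    """The requested corruption cannot be applied to this name."""


def _perturb_token(token: str, kind: str, rng: np.random.Generator, table: NicknameTable) -> str:
    letters = list(token)
    if kind == "adjacent_typo":
        pos = int(rng.integers(len(letters)))
        nbrs = sorted(keyboard_neighbors(letters[pos]))
        letters[pos] = nbrs[int(rng.integers(len(nbrs)))]
        return "".join(letters)
    if kind == "vowel_drop":
        sites = [i for i, c in enumerate(letters) if c in VOWELS]
        if not sites:
            raise PerturbationError(f"no vowel to drop in {token!r}")
        del letters[sites[int(rng.integers(len(sites)))]]
        return "".join(letters)
    if kind == "letter_double":
        pos = int(rng.integers(len(letters)))
        letters.insert(pos, letters[pos])
        return "".join(letters)
    if kind == "samesound_swap":
        sites = [i for i, c in enumerate(letters) if c in SOUND_GROUPS or c in VOWELS]
        if not sites:
            raise PerturbationError(f"no sound-group letter in {token!r}")
        pos = sites[int(rng.integers(len(sites)))]
        c = letters[pos]
        if c in VOWELS:
            alts = sorted(VOWELS - {c})
        else:
            group = SOUND_GROUPS[c]
            alts = sorted(l for l, g in SOUND_GROUPS.items() if g == group and l != c)
        if not alts:
            raise PerturbationError(f"letter {c!r} has no sound-group sibling")
        letters[pos] = alts[int(rng.integers(len(alts)))]
        return "".join(letters)
    raise AssertionError(kind)


def perturb(
    name: NormalizedName | str,
    spec: PerturbationSpec,
    table: NicknameTable | None = None,
) -> str:
    """Corrupt a normalized name into a raw query string.

    Applies ``spec.n_edits`` edits of ``spec.kind``; positions and
    replacement choices are drawn deterministically from ``spec.seed``.
    ``nickname_swap`` replaces the given (first) token by a random
    nickname-table variant; the other kinds edit one random token per
    edit.  Raises :class:`PerturbationError` when the kind cannot be
    applied (no vowel to drop, no nickname variant known).
    """
    if isinstance(name, str):
        name = normalize(name, stopterms=())
    if not name.tokens:
        raise ValueError("cannot perturb an empty name")
    table = table if table is not None else NicknameTable()
    rng = np.random.default_rng(spec.seed)
    tokens = list(name.tokens)
    for _ in range(spec.n_edits):
        if spec.kind == "nickname_swap":
            variants = table.variants(tokens[0])
            if not variants:
                raise PerturbationError(f"no nickname variant for {tokens[0]!r}")
            tokens[0] = variants[int(rng.integers(len(variants)))][0]
        else:
            which = int(rng.integers(len(tokens)))
            # if the chosen token cannot host the edit, fall back to any that can
            order = [which] + [i for i in range(len(tokens)) if i != which]
            for idx in order:
                try:
                    tokens[idx] = _perturb_token(tokens[idx], spec.kind, rng, table)
                    break
                except PerturbationError:
                    continue
            else:
                raise PerturbationError(
                    f"{spec.kind} not applicable to any token of {' '.join(tokens)!r}"
                )
    return " ".join(tokens)


def make_challenge(
    directory: Sequence[DirectoryEntry],
    specs: Sequence[PerturbationSpec],
    seed: int,
    table: NicknameTable | None = None,
    max_draws: int = 200,
) -> list[ChallengeCase]:
    """Build a synthetic challenge set: one case per perturbation spec.

    For each spec an entry is sampled from the directory and its full
    name corrupted; the case's expected name is the source entry's
    display name.  If a sampled entry cannot host the perturbation
    (e.g. ``nickname_swap`` on a name with no table variants), another
    entry is drawn, up to ``max_draws`` attempts, before erroring out.
    Deterministic under ``seed``.
    """
    if not directory:
        raise ValueError("directory is empty")
    rng = np.random.default_rng(seed)
    cases = []
    for spec in specs:
        err: PerturbationError | None = None
        for _ in range(max_draws):
            entry = directory[int(rng.integers(len(directory)))]
            sub_seed = int(rng.integers(2**31))
            full = normalize(f"{entry.given_name} {entry.surname}", stopterms=())
            try:
                query = perturb(
                    full,
                    PerturbationSpec(spec.kind, spec.n_edits, sub_seed),
                    table,
                )
            except PerturbationError as exc:
                err = exc
                continue
            cases.append(ChallengeCase(query=query, expected_display_name=entry.display_name))
            break
        else:
            raise PerturbationError(
                f"no directory entry admits perturbation {spec.kind!r}: {err}"
            )
    return cases


def load_challenge(path: str | Path) -> list[ChallengeCase]:
    """Read a ``query,expected_display_name`` CSV challenge set."""
    cases = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"query", "expected_display_name"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"{path}: header must contain {sorted(required)}")
        for row in reader:
            cases.append(ChallengeCase(row["query"], row["expected_display_name"]))
    if not cases:
        raise ValueError(f"{path}: challenge set is empty")
    return cases


def bundled_challenge() -> list[ChallengeCase]:
    """The ten published example challenge pairs shipped with the package."""
    with resources.as_file(
        resources.files("fuzzydir.data").joinpath("challenge_set.csv")
    ) as p:
        return load_challenge(p)


def save_challenge(cases: Iterable[ChallengeCase], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["query", "expected_display_name"])
        for c in cases:
            writer.writerow([c.query, c.expected_display_name])
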