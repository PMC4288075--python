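# fuzzydir

Fuzzy-match search for name directories — find the physician (or staff
member, or professor) a user meant, even when the query carries a typo,
a phonetic misspelling, or a nickname.

Conventional "find a doctor" search boxes require an exact match: type
`smitj` and Dr. Smith is unreachable. Yet almost all failed name
queries fall into three mechanical classes:

* **typographic** — a finger slips to an adjacent key (`smith` → `smitj`;
  j sits next to h on QWERTY);
* **phonetic** — the name is spelled the way it sounds (`smith` →
  `smyth`);
* **nickname** — the directory says William, the user types Bill.

`fuzzydir` unifies all three in a single weighted Levenshtein distance.
For tokens *s*, *t* the score is the minimum total cost of an edit
script transforming *s* into *t*, with per-operation costs

| operation | cost |
|---|---|
| delete a vowel (a e i o u) | 4 |
| delete a letter equal to its predecessor | 4 |
| delete any other letter | 5 |
| substitute sound-alike letters (same Soundex group, e.g. d/t) | 3 |
| substitute keyboard-adjacent letters (e.g. h/j) | 3 |
| substitute any other pair | 4 |
| substitute a letter for itself | 0 |

Insertions mirror deletions, keeping the distance symmetric. Nicknames
enter through a lookup table of (canonical, nickname) pairs with a
match likelihood *p* (William→Bill 0.9, William→Will 0.45): a
nickname branch scores `d(query, variant) + α·(1 − p)` with α = 2 by
default, so a common nickname costs almost nothing. Entries are ranked
by score; the top *k* (default 10) are returned.

For comparison the package ships three baseline engines — exact match,
surname-Soundex, and top-k retrieval under the classic unit-cost
Levenshtein distance — plus an accuracy@1/accuracy@k evaluation
harness, a seeded generator of synthetic directories and corrupted
queries, and a name-diversity utility (coverage curves and two-sample
Kolmogorov–Smirnov tests) for quantifying how much harder rare names
make the problem.

## Worked example

Build a directory of the ten bundled challenge names (real
query/true-name pairs, e.g. `rousch` → Stephen Roush) plus 100 seeded
synthetic distractors, then search and evaluate:

```python
import fuzzydir as fd
from fuzzydir.evaluate import bundled_challenge, evaluate, generate_directory

cases = bundled_challenge()
gold = []
for i, c in enumerate(cases):
    toks = fd.normalize(c.expected_display_name).tokens
    gold.append(fd.DirectoryEntry(f"gold{i:02d}", toks[0], " ".join(toks[1:]),
                                  c.expected_display_name))
directory = gold + generate_directory(100, seed=42)

engine = fd.SearchEngine(directory, fd.EngineConfig(k=10), fd.bundled_nicknames())
for r in engine.search("tim swan")[:3]:
    print(f"{r.rank}  {r.entry_id}  {r.display_name}  {r.score:g}")
for variant in ("exact", "soundex", "simple_ld", "fuzzy_custom"):
    print(evaluate(engine.with_variant(variant), cases).summary())
```

prints

```
1  gold09  Timothy Swan  0.4
2  dir0020  Thomas Dixon  17.4
3  dir0035  James Bell  19.4
exact: 0/10 at rank 1 (0%), 0/10 in top 10 (0%)
soundex: 10/10 at rank 1 (100%), 10/10 in top 10 (100%)
simple_ld: 10/10 at rank 1 (100%), 10/10 in top 10 (100%)
fuzzy_custom: 10/10 at rank 1 (100%), 10/10 in top 10 (100%)
```

The query `tim swan` never exactly matches the directory entry
"Timothy Swan", so the exact engine scores 0/10 on the challenge set —
while the nickname branch prices Tim-for-Timothy at only
α·(1 − 0.8) = 0.4, far below every distractor. Distances themselves
are one call away: `fd.weighted_distance("smith", "smitj")` is 3.0
(one adjacent-key substitution) where `fd.unit_distance` says 1.

The same pipeline is scriptable from the shell:

```sh
fuzzydir gen-directory --n 800 --seed 1 --out dir.csv
fuzzydir gen-challenge --directory dir.csv --n 100 --seed 2 --out cases.csv
fuzzydir evaluate --directory dir.csv --challenge cases.csv --engine fuzzy_custom
fuzzydir search --directory dir.csv --query "Dr. Smoth" --k 3
fuzzydir coverage --freq names.csv --fraction 0.7
fuzzydir config init        # emit the default cost model / engine config
```

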