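# Methods

## Problem and model

Given a free-text query and a directory of (given name, surname)
records, rank the records by how plausibly the query is a rendering of
each name. Three failure mechanisms dominate real name queries —
keyboard slips, phonetic spellings, and nicknames — and the model
prices each of them cheaply inside one weighted Levenshtein distance
rather than bolting three matchers together.

The distance between lowercase tokens is the minimum total cost over
edit scripts (deletions, insertions, substitutions), computed by the
standard O(|s|·|t|) dynamic program with position-dependent costs:

* **Deletion**: 4 for a vowel; 4 for a letter equal to its immediate
  predecessor in the source string ("repetitive letters"); 5 otherwise.
  The predecessor at position 0 is undefined, so the first letter can
  only be a vowel-or-default deletion.
* **Substitution**: 0 for identical letters; 3 when the letters share
  an American Soundex digit group (d/t, s/z, b/v, …) or sit on
  adjacent QWERTY keys; 4 otherwise.
* **Insertion**: mirrored from deletion (the inserted letter's cost,
  with the repeat rule read against its predecessor in the *target*
  string). The mirror is a design choice — the cost table itself only
  names deletions and substitutions — and is what makes the distance
  symmetric, which we verify by property test.

Vowel–vowel substitutions are treated as sound-alike (cost 3): Soundex
drops all vowels identically and vowel swaps are the bulk of phonetic
misspellings. Uncoded consonant pairs (h/w/y against anything else)
are not discounted. `same_sound` is reflexive by definition so the
relation behaves as an equivalence-like predicate even on uncoded
letters; this never affects costs because identical letters already
substitute at 0.

There is no transposition (Damerau) operation; an adjacent-letter swap
costs one substitution-pair, typically 6–8.

### Keyboard adjacency

The "eight surrounding keys" are read from a grid-aligned QWERTY
layout (`qwertyuiop` / `asdfghjkl` / `zxcvbnm` at equal column
indices): the neighbors of a key are the letter keys at column ±1 in
its own and the two adjacent rows. Interior home-row keys (s d f g h)
then have exactly eight letter neighbors; edge and corner keys have
fewer; non-letter keys are ignored. The table ships as
`data/keyboard_qwerty.csv` (one `letter,neighbors` row per key) so the
geometry is auditable and replaceable; the loader enforces symmetry.
A physically staggered-row reading would give home-row keys only six
letter neighbors, contradicting the eight-key rule, which is why the
grid alignment was chosen.

### Soundex

Standard American Soundex: keep the first letter; code the rest by
digit group (b f p v → 1; c g j k q s x z → 2; d t → 3; l → 4;
m n → 5; r → 6); h and w are transparent (a repeated digit across them
still collapses); vowels and y separate; pad/truncate to letter + three
digits. The encoder is cross-checked in the tests against an
independently formulated map-then-collapse implementation on a
thousand random tokens, plus the classic tricky cases (ashcraft,
tymczak, pfister).

### Nicknames

A CSV table of (canonical, nickname, likelihood ∈ (0,1]) pairs, indexed
both ways. The reverse direction (nickname in the query, canonical in
the directory) reuses the forward likelihood: one number is stored per
pair, and direction-specific priors are not recoverable from the
bundled fixture. During scoring, a token pair (q, t) may route through
any table variant v of either side at cost
`distance(q or v, t or v) + α·(1 − p)`.

* **α (`nickname_penalty_weight`), default 2.0** — converts likelihood
  into score units. At α = 2 a 0.9-likelihood nickname costs 0.2,
  far below the cheapest real edit (3), while a 0.5-likelihood variant
  costs 1.0 — still competitive but rankable below better evidence.
  α = 0 makes all table variants free; large α disables the table.
* Nickname branches apply to **given-name comparisons only**: the
  table is a census-style first-name table, and surname look-alikes
  are already handled by the phonetic/typo discounts.

The bundled `data/nicknames.csv` is a ~70-pair fixture of common US
pairs. The two published likelihoods (William→Bill 0.9,
William→Will 0.45) are kept verbatim; the remaining pairs carry a
documented placeholder of 0.8 (0.85 for the stephen/steven spelling
variant). Production use should supply a full census-derived table.

## Query scoring

Queries are normalized (lowercase, ASCII transliteration, punctuation
stripped, hyphen/whitespace tokenization, credential stop-terms
removed; the default stop list `dr md do phd facs faap np pa rn mr mrs
ms` is a configurable file). Then:

* one token → best of (vs given name, vs surname): surname-only
  queries are common;
* two tokens → the cheaper of the two token-to-field assignments,
  summed;
* more tokens → best two-token sub-assignment plus one default
  deletion (5) per dropped token.

Ties break by (score, surname, id), making every ranking
deterministic; the top-k list is the prefix of the full sorted list.
Scores are not length-normalized: within one query all candidates are
comparable, which is all ranking needs.

## Baseline engines

* **exact** — normalized full-name equality (either token order).
* **soundex** — entries whose surname code equals any query token's
  code; for multi-token queries a given-name code match on another
  token ranks the entry higher. The published description does not fix
  this rule precisely; surname-anchored matching is our
  reconstruction.
* **simple_ld** — identical pipeline to the customized engine with
  unit-cost Levenshtein (via edlib) and no nickname branches.

## Synthetic benchmark

Real challenge sets pair failed search-log queries with hand-resolved
directory entries and are not redistributable, so the evaluation
module generates its own study material:

* **Directories** are sampled from bundled frequency pools (~200 given
  names, ~460 surnames with rough US-census-shaped counts, plus a few
  rare names); duplicate full names are redrawn, since a directory
  listing disambiguates people. Default benchmark size is 800 entries,
  the scale of a large group practice.
* **Queries** corrupt a sampled entry's full name with one of five
  seeded perturbations mapping onto the three failure classes:
  `adjacent_typo` (keyboard neighbor substitution), `vowel_drop`,
  `letter_double`, `samesound_swap` (within a Soundex group, or
  vowel↔vowel), `nickname_swap` (given name replaced by a table
  variant). The acceptance benchmark uses 500 single-edit queries
  cycling through all five kinds. If a sampled entry cannot host the
  requested perturbation (no vowel, no known nickname), another entry
  is drawn, up to 200 attempts, before erroring.

What the generator does **not** emulate: real query length/severity
mixtures (multi-error queries, truncations, "Last, First" order),
non-census name diversity (the pools are small and US-centric),
hyphenated or compound surnames at realistic rates, and the empirical
nickname-usage distribution. Passing the benchmark therefore shows the
engines' *relative* ordering under controlled single-error conditions
— exact ≤ Soundex ≤ simple LD ≤ customized, top-ten ≥ top-one — not
the absolute accuracies one would measure on production logs, and the
published headline percentages are deliberately not asserted.

## Diversity analysis

`coverage_curve` sorts a name-frequency table by descending count
(ties by name, for determinism) and accumulates to fractions;
`coverage_count(table, f)` is the minimal prefix reaching coverage f
(an epsilon of 1e-12 guards exactly-attained fractions against float
rounding). Two curves are compared by discretizing each into ~n draws
of "rank of the name covering a random individual"
(`curve_to_sample`, ranks repeated proportionally to coverage
increments) and applying the two-sample Kolmogorov–Smirnov test
(scipy, asymptotic p-value — appropriate at the sample sizes used and
matching the reported use of the test). The exact discretization a
given study used is rarely stated; the generic two-sample primitive is
the testable contract, and D is verified against a brute-force
ECDF-gap enumeration.

## Numerical and testing choices

* All costs are floats in a frozen `CostModel`; validation enforces
  the orderings that make the model meaningful (discounted ≤ default).
* Pairwise distances are memoized per engine; entry-name tokenization
  is memoized globally. Linear scan over the directory is in-contract
  up to ~10⁵ entries.
* The DP is verified against exhaustive edit-script enumeration
  (plain recursion, no memoization — a genuinely independent route) on
  hundreds of random pairs of length ≤ 6, under the default and a
  deliberately skewed cost model.
* Degenerate inputs: empty queries are errors at the engine boundary;
  empty tokens are legal distance arguments (pure insertion/deletion
  cost); `soundex("")` is an error.
* Problem sizes in the test suite (110-entry fixture directory;
  800-entry/500-query benchmark; 500 oracle pairs; 1000-token Soundex
  cross-check) keep the full suite under a minute while leaving the
  statistical assertions comfortable margins.

## Known limitations

* The cost constants are calibrated to anglophone QWERTY typing;
  other layouts need a different adjacency CSV, and heavily
  non-English phonologies are poorly served by Soundex groups.
* Insertion-cost mirroring is a modeling choice; an asymmetric model
  (queries corrupt directory names, not vice versa) could price
  insertions independently.
* The nickname fixture's placeholder likelihoods (0.8) are not
  empirical; rankings among nickname candidates are only as good as
  the supplied table.
* No indexing: latency grows linearly with directory size.
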