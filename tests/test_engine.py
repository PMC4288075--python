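import pytest

from fuzzydir.distance import WeightedLevenshtein, weighted_distance
from fuzzydir.engine import (
    DirectoryEntry,
    EngineConfig,
    SearchEngine,
    entry_score,
    load_directory,
    save_directory,
    token_score,
)

WL = WeightedLevenshtein()


def make_entry(i, given, surname):
    return DirectoryEntry(
        id=f"e{i:03d}",
        given_name=given,
        surname=surname,
        display_name=f"{given.capitalize()} {surname.capitalize()}",
    )


@pytest.fixture
def small_directory():
    return [
        make_entry(1, "timothy", "swan"),
        make_entry(2, "william", "roush"),
        make_entry(3, "maria", "alvarez"),
        make_entry(4, "richard", "reinhart"),
        make_entry(5, "scott", "erickson"),
    ]


class TestTokenScore:
    def test_identity_is_zero(self, nick_table):
        assert token_score("smith", "smith", WL, nick_table) == 0.0

    def test_nickname_branch_beats_raw_distance(self, nick_table):
        score = token_score("bill", "william", WL, nick_table, alpha=2.0)
        assert score == pytest.approx(2.0 * (1 - 0.9))
        assert score < WL.distance("bill", "william")
        tim = token_score("tim", "timothy", WL, nick_table, alpha=2.0)
        assert tim < WL.distance("tim", "timothy")

    def test_no_table_means_raw_distance(self):
        assert token_score("bill", "william", WL, None) == WL.distance("bill", "william")

    def test_alpha_scales_the_penalty(self, nick_table):
        cheap = token_score("bill", "william", WL, nick_table, alpha=0.0)
        dear = token_score("bill", "william", WL, nick_table, alpha=10.0)
        assert cheap == 0.0
        assert dear > cheap


class TestEntryScore:
    def test_single_token_takes_better_of_given_and_surname(self, nick_table):
        entry = make_entry(4, "richard", "reinhart")
        score = entry_score(["reinhardt"], entry, EngineConfig(), nick_table, WL)
        assert score == WL.distance("reinhardt", "reinhart")

    def test_two_tokens_best_assignment(self, nick_table):
        entry = make_entry(1, "timothy", "swan")
        score = entry_score(["tim", "swan"], entry, EngineConfig(), nick_table, WL)
        assert score == token_score("tim", "timothy", WL, nick_table, 2.0)
        # order of query tokens must not matter
        flipped = entry_score(["swan", "tim"], entry, EngineConfig(), nick_table, WL)
        assert flipped == score

    def test_exact_full_match_is_zero(self, nick_table):
        entry = make_entry(1, "timothy", "swan")
        assert entry_score(["timothy", "swan"], entry, EngineConfig(), nick_table, WL) == 0.0

    def test_extra_tokens_cost_deletions(self, nick_table):
        entry = make_entry(1, "timothy", "swan")
        config = EngineConfig()
        base = entry_score(["timothy", "swan"], entry, config, nick_table, WL)
        padded = entry_score(["timothy", "swan", "junk"], entry, config, nick_table, WL)
        assert padded == base + config.cost_model.default_deletion

    def test_empty_query_rejected(self, nick_table):
        with pytest.raises(ValueError):
            entry_score([], make_entry(1, "a", "b"), EngineConfig(), nick_table, WL)


class TestFuzzySearch:
    def test_exact_query_ranks_first_with_zero_score(self, small_directory, nick_table):
        engine = SearchEngine(small_directory, EngineConfig(k=3), nick_table)
        results = engine.search("Maria Alvarez")
        assert results[0].entry_id == "e003"
        assert results[0].score == 0.0
        assert results[0].rank == 1

    def test_zero_score_iff_exact_normalized_match(self, small_directory, nick_table):
        engine = SearchEngine(small_directory, EngineConfig(k=5), nick_table)
        assert engine.search("alvarez maria")[0].score == 0.0
        assert engine.search("alvares maria")[0].score > 0.0

    def test_topk_truncates_sorted_list(self, small_directory, nick_table):
        full = SearchEngine(small_directory, EngineConfig(k=5), nick_table).search("tim")
        top2 = SearchEngine(small_directory, EngineConfig(k=2), nick_table).search("tim")
        assert [r.entry_id for r in top2] == [r.entry_id for r in full[:2]]
        assert [r.rank for r in full] == [1, 2, 3, 4, 5]

    def test_deterministic(self, small_directory, nick_table):
        engine = SearchEngine(small_directory, EngineConfig(), nick_table)
        a = engine.search("erikson")
        b = engine.search("erikson")
        assert a == b

    def test_degenerate_query_rejected(self, small_directory):
        engine = SearchEngine(small_directory, EngineConfig())
        with pytest.raises(ValueError):
            engine.search("Dr. MD")

    def test_tie_break_by_surname_then_id(self, nick_table):
        directory = [
            make_entry(2, "ann", "zeta"),
            make_entry(1, "ann", "beta"),
        ]
        engine = SearchEngine(directory, EngineConfig(), nick_table)
        results = engine.search("ann")
        assert [r.entry_id for r in results] == ["e001", "e002"]


class TestBaselines:
    def test_exact_requires_full_equality(self, small_directory):
        engine = SearchEngine(small_directory, EngineConfig(engine_variant="exact"))
        assert engine.search("tim swan") == []
        hit = engine.search("timothy swan")
        assert hit[0].entry_id == "e001" and hit[0].rank == 1
        with pytest.raises(ValueError):
            engine.search("")

    def test_soundex_matches_code_equal_surnames(self, small_directory):
        engine = SearchEngine(small_directory, EngineConfig(engine_variant="soundex"))
        assert engine.search("smyth") == []  # no S530 surname present
        hits = engine.search("rousch")
        assert [r.entry_id for r in hits] == ["e002"]
        assert engine.search("zzz") == []

    def test_soundex_two_token_query_prefers_given_match(self):
        directory = [
            make_entry(1, "william", "roush"),
            make_entry(2, "scott", "roush"),
        ]
        engine = SearchEngine(directory, EngineConfig(engine_variant="soundex"))
        hits = engine.search("scot rousch")
        assert hits[0].entry_id == "e002"

    def test_simple_ld_scores_unit_distance(self, small_directory):
        engine = SearchEngine(small_directory, EngineConfig(engine_variant="simple_ld"))
        hits = engine.search("swann")
        assert hits[0].entry_id == "e001"
        assert hits[0].score == 1.0

    def test_simple_ld_gives_no_nickname_discount(self, small_directory, nick_table):
        simple = SearchEngine(
            small_directory, EngineConfig(engine_variant="simple_ld"), nick_table
        )
        fuzzy = SearchEngine(small_directory, EngineConfig(), nick_table)
        q = "bill roush"
        simple_score = next(r for r in simple.search(q) if r.entry_id == "e002").score
        fuzzy_score = next(r for r in fuzzy.search(q) if r.entry_id == "e002").score
        assert simple_score == 4.0  # unit_distance(bill, william) = 4
        assert fuzzy_score < simple_score


class TestConfigAndIO:
    def test_config_validation(self):
        with pytest.raises(ValueError):
            EngineConfig(k=0)
        with pytest.raises(ValueError):
            EngineConfig(nickname_penalty_weight=-1)
        with pytest.raises(ValueError):
            EngineConfig(engine_variant="bogus")

    def test_config_json_roundtrip(self):
        config = EngineConfig(k=5, nickname_penalty_weight=3.0, engine_variant="simple_ld")
        assert EngineConfig.from_json(config.to_json()) == config

    def test_directory_csv_roundtrip(self, tmp_path, small_directory):
        p = tmp_path / "dir.csv"
        save_directory(small_directory, p)
        loaded = load_directory(p)
        assert [e.id for e in loaded] == [e.id for e in small_directory]
        assert loaded[0].given_name == "timothy"

    def test_duplicate_ids_rejected(self, small_directory):
        with pytest.raises(ValueError, match="unique"):
            SearchEngine(small_directory + [small_directory[0]], EngineConfig())

    def test_empty_directory_rejected(self):
        with pytest.raises(ValueError):
            SearchEngine([], EngineConfig())
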