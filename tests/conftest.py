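import pytest

import fuzzydir as fd
from fuzzydir.evaluate import bundled_challenge, generate_directory


@pytest.fixture(scope="session")
def nick_table():
    return fd.bundled_nicknames()


@pytest.fixture(scope="session")
def challenge_cases():
    """The ten published example (query, true name) pairs."""
    return bundled_challenge()


@pytest.fixture(scope="session")
def gold_entries(challenge_cases):
    """Directory entries for the ten true names of the challenge fixture."""
    entries = []
    for i, case in enumerate(challenge_cases):
        tokens = fd.normalize(case.expected_display_name).tokens
        entries.append(
            fd.DirectoryEntry(
                id=f"gold{i:02d}",
                given_name=tokens[0],
                surname=" ".join(tokens[1:]),
                display_name=case.expected_display_name,
            )
        )
    return entries


@pytest.fixture(scope="session")
def fixture_directory(gold_entries):
    """Ten gold names plus 100 seeded synthetic distractors."""
    return gold_entries + generate_directory(100, seed=42)
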