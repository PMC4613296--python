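import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("ci")

from axomir import simlib  # noqa: E402
from axomir.knownmatch import MiRNAReferenceEntry, family_key  # noqa: E402


def entry(name: str, seq: str) -> MiRNAReferenceEntry:
    return MiRNAReferenceEntry(name, family_key(name), seq)


@pytest.fixture(scope="session")
def toy_reference() -> list[MiRNAReferenceEntry]:
    """Hand-picked mature sequences, pairwise well separated."""
    return [
        entry("aml-let-7a-5p", "TGAGGTAGTAGGTTGTATAGTT"),
        entry("aml-let-7a-3p", "CTATACAATCTACTGTCTTTCC"),
        entry("aml-mir-21", "TAGCTTATCAGACTGATGTTGA"),
        entry("aml-mir-206", "TGGAATGTAAGGAAGTGTGTGG"),
    ]


@pytest.fixture(scope="session")
def clean_scenario() -> simlib.SimulationConfig:
    """Noise-free-substitution scenario: the stated world of the planted
    novel-family recovery check (fold change 4, substitution rate 0)."""
    return simlib.make_scenario(20257, substitution_rate=0.0)


@pytest.fixture(scope="session")
def clean_sim(clean_scenario):
    return simlib.generate_libraries(clean_scenario)


@pytest.fixture(scope="session")
def noisy_scenario() -> simlib.SimulationConfig:
    """Same world with 1% per-base substitution noise, under which >=95% of
    reads carry at most two substitutions."""
    return simlib.make_scenario(20257, substitution_rate=0.01)


@pytest.fixture(scope="session")
def noisy_sim(noisy_scenario):
    return simlib.generate_libraries(noisy_scenario)
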