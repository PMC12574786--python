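from pathlib import Path

import pytest

from odpipeline.lexicon import DrugEntry, DrugLexicon, default_lexicon
from odpipeline.synth import SynthConfig, write_bundle


@pytest.fixture(scope="session")
def lexicon() -> DrugLexicon:
    return default_lexicon()


@pytest.fixture()
def tiny_lexicon() -> DrugLexicon:
    """Small hand-built vocabulary with known class memberships."""
    return DrugLexicon(
        [
            DrugEntry(
                "fentanyl",
                frozenset({"n-phenyl-n-[1-(2-phenylethyl)-4-piperidinyl]-propanamide"}),
                frozenset({"opioid"}),
            ),
            DrugEntry("4-fluorobutyrfentanyl", frozenset({"4-fbf"}), frozenset({"opioid"})),
            DrugEntry("cocaine", frozenset({"coke"}), frozenset({"stimulant"})),
            DrugEntry("kratom", frozenset({"mitragynine"}), frozenset({"stimulant", "opioid"})),
            DrugEntry("ethanol", frozenset({"alcohol"}), frozenset({"alcohol"})),
        ]
    )


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory) -> Path:
    """Seeded six-dialect fixture bundle (typo rate 0) with pipeline config."""
    out = tmp_path_factory.mktemp("bundle")
    config = SynthConfig(seed=11, n_records=500, typo_rate=0.0)
    write_bundle(config, out)
    return out
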