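"""Shared fixtures: built-in taxonomy/rules and a small synthetic dataset."""

import pandas as pd
import pytest

from vetpharm import map_consultations
from vetpharm import synthdata as sd


@pytest.fixture(scope="session")
def taxonomy():
    return sd.builtin_taxonomy()


@pytest.fixture(scope="session")
def ruleset(taxonomy):
    return sd.builtin_ruleset(taxonomy)


@pytest.fixture(scope="session")
def small_dataset():
    """Desk-scale dataset: 8 practices, ~3.6k consultations."""
    cfg = sd.SynthConfig(n_practices=8, n_animals=600,
                         consults_per_animal=6.0, seed=7)
    return sd.generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_records(small_dataset):
    return small_dataset[0]


@pytest.fixture(scope="session")
def small_gt(small_dataset):
    return small_dataset[1]


@pytest.fixture(scope="session")
def small_events(small_records, ruleset):
    events, report = map_consultations(small_records, ruleset)
    return events


def toy_taxonomy_frame(patterns):
    """One single-PC antibiotic entry per pattern (text-mapping test helper)."""
    return pd.DataFrame(
        [
            {"agent": f"agent{i}", "pc": f"pc{i}", "pf": "antibiotic",
             "authorisation": "veterinary"}
            for i in range(len(patterns))
        ]
    )


def toy_rules_frame(patterns):
    return pd.DataFrame(
        [
            {"kind": "identification_string", "pattern": p,
             "agent": f"agent{i}", "pc": f"pc{i}", "priority": i}
            for i, p in enumerate(patterns)
        ]
    )
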