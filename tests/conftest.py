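import random
import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # oracle / rest_stub helpers

from fhirtab.fixtures import FixtureConfig, default_fixture_config, generate_dataset
from fhirtab.mapping import drf_run
from fhirtab.model import ResourceType
from fhirtab.source import open_source
from fhirtab.store import create_schema


@pytest.fixture(scope="session")
def default_config():
    return default_fixture_config()


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, default_config):
    """The default 700-resource dataset, generated once per session."""
    out = tmp_path_factory.mktemp("fixture")
    generate_dataset(default_config, out)
    return out


@pytest.fixture(scope="session")
def loaded(tmp_path_factory, fixture_dir):
    """(schema, mapping report) after a full DRF run over the default dataset."""
    store = tmp_path_factory.mktemp("store") / "store.sqlite"
    schema = create_schema(str(store))
    source = open_source(str(fixture_dir))
    report = drf_run(source, list(ResourceType), schema)
    return schema, report


def random_valid_config(seed: int) -> FixtureConfig:
    """A small random FixtureConfig satisfying every invariant."""
    rng = random.Random(seed)
    n_pat = rng.randint(5, 40)
    n_prac = rng.randint(1, 10)
    male = rng.randint(0, n_pat)
    gender_quota = {"male": male, "female": n_pat - male}

    years = rng.sample(range(1950, 2022), rng.randint(2, 8))
    birth_hist = _random_histogram(rng, years, n_pat)

    labels = rng.sample(
        ["Shellfish", "Latex", "Codeine", "Peanut", "Dust", "Aspirin", "Wool"],
        rng.randint(1, 5),
    )
    n_allergy = rng.randint(len(labels), min(3 * len(labels), n_pat * len(labels)))
    allergy_table = _random_histogram(rng, labels, n_allergy, cap=n_pat)
    n_allergy = sum(allergy_table.values())

    tests = rng.sample(["HIV", "CBC", "MRI", "COVID", "SGPT", "X-Ray"], rng.randint(1, 4))
    n_sr = rng.randint(len(tests), 4 * len(tests))
    test_table = _random_histogram(rng, tests, n_sr)
    order_years = rng.sample(range(1950, 2022), rng.randint(1, min(6, n_sr)))
    order_hist = _random_histogram(rng, order_years, n_sr)

    return FixtureConfig(
        counts_per_type={
            ResourceType.PATIENT: n_pat,
            ResourceType.ALLERGY_INTOLERANCE: n_allergy,
            ResourceType.PRACTITIONER: n_prac,
            ResourceType.CONDITION: rng.randint(0, 10),
            ResourceType.SERVICE_REQUEST: n_sr,
            ResourceType.DIAGNOSTIC_REPORT: rng.randint(0, n_sr),
            ResourceType.APPOINTMENT: rng.randint(0, 10),
        },
        gender_quota=gender_quota,
        birth_year_histogram=birth_hist,
        allergy_table=allergy_table,
        test_table=test_table,
        order_year_histogram=order_hist,
        seed=seed,
    )


def _random_histogram(rng, keys, total, cap=None):
    """Distribute `total` units over `keys`, at least one each, ≤ cap each."""
    keys = list(keys)
    hist = {k: 1 for k in keys}
    remaining = total - len(keys)
    while remaining > 0:
        k = rng.choice(keys)
        if cap is not None and hist[k] >= cap:
            if all(hist[j] >= cap for j in keys):
                break
            continue
        hist[k] += 1
        remaining -= 1
    return hist
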