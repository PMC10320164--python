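from pathlib import Path

import pytest

from mycomine.fixtures import (FixtureSpec, PlantedEvent, generate_collection,
                               write_collection)


@pytest.fixture(scope="session")
def collection():
    """One rich synthetic study shared across tests: a planted in-BGC
    duplication, an outside-BGC duplication, a resistance gene and DUF genes."""
    spec = FixtureSpec(
        seed=7,
        planted_events=[
            PlantedEvent("og0003", "qry01", extra_copies=1, inside_bgc=True),
            PlantedEvent("og0006", "qry01", extra_copies=2, inside_bgc=False),
        ],
        plant_resistance=True,
        n_duf_genes=2,
    )
    return generate_collection(spec)


@pytest.fixture(scope="session")
def collection_dir(collection, tmp_path_factory) -> Path:
    out = tmp_path_factory.mktemp("fixture_collection")
    write_collection(collection, out)
    return out


@pytest.fixture(scope="session")
def refset_and_results(collection, tmp_path_factory):
    from mycomine.fixtures import screen_collection

    work = tmp_path_factory.mktemp("pipeline")
    return screen_collection(collection, work, mode="default")


@pytest.fixture(scope="session")
def refset(refset_and_results):
    return refset_and_results[0]


@pytest.fixture(scope="session")
def results(refset_and_results):
    return refset_and_results[1]


@pytest.fixture(scope="session")
def refset_bundle(refset, tmp_path_factory) -> Path:
    from mycomine.refset import save_refset

    out = tmp_path_factory.mktemp("refset_bundle") / "toyset"
    save_refset(refset, out)
    return out
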