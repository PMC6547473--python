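"""Shared fixtures: a small synthetic catalog, host genome, registry and
simulated sample, generated once per session."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from ngl import fixtures
from ngl.references import Registry
from ngl.seqio import ShortRead

# property tests replay the same example sequence on every run
settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def mkread(quals, bases=None, name="r1"):
    """ShortRead from a quality list (bases default to 'A' * len)."""
    quals = list(quals)
    if bases is None:
        bases = "A" * len(quals)
    return ShortRead(name, bases, quals)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    return tmp_path_factory.mktemp("fixture")


@pytest.fixture(scope="session")
def tiny_catalog(fixture_dir):
    return fixtures.make_catalog(fixture_dir / "catalog", n_genes=8,
                                 length_range=(300, 600), n_ogs=4, n_kos=5, seed=11)


@pytest.fixture(scope="session")
def dup_catalog(fixture_dir):
    """Catalog whose last gene duplicates the first (multi-mapper tests)."""
    return fixtures.make_catalog(fixture_dir / "dup_catalog", n_genes=5,
                                 length_range=(300, 500), n_ogs=5, n_kos=5, seed=7,
                                 duplicate_pair=True)


@pytest.fixture(scope="session")
def host_fasta(fixture_dir):
    return fixtures.make_host(fixture_dir / "host", length=20_000, seed=12)


@pytest.fixture(scope="session")
def registry(fixture_dir, tiny_catalog, host_fasta):
    path = fixtures.make_fixture_registry(
        fixture_dir, tiny_catalog, host_fasta,
        catalog_keys=("igc", "om-rgc", "mouse-gut", "pig-gut", "dog-gut"),
        host_keys=("hg19", "mm10", "sus-scrofa", "canis-familiaris"))
    return Registry.load(path)


@pytest.fixture(scope="session")
def small_sample(fixture_dir, tiny_catalog, host_fasta):
    """2,000 zero-error reads, 20% from the host sequence."""
    return fixtures.simulate_reads(
        tiny_catalog, fixture_dir / "sample", n_reads=2_000, read_length=100,
        error_rate=0.0, host_fasta=host_fasta, host_fraction=0.2, seed=13)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
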