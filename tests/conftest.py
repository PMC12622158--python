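"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pytest

from cysligand.embeddings import SyntheticEmbeddingProvider
from cysligand.records import CuratedDB, ProteinEntry, SiteRecord
from cysligand.synthgen import GeneratorConfig, simulate_database


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(n_proteins=40, seed=7)


@pytest.fixture(scope="session")
def small_db_gt(small_config):
    return simulate_database(small_config)


@pytest.fixture(scope="session")
def provider(small_config):
    return SyntheticEmbeddingProvider(dim=small_config.embedding_dim,
                                      n_archetypes=small_config.n_archetypes,
                                      seed=small_config.seed)


def make_records(spec):
    """Build SiteRecords from (label, source) tuples for a single toy site."""
    return [
        SiteRecord(uid="P1", position=3, label=label, source_id=source,
                   record_id=f"R{i}")
        for i, (label, source) in enumerate(spec)
    ]


@pytest.fixture
def toy_db():
    """Two proteins, hand-written records (positions index 'C' residues)."""
    proteins = {
        "P1": ProteinEntry("P1", "AACAAACAAACA" + "A" * 20),   # C at 3, 8, 11
        "P2": ProteinEntry("P2", "CCAAAAAAAA" + "A" * 20),     # C at 1, 2
    }
    records = [
        SiteRecord("P1", 3, "pos", "A", "r1"),
        SiteRecord("P1", 3, "pos", "A", "r2"),
        SiteRecord("P1", 3, "pos", "B", "r3"),
        SiteRecord("P1", 3, "neg", "C", "r4"),
        SiteRecord("P1", 8, "neg", "A", "r5"),
        SiteRecord("P2", 1, "pos", "B", "r6"),
    ]
    return CuratedDB(proteins=proteins, records=records)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
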