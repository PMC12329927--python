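"""Shared fixtures: a small synthetic study that exercises every stage."""

from __future__ import annotations

import numpy as np
import pytest

from mockeval.synthetic import (ReadSimParams,
                                build_mock_communities, build_reference_db,
                                generate_marker_sequences, generate_taxonomy)


@pytest.fixture(scope="session")
def species_small():
    """12 genera / ~18 species with ITS1+ITS2 markers (seeded)."""
    skeletons = generate_taxonomy(n_genera=12, seed=11)
    return generate_marker_sequences(skeletons, seed=11)


@pytest.fixture(scope="session")
def db_complete(species_small):
    """Complete, fully annotated reference database over both markers."""
    db = build_reference_db(species_small, marker="ITS1", name="dbfull", seed=11)
    db2 = build_reference_db(species_small, marker="ITS2", name="dbfull", seed=11)
    db.entries.extend(db2.entries)
    db.subgeneric_map.update(db2.subgeneric_map)
    return db


@pytest.fixture(scope="session")
def communities_small(species_small):
    return build_mock_communities(species_small, n_communities=4, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


@pytest.fixture()
def clean_sim_params():
    """Error-free, chimera-free read simulation."""
    return ReadSimParams(reads_per_community=300, substitution_error_rate=0.0,
                        chimera_rate=0.0, seed=5)


def random_seq(rng, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def mutate_at(seq: str, positions, rng) -> str:
    chars = list(seq)
    for p in positions:
        choices = [c for c in "ACGT" if c != chars[p]]
        chars[p] = choices[rng.integers(0, 3)]
    return "".join(chars)
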