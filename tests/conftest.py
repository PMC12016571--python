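"""Shared fixtures: a small seeded synthetic study reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

from nphosite.dataset import encode_examples
from nphosite.model import DEFAULT_COMBOS, train_model
from nphosite.seqio import CANONICAL_AA, PeptideWindow, ProteinRecord
from nphosite.synthetic import SimulationConfig, generate_proteome, \
    make_benchmark


def make_window(peptide: str, protein_id: str = "P1",
                position: int = 16) -> PeptideWindow:
    return PeptideWindow(peptide=peptide, protein_id=protein_id,
                         position=position)


def random_window(rng: np.random.Generator, center: str = "H",
                  w: int = 31) -> PeptideWindow:
    letters = rng.choice(list(CANONICAL_AA), size=w)
    letters[w // 2] = center
    return make_window("".join(letters))


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    return SimulationConfig(n_proteins=60, seed=123)


@pytest.fixture(scope="session")
def small_proteome(small_cfg):
    return generate_proteome(small_cfg)


@pytest.fixture(scope="session")
def small_benchmark(small_cfg):
    benchmark, summary = make_benchmark(small_cfg)
    return benchmark


@pytest.fixture(scope="session")
def phis_bundle(small_benchmark):
    """A pHis classifier trained on the small synthetic benchmark."""
    data = encode_examples(small_benchmark["pHis"], DEFAULT_COMBOS["pHis"])
    return train_model(data, seed=7,
                       hyperparameters={"n_estimators": 80})


@pytest.fixture()
def toy_proteins() -> list[ProteinRecord]:
    return [
        ProteinRecord(id="P1", sequence="ACDEFGHIKLMNPQRHTVWYACDEFGHIKLM"),
        ProteinRecord(id="P2", sequence="MKKHEEASPKLRRSPSAGHKRA"),
    ]
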