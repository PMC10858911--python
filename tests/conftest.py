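"""Shared fixtures: the canonical separable two-species synthetic task.

The task pairs a short-pattern species (2-3 flashes, 0.3 s gaps, 0.1 s
flashes) with a long-pattern species (15-16 flashes, 0.8 s gaps, 0.2 s
flashes) — disjoint in all three flash statistics, the way real sympatric
species pairs differ — with tight within-species variability so that every
classifier family (template matching, SVM, GRU) can in principle separate
them. The trained GRU is session-scoped because training dominates runtime.
"""

import warnings

import numpy as np
import pytest

from fireflash import (
    GRUClassifier,
    GRUConfig,
    SequenceDataset,
    SpeciesParams,
    generate_population,
)

warnings.filterwarnings("ignore", message="The `probability` parameter")

SHORT_SPECIES = SpeciesParams("sp_short", count_mean=2.5, count_sd=0.5,
                              gap_mean_s=0.30, gap_sd_s=0.02,
                              dur_mean_s=0.10, dur_sd_s=0.02)
LONG_SPECIES = SpeciesParams("sp_long", count_mean=15.5, count_sd=0.5,
                             gap_mean_s=0.80, gap_sd_s=0.02,
                             dur_mean_s=0.20, dur_sd_s=0.02)


def make_pair_dataset(n_per_species: int, seed: int) -> SequenceDataset:
    rng = np.random.default_rng(seed)
    seqs = (generate_population(SHORT_SPECIES, n_per_species, rng).sequences
            + generate_population(LONG_SPECIES, n_per_species, rng).sequences)
    return SequenceDataset(seqs)


@pytest.fixture(scope="session")
def pair_species():
    return SHORT_SPECIES, LONG_SPECIES


@pytest.fixture(scope="session")
def pair_train():
    return make_pair_dataset(200, seed=101)


@pytest.fixture(scope="session")
def pair_val():
    return make_pair_dataset(50, seed=102)


@pytest.fixture(scope="session")
def pair_test():
    return make_pair_dataset(50, seed=103)


@pytest.fixture(scope="session")
def trained_gru(pair_train, pair_val):
    """GRU trained on the separable task; batch size and learning rate are
    taken from the study's hyperparameter grid, epochs capped for the small
    synthetic problem."""
    config = GRUConfig(learning_rate=1e-3, batch_size=8, max_epochs=6,
                       early_stop_patience=6, n_species=2, seed=0)
    return GRUClassifier(config).fit(pair_train, pair_val)
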