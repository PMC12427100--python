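import numpy as np
import pandas as pd
import pytest

from lipidprog import AbundanceMatrix, ClinicalTable, SyntheticConfig, generate_cohort, preprocess
from lipidprog.nomenclature import characteristic_table, parse_many


def small_config(**overrides) -> SyntheticConfig:
    """A scaled-down cohort for fast unit tests (full-size runs live in the
    acceptance tests)."""
    defaults = dict(
        n_samples=40,
        n_species=80,
        class_composition={"PC": 20, "TAG": 18, "SM": 10, "CE": 8,
                           "PC O-": 10, "PE O-": 8, "LPE O-": 6},
        n_genes=60,
        n_module_genes=12,
        seed=7,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_config())


@pytest.fixture(scope="session")
def small_clean(small_cohort):
    lipids, genes, clinical, truth = small_cohort
    clean = preprocess(lipids)
    species, failed = parse_many(clean.species_ids)
    assert not failed
    chars = characteristic_table(species)
    return clean, genes, clinical, truth, chars


@pytest.fixture()
def toy_clinical():
    """Six-subject worked fixture with one tied event time."""
    return ClinicalTable(
        pd.DataFrame(
            {
                "time": [5.0, 8.0, 8.0, 12.0, 16.0, 20.0],
                "event": [1, 1, 1, 0, 1, 0],
            },
            index=[f"P{i}" for i in range(1, 7)],
        )
    )


def log10_matrix(values: np.ndarray, species=None, samples=None) -> AbundanceMatrix:
    values = np.asarray(values, float)
    species = species or [f"sp{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return AbundanceMatrix(
        pd.DataFrame(values, index=species, columns=samples), scale="log10"
    )
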