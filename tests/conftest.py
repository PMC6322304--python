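import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from pepdegradome import (  # noqa: E402
    ProteomeMap,
    RunConfig,
    SimulationConfig,
    bundled_aaindex_path,
    generate_proteome,
    read_aaindex1,
    simulate_digestion,
)


@pytest.fixture(scope="session")
def aaindex_mini():
    return read_aaindex1(bundled_aaindex_path())


@pytest.fixture
def tiny_proteome():
    return ProteomeMap({
        "P1": "MKKAAPLQG",
        "P2": "MKMK",
        "P3": "ACDEFGHIKLMNPQRSTVWYACDEFGHIKL",
    })


@pytest.fixture
def run_config():
    return RunConfig()


def make_peptide_row(sequence, protein, start, end, condition="control",
                     compartment="cell", repeats=(1, 2), **intensities):
    row = {
        "sequence": sequence,
        "proteins": [protein] if protein else [],
        "start": start,
        "end": end,
        "condition": condition,
        "compartment": compartment,
        "repeats": frozenset(repeats),
        "unmapped": protein is None,
        "ambiguous": False,
        "nonstandard": False,
        "matches": [(protein, start, end)] if protein else [],
    }
    row.update(intensities)
    return row


def make_table(rows):
    df = pd.DataFrame(rows)
    df["start"] = df["start"].astype("Int64")
    df["end"] = df["end"].astype("Int64")
    return df


@pytest.fixture(scope="session")
def small_simulation():
    """A small but complete simulated study shared across tests."""
    cfg = SimulationConfig(
        n_proteins=120, peptides_per_compartment=300,
        treatment_extra_fraction={"cell": 0.1, "secretome": 0.05},
        rng_seed=11,
    )
    rng = np.random.default_rng(cfg.rng_seed)
    proteome, topology = generate_proteome(cfg, rng)
    peptides, truth = simulate_digestion(proteome, topology, cfg, rng=rng)
    return cfg, proteome, topology, peptides, truth
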