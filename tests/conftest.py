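"""Shared fixtures: the default synthetic study and its networks.

The heavy objects (full study, SparCC with 1000 permutations, the
decontamination run) are session-scoped so the unit and acceptance
suites share one computation.
"""

import numpy as np
import pandas as pd
import pytest

from concreta.cooccurrence import proportionality_rho, sparcc
from concreta.decontaminate import run_decontamination
from concreta.simulate import SimulationConfig, generate_study
from concreta.tables_io import AsvRecord, AsvTable

STUDY_SEED = 1
NETWORK_SEED = 7


@pytest.fixture(scope="session")
def default_study():
    return generate_study(SimulationConfig(seed=STUDY_SEED))


@pytest.fixture(scope="session")
def study_networks(default_study):
    table, *_ = default_study
    real = table.select_samples(
        list(table.metadata.index[~table.is_negative()]))
    return {
        "sparcc": sparcc(real, permutations=1000, seed=NETWORK_SEED),
        "rho": proportionality_rho(real),
    }


@pytest.fixture(scope="session")
def decontam_run(default_study, study_networks):
    table, records, _tree, lab_ref, _truth = default_study
    return run_decontamination(table, records, study_networks, lab_ref)


@pytest.fixture()
def tiny_table():
    counts = pd.DataFrame(
        [[5, 0, 2], [1, 3, 0], [0, 2, 7]],
        index=["s1", "s2", "s3"], columns=["a1", "a2", "a3"])
    metadata = pd.DataFrame({
        "sample_type": ["concrete", "concrete", "negative_control"],
        "series": ["reactive", "mitigated", "none"],
        "months": [0.0, 3.0, 0.0],
        "temperature": [15.0, 20.0, 15.0],
        "replicate": ["R1", "R1", "R1"],
    }, index=["s1", "s2", "s3"])
    return AsvTable(counts, metadata)


def make_records(seqs: dict):
    return [AsvRecord(k, v) for k, v in seqs.items()]
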