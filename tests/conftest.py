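"""Shared fixtures: one small and one study-scale synthetic reference,
QC'd single-cell data and a signature, built once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from braincyto import single_cell as scm
from braincyto.config import SimulationConfig
from braincyto.simulate import simulate_reference


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(n_genes=600, n_cells_per_type=60, seed=11)


@pytest.fixture(scope="session")
def small_reference(small_config):
    return simulate_reference(small_config)


@pytest.fixture(scope="session")
def study_config() -> SimulationConfig:
    """Full-size study conditions: 2000 genes, default cohort designs."""
    return SimulationConfig(n_genes=2000, n_cells_per_type=120, seed=7)


@pytest.fixture(scope="session")
def study_reference(study_config):
    return simulate_reference(study_config)


def qc_chain(reference):
    metrics = scm.compute_cell_qc(reference)
    kept, _ = scm.filter_cells(metrics)
    sc = reference.subset(cells=kept)
    sc = sc.subset(genes=scm.filter_genes_sc(sc))
    return sc


@pytest.fixture(scope="session")
def study_sc(study_reference):
    return qc_chain(study_reference)


@pytest.fixture(scope="session")
def study_signature(study_sc):
    decomp = scm.decompose_variance(study_sc)
    return scm.build_signature(study_sc, decomp.retained)


@pytest.fixture(scope="session")
def small_sc(small_reference):
    return qc_chain(small_reference)


@pytest.fixture(scope="session")
def small_signature(small_sc):
    decomp = scm.decompose_variance(small_sc)
    return scm.build_signature(small_sc, decomp.retained)
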