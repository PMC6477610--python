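"""Shared fixtures: canned experiments are expensive, run each once."""

import pytest

import cpgnet as c
from cpgnet.protocols import (baseline_perturbation_experiment,
                              deletion_experiment, mlr_drive_experiment,
                              pf_memory_experiment)


@pytest.fixture(scope="session")
def mlr_result():
    return mlr_drive_experiment()


@pytest.fixture(scope="session")
def pf_memory_result():
    return pf_memory_experiment()


@pytest.fixture(scope="session")
def pf_deletion_result():
    return deletion_experiment(layer="PF")


@pytest.fixture(scope="session")
def rg_deletion_result():
    return deletion_experiment(layer="RG")


@pytest.fixture(scope="session")
def baseline_result():
    return baseline_perturbation_experiment()
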