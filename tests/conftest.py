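from pathlib import Path

import pytest

from tdrscape.align import quantify_samples
from tdrscape.simulate import (
    ConditionProfile,
    SampleSpec,
    DEFAULT_ADAPTER,
    extracellular_mixture,
    cellular_mixture,
    simulate_library,
    toy_reference,
)

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def reference():
    return toy_reference(seed=0)


@pytest.fixture(scope="session")
def ex_library(reference, tmp_path_factory):
    """A small extracellular library (AlkB-treated) with ground truth."""
    out_dir = tmp_path_factory.mktemp("ex_library")
    profile = ConditionProfile(
        condition="control", compartment="Ex", mixture=extracellular_mixture()
    )
    return simulate_library(
        out_dir, [SampleSpec("ex1", profile, 6000, alkb=True)], reference, seed=11
    )


@pytest.fixture(scope="session")
def ex_quantified(reference, ex_library):
    """The extracellular library pushed through trim/align/count."""
    fastqs = {s: str(p) for s, p in ex_library["fastq"].items()}
    return quantify_samples(fastqs, reference, DEFAULT_ADAPTER)


@pytest.fixture(scope="session")
def paper_names():
    return [
        line.strip()
        for line in (DATA_DIR / "tdr_names.txt").read_text().splitlines()
        if line.strip()
    ]
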