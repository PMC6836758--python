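import numpy as np
import pytest

from phyloabc.data_model import LocusSpec, SeqRecordEntry
from phyloabc.synthetic import (
    ParameterDraw,
    PriorSpec,
    SamplingDesign,
    ScenarioSpec,
    builtin_scenarios,
    default_design,
    default_loci,
)


def records_from_seqs(seqs, pop="P1", region="NWP", start=0):
    """One haploid record per sequence."""
    return [
        SeqRecordEntry(f"{pop}_i{start + i}", pop, region, s, 0)
        for i, s in enumerate(seqs)
    ]


@pytest.fixture(scope="session")
def scenarios():
    return builtin_scenarios()


@pytest.fixture(scope="session")
def loci():
    return default_loci()


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture(scope="session")
def single_pop_scenario():
    """One constant-size population; size parameter N."""

    def make(N: float) -> tuple[ScenarioSpec, ParameterDraw]:
        sc = ScenarioSpec(
            id="one",
            populations=("P",),
            events=(),
            size_param={"P": "N"},
            priors={"N": PriorSpec(1.0, 1e8)},
        )
        return sc, ParameterDraw("one", {"N": float(N)}, 0)

    return make


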