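import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from fiberlfq.io import ProteinGroupTable, SampleDesign
from fiberlfq.preprocess import LogMatrix

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_design(n_subjects: int = 5, fibers=("slow", "fast"), times=("PRE", "POST")):
    rows = [
        (f"{f}_{t}_S{s}", f"S{s}", f, t)
        for s in range(1, n_subjects + 1)
        for f in fibers
        for t in times
    ]
    return SampleDesign(
        pd.DataFrame(rows, columns=["sample_id", "subject_id", "fiber_type", "timepoint"])
    )


def make_table(values: pd.DataFrame, design: SampleDesign) -> ProteinGroupTable:
    """ProteinGroupTable from a plain intensity DataFrame (linear units)."""
    meta = pd.DataFrame(
        {
            "accessions": [str(i) for i in values.index],
            "gene_name": ["" for _ in values.index],
            "unique_peptides": [1 for _ in values.index],
        },
        index=values.index,
    )
    return ProteinGroupTable(values.copy(), meta, design)


def make_log_matrix(values: pd.DataFrame, design: SampleDesign) -> LogMatrix:
    return LogMatrix(values.astype(float), design)


@pytest.fixture(scope="session")
def design5():
    return make_design(5)


@pytest.fixture(scope="session")
def sim_default():
    """One default simulated experiment, shared across read-only tests."""
    from fiberlfq.simulate import SimConfig, generate_experiment

    return generate_experiment(SimConfig(seed=1))
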