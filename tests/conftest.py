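import numpy as np
import pandas as pd
import pytest

from amlproteo.config import GeneratorConfig
from amlproteo.design import StudyDesign, cohort_design
from amlproteo.simulate import generate_study


@pytest.fixture(scope="session")
def design():
    return cohort_design()


@pytest.fixture(scope="session")
def small_study(design):
    """A small planted study reused across read-only tests."""
    cfg = GeneratorConfig(n_proteins=80, changed_fraction=0.1, seed=11)
    return generate_study(cfg, design)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_comparisons(rows):
    """Build a ProteinComparison frame from (run, protein, sample, control,
    log2_ratio, significant) tuples."""
    frame = pd.DataFrame(
        rows, columns=["run_id", "protein_id", "sample_id", "control_id",
                       "log2_ratio", "significant"],
    )
    frame["n_peptides"] = 1
    frame["direction"] = np.where(frame["significant"],
                                  np.sign(frame["log2_ratio"]).astype(int), 0)
    return frame
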