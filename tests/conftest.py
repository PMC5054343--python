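import numpy as np
import pandas as pd
import pytest

from hepatlas.io_formats import AbundanceMatrix, AnnotationDB, SampleInfo
from hepatlas.synthetic_data import GeneratorConfig, generate_cohort


def make_matrix(values, genes=None, cells=("HC", "HSC", "KC", "LSEC"),
                n_replicates=1, unit="ibaq"):
    """Build a small AbundanceMatrix from a genes x cells array; replicate
    columns are exact copies unless a dict {label: column} is given."""
    values = np.asarray(values, dtype=float)
    if genes is None:
        genes = [f"g{i}" for i in range(values.shape[0])]
    samples, cols = [], {}
    for ci, cell in enumerate(cells):
        for r in range(1, n_replicates + 1):
            s = SampleInfo(cell, r)
            samples.append(s)
            cols[s.label] = values[:, ci]
    return AbundanceMatrix(pd.DataFrame(cols, index=genes), samples, unit=unit)


@pytest.fixture(scope="session")
def disjoint_annotation():
    """Four disjoint categories over 8 genes."""
    return AnnotationDB(
        {
            "c1": frozenset({"g0", "g1"}),
            "c2": frozenset({"g2", "g3"}),
            "c3": frozenset({"g4", "g5"}),
            "c4": frozenset({"g6", "g7"}),
        }
    )


@pytest.fixture(scope="session")
def cohort_default():
    return generate_cohort(GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def cohort_noiseless():
    return generate_cohort(GeneratorConfig(seed=11, noise_sd=0.0))
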