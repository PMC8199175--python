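import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from oncomir.io_matrix import ExpressionMatrix

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")


def make_matrix(values, groups, cohort="discovery", patient_ids=None,
                total_reads=None, unit="counts", mirna_ids=None):
    """Build a small ExpressionMatrix from a 2-D array and group labels."""
    values = np.asarray(values, dtype=float)
    n_mir, n_samp = values.shape
    mirnas = mirna_ids or [f"mir-{i}" for i in range(n_mir)]
    samples = [f"s{j}" for j in range(n_samp)]
    meta = pd.DataFrame(
        {
            "patient_id": patient_ids or samples,
            "group": groups,
            "cohort": cohort,
            "total_reads": total_reads if total_reads is not None
            else [10_000_000] * n_samp,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    vals = pd.DataFrame(values, index=pd.Index(mirnas, name="mirna_id"),
                        columns=samples)
    return ExpressionMatrix(values=vals, meta=meta, unit=unit)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_counts():
    """3 miRNAs × 4 samples, two groups."""
    return make_matrix(
        [[0, 5, 10, 2], [10, 0, 3, 8], [100, 50, 25, 70]],
        groups=["ANL", "ANL", "LUAD", "LUAD"],
    )
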