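import numpy as np
import pandas as pd
import pytest

import mirmix as mm
from mirmix import preprocess


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic cohort (2000 genes, 200 miRNA strands, 100 samples)."""
    return mm.generate_joint_dataset(mm.SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def log_views(bundle):
    """Preprocessed (filtered, log2) views of the default cohort."""
    mrna = preprocess.log2_with_pseudo(
        preprocess.filter_cv_outliers(preprocess.filter_low_abundance(bundle.E_m))
    )
    mirna = preprocess.log2_with_pseudo(
        preprocess.filter_cv_outliers(preprocess.filter_low_abundance(bundle.E_mi))
    )
    return mrna, mirna


@pytest.fixture(scope="session")
def fitted_model(log_views):
    mrna, mirna = log_views
    return mm.fit_joint_ica(mrna, mirna, 3, seed=7)


def make_matrix(values, unit="RPM", kind="miRNA-strand", prefix="f"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    idx = [f"{prefix}{i}" for i in range(values.shape[0])]
    cols = [f"s{i}" for i in range(values.shape[1])]
    return mm.ExpressionMatrix(pd.DataFrame(values, index=idx, columns=cols), unit, kind)
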