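import numpy as np
import pandas as pd
import pytest

from prognosig.core_data import (ClinicalTable, ExpressionMatrix, HIGH_RISK,
                                 LOW_RISK, PrognosisLabels)


@pytest.fixture
def toy_expr():
    """3 probes x 6 samples with a clean class separation in gene A."""
    data = pd.DataFrame(
        {
            "s1": [1.0, 5.0, 2.0],
            "s2": [2.0, 5.0, 2.0],
            "s3": [3.0, 5.0, 2.0],
            "s4": [11.0, 5.0, 2.0],
            "s5": [12.0, 5.0, 2.0],
            "s6": [13.0, 5.0, 2.0],
        },
        index=["gA", "gConst", "gFlat"],
    )
    return ExpressionMatrix(data)


@pytest.fixture
def toy_labels():
    return PrognosisLabels(labels=pd.Series(
        [HIGH_RISK, HIGH_RISK, HIGH_RISK, LOW_RISK, LOW_RISK, LOW_RISK],
        index=["s1", "s2", "s3", "s4", "s5", "s6"], dtype=object))


@pytest.fixture
def clinical_10():
    """10 samples: 4 deaths before 60, 4 survivors past 60, 2 censored early."""
    df = pd.DataFrame({
        "time_months": [12, 24, 36, 48, 70, 80, 90, 100, 30, 50],
        "event":       [1,  1,  1,  1,  0,  1,  0,  1,  0,  0],
    }, index=[f"p{i}" for i in range(10)])
    return ClinicalTable(df)


def random_expr(rng, n_genes, n_samples, prefix="g"):
    data = pd.DataFrame(
        np.abs(rng.normal(100, 25, size=(n_genes, n_samples))),
        index=[f"{prefix}{i}" for i in range(n_genes)],
        columns=[f"s{i}" for i in range(n_samples)],
    )
    return ExpressionMatrix(data)


def balanced_labels(n_samples):
    half = n_samples // 2
    vals = [HIGH_RISK] * half + [LOW_RISK] * (n_samples - half)
    return PrognosisLabels(labels=pd.Series(
        vals, index=[f"s{i}" for i in range(n_samples)], dtype=object))
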