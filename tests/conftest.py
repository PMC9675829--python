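import numpy as np
import pandas as pd
import pytest

from t2dsub import clustering, cohort, synthetic


@pytest.fixture(scope="session")
def small_params():
    """Desk-scale preset used by most module tests."""
    return synthetic.SimulationParams(
        n_cases=420, n_controls=600, n_proteins=80, n_metabolites=60, seed=11
    )


@pytest.fixture(scope="session")
def small_cohort(small_params):
    table, truth = synthetic.generate_cohort(small_params)
    table = table.copy()
    table["status"] = cohort.classify_table(table)
    return table, truth


@pytest.fixture(scope="session")
def t2d_standardized(small_cohort):
    table, truth = small_cohort
    t2d = table.index[table["status"] == "T2D"]
    X_std, params = clustering.standardize(table.loc[t2d])
    return X_std, params


@pytest.fixture(scope="session")
def fitted_model(t2d_standardized):
    X_std, params = t2d_standardized
    return clustering.fit_cluster_model(
        X_std, k=4, restarts=50, seed=11, standardization=params
    )


@pytest.fixture(scope="session")
def small_proteins(small_cohort, small_params):
    _, truth = small_cohort
    return synthetic.generate_omics(truth, small_params, "protein")


def truth_subtypes(truth) -> pd.Series:
    """Generative subtype names for all T2D cases."""
    return pd.Series(
        {s: synthetic.SUBTYPE_NAMES[i] for s, i in truth.subtype.items()}
    ).sort_index()


def planted_features(truth, prefix: str, targets) -> list[str]:
    return sorted(
        f
        for f, (tgt, _) in truth.features.items()
        if f.startswith(prefix) and tgt in targets
    )
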