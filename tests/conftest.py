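import numpy as np
import pandas as pd
import pytest

from mlrdecon import presets, simulate


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-sample cohort with compositions and relapse labels."""
    spec = simulate.CohortSpec(n_samples=40, seed=7)
    return simulate.generate_compositions(spec), simulate.generate_relapse_labels(spec)


@pytest.fixture(scope="session")
def study_cohort():
    """Study-scale cohort: 108 samples, relapse fraction 38/101."""
    spec = presets.default_cohort_spec(seed=11)
    return simulate.generate_compositions(spec), simulate.generate_relapse_labels(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(2013)


def normal_equations_fit(X: np.ndarray, y: np.ndarray):
    """Independent brute-force OLS oracle: explicit (X'X)^-1 X'y with
    textbook SE, t and two-sided p."""
    from scipy import stats

    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    df = X.shape[0] - X.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(np.diag(XtX_inv) * sigma2)
    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df)
    return beta, se, t, p, df
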