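import numpy as np
import pytest

import bmrkit as bk


@pytest.fixture
def rng():
    return np.random.default_rng(20160831)


@pytest.fixture(scope="session")
def default_cohort():
    """One derivation-style cohort (121 men / 111 women) at generator defaults."""
    return bk.generate_cohort(seed=42)


@pytest.fixture(scope="session")
def registry():
    return bk.builtin_equations()


def brute_force_steady_state(series, window, cv_max):
    """Independent exhaustive window scan (Python loop, sample CV, ddof=1)."""
    dt = series.t[1] - series.t[0]
    width = int(round(window / dt))
    best = None
    for i in range(series.n - width + 1):
        vo2 = series.vo2[i:i + width]
        vco2 = series.vco2[i:i + width]
        cv_o = vo2.std(ddof=1) / vo2.mean()
        cv_c = vco2.std(ddof=1) / vco2.mean()
        if cv_o <= cv_max and cv_c <= cv_max:
            score = cv_o + cv_c
            if best is None or score < best[0] - 0:
                if best is None or score < best[0]:
                    best = (score, float(series.t[i]), cv_o, cv_c)
    return best


def normal_equations_ols(y, X):
    """Hand-rolled OLS oracle: explicit normal equations with intercept.

    Returns (coefficients incl. intercept first, r2, rd).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    A = np.column_stack([np.ones(len(y)), X])
    beta = np.linalg.solve(A.T @ A, A.T @ y)
    resid = y - A @ beta
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    k = X.shape[1]
    rd = np.sqrt(sse / (len(y) - k - 1))
    return beta, 1 - sse / sst, rd
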