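import numpy as np
import pytest

import dmnconn as dc


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def labels16():
    return dc.default_region_labels()


@pytest.fixture
def small_sine_ts():
    """A 10 Hz sinusoid on 2 channels at 300 Hz."""
    fs = 300.0
    t = np.arange(int(fs * 20)) / fs
    data = np.vstack([np.sin(2 * np.pi * 10 * t),
                      np.cos(2 * np.pi * 10 * t)])
    return dc.SourceTimeSeries(data, fs=fs, region_labels=["a", "b"])


def schur_partial_correlation(cov: np.ndarray) -> np.ndarray:
    """Independent oracle: pairwise conditional covariance via Schur complement.

    For each pair (i, j), regress out all remaining variables by
    conditioning: Sigma_A|B = Sigma_AA - Sigma_AB Sigma_BB^-1 Sigma_BA,
    then correlate the conditional pair. Algebraically this is the
    regression-residual definition of partial correlation.
    """
    cov = np.asarray(cov, float)
    n = cov.shape[0]
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            a = [i, j]
            b = [k for k in range(n) if k not in a]
            s_ab = cov[np.ix_(a, b)]
            cond = cov[np.ix_(a, a)] - s_ab @ np.linalg.solve(
                cov[np.ix_(b, b)], s_ab.T)
            r = cond[0, 1] / np.sqrt(cond[0, 0] * cond[1, 1])
            out[i, j] = out[j, i] = r
    return out


@pytest.fixture
def random_spd_covariances(rng):
    """50 well-conditioned random SPD covariance matrices, 8 variables."""
    covs = []
    for _ in range(50):
        a = rng.standard_normal((8, 8))
        covs.append(a @ a.T + 0.5 * np.eye(8))
    return covs
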