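import dataclasses
import itertools
import logging

import numpy as np
import pytest

import emgrepro as er

logging.getLogger("emgrepro").setLevel(logging.ERROR)

N = 100


@pytest.fixture(scope="session")
def mini_spec():
    """Scaled-down cohort: 3 subjects x 3 reps at 1074 Hz, short self-paced trials."""
    return dataclasses.replace(
        er.make_default_spec(),
        n_subjects=3,
        n_reps=3,
        fs=1074.0,
        duration_range=(1.2, 1.8),
        seed=7,
    )


@pytest.fixture(scope="session")
def mini_trials(mini_spec):
    return er.generate_cohort(mini_spec)


@pytest.fixture(scope="session")
def mini_profiles(mini_trials):
    profiles, _ = er.preprocess_cohort(mini_trials)
    return profiles


def bump(center, width=8.0, amplitude=1.0, baseline=0.0, n=N):
    """Smooth unimodal Gaussian-bump profile on the n-point cycle grid."""
    p = np.arange(n, dtype=float)
    return baseline + amplitude * np.exp(-((p - center) ** 2) / (2.0 * width**2))


def random_profile(rng, n=N, nonneg=True):
    """Random smooth profile: low-pass-ish filtered noise, optionally rectified."""
    raw = rng.standard_normal(n + 20)
    kernel = np.hanning(9)
    smooth = np.convolve(raw, kernel / kernel.sum(), mode="same")[10 : 10 + n]
    return np.abs(smooth) if nonneg else smooth


def brute_force_xcorr(a, b, max_lag=25, method="norm_coeff"):
    """Independent oracle: explicit double loop over lags and overlap products."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n = a.size
    candidates = []
    for k in range(-max_lag, max_lag + 1):
        pairs = [(a[i], b[i + k]) for i in range(n) if 0 <= i + k < n]
        xs = np.array([p[0] for p in pairs])
        ys = np.array([p[1] for p in pairs])
        if method == "norm_coeff":
            c = float(sum(x * y for x, y in pairs)) / (
                np.sqrt(sum(x * x for x in a)) * np.sqrt(sum(y * y for y in b))
            )
        else:
            if xs.size < 2 or xs.std() == 0 or ys.std() == 0:
                continue
            c = float(np.corrcoef(xs, ys)[0, 1])
        candidates.append((c, k))
    best = sorted(candidates, key=lambda ck: (-ck[0], abs(ck[1]), ck[1]))[0]
    return best  # (coefficient, lag)


def pairwise_mean_oracle(profiles, max_lag=25, method="norm_coeff"):
    vals = [
        brute_force_xcorr(profiles[i], profiles[j], max_lag, method)[0]
        for i, j in itertools.combinations(range(len(profiles)), 2)
    ]
    return float(np.mean(vals))
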