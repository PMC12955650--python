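import numpy as np
import pytest
from scipy.stats import norm

import uvsdt as u


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def exact_table(mu, sigma, criteria, n_per_class=100_000):
    """Rating table with the exact model-expected frequencies.

    The frequencies are the model cell probabilities scaled by the
    per-class trial count; marked padded so it can be fed straight to
    the fitter (all cells are strictly positive for interior criteria).
    """
    params = u.UVSDTParams(mu, sigma, criteria)
    pa, pp = u.cell_probabilities(params)
    freq = np.vstack([pa, pp]) * n_per_class
    return u.RatingTable(n_levels=params.n_levels, freq=freq, padded=True)


def random_table(rng, n_levels=2, max_count=20):
    """Random small integer rating table with nonzero row sums."""
    while True:
        freq = rng.integers(0, max_count + 1, size=(2, 2 * n_levels)).astype(float)
        if np.all(freq.sum(axis=1) > 0):
            return u.RatingTable(n_levels=n_levels, freq=freq)


def grid_best_loglik(table, n_grid=21):
    """Brute-force oracle: best log-likelihood over a (mu, sigma,
    criterion-shift) grid, with criteria anchored at -z(cumulative FA).

    Independent of the optimizer path: probabilities come straight from
    Gaussian CDF differences here.
    """
    fa, _ = table.cumulative_rates()
    base = -norm.ppf(np.clip(fa, 1e-6, 1 - 1e-6))[::-1]
    base = np.maximum.accumulate(base + np.arange(base.size) * 1e-3)
    mus = np.linspace(0.0, 3.0, n_grid)
    sigmas = np.linspace(0.5, 3.0, n_grid)
    shifts = np.linspace(-1.0, 1.0, n_grid)
    best = -np.inf
    freq = table.freq
    for shift in shifts:
        e = np.concatenate(([-np.inf], base + shift, [np.inf]))
        pa = np.maximum(np.diff(norm.cdf(e))[::-1], 1e-300)
        ll_absent = float(np.sum(freq[0] * np.log(pa)))
        for mu in mus:
            for sigma in sigmas:
                pp = np.maximum(np.diff(norm.cdf((e - mu) / sigma))[::-1], 1e-300)
                ll = ll_absent + float(np.sum(freq[1] * np.log(pp)))
                if ll > best:
                    best = ll
    return best
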