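import numpy as np
import pandas as pd
import pytest

import circamir as cm


@pytest.fixture(scope="session")
def small_nascent_pair():
    """200-transcript paired nascent simulation, 20% rhythmic."""
    params = cm.RhythmSimParams(n_transcripts=200, frac_rhythmic=0.2, seed=101)
    a, b, truth = cm.simulate_nascent_pair(params)
    return a, b, truth


@pytest.fixture(scope="session")
def oe_design():
    """Planted 2x2 over-expression design with default effect sizes."""
    params = cm.OeSimParams(n_genes=800, seed=202)
    return cm.simulate_overexpression(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def random_series(rng, n=12, amp_range=(0.3, 0.9), noise_sd=0.05, period=24.0):
    """Noisy cosine series with modest amplitude (helper for oracles).

    Sampled on the balanced 4-h/48-h grid: with full cycles the harmonic
    regressors are orthogonal, which makes the grid-fit amplitude agree
    with the analytic fit to second order in the grid step.
    """
    t = 4.0 * np.arange(n)
    m = rng.uniform(3, 8)
    a = rng.uniform(*amp_range)
    phi = rng.uniform(0, period)
    y = m + a * np.cos(2 * np.pi * (t - phi) / period) + rng.normal(0, noise_sd, n)
    return t, y


def grid_cosine_fit(t, y, period=24.0, step=0.01):
    """Exhaustive shifted-cosine fit: at each grid phase solve the 2-parameter
    least squares (mesor + amplitude), keep the minimum-RSS phase.

    Independent oracle for the harmonic-regression fitter.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    w = 2 * np.pi / period
    phis = np.arange(0.0, period, step)
    best = (np.inf, 0.0, 0.0)
    for phi in phis:
        c = np.cos(w * (t - phi))
        X = np.column_stack([np.ones(t.size), c])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        rss = float(r @ r)
        if rss < best[0]:
            best = (rss, phi, beta[1])
    rss, phi, amp = best
    if amp < 0:
        amp = -amp
        phi = (phi + period / 2) % period
    return phi, amp
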