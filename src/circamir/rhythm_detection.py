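"""Cosine fitting and cross-dataset circadian consistency scoring.

The core model is a single-harmonic regression with fixed period T
(default 24 h)::

    x(t) = m + a cos(wt) + b sin(wt),   w = 2*pi/T

which is the linear re-parameterisation of a shifted cosine
``m + A cos(w (t - phi))`` with amplitude ``A = sqrt(a^2 + b^2)`` and
peak phase ``phi = atan2(b, a) / w`` (hours, in ``[0, T)``).  Rhythmicity
is tested with the F-test of the two harmonic terms against the
intercept-only model (df = 2, n - 3).  Replicates and multi-day samples
enter through the periodic regressors, so times need not be reduced
modulo the period by the caller.

Two independent time courses (e.g. GRO-seq and Nascent-seq) are combined
into a consistency score

    S = -log2(p1) - log2(p2)        [bits]

and a circular phase difference; a transcript is called circadian when
``S > score_min`` (default 9) and the phase difference is below
``phasediff_max`` (default 4 h).

Mature-level series, which oscillate at strongly attenuated amplitude,
are tested with relaxed criteria: one-way ANOVA across time groups and
the cosine fit must both reach p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import TimeSeriesMatrix

#: Smallest p-value used before taking logs, keeping scores finite.
P_FLOOR = 1e-300

DEFAULT_PERIOD = 24.0
DEFAULT_SCORE_MIN = 9.0
DEFAULT_PHASEDIFF_MAX = 4.0


@dataclass(frozen=True)
class CosineFit:
    """Single-transcript harmonic fit.

    Attributes
    ----------
    mesor : fitted baseline m.
    amplitude : cosine amplitude A >= 0.
    phase : time of the fitted maximum, hours in [0, period).
    pvalue : F-test p of the harmonic terms vs intercept only.
    rel_amplitude : log2((m+A)/(m-A)), the log2 peak-to-trough ratio of
        the fitted curve; NaN when m <= A (trough at or below zero).
    """

    mesor: float
    amplitude: float
    phase: float
    pvalue: float
    rel_amplitude: float
    period: float = DEFAULT_PERIOD
    n: int = 0


@dataclass(frozen=True)
class ConsistencyResult:
    """Cross-dataset agreement of two cosine fits."""

    score: float
    phase_diff: float
    combined_phase: float
    passed: bool


def _check_times(times: np.ndarray, period: float) -> None:
    distinct = np.unique(np.round(np.mod(times, period), 9)).size
    if distinct < 4:
        raise ValueError(
            f"need >= 4 distinct times modulo the period, got {distinct}"
        )


def harmonic_regression(
    times: np.ndarray, values: np.ndarray, period: float = DEFAULT_PERIOD
):
    """Vectorised harmonic OLS over many series sharing one time grid.

    Parameters
    ----------
    times : (n,) sample times in hours.
    values : (m, n) or (n,) expression values.
    period : oscillation period in hours.

    Returns
    -------
    dict of 1-D arrays: ``mesor``, ``amplitude``, ``phase``, ``pvalue``,
    ``rel_amplitude``, ``coef_cos``, ``coef_sin``.

    Notes
    -----
    Constant series get amplitude 0 and p = 1 (not an error); essentially
    perfect fits are floored at ``P_FLOOR``.
    """
    t = np.asarray(times, dtype=float)
    Y = np.atleast_2d(np.asarray(values, dtype=float))
    if Y.shape[1] != t.size:
        raise ValueError("values do not align with times")
    if not np.isfinite(Y).all():
        raise ValueError("non-finite expression values")
    _check_times(t, period)
    n = t.size
    w = 2.0 * np.pi / period
    X = np.column_stack([np.ones(n), np.cos(w * t), np.sin(w * t)])
    # one pseudoinverse serves every series on this grid
    B = Y @ np.linalg.pinv(X).T
    resid = Y - B @ X.T
    rss1 = np.einsum("ij,ij->i", resid, resid)
    dev = Y - Y.mean(axis=1, keepdims=True)
    rss0 = np.einsum("ij,ij->i", dev, dev)

    scale = np.maximum(np.abs(Y).max(axis=1), 1.0) ** 2
    constant = rss0 <= n * 1e-24 * scale
    perfect = (rss1 <= n * 1e-24 * scale) & ~constant

    df2 = n - 3
    ss_harm = np.maximum(rss0 - rss1, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fstat = (ss_harm / 2.0) / (rss1 / df2)
    pvalue = stats.f.sf(fstat, 2, df2)
    pvalue = np.where(constant, 1.0, pvalue)
    pvalue = np.where(perfect, P_FLOOR, pvalue)
    pvalue = np.clip(pvalue, P_FLOOR, 1.0)

    a, b = B[:, 1], B[:, 2]
    amplitude = np.hypot(a, b)
    amplitude = np.where(constant, 0.0, amplitude)
    phase = np.mod(np.arctan2(b, a) / w, period)
    phase = np.where(constant, 0.0, phase)
    mesor = B[:, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(
            mesor > amplitude,
            np.log2((mesor + amplitude) / (mesor - amplitude)),
            np.nan,
        )
    return {
        "mesor": mesor,
        "amplitude": amplitude,
        "phase": phase,
        "pvalue": pvalue,
        "rel_amplitude": rel,
        "coef_cos": np.where(constant, 0.0, a),
        "coef_sin": np.where(constant, 0.0, b),
    }


def fit_cosine(times, values, period: float = DEFAULT_PERIOD) -> CosineFit:
    """Fit one series; see :func:`harmonic_regression` for the model."""
    r = harmonic_regression(times, np.asarray(values, dtype=float), period)
    return CosineFit(
        mesor=float(r["mesor"][0]),
        amplitude=float(r["amplitude"][0]),
        phase=float(r["phase"][0]),
        pvalue=float(r["pvalue"][0]),
        rel_amplitude=float(r["rel_amplitude"][0]),
        period=period,
        n=np.asarray(times).size,
    )


def fit_cosine_matrix(
    tsm: TimeSeriesMatrix, period: float = DEFAULT_PERIOD
) -> pd.DataFrame:
    """Per-transcript cosine fits for a whole matrix.

    Returns a DataFrame indexed by transcript with columns ``mesor``,
    ``amplitude``, ``phase``, ``pvalue``, ``rel_amplitude``.
    """
    r = harmonic_regression(tsm.times, tsm.values.to_numpy(dtype=float), period)
    return pd.DataFrame(
        {k: r[k] for k in ("mesor", "amplitude", "phase", "pvalue", "rel_amplitude")},
        index=tsm.transcripts,
    )


def circular_phase_diff(phi1, phi2, period: float = DEFAULT_PERIOD):
    """Shortest distance between two phases on the circle, in [0, period/2]."""
    d = np.abs(np.asarray(phi1) - np.asarray(phi2)) % period
    return np.minimum(d, period - d)


def _weighted_circular_mean(phases, weights, period: float) -> np.ndarray:
    ang = 2.0 * np.pi * np.asarray(phases) / period
    w = np.asarray(weights)
    z = (w * np.exp(1j * ang)).sum(axis=0)
    return np.mod(np.angle(z) * period / (2.0 * np.pi), period)


def consistency_score(
    fit1: CosineFit,
    fit2: CosineFit,
    score_min: float = DEFAULT_SCORE_MIN,
    phasediff_max: float = DEFAULT_PHASEDIFF_MAX,
) -> ConsistencyResult:
    """Combine two independent cosine fits into a consistency call.

    The score ``S = -log2 p1 - log2 p2`` sums evidence in bits; the
    combined phase is the circular mean of the two peak phases weighted
    by each dataset's ``-log2 p``.
    """
    period = fit1.period
    p1 = max(fit1.pvalue, P_FLOOR)
    p2 = max(fit2.pvalue, P_FLOOR)
    s = -np.log2(p1) - np.log2(p2)
    dphi = float(circular_phase_diff(fit1.phase, fit2.phase, period))
    combined = float(
        _weighted_circular_mean(
            np.array([[fit1.phase], [fit2.phase]]),
            np.array([[-np.log2(p1)], [-np.log2(p2)]]),
            period,
        )[0]
    )
    passed = (s > score_min) and (dphi < phasediff_max)
    return ConsistencyResult(
        score=float(s), phase_diff=dphi, combined_phase=combined, passed=bool(passed)
    )


def consistency_table(
    tsm1: TimeSeriesMatrix,
    tsm2: TimeSeriesMatrix,
    period: float = DEFAULT_PERIOD,
    score_min: float = DEFAULT_SCORE_MIN,
    phasediff_max: float = DEFAULT_PHASEDIFF_MAX,
) -> pd.DataFrame:
    """Full two-dataset screen for circadian transcripts.

    Both matrices must share their transcript universe (intersection is
    used, original order of ``tsm1`` kept).  Columns: ``p_dataset1``,
    ``p_dataset2``, ``phase1``, ``phase2``, ``score``, ``phase_diff``,
    ``combined_phase``, ``pass``.
    """
    shared = [tx for tx in tsm1.transcripts if tx in set(tsm2.transcripts)]
    if not shared:
        raise ValueError("matrices share no transcripts")
    f1 = fit_cosine_matrix(tsm1, period).loc[shared]
    f2 = fit_cosine_matrix(tsm2, period).loc[shared]
    l1 = -np.log2(np.clip(f1["pvalue"].to_numpy(), P_FLOOR, 1.0))
    l2 = -np.log2(np.clip(f2["pvalue"].to_numpy(), P_FLOOR, 1.0))
    score = l1 + l2
    dphi = circular_phase_diff(f1["phase"].to_numpy(), f2["phase"].to_numpy(), period)
    combined = _weighted_circular_mean(
        np.vstack([f1["phase"].to_numpy(), f2["phase"].to_numpy()]),
        np.vstack([l1, l2]),
        period,
    )
    return pd.DataFrame(
        {
            "p_dataset1": f1["pvalue"].to_numpy(),
            "p_dataset2": f2["pvalue"].to_numpy(),
            "phase1": f1["phase"].to_numpy(),
            "phase2": f2["phase"].to_numpy(),
            "score": score,
            "phase_diff": dphi,
            "combined_phase": combined,
            "pass": (score > score_min) & (dphi < phasediff_max),
        },
        index=pd.Index(shared, name="transcript"),
    )


def fit_cosine_shared_phase(
    tsm1: TimeSeriesMatrix,
    tsm2: TimeSeriesMatrix,
    period: float = DEFAULT_PERIOD,
    grid_step: float = 0.05,
) -> pd.DataFrame:
    """Joint fit with one shared peak phase across both datasets.

    For each candidate phase on a grid the model
    ``x_d(t) = m_d + A_d cos(w (t - phi))`` is linear per dataset; the
    phase minimising the pooled residual sum of squares wins.  Exposed as
    an alternative reading of a "common cosine" criterion; the default
    screen fits the datasets separately and compares phases.
    """
    shared = [tx for tx in tsm1.transcripts if tx in set(tsm2.transcripts)]
    Y1 = tsm1.values.loc[shared].to_numpy(dtype=float)
    Y2 = tsm2.values.loc[shared].to_numpy(dtype=float)
    w = 2.0 * np.pi / period
    phis = np.arange(0.0, period, grid_step)
    best_rss = np.full(len(shared), np.inf)
    best_phi = np.zeros(len(shared))
    best_amp = np.zeros((len(shared), 2))

    def _rss_at(Y, t, phi):
        c = np.cos(w * (t - phi))
        X = np.column_stack([np.ones(t.size), c])
        B = Y @ np.linalg.pinv(X).T
        R = Y - B @ X.T
        return np.einsum("ij,ij->i", R, R), B[:, 1]

    for phi in phis:
        r1, a1 = _rss_at(Y1, tsm1.times, phi)
        r2, a2 = _rss_at(Y2, tsm2.times, phi)
        rss = r1 + r2
        better = rss < best_rss
        best_rss[better] = rss[better]
        best_phi[better] = phi
        best_amp[better, 0] = a1[better]
        best_amp[better, 1] = a2[better]
    # a negative amplitude at phase phi is a positive one at phi + T/2
    flip = best_amp[:, 0] + best_amp[:, 1] < 0
    best_phi[flip] = np.mod(best_phi[flip] + period / 2.0, period)
    best_amp[flip] *= -1.0
    return pd.DataFrame(
        {
            "phase": best_phi,
            "amplitude1": best_amp[:, 0],
            "amplitude2": best_amp[:, 1],
            "rss": best_rss,
        },
        index=pd.Index(shared, name="transcript"),
    )


def compute_rpkm(
    counts: pd.DataFrame, lengths: pd.Series, library_sizes: pd.Series
) -> pd.DataFrame:
    """Reads per kilobase of transcript per million mapped reads.

    ``value = count / (length/1000) / (library_size/1e6)``.
    """
    lengths = lengths.reindex(counts.index)
    library_sizes = library_sizes.reindex(counts.columns)
    if lengths.isna().any():
        raise ValueError(f"missing length for {lengths.index[lengths.isna()][0]!r}")
    if library_sizes.isna().any():
        raise ValueError(
            f"missing library size for {library_sizes.index[library_sizes.isna()][0]!r}"
        )
    if (lengths <= 0).any():
        raise ValueError(f"nonpositive length for {lengths.index[lengths <= 0][0]!r}")
    if (library_sizes <= 0).any():
        raise ValueError(
            f"nonpositive library size for {library_sizes.index[library_sizes <= 0][0]!r}"
        )
    kb = lengths.to_numpy(dtype=float)[:, None] / 1e3
    millions = library_sizes.to_numpy(dtype=float)[None, :] / 1e6
    return counts.astype(float) / kb / millions


def mature_rhythm_test(
    times,
    values,
    period: float = DEFAULT_PERIOD,
    alpha: float = 0.05,
) -> tuple[float, float, bool]:
    """Relaxed rhythmicity test for dampened mature-level series.

    Runs a one-way ANOVA across time groups (times compared modulo the
    period) plus the cosine fit on all points; the series passes when
    both p-values are below ``alpha``.

    Returns ``(anova_p, cosine_p, passed)``.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    keys = np.round(np.mod(t, period), 9)
    groups = [y[keys == k] for k in np.unique(keys)]
    if len(groups) < 2:
        raise ValueError("need >= 2 time groups")
    if max(len(g) for g in groups) < 2:
        raise ValueError("one-way ANOVA needs replicates in at least one time group")
    if np.ptp(y) == 0:
        anova_p = 1.0
    else:
        _, anova_p = stats.f_oneway(*groups)
        if not np.isfinite(anova_p):
            anova_p = 1.0
    cosine_p = fit_cosine(t, y, period).pvalue
    return float(anova_p), float(cosine_p), bool(anova_p < alpha and cosine_p < alpha)
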