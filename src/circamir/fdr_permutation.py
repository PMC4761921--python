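"""Permutation estimate of the consistency-screen false discovery rate.

The circadian call (score > score_min and phase difference <
phasediff_max) has no closed-form null, so its FDR is estimated
empirically: sample labels are shuffled, the full two-dataset screen is
re-run, and

    FDR = mean(passing transcripts per permutation) / passing transcripts (real)

Shuffling each transcript's values across samples independently within
each dataset (the default) destroys both the rhythm and any
cross-dataset phase agreement while preserving every transcript's value
distribution.  A whole-row alternative, which permutes transcript
identities within each dataset and therefore keeps each row's temporal
structure but breaks the pairing between datasets, is available as
``mode="row_swap"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import TimeSeriesMatrix
from .rhythm_detection import (
    DEFAULT_PERIOD,
    DEFAULT_PHASEDIFF_MAX,
    DEFAULT_SCORE_MIN,
    P_FLOOR,
    circular_phase_diff,
    harmonic_regression,
)

PERMUTATION_MODES = ("within_transcript", "row_swap")


@dataclass
class FdrEstimate:
    """Permutation FDR of the consistency classifier.

    ``fdr`` is capped at 1.0 for reporting; ``fdr_raw`` keeps the raw
    ratio.  Both are ``None`` when no real transcript passes (the
    estimate is undefined, not an error).
    """

    n_permutations: int
    score_min: float
    phasediff_max: float
    n_pass_real: int
    mean_pass_permuted: float
    fdr: float | None
    fdr_raw: float | None
    pass_counts: list[int] = field(default_factory=list)
    seed: int | None = None
    mode: str = "within_transcript"

    def to_dict(self) -> dict:
        return {
            "n_permutations": self.n_permutations,
            "score_min": self.score_min,
            "phasediff_max": self.phasediff_max,
            "n_pass_real": self.n_pass_real,
            "mean_pass_permuted": self.mean_pass_permuted,
            "fdr": self.fdr,
            "fdr_raw": self.fdr_raw,
            "pass_counts": list(self.pass_counts),
            "seed": self.seed,
            "mode": self.mode,
        }


class _ScreenScorer:
    """Pre-factorised harmonic fits for repeated scoring of one matrix pair."""

    def __init__(self, tsm1: TimeSeriesMatrix, tsm2: TimeSeriesMatrix, period: float):
        shared = [tx for tx in tsm1.transcripts if tx in set(tsm2.transcripts)]
        if not shared:
            raise ValueError("matrices share no transcripts")
        self.period = period
        self.t1 = np.asarray(tsm1.times, dtype=float)
        self.t2 = np.asarray(tsm2.times, dtype=float)
        self.Y1 = tsm1.values.loc[shared].to_numpy(dtype=float)
        self.Y2 = tsm2.values.loc[shared].to_numpy(dtype=float)

    def pass_count(self, Y1, Y2, score_min, phasediff_max) -> int:
        r1 = harmonic_regression(self.t1, Y1, self.period)
        r2 = harmonic_regression(self.t2, Y2, self.period)
        s = -np.log2(np.clip(r1["pvalue"], P_FLOOR, 1.0)) - np.log2(
            np.clip(r2["pvalue"], P_FLOOR, 1.0)
        )
        dphi = circular_phase_diff(r1["phase"], r2["phase"], self.period)
        return int(((s > score_min) & (dphi < phasediff_max)).sum())


def _shuffle_rows(Y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independently permute each row's values across columns."""
    order = rng.random(Y.shape).argsort(axis=1)
    return np.take_along_axis(Y, order, axis=1)


def permute_and_score(
    tsm1: TimeSeriesMatrix,
    tsm2: TimeSeriesMatrix,
    n_perm: int,
    seed: int,
    period: float = DEFAULT_PERIOD,
    score_min: float = DEFAULT_SCORE_MIN,
    phasediff_max: float = DEFAULT_PHASEDIFF_MAX,
    mode: str = "within_transcript",
) -> np.ndarray:
    """Pass counts of the consistency screen under permuted data.

    Per-permutation RNG streams are spawned deterministically from
    ``seed``, so results are reproducible and independent of how the
    loop might be chunked.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if mode not in PERMUTATION_MODES:
        raise ValueError(f"mode must be one of {PERMUTATION_MODES}")
    scorer = _ScreenScorer(tsm1, tsm2, period)
    streams = np.random.SeedSequence(seed).spawn(n_perm)
    counts = np.empty(n_perm, dtype=int)
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        if mode == "within_transcript":
            Y1 = _shuffle_rows(scorer.Y1, rng)
            Y2 = _shuffle_rows(scorer.Y2, rng)
        else:  # row_swap: re-pair transcripts across datasets
            Y1 = scorer.Y1[rng.permutation(scorer.Y1.shape[0])]
            Y2 = scorer.Y2[rng.permutation(scorer.Y2.shape[0])]
        counts[i] = scorer.pass_count(Y1, Y2, score_min, phasediff_max)
    return counts


def estimate_fdr(
    n_pass_real: int,
    permuted_counts,
    score_min: float = DEFAULT_SCORE_MIN,
    phasediff_max: float = DEFAULT_PHASEDIFF_MAX,
    seed: int | None = None,
    mode: str = "within_transcript",
) -> FdrEstimate:
    """Turn permutation pass counts into an FDR estimate."""
    counts = np.asarray(permuted_counts, dtype=float)
    if counts.size < 1:
        raise ValueError("need at least one permutation")
    mean_perm = float(counts.mean())
    if n_pass_real > 0:
        raw = mean_perm / n_pass_real
        fdr = min(raw, 1.0)
    else:
        raw = None
        fdr = None
    return FdrEstimate(
        n_permutations=int(counts.size),
        score_min=score_min,
        phasediff_max=phasediff_max,
        n_pass_real=int(n_pass_real),
        mean_pass_permuted=mean_perm,
        fdr=fdr,
        fdr_raw=raw,
        pass_counts=[int(c) for c in counts],
        seed=seed,
        mode=mode,
    )


def permutation_fdr(
    tsm1: TimeSeriesMatrix,
    tsm2: TimeSeriesMatrix,
    n_perm: int,
    seed: int,
    period: float = DEFAULT_PERIOD,
    score_min: float = DEFAULT_SCORE_MIN,
    phasediff_max: float = DEFAULT_PHASEDIFF_MAX,
    mode: str = "within_transcript",
) -> FdrEstimate:
    """One-call convenience: real screen + permutations + FDR estimate."""
    from .rhythm_detection import consistency_table

    real = consistency_table(
        tsm1, tsm2, period=period, score_min=score_min, phasediff_max=phasediff_max
    )
    counts = permute_and_score(
        tsm1,
        tsm2,
        n_perm,
        seed,
        period=period,
        score_min=score_min,
        phasediff_max=phasediff_max,
        mode=mode,
    )
    return estimate_fdr(
        int(real["pass"].sum()),
        counts,
        score_min=score_min,
        phasediff_max=phasediff_max,
        seed=seed,
        mode=mode,
    )
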