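"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the statistical structure of the real study
designs so the whole pipeline is testable without any download:

- a pair of nascent-transcription time courses (GRO-seq / Nascent-seq
  stand-ins) sharing planted cosine rhythms but carrying independent
  noise, sampled by default every 4 h over 48 h (dataset A) and every
  3 h over 24 h (dataset B) to exercise unequal designs;
- dampened mature-miRNA series derived from the primary rhythms through
  first-order degradation kinetics;
- a 2x2 (CT10/CT22 x over-expression/control) expression table with two
  replicates per cell, planted main effects, optional planted
  amplitude shifts, and miRNA-target annotations enriched among the
  planted under-expressed genes;
- ChIP-style binding peaks placed in promoter windows with elevated odds
  on circadian transcripts.

Expression noise is multiplicative lognormal: nascent RPKM is positive
and right-skewed, and the lognormal keeps strict positivity without
truncation.  Every generator is a pure function of its parameters and
seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import DesignedExpression, TimeSeriesMatrix
from .network import BindingCall, GenomicInterval, TranscriptModel, promoter_window


def _fold_to_amplitude(log2_fold: np.ndarray) -> np.ndarray:
    """Map a log2 peak/trough fold to the cosine amplitude fraction a.

    ``(1+a)/(1-a) = 2**fold``  =>  ``a = (F-1)/(F+1) in (0, 1)``.
    """
    F = np.exp2(log2_fold)
    return (F - 1.0) / (F + 1.0)


@dataclass
class RhythmSimParams:
    """Conditions for the paired nascent time-series generator.

    Defaults mirror the study designs: a 12-point, 4-h-step, 48-h series
    (dataset A) and an 8-point, 3-h-step, 24-h series (dataset B);
    planted rhythms have peak/trough folds of 2-8 (log2 fold 1-3) and
    lognormal noise sigma 0.2 on the natural-log scale.
    """

    n_transcripts: int = 1000
    frac_rhythmic: float = 0.2
    sampling_start: float = 0.0
    sampling_step: float = 4.0
    n_points: int = 12
    b_sampling_start: float = 0.0
    b_sampling_step: float = 3.0
    b_n_points: int = 8
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 1.0
    rel_amplitude_range: tuple[float, float] = (1.0, 3.0)
    noise_sd: float = 0.2
    period: float = 24.0
    inter_dataset_phase_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.frac_rhythmic <= 1.0:
            raise ValueError("frac_rhythmic must lie in [0, 1]")
        if self.n_transcripts < 1:
            raise ValueError("n_transcripts must be positive")
        if min(self.n_points, self.b_n_points) < 4:
            raise ValueError("need >= 4 time points per dataset (fit underdetermined)")
        for name in ("sampling_step", "b_sampling_step", "baseline_log_sd", "period"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.rel_amplitude_range
        if not (0 < lo <= hi):
            raise ValueError("rel_amplitude_range must be positive and ordered")
        if self.noise_sd < 0 or self.inter_dataset_phase_sd < 0:
            raise ValueError("noise scales must be nonnegative")
        # amplitude fraction from a finite fold is always < 1, but guard anyway
        if _fold_to_amplitude(np.array([hi]))[0] >= 1.0:
            raise ValueError("relative amplitude implies a >= 1 (negative expression)")

    def grid(self, dataset: str) -> np.ndarray:
        if dataset == "A":
            return self.sampling_start + self.sampling_step * np.arange(self.n_points)
        return self.b_sampling_start + self.b_sampling_step * np.arange(self.b_n_points)


@dataclass
class OeSimParams:
    """Conditions for the 2x2 over-expression generator.

    The design copies the animal experiment: two treated and two control
    animals at each of CT10 and CT22 (``reps_per_cell=2``).  Planted
    treatment effects are predominantly repressive
    (``frac_under_vs_over``) and target annotations are enriched among
    planted under-expressed genes by ``target_enrichment`` odds.
    """

    n_genes: int = 2000
    frac_treatment_affected: float = 0.3
    frac_under_vs_over: float = 0.8
    frac_time_affected: float = 0.3
    effect_log2fc: float = 1.0
    time_log2fc: float = 1.0
    reps_per_cell: int = 2
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 1.0
    noise_sd: float = 0.25
    target_enrichment: float = 2.0
    base_target_prob: float = 0.25
    frac_amplitude_shift: float = 0.0
    amplitude_shift_log2: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for name in (
            "frac_treatment_affected",
            "frac_under_vs_over",
            "frac_time_affected",
            "frac_amplitude_shift",
            "base_target_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.reps_per_cell < 2:
            raise ValueError("reps_per_cell must be >= 2 (ANOVA needs residual df)")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.target_enrichment < 0:
            raise ValueError("target_enrichment must be nonnegative")


@dataclass
class GroundTruth:
    """Planted truth emitted alongside every simulated dataset."""

    transcripts: pd.DataFrame | None = None
    genes: pd.DataFrame | None = None
    params: dict = field(default_factory=dict)

    def to_dir(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if self.transcripts is not None:
            self.transcripts.to_csv(outdir / "truth_transcripts.tsv", sep="\t")
        if self.genes is not None:
            self.genes.to_csv(outdir / "truth_genes.tsv", sep="\t")
        with open(outdir / "truth_params.json", "w") as fh:
            json.dump(self.params, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")


def simulate_nascent_pair(
    params: RhythmSimParams,
) -> tuple[TimeSeriesMatrix, TimeSeriesMatrix, GroundTruth]:
    """Two independent nascent time courses with shared planted rhythms.

    Rhythmic transcripts follow
    ``x(t) = exp(b) * (1 + a cos(2 pi (t - phi)/T)) * exp(eps)`` with
    ``eps ~ N(0, noise_sd)`` drawn independently per dataset and sample;
    non-rhythmic transcripts have ``a = 0``.  Phases are uniform on
    [0, T) and shared between the datasets (an optional inter-dataset
    phase jitter is off by default), so the planted truth defines the
    cross-dataset consistency target exactly.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_transcripts
    ids = pd.Index([f"tx{i:05d}" for i in range(n)], name="transcript")
    n_rhythmic = int(round(params.frac_rhythmic * n))
    rhythmic = np.zeros(n, dtype=bool)
    rhythmic[rng.choice(n, size=n_rhythmic, replace=False)] = True
    phases = rng.uniform(0.0, params.period, size=n)
    lo, hi = params.rel_amplitude_range
    folds = rng.uniform(lo, hi, size=n)
    a = np.where(rhythmic, _fold_to_amplitude(folds), 0.0)
    if (a >= 1.0).any():
        raise ValueError("amplitude fraction a >= 1 would give negative expression")
    baselines = np.exp(rng.normal(params.baseline_log_mean, params.baseline_log_sd, n))

    def _dataset(label: str, times: np.ndarray, phase_jitter: np.ndarray) -> TimeSeriesMatrix:
        phi = np.mod(phases + phase_jitter, params.period)
        curve = 1.0 + a[:, None] * np.cos(
            2.0 * np.pi * (times[None, :] - phi[:, None]) / params.period
        )
        noise = np.exp(rng.normal(0.0, params.noise_sd, size=(n, times.size)))
        values = baselines[:, None] * curve * noise
        return TimeSeriesMatrix(
            values=pd.DataFrame(values, index=ids, columns=range(times.size)),
            times=times,
            dataset=label,
        )

    jitter_a = np.zeros(n)
    jitter_b = (
        rng.normal(0.0, params.inter_dataset_phase_sd, n)
        if params.inter_dataset_phase_sd > 0
        else np.zeros(n)
    )
    tsm_a = _dataset("synthetic-GRO-seq", params.grid("A"), jitter_a)
    tsm_b = _dataset("synthetic-Nascent-seq", params.grid("B"), jitter_b)
    truth = GroundTruth(
        transcripts=pd.DataFrame(
            {
                "rhythmic": rhythmic,
                "phase": np.where(rhythmic, phases, np.nan),
                "rel_amplitude_log2": np.where(rhythmic, folds, 0.0),
                "amplitude_fraction": a,
                "baseline": baselines,
            },
            index=ids,
        ),
        params=asdict(params),
    )
    return tsm_a, tsm_b, truth


def simulate_mature(
    primary_truth: GroundTruth,
    half_life: float = 119.0,
    period: float = 24.0,
    sampling_start: float = 0.0,
    sampling_step: float = 4.0,
    n_points: int = 6,
    reps: int = 3,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> TimeSeriesMatrix:
    """Mature-level series implied by first-order degradation kinetics.

    At steady state of ``dP/dt = s(t) - k P`` with sinusoidal synthesis,
    a primary rhythm of relative amplitude ``a`` yields a mature rhythm
    of amplitude ``a * k/sqrt(k^2 + w^2)`` peaking
    ``arctan(w/k)/w`` hours later (``k = ln2/half_life``,
    ``w = 2 pi/period``).  The default grid (6 points x 3 replicates
    over 24 h) matches a qPCR-style validation design.
    """
    if half_life <= 0:
        raise ValueError("half_life must be positive")
    if primary_truth.transcripts is None:
        raise ValueError("primary ground truth carries no transcript table")
    tr = primary_truth.transcripts
    rng = np.random.default_rng(seed)
    k = np.log(2.0) / half_life
    w = 2.0 * np.pi / period
    attenuation = k / np.hypot(k, w)
    lag = np.arctan2(w, k) / w
    base_times = sampling_start + sampling_step * np.arange(n_points)
    times = np.repeat(base_times, reps)
    replicates = np.tile(np.arange(1, reps + 1), n_points)
    a = tr["amplitude_fraction"].to_numpy() * attenuation
    phi = np.where(
        tr["rhythmic"].to_numpy(), np.mod(tr["phase"].to_numpy() + lag, period), 0.0
    )
    baselines = tr["baseline"].to_numpy()
    curve = 1.0 + a[:, None] * np.cos(
        2.0 * np.pi * (times[None, :] - phi[:, None]) / period
    )
    noise = np.exp(rng.normal(0.0, noise_sd, size=(len(tr), times.size)))
    values = baselines[:, None] * curve * noise
    return TimeSeriesMatrix(
        values=pd.DataFrame(values, index=tr.index, columns=range(times.size)),
        times=times,
        dataset="synthetic-mature",
        replicates=replicates,
    )


def simulate_overexpression(
    params: OeSimParams,
) -> tuple[DesignedExpression, GroundTruth, list[str]]:
    """2x2xr over-expression table with planted effects and targets.

    log2-expression is generated directly as
    ``mu + time_effect*1[CT10] + treatment_effect*1[oe] (+ shift on the
    CT10,oe cell) + N(0, noise_sd)`` and exponentiated; the ANOVA
    operates on logs, so planting on the log scale sidesteps any
    count-model assumption.  Planted under-expressed genes are
    target-annotated at ``target_enrichment``-fold odds.  Ground truth
    records the planted Group I-IV label (both effects present) and the
    planted amplitude-change class.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_genes
    ids = pd.Index([f"gene{i:05d}" for i in range(n)], name="gene")

    trt_affected = rng.random(n) < params.frac_treatment_affected
    under = rng.random(n) < params.frac_under_vs_over
    trt_dir = np.where(under, "under", "over")
    trt_effect = np.where(trt_affected, np.where(under, -1.0, 1.0) * params.effect_log2fc, 0.0)

    time_affected = rng.random(n) < params.frac_time_affected
    ct10_peak = rng.random(n) < 0.5
    time_dir = np.where(ct10_peak, "CT10>CT22", "CT10<CT22")
    time_effect = np.where(
        time_affected, np.where(ct10_peak, 1.0, -1.0) * params.time_log2fc, 0.0
    )

    # planted amplitude modulation: an interaction term on the (CT10, oe)
    # cell, oriented by the gene's peak side so "increased" always means a
    # larger oscillation magnitude under over-expression
    shifted = time_affected & (rng.random(n) < params.frac_amplitude_shift)
    shift_up = rng.random(n) < 0.5
    amp_class = np.full(n, "unchanged", dtype=object)
    amp_class[shifted & shift_up] = "increased"
    amp_class[shifted & ~shift_up] = "decreased"
    oriented = np.where(shift_up, 1.0, -1.0) * params.amplitude_shift_log2
    interaction = np.where(
        shifted, np.where(ct10_peak, oriented, -oriented), 0.0
    )

    group = np.full(n, "none", dtype=object)
    both = trt_affected & time_affected
    group[both & ct10_peak & under] = "I"
    group[both & ct10_peak & ~under] = "II"
    group[both & ~ct10_peak & under] = "III"
    group[both & ~ct10_peak & ~under] = "IV"

    mu = rng.normal(params.baseline_log2_mean, params.baseline_log2_sd, n)
    samples, columns = [], []
    for time in ("CT10", "CT22"):
        for treatment in ("oe", "null"):
            for rep in range(1, params.reps_per_cell + 1):
                is_ct10 = 1.0 if time == "CT10" else 0.0
                is_oe = 1.0 if treatment == "oe" else 0.0
                log2x = (
                    mu
                    + time_effect * is_ct10
                    + trt_effect * is_oe
                    + interaction * is_ct10 * is_oe
                    + rng.normal(0.0, params.noise_sd, n)
                )
                samples.append(np.exp2(log2x))
                columns.append(f"{time}_{treatment}_{rep}")
    values = pd.DataFrame(np.column_stack(samples), index=ids, columns=columns)
    design = pd.DataFrame(
        {
            "time": [c.split("_")[0] for c in columns],
            "treatment": [c.split("_")[1] for c in columns],
            "replicate": [int(c.split("_")[2]) for c in columns],
        },
        index=pd.Index(columns, name="sample"),
    )

    planted_under = trt_affected & under
    odds = np.where(planted_under, params.target_enrichment, 1.0)
    p0 = params.base_target_prob
    p_target = odds * p0 / (1.0 - p0 + odds * p0)
    is_target = rng.random(n) < p_target
    target_list = list(ids[is_target])

    truth = GroundTruth(
        genes=pd.DataFrame(
            {
                "treatment_affected": trt_affected,
                "treatment_direction": np.where(trt_affected, trt_dir, ""),
                "time_affected": time_affected,
                "time_direction": np.where(time_affected, time_dir, ""),
                "group": group,
                "amp_class": amp_class,
                "planted_delta_ra": np.where(shifted, params.amplitude_shift_log2, 0.0),
                "is_target": is_target,
            },
            index=ids,
        ),
        params=asdict(params),
    )
    return DesignedExpression(values=values, design=design), truth, target_list


def simulate_binding(
    n_transcripts: int,
    circadian_flags,
    regulators=("BMAL1", "CLOCK", "REV-ERBA", "PER1"),
    enrichment_odds: float | dict[str, float] = 3.0,
    seed: int = 0,
    base_prob: float = 0.3,
    peak_width: int = 400,
    transcript_length: int = 10_000,
    spacing: int = 60_000,
    upstream: int = 5000,
    n_bmal1_datasets: int = 6,
) -> tuple[list[BindingCall], list[TranscriptModel]]:
    """Promoter-placed ChIP peaks with circadian enrichment.

    Transcripts are laid out on one synthetic chromosome with enough
    spacing that promoter windows never overlap.  Each regulator binds a
    transcript's promoter with probability ``base_prob``, raised to
    odds-multiplied probability on circadian transcripts.  BMAL1 calls
    draw a dataset-support count uniform on 1..``n_bmal1_datasets``;
    other regulators carry support 1.
    """
    flags = np.asarray(circadian_flags, dtype=bool)
    if flags.size != n_transcripts:
        raise ValueError("circadian_flags must have length n_transcripts")
    if isinstance(enrichment_odds, dict):
        odds_for = dict(enrichment_odds)
    else:
        odds_for = {r: float(enrichment_odds) for r in regulators}
    for r, o in odds_for.items():
        if o < 1.0:
            raise ValueError(f"enrichment_odds for {r!r} must be >= 1")
    rng = np.random.default_rng(seed)
    transcripts = []
    for i in range(n_transcripts):
        start = upstream + 1000 + i * spacing
        strand = "+" if i % 2 == 0 else "-"
        transcripts.append(
            TranscriptModel(
                id=f"tx{i:05d}",
                interval=GenomicInterval("chrS", start, start + transcript_length, strand),
            )
        )
    calls: list[BindingCall] = []
    for reg in regulators:
        odds = odds_for.get(reg, 1.0)
        p_circ = odds * base_prob / (1.0 - base_prob + odds * base_prob)
        p = np.where(flags, p_circ, base_prob)
        bound = rng.random(n_transcripts) < p
        for i in np.flatnonzero(bound):
            win = promoter_window(transcripts[i], upstream)
            lo = win.start
            hi = max(win.end - peak_width, lo + 1)
            s = int(rng.integers(lo, hi))
            support = (
                int(rng.integers(1, n_bmal1_datasets + 1)) if reg == "BMAL1" else 1
            )
            calls.append(
                BindingCall(
                    regulator=reg,
                    interval=GenomicInterval("chrS", s, s + peak_width, "+"),
                    n_supporting_datasets=support,
                )
            )
    return calls, transcripts
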