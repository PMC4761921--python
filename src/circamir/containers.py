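"""In-memory containers for timed expression data.

Two containers cover the pipeline's tabular inputs:

:class:`TimeSeriesMatrix`
    transcripts x timed samples of nonnegative expression (RPKM or
    normalized counts), each sample annotated with a circadian time
    (CT, hours) and an optional replicate index.

:class:`DesignedExpression`
    genes x samples from a 2x2 factorial design with factors
    ``time`` (CT10/CT22) and ``treatment`` (oe/null) plus replicates.

Both round-trip through plain TSV.  Time-series column headers follow
``CT<float>[_rep<k>]`` (e.g. ``CT8``, ``CT8_rep2``); the first column of
every TSV is the transcript/gene identifier.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

_CT_COLUMN = re.compile(r"^CT(?P<time>-?\d+(?:\.\d+)?)(?:_rep(?P<rep>\d+))?$")


def _format_ct(time: float, rep: int | None) -> str:
    label = f"CT{time:g}"
    if rep is not None:
        label += f"_rep{rep:d}"
    return label


@dataclass
class TimeSeriesMatrix:
    """Expression matrix over a circadian time course.

    Parameters
    ----------
    values
        DataFrame of nonnegative expression, transcripts as rows and one
        column per sample.
    times
        Circadian time in hours for each sample column.  Times may exceed
        the period (multi-day designs); periodic operations reduce them
        modulo the period.
    dataset
        Free-text label of the originating assay (e.g. ``"GRO-seq"``).
    replicates
        Optional replicate index per sample column (1-based).
    """

    values: pd.DataFrame
    times: np.ndarray
    dataset: str = ""
    replicates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.values.shape[1] != self.times.size:
            raise ValueError(
                f"{self.values.shape[1]} sample columns but {self.times.size} times"
            )
        if not np.isfinite(self.times).all():
            raise ValueError("sample times must be finite")
        vals = self.values.to_numpy()
        if vals.size and (np.asarray(vals, dtype=float) < 0).any():
            raise ValueError("expression values must be nonnegative")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate transcript id: {dup!r}")
        if self.replicates is not None:
            self.replicates = np.asarray(self.replicates, dtype=int)
            if self.replicates.size != self.times.size:
                raise ValueError("replicates must align with sample columns")

    @property
    def transcripts(self) -> pd.Index:
        return self.values.index

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def n_distinct_times(self, period: float = 24.0) -> int:
        """Number of distinct sampling times modulo ``period``."""
        return np.unique(np.round(np.mod(self.times, period), 9)).size

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        reps = self.replicates if self.replicates is not None else [None] * self.n_samples
        out.columns = [_format_ct(t, r) for t, r in zip(self.times, reps)]
        out.index.name = "transcript"
        out.to_csv(path, sep="\t", float_format="%.6g")

    @classmethod
    def from_tsv(cls, path: str | Path, dataset: str = "") -> "TimeSeriesMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        times, reps, any_rep = [], [], False
        for col in df.columns:
            m = _CT_COLUMN.match(str(col))
            if m is None:
                raise ValueError(
                    f"column {col!r} does not match 'CT<float>[_rep<k>]'"
                )
            times.append(float(m.group("time")))
            rep = m.group("rep")
            any_rep = any_rep or rep is not None
            reps.append(int(rep) if rep is not None else 1)
        return cls(
            values=df,
            times=np.array(times),
            dataset=dataset or str(path),
            replicates=np.array(reps) if any_rep else None,
        )


@dataclass
class DesignedExpression:
    """Factorial (time x treatment) expression table.

    ``design`` is indexed by sample name with columns ``time`` (values
    ``"CT10"``/``"CT22"``), ``treatment`` (``"oe"``/``"null"``) and
    ``replicate``.  Every sample column of ``values`` must appear in the
    design.  The two-factor ANOVA operates on ``log2(x + 1)`` internally;
    values stored here stay on the raw (linear) scale.
    """

    values: pd.DataFrame
    design: pd.DataFrame

    TIMES = ("CT10", "CT22")
    TREATMENTS = ("oe", "null")

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.design.index)
        if missing:
            raise ValueError(f"samples missing from design: {sorted(missing)[:3]}")
        self.design = self.design.loc[list(self.values.columns)]
        bad_t = set(self.design["time"]) - set(self.TIMES)
        if bad_t:
            raise ValueError(f"unknown time levels: {bad_t}")
        bad_g = set(self.design["treatment"]) - set(self.TREATMENTS)
        if bad_g:
            raise ValueError(f"unknown treatment levels: {bad_g}")
        cell_sizes = self.design.groupby(["time", "treatment"], observed=True).size()
        if len(cell_sizes) < 4:
            raise ValueError("every (time, treatment) cell needs at least one sample")
        if (cell_sizes < 1).any() or cell_sizes.max() < 2:
            raise ValueError("at least one design cell needs >= 2 replicates")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def samples_where(self, time: str | None = None, treatment: str | None = None) -> list[str]:
        mask = pd.Series(True, index=self.design.index)
        if time is not None:
            mask &= self.design["time"] == time
        if treatment is not None:
            mask &= self.design["treatment"] == treatment
        return list(self.design.index[mask])

    def to_tsv(self, expr_path: str | Path, design_path: str | Path) -> None:
        out = self.values.copy()
        out.index.name = "gene"
        out.to_csv(expr_path, sep="\t", float_format="%.6g")
        d = self.design.copy()
        d.index.name = "sample"
        d.to_csv(design_path, sep="\t")

    @classmethod
    def from_tsv(cls, expr_path: str | Path, design_path: str | Path) -> "DesignedExpression":
        values = pd.read_csv(expr_path, sep="\t", index_col=0)
        # keep_default_na: the control arm is literally named "null"
        design = pd.read_csv(design_path, sep="\t", index_col=0, keep_default_na=False)
        design.index = design.index.astype(str)
        values.columns = values.columns.astype(str)
        return cls(values=values, design=design)
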