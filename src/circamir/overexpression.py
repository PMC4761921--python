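"""Two-factor analysis of the miR-378 over-expression design.

The experiment crosses circadian time (CT10 vs CT22) with adenoviral
treatment (miRNA over-expression ``oe`` vs ``null`` control), with
replicate livers per cell.  Per gene, a main-effects two-way ANOVA on
``log2(x + 1)`` yields p-values for each factor; genes significant for
both (raw p < 0.05, no multiple-testing correction — the screen is
deliberately permissive and validated downstream) are partitioned into
four groups by peak side x treatment direction:

    Group I    peak CT10, under-expressed in oe
    Group II   peak CT10, over-expressed in oe
    Group III  peak CT22, under-expressed in oe
    Group IV   peak CT22, over-expressed in oe

Groups I and III (the repressed, hence plausibly direct, targets) form
the "circadian targets" set used by the amplitude and network analyses.
Enrichment of gene sets is tested with Fisher's exact test or a pooled
two-proportion z-test, matching the statistics used for the published
comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DesignedExpression

GROUPS = ("I", "II", "III", "IV")


@dataclass
class EnrichmentResult:
    """2x2 enrichment outcome (counts, odds ratio, p, test used)."""

    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float
    test: str
    haldane: bool = False

    def to_dict(self) -> dict:
        return {
            "table": [list(r) for r in self.table],
            "odds_ratio": self.odds_ratio,
            "p_value": self.p_value,
            "test": self.test,
            "haldane": self.haldane,
        }


def _anova_rss(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    B = Y @ np.linalg.pinv(X).T
    R = Y - B @ X.T
    return np.einsum("ij,ij->i", R, R)


def two_way_anova(
    de: DesignedExpression,
    alpha: float = 0.05,
    interaction: bool = False,
    transform=None,
) -> pd.DataFrame:
    """Per-gene main-effects ANOVA over the 2x2 design.

    Parameters
    ----------
    de
        The factorial expression table (raw scale).
    alpha
        Significance cutoff used for directions and group labels.
    interaction
        Include the time x treatment interaction in the model; main
        effects are then tested against the full model (type-II drop
        tests, identical to type III in a balanced 2x2).
    transform
        Callable applied to the raw values before fitting; default
        ``log2(x + 1)``.

    Returns
    -------
    DataFrame indexed by gene: ``p_treatment``, ``p_time``,
    ``F_treatment``, ``F_time``, ``treatment_direction`` (under/over in
    oe vs null; only set when p_treatment < alpha), ``time_direction``
    (CT10>CT22 / CT10<CT22 from the null-arm marginal means; only set
    when p_time < alpha) and ``group``.
    """
    if transform is None:
        transform = lambda x: np.log2(x + 1.0)
    Y = transform(de.values.to_numpy(dtype=float))
    x_time = (de.design["time"] == "CT10").to_numpy(dtype=float)
    x_trt = (de.design["treatment"] == "oe").to_numpy(dtype=float)
    n = Y.shape[1]
    cols = [np.ones(n), x_time, x_trt]
    if interaction:
        cols.append(x_time * x_trt)
    X_full = np.column_stack(cols)
    p = X_full.shape[1]
    df_resid = n - p
    if df_resid <= 0:
        raise ValueError(
            "no residual degrees of freedom; the design needs >= 2 replicates "
            "in at least one (time, treatment) cell"
        )
    rss_full = _anova_rss(Y, X_full)
    drop_time = np.column_stack([c for i, c in enumerate(cols) if i != 1])
    drop_trt = np.column_stack([c for i, c in enumerate(cols) if i != 2])
    ss_time = np.maximum(_anova_rss(Y, drop_time) - rss_full, 0.0)
    ss_trt = np.maximum(_anova_rss(Y, drop_trt) - rss_full, 0.0)

    scale = np.maximum(np.abs(Y).max(axis=1), 1.0) ** 2
    tiny = n * 1e-24 * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        F_time = ss_time / (rss_full / df_resid)
        F_trt = ss_trt / (rss_full / df_resid)
    p_time = stats.f.sf(F_time, 1, df_resid)
    p_trt = stats.f.sf(F_trt, 1, df_resid)
    # flat genes: no effect, not an error
    degenerate = rss_full <= tiny
    p_time = np.where(degenerate & (ss_time <= tiny), 1.0, p_time)
    p_trt = np.where(degenerate & (ss_trt <= tiny), 1.0, p_trt)
    F_time = np.where(degenerate & (ss_time <= tiny), 0.0, F_time)
    F_trt = np.where(degenerate & (ss_trt <= tiny), 0.0, F_trt)

    mean_oe = Y[:, x_trt == 1].mean(axis=1)
    mean_null = Y[:, x_trt == 0].mean(axis=1)
    # peak side judged in the untreated arm so the treatment cannot flip it
    null_mask = x_trt == 0
    mean_ct10 = Y[:, null_mask & (x_time == 1)].mean(axis=1)
    mean_ct22 = Y[:, null_mask & (x_time == 0)].mean(axis=1)

    trt_dir = np.where(mean_oe < mean_null, "under", "over")
    trt_dir = np.where(mean_oe == mean_null, "", trt_dir)
    time_dir = np.where(mean_ct10 > mean_ct22, "CT10>CT22", "CT10<CT22")
    time_dir = np.where(mean_ct10 == mean_ct22, "", time_dir)

    out = pd.DataFrame(
        {
            "p_treatment": p_trt,
            "p_time": p_time,
            "F_treatment": F_trt,
            "F_time": F_time,
            "treatment_direction": np.where(p_trt < alpha, trt_dir, ""),
            "time_direction": np.where(p_time < alpha, time_dir, ""),
        },
        index=de.genes,
    )
    out["group"] = classify_groups(out, alpha=alpha)
    return out


def classify_groups(anova: pd.DataFrame, alpha: float = 0.05) -> pd.Series:
    """Group I-IV labels from per-gene ANOVA results.

    Requires both factor p-values below ``alpha``; genes failing either
    cutoff (or with an undefined direction) are labelled ``"none"``.
    The four groups partition the double-significant genes.
    """
    p_t = anova["p_treatment"].to_numpy()
    p_time = anova["p_time"].to_numpy()
    # recompute directions undiluted by the alpha gating of two_way_anova
    trt = anova["treatment_direction"].to_numpy().astype(object)
    tim = anova["time_direction"].to_numpy().astype(object)
    sig = (p_t < alpha) & (p_time < alpha)
    labels = np.full(len(anova), "none", dtype=object)
    labels[sig & (tim == "CT10>CT22") & (trt == "under")] = "I"
    labels[sig & (tim == "CT10>CT22") & (trt == "over")] = "II"
    labels[sig & (tim == "CT10<CT22") & (trt == "under")] = "III"
    labels[sig & (tim == "CT10<CT22") & (trt == "over")] = "IV"
    return pd.Series(labels, index=anova.index, name="group")


def circadian_targets(anova: pd.DataFrame) -> pd.Index:
    """Genes in Groups I or III: repressed, circadian-time-dependent."""
    return anova.index[anova["group"].isin(["I", "III"])]


def fisher_enrichment(
    hits_in_set: int, set_size: int, hits_in_rest: int, rest_size: int
) -> EnrichmentResult:
    """Two-sided Fisher exact test of a 2x2 membership table.

    The table is ``[[hits_in_set, set_size - hits_in_set],
    [hits_in_rest, rest_size - hits_in_rest]]``.  The reported odds
    ratio is the sample (cross-product) OR; when any cell is zero a 0.5
    Haldane-Anscombe correction is applied to the OR only (flagged), the
    exact p-value is untouched.
    """
    a, b = hits_in_set, set_size - hits_in_set
    c, d = hits_in_rest, rest_size - hits_in_rest
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be nonnegative and hits <= size")
    if set_size + rest_size == 0:
        raise ValueError("empty universe")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    haldane = min(a, b, c, d) == 0
    if haldane:
        orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orr = (a * d) / (b * c)
    return EnrichmentResult(
        table=((a, b), (c, d)),
        odds_ratio=float(orr),
        p_value=float(p),
        test="fisher_exact_two_sided",
        haldane=haldane,
    )


def proportion_enrichment(k1: int, n1: int, k2: int, n2: int) -> EnrichmentResult:
    """Two-sided two-sample proportion z-test (pooled, no continuity).

    Tests ``k1/n1`` against ``k2/n2`` with the pooled-variance z
    statistic.  This is the "proportion test" used for binding-site and
    circadian-gene enrichments.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("need 0 <= k <= n in both groups")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    var = pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2)
    if var == 0:
        z = 0.0
    else:
        z = (p1 - p2) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    a, b = k1, n1 - k1
    c, d = k2, n2 - k2
    haldane = min(a, b, c, d) == 0
    if haldane:
        orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orr = (a * d) / (b * c)
    return EnrichmentResult(
        table=((a, b), (c, d)),
        odds_ratio=float(orr),
        p_value=float(min(p, 1.0)),
        test="two_proportion_z_pooled",
        haldane=haldane,
    )


def peak_time_profile(
    gene_sets: dict[str, list],
    peak_times: pd.Series,
    period: float = 24.0,
    n_bins: int = 24,
) -> dict[str, dict]:
    """Circular peak-time histograms for gene sets.

    ``peak_times`` maps gene -> circadian peak hour in [0, period).
    Each set yields bin counts, the circular mean (hours) and the mean
    resultant length (1 = fully concentrated, 0 = uniform).  Genes
    absent from ``peak_times`` are skipped; an empty set gives an empty
    profile with NaN mean.
    """
    pt = peak_times.dropna()
    if ((pt < 0) | (pt >= period)).any():
        raise ValueError(f"peak times must lie in [0, {period})")
    edges = np.linspace(0.0, period, n_bins + 1)
    profiles: dict[str, dict] = {}
    for name, genes in gene_sets.items():
        hours = pt.reindex(pd.Index(genes)).dropna().to_numpy(dtype=float)
        counts, _ = np.histogram(hours, bins=edges)
        if hours.size == 0:
            mean, r = float("nan"), float("nan")
        else:
            ang = 2.0 * np.pi * hours / period
            z = np.exp(1j * ang).mean()
            mean = float(np.mod(np.angle(z) * period / (2.0 * np.pi), period))
            r = float(np.abs(z))
        profiles[name] = {
            "counts": counts.tolist(),
            "bin_edges": edges.tolist(),
            "circular_mean": mean,
            "resultant_length": r,
            "n": int(hours.size),
        }
    return profiles
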