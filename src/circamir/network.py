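"""Promoter windows, TSS correction, ChIP-peak regulator assignment and
miRNA/TF regulatory-motif construction.

Coordinates are 0-based half-open (BED convention) throughout; GTF-style
1-based inputs must be converted at the reader.  A transcript's promoter
is the window from 5 kb upstream of its 5' end to its 3' end, so a
regulator "binds" a transcript when one of its ChIP peaks overlaps that
window by at least one base.  Binding calls carry a dataset-support
count; BMAL1 requires support from >= 2 of its 6 ChIP-seq datasets
while every other regulator needs just one.

De-novo assembled transcript models may miss the true start site, so 5'
ends without promoter marks are corrected to the center of the nearest
H3K4me3 (fallback Pol II) peak.

Finally, TF binding edges, functional-regulation flags and miRNA target
edges are joined into the two feed-forward regulatory motifs: BMAL1/CLOCK
with the miRNA on CT10-peaking repressed targets (Group I), and
REV-ERBa/b with the miRNA on CT22-peaking repressed targets (Group III).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .overexpression import EnrichmentResult, proportion_enrichment

DEFAULT_UPSTREAM = 5000
DEFAULT_MAX_TSS_DISTANCE = 10_000

#: minimum number of supporting ChIP-seq datasets per regulator
DEFAULT_SUPPORT_RULE = {"BMAL1": 2}
DEFAULT_SUPPORT = 1

MOTIF1_TFS = frozenset({"BMAL1", "CLOCK"})
MOTIF2_TFS = frozenset({"REV-ERBA", "REV-ERBB", "NR1D1", "NR1D2"})
MOTIF1_LABEL = "BMAL1/CLOCK"
MOTIF2_LABEL = "REV-ERBa/b"


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"need 0 <= start < end, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    def overlaps(self, other: "GenomicInterval") -> bool:
        """>= 1 shared base under half-open semantics; strand-blind."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TranscriptModel:
    id: str
    interval: GenomicInterval
    tss_status: str | None = None  # h3k4me3_and_polii | h3k4me3_only | corrected | uncorrectable

    @property
    def five_prime(self) -> int:
        iv = self.interval
        return iv.start if iv.strand == "+" else iv.end - 1

    @property
    def three_prime(self) -> int:
        iv = self.interval
        return iv.end - 1 if iv.strand == "+" else iv.start


@dataclass(frozen=True)
class BindingCall:
    regulator: str
    interval: GenomicInterval
    n_supporting_datasets: int = 1

    def __post_init__(self):
        if self.n_supporting_datasets < 1:
            raise ValueError("a binding call needs >= 1 supporting dataset")


@dataclass(frozen=True)
class RegulatoryMotif:
    """One TF-set/miRNA/target triple; type 1 = activator arm (CT10),
    type 2 = repressor arm (CT22)."""

    tf_set: str
    mirna: str
    target: str
    group: str
    motif_type: int


def promoter_window(
    t: TranscriptModel, upstream: int = DEFAULT_UPSTREAM
) -> GenomicInterval:
    """Window from ``upstream`` bp before the 5' end to the 3' end.

    Strand-aware and clipped at coordinate 0.
    """
    iv = t.interval
    if iv.strand == "+":
        return GenomicInterval(iv.chrom, max(0, iv.start - upstream), iv.end, "+")
    return GenomicInterval(iv.chrom, iv.start, iv.end + upstream, "-")


def _peak_center(iv: GenomicInterval) -> int:
    return (iv.start + iv.end) // 2


def correct_tss(
    t: TranscriptModel,
    h3k4me3: list[GenomicInterval],
    polii: list[GenomicInterval],
    tss_window: int = 1000,
    max_distance: int = DEFAULT_MAX_TSS_DISTANCE,
    anchor: str = "h3k4me3_first",
) -> TranscriptModel:
    """Validate or correct a transcript's 5' end against promoter marks.

    A mark "supports" the transcript when it overlaps the window of
    ``tss_window`` bp either side of the current 5' end.  Outcomes:

    - both H3K4me3 and Pol II support -> status ``h3k4me3_and_polii``,
      coordinates unchanged;
    - H3K4me3 only -> ``h3k4me3_only``, unchanged;
    - neither -> the 5' end moves to ``floor((start+end)/2)`` of the
      nearest anchor peak (H3K4me3, falling back to Pol II when
      ``anchor="h3k4me3_first"``; both pooled when
      ``anchor="h3k4me3_or_polii"``) measured peak-center to 5' end,
      ties broken toward upstream; status ``corrected``.  Anchors may
      lie downstream (a de-novo model over-extended at its 5' end) but
      never past the 3' end;
    - no usable anchor within ``max_distance`` -> ``uncorrectable``,
      unchanged.

    The operation is idempotent on coordinates: a corrected 5' end sits
    inside its anchor peak, which then overlaps the new 5'-end window,
    so a second pass leaves the model alone.
    """
    if anchor not in ("h3k4me3_first", "h3k4me3_or_polii"):
        raise ValueError(f"unknown anchor policy {anchor!r}")
    five0 = t.five_prime
    win = GenomicInterval(
        t.interval.chrom, max(0, five0 - tss_window), five0 + tss_window
    )
    has_h3 = any(win.overlaps(p) for p in h3k4me3)
    has_pol = any(win.overlaps(p) for p in polii)
    if has_h3 and has_pol:
        return replace(t, tss_status="h3k4me3_and_polii")
    if has_h3:
        return replace(t, tss_status="h3k4me3_only")

    iv = t.interval
    five = t.five_prime
    upstream_sign = -1 if iv.strand == "+" else 1  # direction of upstream moves

    def _usable(center: int) -> bool:
        # moving the 5' end must keep start < end
        if iv.strand == "+":
            return center < iv.end
        return center >= iv.start

    def _nearest(peaks: list[GenomicInterval]) -> tuple[int, int] | None:
        best: tuple[int, int] | None = None  # (distance, center)
        for p in peaks:
            if p.chrom != iv.chrom:
                continue
            center = _peak_center(p)
            d = abs(center - five)
            if d > max_distance or not _usable(center):
                continue
            if best is None or d < best[0]:
                best = (d, center)
            elif d == best[0]:
                # tie: prefer the upstream candidate
                if (center - five) * upstream_sign > (best[1] - five) * upstream_sign:
                    best = (d, center)
        return best

    if anchor == "h3k4me3_first":
        best = _nearest(h3k4me3) or _nearest(polii)
    else:
        best = _nearest(list(h3k4me3) + list(polii))
    if best is None:
        return replace(t, tss_status="uncorrectable")
    center = best[1]
    if iv.strand == "+":
        new_iv = GenomicInterval(iv.chrom, center, iv.end, "+")
    else:
        new_iv = GenomicInterval(iv.chrom, iv.start, center + 1, "-")
    return TranscriptModel(id=t.id, interval=new_iv, tss_status="corrected")


def assign_regulators(
    transcripts: list[TranscriptModel],
    calls: list[BindingCall],
    support_rule: dict[str, int] | None = None,
    default_support: int | None = DEFAULT_SUPPORT,
    upstream: int = DEFAULT_UPSTREAM,
) -> pd.DataFrame:
    """Regulator -> transcript binding edges from ChIP peak calls.

    An edge exists when a peak of the regulator overlaps the
    transcript's promoter window (>= 1 bp) and the call's dataset
    support meets the regulator's rule (default: BMAL1 >= 2, others
    >= 1).  With ``default_support=None`` a regulator absent from
    ``support_rule`` is an error.

    Returns a deduplicated DataFrame with columns ``regulator``,
    ``transcript``, sorted for deterministic output.
    """
    if support_rule is None:
        support_rule = dict(DEFAULT_SUPPORT_RULE)
    trees: dict[str, IntervalTree] = {}
    for t in transcripts:
        win = promoter_window(t, upstream)
        trees.setdefault(win.chrom, IntervalTree()).addi(win.start, win.end, t.id)
    edges: set[tuple[str, str]] = set()
    for call in calls:
        if call.regulator in support_rule:
            need = support_rule[call.regulator]
        elif default_support is not None:
            need = default_support
        else:
            raise KeyError(
                f"regulator {call.regulator!r} missing from support rule table"
            )
        if call.n_supporting_datasets < need:
            continue
        tree = trees.get(call.interval.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(call.interval.start, call.interval.end):
            edges.add((call.regulator, hit.data))
    return pd.DataFrame(
        sorted(edges), columns=["regulator", "transcript"]
    )


def binding_enrichment(
    circadian_transcripts,
    all_transcripts,
    edges: pd.DataFrame,
    regulator: str,
) -> EnrichmentResult:
    """Is the regulator's bound fraction elevated among circadian
    transcripts relative to all transcripts?  Two-proportion z-test;
    note the circadian set is a subset of the background, mirroring the
    published comparison, so the test is conservative.
    """
    circ = set(circadian_transcripts)
    universe = set(all_transcripts)
    if not circ or not universe:
        raise ValueError("transcript sets must be nonempty")
    if not circ <= universe:
        raise ValueError("circadian transcripts must be a subset of all transcripts")
    bound = set(edges.loc[edges["regulator"] == regulator, "transcript"])
    return proportion_enrichment(
        len(circ & bound), len(circ), len(universe & bound), len(universe)
    )


def build_motifs(
    tf_edges: pd.DataFrame,
    mirna_target_edges: pd.DataFrame,
    groups: pd.Series,
) -> list[RegulatoryMotif]:
    """Assemble the two feed-forward regulatory motifs.

    Parameters
    ----------
    tf_edges
        Columns ``tf``, ``target`` and optionally ``functional`` (bool;
        knockout-based functional evidence — rows without it are treated
        as functional).  TF regulation requires both the binding edge
        and a true functional flag.
    mirna_target_edges
        Columns ``mirna``, ``target``.
    groups
        Per-gene Group I-IV labels (``"none"`` allowed) from the
        over-expression classification.

    Returns a deterministically sorted motif list: type 1 joins Group I
    targets bound by BMAL1/CLOCK, type 2 joins Group III targets bound
    by REV-ERBa/b; both require a miRNA edge on the target.
    """
    if tf_edges.empty or mirna_target_edges.empty:
        return []
    tf = tf_edges.copy()
    if "functional" not in tf.columns:
        tf["functional"] = True
    tf = tf[tf["functional"].astype(bool)]
    tf_names = tf["tf"].astype(str).str.upper()
    motifs: list[RegulatoryMotif] = []
    for tfs, label, group, mtype in (
        (MOTIF1_TFS, MOTIF1_LABEL, "I", 1),
        (MOTIF2_TFS, MOTIF2_LABEL, "III", 2),
    ):
        bound = set(tf.loc[tf_names.isin(tfs), "target"])
        in_group = set(groups.index[groups == group])
        for _, row in mirna_target_edges.iterrows():
            target = row["target"]
            if target in bound and target in in_group:
                motifs.append(
                    RegulatoryMotif(
                        tf_set=label,
                        mirna=str(row["mirna"]),
                        target=str(target),
                        group=group,
                        motif_type=mtype,
                    )
                )
    return sorted(motifs, key=lambda m: (m.motif_type, m.mirna, m.target))


# ---------------------------------------------------------------------------
# BED I/O

def read_peaks_bed(path: str | Path, regulator: str | None = None) -> list[BindingCall]:
    """Read BED6 peaks into binding calls.

    Column 4 (name) is the regulator unless overridden; column 5 (score)
    is the dataset-support count (missing/0 -> 1).
    """
    calls = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name = f[3] if len(f) > 3 and regulator is None else (regulator or ".")
            support = int(float(f[4])) if len(f) > 4 and f[4] not in (".", "") else 1
            strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else "+"
            calls.append(
                BindingCall(
                    regulator=name,
                    interval=GenomicInterval(chrom, start, end, strand),
                    n_supporting_datasets=max(support, 1),
                )
            )
    return calls


def write_peaks_bed(calls: list[BindingCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in calls:
            iv = c.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{c.regulator}"
                f"\t{c.n_supporting_datasets}\t{iv.strand}\n"
            )


def read_transcripts_bed12(path: str | Path) -> list[TranscriptModel]:
    """Read transcript models from BED12 (only cols 1-6 are used)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append(
                TranscriptModel(
                    id=f[3],
                    interval=GenomicInterval(f[0], int(f[1]), int(f[2]), f[5]),
                )
            )
    return out


def write_transcripts_bed12(transcripts: list[TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            iv = t.interval
            length = len(iv)
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        str(iv.start),
                        str(iv.end),
                        t.id,
                        "0",
                        iv.strand,
                        str(iv.start),
                        str(iv.end),
                        "0",
                        "1",
                        f"{length},",
                        "0,",
                    ]
                )
                + "\n"
            )
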