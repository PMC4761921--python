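# Methods

This note documents the statistical models implemented in `circamir`, the
choices made where the design was genuinely open, and what the synthetic-data
validation does and does not establish.

## Rhythm detection

**Model.** Each transcript's time course is fit by single-harmonic ordinary
least squares with fixed period T (default 24 h):

    x(t) = m + a·cos(ωt) + b·sin(ωt),   ω = 2π/T.

This is the linear re-parameterisation of a shifted cosine
`m + A·cos(ω(t − φ))`; amplitude and peak phase are recovered as
`A = √(a² + b²)`, `φ = atan2(b, a)/ω ∈ [0, T)`. Rhythmicity is tested by the
F-test of the two harmonic terms against the intercept-only model, df (2,
n − 3), where n counts samples (replicates and multi-day points enter through
the periodic regressors; no explicit reduction modulo T is needed). The
equivalence of this linear fit with an explicit shifted-cosine grid search is
property-tested: on a balanced grid the two agree in phase to the grid step
and in amplitude to second order in the step. A joint fit sharing one phase
across two datasets is exposed (`fit_cosine_shared_phase`, profile over a
phase grid) but the default screen fits datasets separately and compares.

**Degenerate inputs.** A constant series is not an error: it gets A = 0,
p = 1. Essentially perfect fits are floored at p = 1e−300 so that log-scores
stay finite. Fewer than four distinct times modulo the period is an error
(the three-parameter model would be saturated or under-determined).

**Consistency score.** Two independent datasets are combined as
`S = −log₂p₁ − log₂p₂` (bits) with circular phase difference
`Δφ = min(|φ₁−φ₂|, T−|φ₁−φ₂|)`. The call is strict: `S > 9` **and**
`Δφ < 4 h`. The single reported phase is the circular mean of the two peak
phases weighted by each dataset's `−log₂p`; the weighting is this package's
choice — any reasonable combination rule gives near-identical results when
the phases already agree within 4 h, which the pass rule guarantees.

**Mature-level test.** Mature series oscillate at strongly attenuated
amplitude, so they are tested with relaxed criteria: one-way ANOVA across
time groups *and* the cosine fit, both at p < 0.05.

## Permutation FDR

"Shuffle" is ambiguous for a two-matrix screen. The default permutation
shuffles each transcript's values across samples independently within each
dataset: this destroys the rhythm and the cross-dataset phase agreement while
preserving every transcript's marginal value distribution, which is exactly
the null the score is meant to reject. A whole-row alternative (permute
transcript identities within each dataset, preserving single-dataset rhythms
but breaking the pairing) is available behind `mode="row_swap"`; it yields a
more conservative (larger) null pass rate because genuinely rhythmic rows can
still score on one dataset. The estimate is
`FDR = mean(permuted passes)/real passes`, reported capped at 1 with the raw
ratio retained, and undefined (reported, not raised) when nothing passes.
Per-permutation RNG streams are spawned from one seed via
`SeedSequence.spawn`, so results are independent of loop chunking.

## Over-expression analysis

The 2×2 design (CT10/CT22 × oe/null, ≥ 2 replicates in at least one cell) is
analysed per gene with a **main-effects** two-way ANOVA on `log2(x + 1)`:
with two replicates per cell this leaves 5 residual df, and only the two
main factors are part of the screening question. An interaction model is
available behind a flag (type-II drop tests; identical to type III in the
balanced case). No multiple-testing correction is applied to the per-gene
p-values — the screen deliberately uses raw 0.05 cutoffs and relies on
downstream validation; this is documented behaviour, not an oversight.

"Peaked around CT10/CT22" is operationalised as the sign of the CT10−CT22
difference of marginal means **in the control arm**, so the treatment cannot
flip a gene's apparent peak side. Groups: I = CT10-peaking & under-expressed,
II = CT10 & over, III = CT22 & under, IV = CT22 & over; the four groups
partition the genes significant for both factors, and I ∪ III is the
"circadian targets" set.

Enrichments use Fisher's exact test (two-sided, hypergeometric; odds ratio is
the sample cross-product ratio, with a flagged 0.5 Haldane–Anscombe
correction applied to the OR only when a cell is zero) or the pooled
two-proportion z-test without continuity correction. The binding enrichment
deliberately compares the circadian *subset* against the *full* transcript
universe (not the complement), mirroring the comparison it models; this makes
the test conservative.

## Relative amplitude and kinetics

With only two sampled times, the oscillation of a gene is proxied by
`RA = log₂(mean CT10 / mean CT22)`. When comparing two conditions, the
difference is oriented by the gene's peak side (inferred from the sign of the
reference-condition RA unless given) so that positive Δ always means a larger
oscillation magnitude; the class boundary is inclusive: |Δ| ≤ 0.5 is
"unchanged", change requires strictly |Δ| > 0.5. Both the raw and oriented
deltas are emitted. For matrices on arbitrary grids, CT10/CT22 values are
taken from the samples circularly nearest those clock times, averaging ties.

The attenuation model is the steady-state response of `dP/dt = s(t) − kP` to
sinusoidal synthesis: relative amplitude shrinks by `k/√(k² + ω²)` and the
peak lags by `arctan(ω/k)/ω` hours (`k = ln2/t½`). At t½ = 119 h and T = 24 h
the attenuation is 0.0222 with a 5.92-h lag — a ~45-fold dampening. This is
considerably stronger than the ~2–3-fold dampening observed for the few
miRNAs that remain detectably rhythmic at mature level; the module asserts
only its own mathematics (validated against numerical ODE integration to
relative error < 1e−3), and the tension is expected — miRNAs that remain
rhythmic at mature level presumably turn over much faster than the average.

## Regulatory network

Coordinates are 0-based half-open throughout; overlap means ≥ 1 shared base
(no minimum-overlap fraction is imposed). The promoter window runs from 5 kb
upstream of the 5′ end to the 3′ end, clipped at zero, so "binding" includes
gene-body peaks. BMAL1 edges require a peak supported by ≥ 2 of its 6
datasets; all other regulators need 1. Regulator assignment uses an interval
tree and is property-tested against a quadratic brute-force scan.

TSS validation checks marks within ±1 kb of the current 5′ end: both
H3K4me3 and Pol II present → confirmed; H3K4me3 only → accepted; neither →
the 5′ end is moved to `floor((start+end)/2)` of the nearest anchor peak
(H3K4me3 first, Pol II as fallback by default; a pooled policy is available),
ties broken toward upstream, with a 10-kb default search radius (no value is
prescribed by the biology; 10 kb spans typical promoter-assignment
distances). Corrections may move the 5′ end downstream (an over-extended
de-novo model) but never past the 3′ end, and the operation is a fixed point
on coordinates: a corrected 5′ end lies inside its anchor peak and is left
alone on a second pass.

Motif construction joins three inputs: TF binding edges, a per-edge
functional flag standing in for knockout under-expression evidence (the AND
rule is implemented; the evidence itself is an input, since it derives from
accession-bound knockout data), and miRNA→target edges. Type 1 pairs
BMAL1/CLOCK with Group I (CT10-peaking, repressed) targets; type 2 pairs
REV-ERBα/β with Group III targets. Output is deterministically sorted.

## Synthetic data

The generators define the study conditions for all validation:

- **Nascent pair** — default 1000 transcripts, 20% rhythmic; dataset A
  samples 12 points at 4-h steps over 48 h, dataset B 8 points at 3-h steps
  over 24 h (deliberately unequal designs). Rhythmic transcripts follow
  `exp(b)·(1 + a·cos(ω(t−φ)))·exp(ε)` with φ uniform on [0, 24), planted
  log₂ peak/trough folds uniform on [1, 3] (2- to 8-fold, i.e.
  a = (F−1)/(F+1) ∈ [1/3, 7/9]), and lognormal noise ε ~ N(0, 0.2). Noise is
  multiplicative lognormal because nascent RPKM is positive and right-skewed;
  the real noise law is unknown, and this choice is flagged for sensitivity
  analysis. Phases are shared exactly between datasets (truth for the
  consistency target); inter-dataset phase jitter is available, default 0.
- **Mature series** — derived from the primary truth through the kinetic
  model above; default grid 6 points × 3 replicates over 24 h, matching a
  qPCR-style validation design.
- **Over-expression** — log₂ expression is generated directly as
  `μ + time·1[CT10] + treatment·1[oe] (+ oriented interaction) + N(0, σ)`
  with baseline μ ~ N(7, 1) (≈ 128 on the linear scale, comfortably clear of
  the +1 pseudocount), default effects of 1 log₂ unit, σ = 0.25, two
  replicates per cell, 80% of planted treatment effects repressive, and
  target annotations at 2-fold odds among planted under-expressed genes.
  Generating on the log scale avoids committing to a count model the
  analysis never uses. Planted amplitude shifts (an interaction on the
  CT10×oe cell, oriented by peak side) are off by default.
- **Binding** — transcripts spaced on one synthetic chromosome so promoter
  windows never overlap; per-regulator binding probability 0.3, raised by an
  odds multiplier on circadian transcripts; BMAL1 support drawn uniformly
  from 1–6.

**What passing tests show — and don't.** The generators realise planted
cosine rhythms with lognormal noise, exact 2×2 factorial structure and
independent per-sample errors. Real nascent-seq data additionally carry
library-size and batch effects, autocorrelated noise, non-sinusoidal wave
shapes and transcript-length biases, none of which are emulated. Recovery
rates measured here (e.g. ≈ 97% sensitivity at 2-fold planted amplitudes,
FDR calibration within 0.01) are therefore statements about the correctness
of the implementation under its stated model, not about performance on any
particular real dataset.

## Numerical choices

- p-values floored at 1e−300 before any log₂; scores stay finite.
- Constant/flat series detected by comparing residual sums of squares to
  `n·1e−24·max(|x|)²`, i.e. machine-precision-scaled, not an absolute cutoff.
- Threshold comparisons are strict where the criterion is stated strictly
  (`S > 9`, `Δφ < 4`, p < 0.05); the RA boundary |Δ| = 0.5 is "unchanged".
- Circular means computed on the unit circle; resultant length reported as
  concentration. Equidistant TSS anchors resolve toward upstream.
- All RNG flows through `numpy.random.default_rng`; multi-draw procedures
  spawn child streams via `SeedSequence` so they are reproducible and
  order-independent.

## Problem sizes used in validation

The shipped validation uses 1000-transcript screens with 500 permutations,
5000-gene null calibrations, 2000-gene recovery designs, and 100-replicate
Monte-Carlo checks for the enrichment operations; these sizes give
Monte-Carlo error comfortably below every asserted margin while keeping the
whole suite fast on a single CPU.

## Known limitations

- The package detects 24-h rhythms only; no period scanning, multi-harmonic
  fits, or nonparametric tests (JTK/ARSER-style) are provided.
- The mature-level kinetic model assumes constant degradation; rhythmic
  decay (e.g. rhythmic exonuclease activity) would break the attenuation
  formula.
- Two-point relative amplitude confounds phase with amplitude for genes
  peaking far from CT10/CT22.
- Enrichment tests treat genes as exchangeable; no covariates (expression
  level, transcript length) are adjusted for.
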