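# circamir

Detection of circadian miRNA **primary transcripts** from nascent-transcription
time series, and downstream analysis of what the miRNAs they encode do to the
circadian transcriptome.

## The problem

Screens for circadian miRNAs at the *mature* level disagree with each other,
because mature miRNAs are extremely stable (average half-life ≈ 119 h in
mammals): even a strongly rhythmic synthesis rate leaves almost no oscillation
in the mature pool. Transcription of the miRNA *primary transcript*
(pri-miRNA), measured by nascent assays such as GRO-seq and Nascent-seq, is a
far more sensitive readout of circadian control. `circamir` implements that
detection strategy and the analyses that follow from it:

1. **Rhythm detection** — per-transcript harmonic regression with fixed 24-h
   period, `x(t) = m + a·cos(ωt) + b·sin(ωt)`, amplitude `A = √(a²+b²)`, peak
   phase `φ = atan2(b,a)/ω`, and an F-test (df 2, n−3) against the flat model.
   Two independent datasets are combined into a significance score
   `S = −log₂p₁ − log₂p₂` (bits); a transcript is called circadian when
   `S > 9` and the circular phase difference is `< 4 h`.
2. **Permutation FDR** — sample labels are shuffled per transcript and the full
   screen re-run; `FDR = mean permuted passes / real passes`.
3. **Over-expression analysis** — per-gene two-way ANOVA (factors: circadian
   time CT10/CT22 and treatment oe/null) on `log2(x+1)`, Group I–IV
   classification by peak side × direction, Fisher-exact and two-proportion
   enrichment tests, circular peak-time profiles.
4. **Relative amplitude** — `RA = log₂(CT10/CT22)` per condition; changes with
   |ΔRA| > 0.5 (oriented by peak side) count as amplitude modulation. The
   first-order kinetic model `dP/dt = s(t) − kP` explains mature-level
   dampening: attenuation `k/√(k²+ω²)`, phase lag `arctan(ω/k)/ω`.
5. **Regulatory network** — promoter windows (5 kb upstream of the 5′ end to
   the 3′ end), TSS correction to H3K4me3/Pol II peak centers, regulator
   assignment from ChIP peaks (BMAL1 needs ≥ 2 of 6 supporting datasets),
   binding enrichment, and the two feed-forward motifs joining BMAL1/CLOCK or
   REV-ERBα/β with a miRNA on its repressed circadian targets.
6. **Synthetic data** — generators that plant known rhythms, effects and
   binding enrichments so every stage can be validated against ground truth.

## Worked example

```python
import circamir as cm

params = cm.RhythmSimParams(n_transcripts=1000, frac_rhythmic=0.2, seed=42)
dataset_a, dataset_b, truth = cm.simulate_nascent_pair(params)
table = cm.consistency_table(dataset_a, dataset_b)
print(int(table["pass"].sum()))          # 199 transcripts called circadian

counts = cm.permute_and_score(dataset_a, dataset_b, n_perm=500, seed=43)
est = cm.estimate_fdr(int(table["pass"].sum()), counts)
print(round(est.fdr, 4))                 # 0.0258
```

Running `python examples/detect_circadian_primaries.py` prints, among other
things:

```
transcripts screened : 1000
called circadian     : 199
planted rhythmic     : 200
sensitivity          : 0.970
false positives      : 5
```

199 of the 1000 simulated transcripts clear the `S > 9 & Δφ < 4 h` bar; 194 of
them are genuinely rhythmic (97% of the 200 planted rhythms) and 5 are false
calls, consistent with the permutation FDR estimate of ≈ 2.6%. The other
scripts in `examples/` walk through the permutation FDR, the over-expression
group classification, amplitude modulation plus kinetics, and the
promoter/motif analysis, each printing the numbers it computes and what they
mean.

A thin CLI wraps the same functions for shell pipelines
(`circamir simulate|rhythm|oe|amplitude|network ...`); every stage is
deterministic given its config and seed.

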