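"""Detect circadian primary transcripts from two nascent time courses.

Simulates a pair of nascent-transcription datasets (a GRO-seq-like
12-point/48-h series and a Nascent-seq-like 8-point/24-h series) sharing
planted cosine rhythms, fits a 24-h cosine to every transcript in each
dataset, and calls a transcript circadian when the summed evidence
S = -log2(p1) - log2(p2) exceeds 9 bits and the two peak phases agree
within 4 h.
"""

import circamir as cm

params = cm.RhythmSimParams(n_transcripts=1000, frac_rhythmic=0.2, seed=42)
dataset_a, dataset_b, truth = cm.simulate_nascent_pair(params)

table = cm.consistency_table(dataset_a, dataset_b)
rhythmic = truth.transcripts["rhythmic"]

n_pass = int(table["pass"].sum())
sensitivity = (table["pass"] & rhythmic).sum() / rhythmic.sum()
false_pos = int((table["pass"] & ~rhythmic).sum())

print(f"transcripts screened : {len(table)}")
print(f"called circadian     : {n_pass}")
print(f"planted rhythmic     : {int(rhythmic.sum())}")
print(f"sensitivity          : {sensitivity:.3f}")
print(f"false positives      : {false_pos}")
print()
print("top five by significance score (S in bits, phases in CT hours):")
top = table.sort_values("score", ascending=False).head(5)
print(top[["score", "phase1", "phase2", "phase_diff", "combined_phase"]].round(2))
# A high S means both datasets independently reject the flat model; a small
# phase_diff means they agree on *when* the transcript peaks.
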