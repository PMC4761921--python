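"""From ChIP peaks to circadian-TF/miRNA feed-forward motifs.

Simulates binding peaks enriched on the promoters of circadian
transcripts, assigns regulators (a peak must overlap the window from
5 kb upstream of the 5' end to the 3' end; BMAL1 additionally needs
support from >= 2 of its 6 datasets), tests binding enrichment with the
two-proportion z-test, and assembles the two regulatory motifs:
BMAL1/CLOCK + miRNA on CT10-peaking repressed targets (Group I) and
REV-ERBa/b + miRNA on CT22-peaking repressed targets (Group III).
"""

import numpy as np
import pandas as pd

import circamir as cm

n = 400
rng = np.random.default_rng(9)
circadian = np.zeros(n, dtype=bool)
circadian[rng.choice(n, 120, replace=False)] = True

calls, transcripts = cm.simulate_binding(
    n, circadian, enrichment_odds=4.0, seed=10
)
edges = cm.assign_regulators(transcripts, calls)
circ_ids = [t.id for t, f in zip(transcripts, circadian) if f]
all_ids = [t.id for t in transcripts]

print("binding enrichment on circadian promoters (proportion test):")
for reg in ("BMAL1", "CLOCK", "REV-ERBA", "PER1"):
    enr = cm.binding_enrichment(circ_ids, all_ids, edges, reg)
    k_c = enr.table[0][0]
    print(f"  {reg:<9}: {k_c}/{len(circ_ids)} circadian bound, p={enr.p_value:.2e}")

# join TF binding with miRNA targeting and over-expression groups
groups = pd.Series("none", index=all_ids)
groups.iloc[:6] = ["I", "I", "III", "III", "I", "III"]
tf_edges = edges.rename(columns={"transcript": "target", "regulator": "tf"})
tf_edges["functional"] = True
mirna_edges = pd.DataFrame({"mirna": "miR-378", "target": all_ids[:6]})
motifs = cm.build_motifs(tf_edges, mirna_edges, groups)
print(f"\nfeed-forward motifs found: {len(motifs)}")
for m in motifs:
    print(f"  type {m.motif_type}: {m.tf_set} + {m.mirna} -> {m.target} (Group {m.group})")
# Type-1 motifs pair the morning activators with morning-peaking repressed
# targets; type-2 pairs the evening repressors with evening-peaking targets.
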