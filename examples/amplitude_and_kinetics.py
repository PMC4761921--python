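"""Relative-amplitude modulation and why mature miRNAs barely oscillate.

Part 1 plants amplitude shifts (|delta RA| = 1) in the over-expression
design and recovers them with the two-point relative amplitude
RA = log2(CT10/CT22); |delta RA| <= 0.5 counts as unchanged.

Part 2 evaluates the first-order kinetic model: a product with half-life
t_1/2 driven by a sinusoidal 24-h synthesis oscillates with its relative
amplitude attenuated by k/sqrt(k^2 + w^2), k = ln2/t_1/2.
"""

import circamir as cm
from circamir.amplitude import design_relative_amplitudes

params = cm.OeSimParams(
    n_genes=2000, frac_time_affected=0.6, frac_amplitude_shift=0.5,
    amplitude_shift_log2=1.0, noise_sd=0.2, seed=53,
)
design, truth, _ = cm.simulate_overexpression(params)
ras = design_relative_amplitudes(design).dropna()
compared = cm.compare_ra(ras["ra_null"], ras["ra_oe"])
print("amplitude-change classes by peak side:")
print(cm.ra_class_counts(compared))
shifted = truth.genes["amp_class"] != "unchanged"
idx = shifted[shifted].index.intersection(compared.index)
agree = (compared.loc[idx, "ra_class"] == truth.genes.loc[idx, "amp_class"]).mean()
print(f"recovery of planted shifts: {agree:.3f}\n")

print("kinetic attenuation of a 24-h rhythm (t_1/2 -> amplitude ratio, lag):")
for half_life in (0.5, 2, 24, 119, 1000):
    m = cm.kinetic_attenuation(half_life, period=24.0)
    print(f"  t1/2 = {half_life:>6g} h : attenuation {m.attenuation:.4f}, "
          f"lag {m.phase_lag:.2f} h")
# At the ~119 h average miRNA half-life the attenuation is ~0.022: a
# strongly rhythmic primary transcript yields a mature pool whose
# oscillation is ~45-fold damped, usually below detection.
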