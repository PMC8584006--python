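"""Iterative phospho-motif discovery (motif-x style).

Foreground: the 13-mer windows of all serine phosphosites.  Background: all
serine-centred windows in the proteome.  The algorithm repeatedly fixes the
(offset, residue) pair with the smallest binomial-tail p-value (< 1e-6),
restricts both sets, and accepts motifs supported by more than 20 windows.
"""

import phosflow as pf
from phosflow import SimConfig, simulate_study

study = simulate_study(SimConfig(seed=1))
foreground = [s.window for s in study.sites if s.residue == "S"]
background = pf.proteome_windows(study.proteome, "S", max_windows=20000)

motifs = pf.motif_x(foreground, background, "S")
print(f"{len(motifs)} serine motifs from {len(foreground)} windows:")
for m in motifs:
    print(f"  {m.pattern:<10} fg={m.n_foreground_matches:<4} "
          f"score={m.score:.1f}")

heat = pf.position_residue_heatmap(foreground, background)
top = heat.stack().sort_values(ascending=False).head(3)
print("strongest position-residue enrichments (log2 fg/bg):")
for (residue, offset), value in top.items():
    print(f"  {residue} at {offset:+d}: {value:.2f}")

# The proline-directed [SP], basophilic [RxxS] and the two-position kinase
# consensi planted by the generator are returned with their foreground
# support; each motif's score sums -log10 of its accepted step p-values.
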