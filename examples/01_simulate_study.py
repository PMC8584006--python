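"""Generate a synthetic phosphoproteomics study and inspect its structure.

The generator produces a proteome, phosphosites with S/T/Y proportions near
83/12/5, kinase ground truth (substrate edges and five planted activity
shifts) and TMT-like intensities for three ripening conditions x three
replicates.  Everything is deterministic under the seed.
"""

from collections import Counter

from phosflow import SimConfig, simulate_study

study = simulate_study(SimConfig(seed=1))

print(f"proteins:        {len(study.proteome)}")
print(f"phosphosites:    {len(study.sites)}")
mix = Counter(s.residue for s in study.sites)
total = len(study.sites)
print("residue mix:     "
      + ", ".join(f"{r} {100 * mix[r] / total:.1f}%" for r in "STY"))
per_protein = Counter(s.protein_id for s in study.sites)
frac1 = sum(1 for c in per_protein.values() if c == 1) / len(per_protein)
print(f"1-site proteins: {100 * frac1:.1f}%")
print(f"substrate edges: {len(study.truth.edges)} over "
      f"{study.config.n_kinases} kinases")
planted = study.truth.planted_kinases(("AC-B4", "AC-MG"))
print(f"planted shifts:  {planted}")
print(f"samples:         {study.quant.samples}")

# The residue mix and sites-per-protein fraction emulate the reference
# study's 83/12/5 S/T/Y split and 56.1% single-site proteins; the planted
# kinases are what the downstream activity inference should recover.
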