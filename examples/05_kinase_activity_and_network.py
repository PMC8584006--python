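"""GSEA-based kinase-activity inference and the regulatory network.

Sites are ranked by log2 fold change; each kinase's substrate set is tested
with the weighted running-sum statistic, normalised against a gene-set
permutation null (NES), and classified activated (NES >= +1) or inhibited
(NES <= -1).  Significant kinases and differential sites form a bipartite
kinase -> site network exported as SIF/GraphML.
"""

import phosflow as pf
from phosflow import SimConfig, simulate_study

study = simulate_study(SimConfig(seed=1))
result = pf.compare(study.quant, ("AC-B4", "AC-MG"))
ranked = pf.rank_metric(result)
substrate_sets = {k: set(v) for k, v in study.truth.substrates.items()}

activities = pf.score_kinases(ranked, substrate_sets, "AC-B4/AC-MG",
                              n_permutations=1000, seed=1)
planted = study.truth.planted_kinases(("AC-B4", "AC-MG"))
print("kinase activities (planted kinases marked):")
for a in sorted(activities, key=lambda a: -abs(a.nes)):
    if a.state != "indeterminate":
        mark = f"  <- planted {planted[a.kinase_id]}" if a.kinase_id in planted else ""
        print(f"  {a.kinase_id}: NES={a.nes:+.2f} p={a.p_perm:.4f} "
              f"{a.state}{mark}")

relations = [pf.KSRelation(k, s, 1.0, True)
             for k, subs in substrate_sets.items() for s in subs]
network = pf.build_network(activities, result, relations)
print(f"network: {network.number_of_nodes()} nodes, "
      f"{network.number_of_edges()} edges")
print(pf.degree_summary(network, top_k=3))

# All five planted kinases should appear with the correct activity sign and
# permutation p below 0.05; the network links them to their significantly
# changed substrate sites.
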