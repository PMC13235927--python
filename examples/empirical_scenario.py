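"""Heterogeneous-trait scenario mirroring a three-host, two-plasmid lab
community, at reduced scale (K = 1e4).

Compares the community's modular infection network against a hypothetical
fully connected one and prints the mean final prevalence of each plasmid:
opening the network flips dominance from the costly broad-host plasmid P2
to the cheaper P1.
"""

import dataclasses

import numpy as np

import plasmidnet as pn
from plasmidnet.experiments import make_empirical_config, replicate_seeds

for structure in ("modular", "full"):
    cfg0 = make_empirical_config(structure, K=1e4, B0=330)
    system = pn.compile_system(cfg0.infection, cfg0.compatibility, cfg0.params)
    prevs, rels = [], []
    for seed in replicate_seeds(1, 10):
        rec = pn.run_simulation(dataclasses.replace(cfg0, seed=int(seed)), system)
        prevs.append(pn.plasmid_prevalence(rec.final_state))
        rels.append(pn.relative_host_abundance(rec.final_state))
    print(f"{structure:8s} I: prevalence P1, P2 = {np.round(np.mean(prevs, 0), 3)}; "
          f"relative abundance H1..H3 = {np.round(np.mean(rels, 0), 3)}")
print("Under the lab-like modular network P2 dominates (it rides the strong")
print("hosts H2 and H3); with a full network the cheaper P1 takes over even")
print("though all trait heterogeneity is unchanged.")
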