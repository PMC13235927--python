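"""The infection propensity tensor on the smallest interesting system.

One host, two mutually compatible plasmids: a donor carrying both can turn
a plasmid-free recipient into one of three transconjugants. Transferring nu
plasmids at once has raw propensity 1/2^(nu-1); each (donor, recipient)
column is then normalized to 1.
"""

import numpy as np

import plasmidnet as pn
from plasmidnet import model_core as mc

I = pn.InfectionNetwork(np.ones((1, 2), dtype=np.int8), "full")
P = pn.build_compatibility_network("full", 2)
tensor = mc.build_propensity_tensor(I, P)

donor, recipient = (0, mc.bitstring_to_index("11")), (0, mc.bitstring_to_index("00"))
r_idx, raw, prob = tensor.columns[(donor, recipient)]
print("donor [1,1] -> recipient [0,0]:")
for r, w, p in zip(r_idx, raw, prob):
    bits = mc.profile_bitstring(mc.enumerate_profiles(2)[r])
    print(f"  transconjugant {bits}: raw 1/2^(nu-1) = {w}, normalized = {p}")
print("The double transfer is penalized (raw 1/2) and the normalized column")
print("(0.4, 0.4, 0.2) is what the simulator samples transconjugants from.")
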