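"""Cross-check the stochastic engine against its deterministic mean field.

A single host with one plasmid at K = 2000: the ensemble mean of stochastic
replicates should track the mean-field trajectory during the demographic
phase, with a small, well-understood finite-size lag once the infection
sweep becomes quasi-exponential.
"""

import dataclasses

import numpy as np

import plasmidnet as pn
from plasmidnet import diagnostics as dg
from plasmidnet.experiments import make_initial_conditions, replicate_seeds

I = pn.InfectionNetwork(np.ones((1, 1), dtype=np.int8), "full")
P = pn.CompatibilityNetwork(np.zeros((1, 1), dtype=np.int8), "full")
params = dataclasses.replace(
    pn.table2_parameters(1, 1), carrying_capacity=2000.0, infection=np.array([1e-4])
)
init = make_initial_conditions(I, 200, 10)
system = pn.compile_system(I, P, params)

grid = np.arange(0.0, 50.0 + 1e-9, 10.0)
runs = [
    pn.run_simulation(
        pn.SimulationConfig(I, P, params, init.copy(), 50.0, 10.0, int(s)), system
    ).states[: len(grid)].reshape(len(grid), -1)
    for s in replicate_seeds(11, 100)
]
mean = np.mean(runs, axis=0)

mf = dg.MeanFieldSystem.build(I, P, params)
sol = dg.integrate_meanfield(mf, init.abundance.reshape(-1).astype(float),
                             (0.0, 50.0), t_eval=grid)

print(f"{'t':>4s} {'stoch free':>10s} {'mf free':>9s} {'stoch inf':>10s} {'mf inf':>9s}")
for m, t in enumerate(grid):
    print(f"{t:4.0f} {mean[m, 0]:10.1f} {sol.y[0, m]:9.1f} "
          f"{mean[m, 1]:10.1f} {sol.y[1, m]:9.1f}")
print("Columns: plasmid-free and plasmid-carrying abundance; the stochastic")
print("ensemble mean lags the deterministic sweep by a few percent of K.")
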