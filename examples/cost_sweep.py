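"""How plasmid cost modulates the effect of network structure.

Runs the full-I control against the modular-P structured cell at three
uniform plasmid costs and prints the mean time until the community collapses
to a single host (longer = more transient coexistence).
"""

import numpy as np

from plasmidnet.engine import SimulationConfig, compile_system, run_simulation
from plasmidnet.experiments import (
    make_initial_conditions,
    replicate_seeds,
    scaled_parameters,
)
from plasmidnet.networks import build_compatibility_network, build_infection_network


def mean_collapse_time(p_structure, cost, n_rep=8, base_seed=3):
    params = scaled_parameters().with_cost(cost)
    I = build_infection_network("full")
    P = build_compatibility_network(p_structure, 4, None)
    init = make_initial_conditions(I, 200, 10)
    system = compile_system(I, P, params)
    times = [
        run_simulation(
            SimulationConfig(I, P, params, init.copy(), 20000.0, 5.0, int(s),
                             stop_mode="single_host"),
            system,
        ).times[-1]
        for s in replicate_seeds(base_seed, n_rep)
    ]
    return float(np.mean(times))


print(f"{'cost':>5s} {'full P':>9s} {'modular P':>10s} {'ratio':>6s}")
for cost in (0.0, 0.3, 0.6):
    t_full = mean_collapse_time("full", cost)
    t_mod = mean_collapse_time("modular", cost)
    print(f"{cost:5.1f} {t_full:9.0f} {t_mod:10.0f} {t_mod / t_full:6.2f}")
print("Mean hours until a single host remains. Structured compatibility")
print("prolongs coexistence mainly at moderate cost: with c = 0 plasmids are")
print("nearly neutral, and at high cost they are purged before mattering.")
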