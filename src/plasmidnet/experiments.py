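"""Experiment suite: factorial design, initial conditions, cost sweep,
and the empirically motivated heterogeneous scenario.

The theoretical experiments form a 3 x 3 factorial design crossing the
infection-network structure (full / nested / modular) with the
compatibility-network structure (full / modular / hub), nine cells in all,
each run as an ensemble of independently seeded replicates.

Communities start plasmid-poor: every host begins with a large plasmid-free
subpopulation and a small subpopulation for each single plasmid it is
susceptible to, so each plasmid is already present in its focal hosts before
any transfer occurs.

Two parameter presets are provided. The *full* preset uses the default
uniform traits (K = 20000, 20000 h horizon, 300 replicates). The *scaled*
preset reduces the community size for desk-scale work (K = 2000 by default)
while preserving the dimensionless infection pressure gamma * K — conjugation
is mass-action in absolute numbers, so gamma must scale inversely with K for
a smaller community to sit in the same dynamical regime — and shrinks the
initial subpopulations proportionally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .engine import CompiledSystem, SimulationConfig, TrajectoryRecord, compile_system, run_simulation
from .metrics import ReplicateEnsemble
from .model_core import CommunityState, TraitParameters, table2_parameters
from .networks import (
    CompatibilityNetwork,
    InfectionNetwork,
    build_compatibility_network,
    build_infection_network,
)

__all__ = [
    "FACTORIAL_CELLS",
    "experiment_code",
    "experiment_label",
    "ExperimentDesign",
    "CostSweepDesign",
    "scaled_parameters",
    "make_initial_conditions",
    "replicate_seeds",
    "run_replicates",
    "run_factorial",
    "run_cost_sweep",
    "make_empirical_config",
]

# Table-order cells: code 1 = (full, full) ... code 9 = (modular, hub)
FACTORIAL_CELLS: tuple[tuple[str, str], ...] = tuple(
    (i_s, p_s)
    for i_s in ("full", "nested", "modular")
    for p_s in ("full", "modular", "hub")
)

_SHORT = {"full": "Full", "nested": "Nest", "modular": "Mod", "hub": "Hub"}


def experiment_code(cell: tuple[str, str]) -> int:
    """1-based code of a factorial cell, in table order."""
    return FACTORIAL_CELLS.index((cell[0], cell[1])) + 1


def experiment_label(cell: tuple[str, str]) -> str:
    return f"{_SHORT[cell[0]]} I {_SHORT[cell[1]]} P"


def scaled_parameters(K: float = 2000.0, reference: Optional[TraitParameters] = None) -> TraitParameters:
    """Default traits rescaled to a smaller community.

    The conjugation rate is multiplied by K_ref / K so that gamma * K — the
    per-capita infection pressure when the community is at capacity — matches
    the reference parameterization.
    """
    ref = reference if reference is not None else table2_parameters()
    factor = ref.carrying_capacity / K
    return replace(ref, carrying_capacity=float(K), infection=ref.infection * factor)


def make_initial_conditions(
    infection: InfectionNetwork,
    plasmid_free: int = 2000,
    monoplasmidic: int = 10,
) -> CommunityState:
    """Initial state: per host, ``plasmid_free`` uninfected individuals plus
    ``monoplasmidic`` individuals for every single plasmid the host admits."""
    n_prof = 2**infection.n_plasmids
    A = np.zeros((infection.n_hosts, n_prof), dtype=np.int64)
    A[:, 0] = plasmid_free
    for i in range(infection.n_hosts):
        for a in range(infection.n_plasmids):
            if infection.matrix[i, a]:
                A[i, 1 << a] = monoplasmidic
    return CommunityState(A)


def replicate_seeds(base_seed: int, n: int) -> np.ndarray:
    """Deterministic per-replicate seeds spawned from one base seed."""
    return np.random.SeedSequence(base_seed).generate_state(n) % np.uint32(2**31)


@dataclass(frozen=True)
class ExperimentDesign:
    """The factorial design: cells, replicate count, seeds, and shared
    simulation settings."""

    cells: tuple[tuple[str, str], ...] = FACTORIAL_CELLS
    replicates: int = 300
    base_seed: int = 0
    params: TraitParameters = field(default_factory=table2_parameters)
    t_max: float = 20000.0
    record_interval: float = 5.0
    plasmid_free: int = 2000
    monoplasmidic: int = 10
    hub_index: int = 0
    stop_mode: Optional[str] = None


@dataclass(frozen=True)
class CostSweepDesign:
    """Uniform plasmid-cost grid crossed with structure cells."""

    costs: tuple[float, ...] = (0.0, 0.15, 0.3, 0.45, 0.6)
    cells: tuple[tuple[str, str], ...] = (("full", "full"), ("modular", "full"))
    replicates: int = 300
    base_seed: int = 0
    params: TraitParameters = field(default_factory=table2_parameters)
    t_max: float = 20000.0
    record_interval: float = 5.0
    plasmid_free: int = 2000
    monoplasmidic: int = 10
    hub_index: int = 0
    stop_mode: Optional[str] = None

    def __post_init__(self):
        if any(not 0 <= c < 1 for c in self.costs):
            raise ValueError("costs must lie in [0, 1)")


def _cell_networks(cell: tuple[str, str], params: TraitParameters, hub_index: int):
    infection = build_infection_network(cell[0], params.n_hosts, params.n_plasmids)
    compatibility = build_compatibility_network(
        cell[1], params.n_plasmids, hub_index if cell[1] == "hub" else None
    )
    return infection, compatibility


def run_replicates(
    infection: InfectionNetwork,
    compatibility: CompatibilityNetwork,
    params: TraitParameters,
    initial_state: CommunityState,
    n_replicates: int,
    base_seed: int,
    t_max: float,
    record_interval: float = 5.0,
    stop_mode: Optional[str] = None,
    label: str = "",
    system: Optional[CompiledSystem] = None,
) -> ReplicateEnsemble:
    """Run an ensemble of replicates differing only in their seeds."""
    if system is None:
        system = compile_system(infection, compatibility, params)
    seeds = replicate_seeds(base_seed, n_replicates)
    trajectories = []
    for seed in seeds:
        cfg = SimulationConfig(
            infection, compatibility, params, initial_state.copy(),
            t_max, record_interval, int(seed), stop_mode,
        )
        trajectories.append(run_simulation(cfg, system))
    return ReplicateEnsemble(trajectories, label)


def run_factorial(design: ExperimentDesign) -> dict[int, ReplicateEnsemble]:
    """Run every cell of the design; returns {experiment code: ensemble}.

    Replicate seeds are spawned per cell from ``base_seed + code`` so cells
    and replicates all use distinct, reproducible streams.
    """
    out: dict[int, ReplicateEnsemble] = {}
    for cell in design.cells:
        code = experiment_code(cell)
        infection, compatibility = _cell_networks(cell, design.params, design.hub_index)
        init = make_initial_conditions(infection, design.plasmid_free, design.monoplasmidic)
        out[code] = run_replicates(
            infection, compatibility, design.params, init,
            design.replicates, design.base_seed + code,
            design.t_max, design.record_interval, design.stop_mode,
            label=experiment_label(cell),
        )
    return out


def run_cost_sweep(design: CostSweepDesign) -> dict[tuple[float, int], ReplicateEnsemble]:
    """Run each (cost, cell) combination; returns {(cost, code): ensemble}."""
    out: dict[tuple[float, int], ReplicateEnsemble] = {}
    for ci, cost in enumerate(design.costs):
        params = design.params.with_cost(cost)
        for cell in design.cells:
            code = experiment_code(cell)
            infection, compatibility = _cell_networks(cell, params, design.hub_index)
            init = make_initial_conditions(
                infection, design.plasmid_free, design.monoplasmidic
            )
            out[(cost, code)] = run_replicates(
                infection, compatibility, params, init,
                design.replicates, design.base_seed + 100 * ci + code,
                design.t_max, design.record_interval, design.stop_mode,
                label=f"{experiment_label(cell)} c={cost}",
            )
    return out


# ---------------------------------------------------------------------------
# empirically motivated heterogeneous scenario

def make_empirical_config(
    infection_structure: str = "modular",
    K: float = 1e5,
    B0: int = 3300,
    t_max: float = 240.0,
    seed: int = 0,
    params: Optional[TraitParameters] = None,
) -> SimulationConfig:
    """Heterogeneous three-host / two-plasmid scenario.

    Mirrors a laboratory community of *P. fluorescens* (H1), *P. putida*
    (H2) and *E. coli* (H3) with plasmids pQBR57 (P1, *Pseudomonas*-specific)
    and pKJK5 (P2, unable to conjugate into H1): a modular infection network
    H1 <- {P1}, H2 <- {P1, P2}, H3 <- {P2} with a full compatibility network.
    ``infection_structure="full"`` swaps in the all-ones infection matrix as
    the counterfactual.

    Trait values honor the orderings observed in that system — growth rates
    H1 <= H2 < H3, conjugation rates H1 = H2 < H3, plasmid costs P1 < P2,
    and competitive effect H1 < H2 < H3 — with magnitudes chosen so that
    infection acts within the 240 h window; pass ``params`` to override.
    Each host starts at ``B0`` cells, half plasmid-free and half split
    evenly over the plasmids it carries (link-balanced).
    """
    if infection_structure == "modular":
        I = InfectionNetwork(np.array([[1, 0], [1, 1], [0, 1]], dtype=np.int8), "custom")
    elif infection_structure == "full":
        I = InfectionNetwork(np.ones((3, 2), dtype=np.int8), "full")
    else:
        raise ValueError("infection_structure must be 'modular' or 'full'")
    P = build_compatibility_network("full", 2)
    if params is None:
        # gamma specified at the K = 1e5 reference scale; rescaled so that
        # gamma * K (infection pressure at capacity) is scale-invariant
        gamma_ref = np.array([1e-7, 1e-7, 3e-7])
        effect = np.array([0.005, 0.01, 0.02])  # competitive effect of H1<H2<H3
        params = TraitParameters(
            growth=np.array([0.9, 0.98, 1.0]),  # elevated bridge-host growth
            death=np.full(3, 0.12),
            infection=gamma_ref * (1e5 / K),
            segregation=np.full(3, 1e-8),
            costs=np.array([0.05, 0.1]),
            carrying_capacity=float(K),
            competition=np.tile(effect, (3, 1)),
        )
    A = np.zeros((3, 4), dtype=np.int64)
    half = B0 // 2
    for i in range(3):
        carried = [a for a in range(2) if I.matrix[i, a]]
        A[i, 0] = B0 - (half // len(carried)) * len(carried)
        for a in carried:
            A[i, 1 << a] = half // len(carried)
    return SimulationConfig(I, P, params, CommunityState(A), t_max, 5.0, seed)
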