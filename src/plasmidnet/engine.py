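"""Exact stochastic simulation of the host–plasmid community.

The dynamics follow the Gillespie (direct-method) algorithm over five event
channels — death, growth, segregation, competition, infection — with
per-capita rates defined in :mod:`plasmidnet.model_core`:

1. compute the five channel totals and their sum ``R``;
2. draw the waiting time ``dt = X / R`` with ``X ~ Exp(mean 1)``;
3. pick a channel with probability ``R_channel / R``;
4. pick the acting subpopulation with weight (per-capita rate x abundance);
   for infection, pick donor (by ``phi * H``), then recipient (by abundance
   within the donor's transfer list), then transconjugant (by the normalized
   propensity column);
5. execute the event: death/competition decrement the actor; growth
   increments it; segregation increments the host's plasmid-free
   subpopulation (failed plasmid transmission at division); infection
   decrements the recipient and increments the transconjugant, leaving the
   donor unchanged.

Subpopulation abundances are recorded on a fixed grid: the state *after*
the first event whose time reaches or passes each multiple of
``record_interval`` is stored at that grid time, and the final state is
always recorded.

Two interchangeable backends are provided. ``backend="fast"`` runs the whole
loop in a numba-compiled kernel with incremental bookkeeping of host totals
and of each donor's summed recipient abundance (the only quantities whose
naive recomputation would dominate runtime). ``backend="reference"`` is a
straightforward pure-Python loop built from the public per-event operations;
it is used to validate the kernel on small systems. Both are deterministic
given a seed, each within its own random-number stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

from . import model_core as mc
from .model_core import CommunityState, TraitParameters, PropensityTensor, TransferLists
from .networks import CompatibilityNetwork, InfectionNetwork

__all__ = [
    "SimulationConfig",
    "EventDraw",
    "TrajectoryRecord",
    "CompiledSystem",
    "compile_system",
    "draw_time_step",
    "sample_event",
    "execute_event",
    "run_simulation",
]

_TERMINATIONS = {
    0: "t_max_reached",
    1: "collapse",
    2: "single_host",
    3: "absorbed_pairs",
    4: "absorbing",  # R = 0 with survivors (no event can occur)
}
_STOP_MODES = {None: 0, "single_host": 1, "absorbed_pairs": 2}


@dataclass(frozen=True)
class SimulationConfig:
    """Everything one replicate needs: networks, traits, initial state,
    horizon, recording grid, seed, and an optional early-stopping rule."""

    infection: InfectionNetwork
    compatibility: CompatibilityNetwork
    params: TraitParameters
    initial_state: CommunityState
    t_max: float
    record_interval: float = 5.0
    seed: int = 0
    stop_mode: Optional[str] = None  # None | "single_host" | "absorbed_pairs"

    def __post_init__(self):
        if self.t_max <= 0 or self.record_interval <= 0:
            raise ValueError("t_max and record_interval must be positive")
        if self.stop_mode not in _STOP_MODES:
            raise ValueError(f"unknown stop_mode {self.stop_mode!r}")


@dataclass(frozen=True)
class EventDraw:
    """One sampled event. ``actor`` is a (host, profile_index) pair;
    recipient/transconjugant are set only for infection events."""

    channel: str
    actor: tuple[int, int]
    recipient: Optional[tuple[int, int]] = None
    transconjugant: Optional[tuple[int, int]] = None
    dt: float = 0.0


@dataclass
class TrajectoryRecord:
    """Recorded snapshots of one replicate plus run metadata."""

    times: np.ndarray  # (n_snap,)
    states: np.ndarray  # (n_snap, n_hosts, n_profiles) int64
    termination: str
    seed: int
    config: SimulationConfig
    n_events: int = 0

    @property
    def final_state(self) -> CommunityState:
        return CommunityState(self.states[-1], float(self.times[-1]))

    @property
    def n_snapshots(self) -> int:
        return len(self.times)


# ---------------------------------------------------------------------------
# system compilation: flatten networks + parameters into kernel arrays

@dataclass
class CompiledSystem:
    """Flat-array view of one (I, P, params) triple.

    Subpopulation slots are numbered ``slot = host * n_profiles +
    profile_index``. Donor→recipient adjacency is stored CSR-style
    (``rec_ptr``/``rec_idx``); each adjacency edge carries its normalized
    propensity column (``col_ptr`` into ``trans_idx``/``trans_cum``, the
    latter cumulative for O(log-free) sampling). ``dof_ptr``/``dof_idx`` is
    the transposed adjacency, used to update donors' recipient sums when a
    slot's abundance changes.
    """

    infection: InfectionNetwork
    compatibility: CompatibilityNetwork
    params: TraitParameters
    feasible: np.ndarray
    tensor: PropensityTensor
    lists: TransferLists
    host_of: np.ndarray
    n_carried: np.ndarray
    mu_s: np.ndarray
    eta_s: np.ndarray
    omega_s: np.ndarray
    gamma_s: np.ndarray
    b: np.ndarray
    K: float
    rec_ptr: np.ndarray
    rec_idx: np.ndarray
    col_ptr: np.ndarray
    trans_idx: np.ndarray
    trans_cum: np.ndarray
    dof_ptr: np.ndarray
    dof_idx: np.ndarray

    @property
    def n_hosts(self) -> int:
        return self.infection.n_hosts

    @property
    def n_profiles(self) -> int:
        return 2**self.infection.n_plasmids


def compile_system(
    infection: InfectionNetwork,
    compatibility: CompatibilityNetwork,
    params: TraitParameters,
) -> CompiledSystem:
    if infection.n_plasmids != compatibility.n_plasmids:
        raise ValueError("infection and compatibility networks disagree on n_plasmids")
    if params.n_hosts != infection.n_hosts or params.n_plasmids != infection.n_plasmids:
        raise ValueError("parameter dimensions do not match the networks")

    n_hosts = infection.n_hosts
    n_prof = 2**infection.n_plasmids
    n_slots = n_hosts * n_prof
    profiles = mc.enumerate_profiles(infection.n_plasmids)
    feasible = mc.feasibility_table(infection, compatibility)
    tensor = mc.build_propensity_tensor(infection, compatibility, feasible)
    lists = mc.build_transfer_lists(infection, compatibility, tensor)

    host_of = np.repeat(np.arange(n_hosts, dtype=np.int64), n_prof)
    n_carried = np.tile(profiles.sum(axis=1).astype(np.int64), n_hosts)
    mu_s = np.zeros(n_slots)
    eta_s = np.zeros(n_slots)
    omega_s = np.zeros(n_slots)
    gamma_s = np.zeros(n_slots)
    for i in range(n_hosts):
        for j in range(n_prof):
            s = i * n_prof + j
            if not feasible[i, j]:
                continue  # infeasible slots keep zero rates; abundance stays 0
            mu_s[s] = params.death[i]
            eta_s[s] = mc.growth_rate(i, profiles[j], params)
            omega_s[s] = mc.segregation_rate(i, profiles[j], params)
            if j != 0:
                gamma_s[s] = params.infection[i]

    # donor -> recipient adjacency, aligned tensor columns
    rec_ptr = np.zeros(n_slots + 1, dtype=np.int64)
    rec_idx_l, col_sizes, trans_idx_l, trans_cum_l = [], [], [], []
    for d in range(n_slots):
        donor = (int(host_of[d]), int(d % n_prof))
        recips = lists.recipients_of(donor)
        for (k, q) in recips:
            r_slot = k * n_prof + q
            rec_idx_l.append(r_slot)
            t_idx, probs = tensor.column(donor, (k, q))
            trans_idx_l.extend(k * n_prof + t for t in t_idx)
            trans_cum_l.extend(np.cumsum(probs))
            col_sizes.append(len(t_idx))
        rec_ptr[d + 1] = rec_ptr[d] + len(recips)
    rec_idx = np.array(rec_idx_l, dtype=np.int64)
    col_ptr = np.concatenate([[0], np.cumsum(col_sizes)]).astype(np.int64)
    trans_idx = np.array(trans_idx_l, dtype=np.int64)
    trans_cum = np.array(trans_cum_l, dtype=np.float64)

    # transpose: recipient slot -> donors listing it
    dof_lists: list[list[int]] = [[] for _ in range(n_slots)]
    for d in range(n_slots):
        for m in range(rec_ptr[d], rec_ptr[d + 1]):
            dof_lists[rec_idx[m]].append(d)
    dof_ptr = np.zeros(n_slots + 1, dtype=np.int64)
    dof_idx_l = []
    for s in range(n_slots):
        dof_idx_l.extend(dof_lists[s])
        dof_ptr[s + 1] = len(dof_idx_l)
    dof_idx = np.array(dof_idx_l, dtype=np.int64)

    return CompiledSystem(
        infection, compatibility, params, feasible, tensor, lists,
        host_of, n_carried, mu_s, eta_s, omega_s, gamma_s,
        params.b_matrix, float(params.carrying_capacity),
        rec_ptr, rec_idx, col_ptr, trans_idx, trans_cum, dof_ptr, dof_idx,
    )


# ---------------------------------------------------------------------------
# public per-event operations (reference semantics)

def draw_time_step(R: float, rng: np.random.Generator) -> float:
    """Waiting time to the next event, ``X / R`` with ``X ~ Exp(mean 1)``.

    Returns ``inf`` when ``R == 0`` (absorbing state: no event can occur).
    """
    if R < 0:
        raise ValueError("total rate must be non-negative")
    if R == 0:
        return float("inf")
    return float(rng.exponential()) / R


def sample_event(
    state: CommunityState,
    params: TraitParameters,
    tensor: PropensityTensor,
    lists: TransferLists,
    rng: np.random.Generator,
    totals: Optional[dict] = None,
) -> EventDraw:
    """Sample channel, actor, and (for infection) recipient/transconjugant."""
    profiles = mc.enumerate_profiles(mc._n_plasmids_of(state))
    if totals is None:
        totals = mc.total_rates(state, params, tensor, lists)
    R = totals["total"]
    if R <= 0:
        raise ValueError("cannot sample an event at zero total rate")
    channels = [c for c in mc.CHANNELS if totals[c] > 0]
    weights = np.array([totals[c] for c in channels])
    channel = channels[rng.choice(len(channels), p=weights / weights.sum())]

    def per_capita(i, j):
        bits = profiles[j]
        if channel == "death":
            return float(params.death[i])
        if channel == "growth":
            return mc.growth_rate(i, bits, params)
        if channel == "segregation":
            return mc.segregation_rate(i, bits, params)
        if channel == "competition":
            return mc.competition_rate(i, bits, state, params)
        return mc.infection_rate(i, bits, state, lists, params)

    keys, w = [], []
    for i in range(state.n_hosts):
        for j in range(state.n_profiles):
            h = int(state.abundance[i, j])
            if h == 0:
                continue
            rate = per_capita(i, j) * h
            if rate > 0:
                keys.append((i, j))
                w.append(rate)
    w = np.asarray(w)
    actor = keys[rng.choice(len(keys), p=w / w.sum())]
    if channel != "infection":
        return EventDraw(channel, actor)

    recips = lists.recipients_of(actor)
    rw = np.array([float(state.abundance[k, q]) for (k, q) in recips])
    recipient = recips[rng.choice(len(recips), p=rw / rw.sum())]
    t_idx, probs = tensor.column(actor, recipient)
    r_profile = int(t_idx[rng.choice(len(t_idx), p=probs)])
    return EventDraw(channel, actor, recipient, (recipient[0], r_profile))


def execute_event(state: CommunityState, ev: EventDraw) -> CommunityState:
    """Apply one event's bookkeeping to ``state`` (mutating it).

    Total community abundance changes by +1 (growth, segregation), -1
    (death, competition) or 0 (infection).
    """
    A = state.abundance
    i, j = ev.actor
    assert A[i, j] >= 1, "sampled actor has zero abundance"
    if ev.channel in ("death", "competition"):
        A[i, j] -= 1
    elif ev.channel == "growth":
        A[i, j] += 1
    elif ev.channel == "segregation":
        A[i, 0] += 1  # plasmid-free daughter; the actor itself is unchanged
    elif ev.channel == "infection":
        k, q = ev.recipient
        kt, r = ev.transconjugant
        assert A[k, q] >= 1, "sampled recipient has zero abundance"
        A[k, q] -= 1
        A[kt, r] += 1
    else:
        raise ValueError(f"unknown channel {ev.channel!r}")
    return state


# ---------------------------------------------------------------------------
# numba kernel (fast backend)

@njit(cache=True)
def _run_kernel(
    H, host_of, n_hosts, mu_s, eta_s, omega_s, gamma_s, b, K,
    rec_ptr, rec_idx, col_ptr, trans_idx, trans_cum, dof_ptr, dof_idx,
    n_carried, free_slot, t_max, rec_int, seed, stop_mode, snaps, snap_t,
):  # pragma: no cover - exercised via run_simulation
    np.random.seed(seed)
    n_slots = H.shape[0]
    T = np.zeros(n_hosts)
    light = 0  # individuals carrying fewer than two plasmids
    for s in range(n_slots):
        T[host_of[s]] += H[s]
        if n_carried[s] < 2:
            light += H[s]
    recip_sum = np.zeros(n_slots)
    for d in range(n_slots):
        acc = 0.0
        for m in range(rec_ptr[d], rec_ptr[d + 1]):
            acc += H[rec_idx[m]]
        recip_sum[d] = acc

    F = np.zeros(n_hosts)
    snaps[0] = H
    snap_t[0] = 0.0
    n_snap = 1
    next_rec = rec_int
    t = 0.0
    n_events = 0
    term = 0  # t_max_reached

    while True:
        total = 0.0
        for i in range(n_hosts):
            acc = 0.0
            for jh in range(n_hosts):
                acc += b[i, jh] * T[jh]
            F[i] = acc / K
            total += T[i]
        if total <= 0:
            term = 1  # collapse
            break
        RD = 0.0
        RG = 0.0
        RS = 0.0
        RC = 0.0
        RI = 0.0
        for s in range(n_slots):
            h = H[s]
            if h == 0:
                continue
            hf = float(h)
            RD += mu_s[s] * hf
            RG += eta_s[s] * hf
            RS += omega_s[s] * hf
            RC += eta_s[s] * hf * F[host_of[s]]
            RI += gamma_s[s] * hf * recip_sum[s]
        R = RD + RG + RS + RC + RI
        if R <= 0.0:
            term = 4  # absorbing: survivors but no possible event
            break
        dt = np.random.exponential() / R
        t_new = t + dt
        if t_new >= t_max:
            # the next event falls beyond the horizon: freeze at t_max
            while next_rec <= t_max + 1e-9 and n_snap < snaps.shape[0]:
                snaps[n_snap] = H
                snap_t[n_snap] = next_rec
                n_snap += 1
                next_rec += rec_int
            t = t_max
            term = 0
            break

        u = np.random.random() * R
        # event execution updates H plus the incremental aggregates:
        # host totals T, donors' recipient sums, and the light-profile count
        if u < RD or u < RD + RG or u < RD + RG + RS:
            if u < RD:
                channel = 0
                target_total = RD
            elif u < RD + RG:
                channel = 1
                target_total = RG
                u -= RD
            else:
                channel = 2
                target_total = RS
                u -= RD + RG
            acc = 0.0
            slot = -1
            for s in range(n_slots):
                h = H[s]
                if h == 0:
                    continue
                if channel == 0:
                    w = mu_s[s] * h
                elif channel == 1:
                    w = eta_s[s] * h
                else:
                    w = omega_s[s] * h
                if w <= 0.0:
                    continue
                acc += w
                slot = s
                if acc >= u:
                    break
            if channel == 0:
                delta_slot = slot
                delta = -1
            elif channel == 1:
                delta_slot = slot
                delta = 1
            else:
                delta_slot = free_slot[host_of[slot]]
                delta = 1
            H[delta_slot] += delta
            T[host_of[delta_slot]] += delta
            if n_carried[delta_slot] < 2:
                light += delta
            for m in range(dof_ptr[delta_slot], dof_ptr[delta_slot + 1]):
                recip_sum[dof_idx[m]] += delta
        elif u < RD + RG + RS + RC:
            u -= RD + RG + RS
            acc = 0.0
            slot = -1
            for s in range(n_slots):
                h = H[s]
                if h == 0:
                    continue
                w = eta_s[s] * h * F[host_of[s]]
                if w <= 0.0:
                    continue
                acc += w
                slot = s
                if acc >= u:
                    break
            H[slot] -= 1
            T[host_of[slot]] -= 1
            if n_carried[slot] < 2:
                light -= 1
            for m in range(dof_ptr[slot], dof_ptr[slot + 1]):
                recip_sum[dof_idx[m]] -= 1
        else:
            u -= RD + RG + RS + RC
            acc = 0.0
            donor = -1
            for s in range(n_slots):
                h = H[s]
                if h == 0:
                    continue
                w = gamma_s[s] * h * recip_sum[s]
                if w <= 0.0:
                    continue
                acc += w
                donor = s
                if acc >= u:
                    break
            v = np.random.random() * recip_sum[donor]
            acc = 0.0
            edge = -1
            recip = -1
            for m in range(rec_ptr[donor], rec_ptr[donor + 1]):
                h = H[rec_idx[m]]
                if h == 0:
                    continue
                acc += h
                edge = m
                recip = rec_idx[m]
                if acc >= v:
                    break
            uu = np.random.random()
            trans = trans_idx[col_ptr[edge]]
            for m in range(col_ptr[edge], col_ptr[edge + 1]):
                trans = trans_idx[m]
                if trans_cum[m] >= uu:
                    break
            H[recip] -= 1
            if n_carried[recip] < 2:
                light -= 1
            for m in range(dof_ptr[recip], dof_ptr[recip + 1]):
                recip_sum[dof_idx[m]] -= 1
            H[trans] += 1
            if n_carried[trans] < 2:
                light += 1
            for m in range(dof_ptr[trans], dof_ptr[trans + 1]):
                recip_sum[dof_idx[m]] += 1

        n_events += 1
        t = t_new
        while next_rec <= t + 1e-9 and n_snap < snaps.shape[0]:
            snaps[n_snap] = H
            snap_t[n_snap] = next_rec
            n_snap += 1
            next_rec += rec_int

        if stop_mode == 1:
            alive = 0
            for i in range(n_hosts):
                if T[i] > 0:
                    alive += 1
            if alive <= 1:
                term = 2 if alive == 1 else 1
                break
        elif stop_mode == 2:
            tot = 0.0
            for i in range(n_hosts):
                tot += T[i]
            if light == 0 and tot > 0:
                term = 3
                break

    # always record the final state (append if past the last grid point,
    # otherwise overwrite the coincident last snapshot)
    if snap_t[n_snap - 1] < t - 1e-9 and n_snap < snaps.shape[0]:
        snaps[n_snap] = H
        snap_t[n_snap] = t
        n_snap += 1
    else:
        snaps[n_snap - 1] = H

    return n_snap, term, t, n_events


# ---------------------------------------------------------------------------
# drivers

def _validate_initial(config: SimulationConfig, system: CompiledSystem) -> None:
    A = config.initial_state.abundance
    if A.shape != (system.n_hosts, system.n_profiles):
        raise ValueError("initial state shape does not match the networks")
    bad = (A > 0) & ~system.feasible
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"initial abundance on infeasible subpopulation (host {i}, profile {j})"
        )


def run_simulation(
    config: SimulationConfig,
    system: Optional[CompiledSystem] = None,
    backend: str = "fast",
) -> TrajectoryRecord:
    """Run one replicate and return its trajectory.

    Identical ``(config, backend)`` pairs give bit-identical trajectories;
    a compiled ``system`` may be shared across replicates of one cell.
    """
    if system is None:
        system = compile_system(config.infection, config.compatibility, config.params)
    _validate_initial(config, system)
    if backend == "fast":
        return _run_fast(config, system)
    if backend == "reference":
        return _run_reference(config, system)
    raise ValueError(f"unknown backend {backend!r}")


def _run_fast(config: SimulationConfig, system: CompiledSystem) -> TrajectoryRecord:
    n_snap_max = int(np.floor(config.t_max / config.record_interval)) + 3
    n_slots = system.n_hosts * system.n_profiles
    snaps = np.zeros((n_snap_max, n_slots), dtype=np.int64)
    snap_t = np.zeros(n_snap_max)
    H0 = config.initial_state.abundance.reshape(-1).astype(np.int64).copy()
    free_slot = np.arange(system.n_hosts, dtype=np.int64) * system.n_profiles
    n_snap, term, _t, n_events = _run_kernel(
        H0, system.host_of, system.n_hosts,
        system.mu_s, system.eta_s, system.omega_s, system.gamma_s,
        system.b, system.K,
        system.rec_ptr, system.rec_idx, system.col_ptr,
        system.trans_idx, system.trans_cum, system.dof_ptr, system.dof_idx,
        system.n_carried, free_slot,
        float(config.t_max), float(config.record_interval),
        int(config.seed) % 2**31, _STOP_MODES[config.stop_mode],
        snaps, snap_t,
    )
    states = snaps[:n_snap].reshape(n_snap, system.n_hosts, system.n_profiles).copy()
    return TrajectoryRecord(
        snap_t[:n_snap].copy(), states, _TERMINATIONS[term], config.seed, config, n_events
    )


def _run_reference(config: SimulationConfig, system: CompiledSystem) -> TrajectoryRecord:
    rng = np.random.default_rng(config.seed)
    state = config.initial_state.copy()
    times = [0.0]
    states = [state.abundance.copy()]
    next_rec = config.record_interval
    t = 0.0
    n_events = 0
    term = "t_max_reached"
    while True:
        if state.total == 0:
            term = "collapse"
            break
        totals = mc.total_rates(state, config.params, system.tensor, system.lists)
        dt = draw_time_step(totals["total"], rng)
        if not np.isfinite(dt):
            term = "absorbing"
            break
        t_new = t + dt
        if t_new >= config.t_max:
            while next_rec <= config.t_max + 1e-9:
                times.append(next_rec)
                states.append(state.abundance.copy())
                next_rec += config.record_interval
            t = config.t_max
            break
        ev = sample_event(state, config.params, system.tensor, system.lists, rng, totals)
        execute_event(state, ev)
        n_events += 1
        t = t_new
        while next_rec <= t + 1e-9:
            times.append(next_rec)
            states.append(state.abundance.copy())
            next_rec += config.record_interval
        alive = int((state.host_totals > 0).sum())
        if config.stop_mode == "single_host" and alive <= 1:
            term = "single_host" if alive == 1 else "collapse"
            break
        if config.stop_mode == "absorbed_pairs":
            n_p = mc._n_plasmids_of(state)
            counts = mc.enumerate_profiles(n_p).sum(axis=1)
            light = int(state.abundance[:, counts < 2].sum())
            if light == 0 and state.total > 0:
                term = "absorbed_pairs"
                break
    if times[-1] < t - 1e-9:
        times.append(t)
        states.append(state.abundance.copy())
    else:
        states[-1] = state.abundance.copy()
    return TrajectoryRecord(
        np.array(times), np.array(states, dtype=np.int64), term, config.seed,
        config, n_events,
    )
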