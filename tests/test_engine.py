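import dataclasses

import numpy as np
import pytest

import plasmidnet as pn
from plasmidnet import model_core as mc
from plasmidnet.engine import (
    EventDraw,
    SimulationConfig,
    compile_system,
    draw_time_step,
    execute_event,
    run_simulation,
    sample_event,
)
from plasmidnet.experiments import make_initial_conditions, scaled_parameters
from plasmidnet.networks import build_compatibility_network, build_infection_network


def _tiny_system(n_plasmids=2, **overrides):
    I = pn.InfectionNetwork(np.ones((1, n_plasmids), dtype=np.int8), "full")
    P = build_compatibility_network("full", n_plasmids)
    base = pn.table2_parameters(1, n_plasmids)
    params = dataclasses.replace(base, **overrides) if overrides else base
    return I, P, params


def test_draw_time_step_mean_and_absorbing():
    rng = np.random.default_rng(0)
    draws = np.array([draw_time_step(100.0, rng) for _ in range(100_000)])
    se = draws.std(ddof=1) / np.sqrt(len(draws))
    assert abs(draws.mean() - 0.01) < 3 * se
    assert draw_time_step(0.0, rng) == np.inf
    with pytest.raises(ValueError):
        draw_time_step(-1.0, rng)


def test_draw_time_step_reproducible():
    a = [draw_time_step(5.0, np.random.default_rng(7)) for _ in range(3)]
    b = [draw_time_step(5.0, np.random.default_rng(7)) for _ in range(3)]
    assert a == b


def test_sample_event_death_only():
    I, P, params = _tiny_system(
        growth=np.zeros(1), infection=np.zeros(1), segregation=np.zeros(1)
    )
    system = compile_system(I, P, params)
    state = mc.CommunityState(np.array([[10, 0, 0, 0]]))
    rng = np.random.default_rng(0)
    for _ in range(20):
        ev = sample_event(state, params, system.tensor, system.lists, rng)
        assert ev.channel == "death"
        assert ev.actor == (0, 0)


def test_sample_event_actor_weights_follow_abundance():
    """Two subpopulations with equal per-capita rates and abundances 100 vs
    300 are picked about 1:3."""
    I, P, params = _tiny_system(
        growth=np.zeros(1), infection=np.zeros(1), segregation=np.zeros(1)
    )
    system = compile_system(I, P, params)
    A = np.zeros((1, 4), dtype=int)
    A[0, 0], A[0, 3] = 100, 300
    state = mc.CommunityState(A)
    rng = np.random.default_rng(1)
    n = 20_000
    hits = sum(
        sample_event(state, params, system.tensor, system.lists, rng).actor == (0, 0)
        for _ in range(n)
    )
    se = np.sqrt(0.25 * 0.75 / n)
    assert abs(hits / n - 0.25) < 4 * se


def test_sample_event_transconjugant_follows_propensity_column():
    """Donor [1,1] -> recipient [0,0]: the double transconjugant [1,1] is
    drawn with the normalized propensity 0.2."""
    I, P, params = _tiny_system(
        growth=np.zeros(1), segregation=np.zeros(1), death=np.zeros(1)
    )
    system = compile_system(I, P, params)
    A = np.zeros((1, 4), dtype=int)
    A[0, 3], A[0, 0] = 5, 5
    state = mc.CommunityState(A)
    rng = np.random.default_rng(2)
    n = 5000
    hits = 0
    for _ in range(n):
        ev = sample_event(state, params, system.tensor, system.lists, rng)
        assert ev.channel == "infection"
        assert ev.actor == (0, 3) and ev.recipient == (0, 0)
        hits += ev.transconjugant == (0, 3)
    se = np.sqrt(0.2 * 0.8 / n)
    assert abs(hits / n - 0.2) < 4 * se


@pytest.mark.parametrize(
    "channel,delta_total",
    [("death", -1), ("competition", -1), ("growth", 1), ("segregation", 1), ("infection", 0)],
)
def test_execute_event_bookkeeping(channel, delta_total):
    A = np.zeros((1, 4), dtype=int)
    A[0, 3], A[0, 0] = 10, 5
    state = mc.CommunityState(A.copy())
    if channel == "infection":
        ev = EventDraw(channel, (0, 3), recipient=(0, 0), transconjugant=(0, 1))
    else:
        ev = EventDraw(channel, (0, 3))
    execute_event(state, ev)
    assert state.total - A.sum() == delta_total
    assert (state.abundance >= 0).all()
    if channel == "segregation":
        assert state.abundance[0, 3] == 10  # actor unchanged
        assert state.abundance[0, 0] == 6  # plasmid-free daughter
    if channel == "infection":
        assert state.abundance[0, 3] == 10  # donor unchanged
        assert state.abundance[0, 0] == 4
        assert state.abundance[0, 1] == 1


def test_execute_event_rejects_empty_actor():
    state = mc.CommunityState(np.zeros((1, 4), dtype=int))
    with pytest.raises(AssertionError):
        execute_event(state, EventDraw("growth", (0, 0)))


def test_fast_backend_is_seed_deterministic(scaled):
    I = build_infection_network("full")
    P = build_compatibility_network("full", 4)
    init = make_initial_conditions(I, 200, 10)
    system = compile_system(I, P, scaled)
    cfg = SimulationConfig(I, P, scaled, init, t_max=50.0, seed=123)
    a = run_simulation(cfg, system)
    b = run_simulation(cfg, system)
    assert np.array_equal(a.times, b.times)
    assert np.array_equal(a.states, b.states)
    c = run_simulation(dataclasses.replace(cfg, seed=124), system)
    assert not np.array_equal(a.states, c.states)


def test_snapshot_grid_and_nonnegativity(scaled):
    I = build_infection_network("modular")
    P = build_compatibility_network("full", 4)
    init = make_initial_conditions(I, 200, 10)
    cfg = SimulationConfig(I, P, scaled, init, t_max=42.0, record_interval=5.0, seed=5)
    rec = run_simulation(cfg)
    assert rec.times[0] == 0.0
    assert rec.times[-1] == pytest.approx(42.0)
    on_grid = rec.times[:-1]
    assert np.allclose(np.mod(on_grid, 5.0), 0.0)
    assert np.all(np.diff(rec.times) > 0)
    assert (rec.states >= 0).all()
    assert rec.termination == "t_max_reached"


def test_collapse_termination():
    I, P, params = _tiny_system(
        growth=np.zeros(1), infection=np.zeros(1), segregation=np.zeros(1)
    )
    init = mc.CommunityState(np.array([[30, 0, 0, 0]]))
    cfg = SimulationConfig(I, P, params, init, t_max=1e6, seed=0)
    rec = run_simulation(cfg)
    assert rec.termination == "collapse"
    assert rec.final_state.total == 0


def test_infeasible_initial_state_rejected(scaled):
    I = build_infection_network("modular")
    P = build_compatibility_network("full", 4)
    A = np.zeros((3, 16), dtype=int)
    A[2, 1] = 5  # P1 cannot infect H3 under modular I
    cfg = SimulationConfig(I, P, scaled, mc.CommunityState(A), t_max=10.0, seed=0)
    with pytest.raises(ValueError, match="infeasible"):
        run_simulation(cfg)


def test_incremental_recipient_sums_match_full_recomputation():
    """The kernel maintains each donor's summed recipient abundance
    incrementally; replay the update rule over random abundance changes and
    compare against recomputation from scratch."""
    I = build_infection_network("modular")
    P = build_compatibility_network("hub", 4, 0)
    system = compile_system(I, P, pn.table2_parameters())
    n_slots = len(system.host_of)
    rng = np.random.default_rng(3)
    H = rng.integers(0, 20, n_slots).astype(np.int64)
    H[~system.feasible.reshape(-1)] = 0
    recip_sum = np.array(
        [H[system.rec_idx[system.rec_ptr[d]:system.rec_ptr[d + 1]]].sum() for d in range(n_slots)],
        dtype=float,
    )
    feasible_slots = np.flatnonzero(system.feasible.reshape(-1))
    for _ in range(500):
        s = int(rng.choice(feasible_slots))
        delta = int(rng.choice([-1, 1])) if H[s] > 0 else 1
        H[s] += delta
        for m in range(system.dof_ptr[s], system.dof_ptr[s + 1]):
            recip_sum[system.dof_idx[m]] += delta
    expected = np.array(
        [H[system.rec_idx[system.rec_ptr[d]:system.rec_ptr[d + 1]]].sum() for d in range(n_slots)],
        dtype=float,
    )
    assert np.array_equal(recip_sum, expected)


def test_backends_agree_statistically():
    """Full per-step recomputation (reference) and the incremental numba
    kernel sample the same process: final totals agree within Monte-Carlo
    error on a small birth-death-infection system."""
    I, P, params = _tiny_system(2)
    params = dataclasses.replace(
        params,
        carrying_capacity=150.0,
        infection=np.array([150 * 1e-5 * 10]),  # keep infection pressure visible
    )
    init = mc.CommunityState(np.array([[40, 5, 5, 0]]))
    system = compile_system(I, P, params)
    t_max = 6.0
    ref = [
        run_simulation(
            SimulationConfig(I, P, params, init.copy(), t_max, 2.0, seed),
            system, backend="reference",
        ).final_state.total
        for seed in range(12)
    ]
    fast = [
        run_simulation(
            SimulationConfig(I, P, params, init.copy(), t_max, 2.0, seed),
            system, backend="fast",
        ).final_state.total
        for seed in range(400)
    ]
    ref, fast = np.array(ref, dtype=float), np.array(fast, dtype=float)
    se = np.sqrt(ref.var(ddof=1) / len(ref) + fast.var(ddof=1) / len(fast))
    assert abs(ref.mean() - fast.mean()) < 3.5 * se


def test_single_host_stop_mode(scaled):
    I = build_infection_network("full")
    P = build_compatibility_network("full", 4)
    init = make_initial_conditions(I, 200, 10)
    cfg = SimulationConfig(
        I, P, scaled, init, t_max=20000.0, seed=11, stop_mode="single_host"
    )
    rec = run_simulation(cfg)
    assert rec.termination == "single_host"
    assert int((rec.final_state.host_totals > 0).sum()) == 1
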