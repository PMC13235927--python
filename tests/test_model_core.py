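import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import plasmidnet as pn
from plasmidnet import model_core as mc
from plasmidnet.networks import build_compatibility_network, build_infection_network


# ---------------------------------------------------------------------------
# profiles

def test_profile_enumeration_order_and_notation():
    profs = mc.enumerate_profiles(2)
    assert [mc.profile_bitstring(b) for b in profs] == ["00", "10", "01", "11"]
    assert mc.enumerate_profiles(0).shape == (1, 0)
    assert len(mc.enumerate_profiles(4)) == 16  # 48 subpopulation slots for 3 hosts
    # leftmost bit is P1: "0011" means carrying P3 and P4
    idx = mc.bitstring_to_index("0011")
    assert sorted(np.flatnonzero(mc.enumerate_profiles(4)[idx])) == [2, 3]


@pytest.mark.parametrize(
    "bits,host,p_structure,expected",
    [
        ([1, 1, 0, 0], 0, "modular", True),   # both plasmids in H1's module, compatible
        ([0, 1, 1, 0], 1, "modular", False),  # P2-P3 incompatible under modular P
        ([0, 1, 1, 0], 1, "full", True),      # same pair allowed when P is full
    ],
)
def test_profile_feasibility(bits, host, p_structure, expected):
    I = build_infection_network("modular")
    P = build_compatibility_network(p_structure, 4)
    assert mc.profile_feasible(bits, host, I, P) is expected


def test_feasible_profile_counts_under_structured_compatibility():
    """Enumeration: hub P admits 8 of 16 profiles, modular P admits 7."""
    I = build_infection_network("full")
    hub = mc.feasibility_table(I, build_compatibility_network("hub", 4, 0))
    mod = mc.feasibility_table(I, build_compatibility_network("modular", 4))
    assert hub.sum(axis=1).tolist() == [8, 8, 8]
    assert mod.sum(axis=1).tolist() == [7, 7, 7]
    # no feasible profile under hub P carries two non-hub plasmids
    profs = mc.enumerate_profiles(4)
    for j in np.flatnonzero(hub[0]):
        assert profs[j, 1:].sum() <= 1


# ---------------------------------------------------------------------------
# per-capita rates

def test_growth_rate_multiplicative_costs(table2):
    assert mc.growth_rate(0, [0, 0, 0, 0], table2) == 1.0
    assert mc.growth_rate(0, [1, 0, 0, 0], table2) == pytest.approx(0.7)
    assert mc.growth_rate(0, [1, 1, 0, 0], table2) == pytest.approx(0.49)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    costs=st.lists(st.floats(0, 0.99), min_size=4, max_size=4),
    bits=st.lists(st.integers(0, 1), min_size=4, max_size=4),
    bump=st.floats(0, 0.5),
    which=st.integers(0, 3),
)
def test_growth_rate_monotone_nonincreasing_in_costs(costs, bits, bump, which):
    base = pn.table2_parameters()
    import dataclasses

    p1 = dataclasses.replace(base, costs=np.array(costs))
    higher = list(costs)
    higher[which] = min(0.999, higher[which] + bump)
    p2 = dataclasses.replace(base, costs=np.array(higher))
    g1 = mc.growth_rate(0, bits, p1)
    g2 = mc.growth_rate(0, bits, p2)
    assert g2 <= g1 + 1e-12
    assert mc.growth_rate(0, bits, dataclasses.replace(base, costs=np.zeros(4))) == 1.0


def test_segregation_rate(table2):
    g = mc.growth_rate(0, [1, 1, 0, 0], table2)
    assert mc.segregation_rate(0, [1, 1, 0, 0], table2) == pytest.approx(1e-8 * g)
    assert mc.segregation_rate(0, [0, 0, 0, 0], table2) == 0.0


def test_competition_rate_examples(table2):
    # single host at carrying capacity: competition balances growth
    state = mc.CommunityState(np.array([[20000] + [0] * 15]))
    single = pn.table2_parameters(n_hosts=1)
    assert mc.competition_rate(0, [0] * 4, state, single) == pytest.approx(1.0)
    # empty community: no pressure
    empty = mc.CommunityState(np.zeros((1, 16), dtype=int))
    assert mc.competition_rate(0, [0] * 4, empty, single) == 0.0
    # two hosts at K/2 each with a_ij=0.01: pressure (1*K/2 + 1.01*K/2)/K
    two = pn.table2_parameters(n_hosts=2)
    A = np.zeros((2, 16), dtype=int)
    A[0, 0] = A[1, 0] = 10000
    st2 = mc.CommunityState(A)
    assert mc.competition_rate(0, [0] * 4, st2, two) == pytest.approx(1.005)


def test_infection_rate_examples(table2):
    I = build_infection_network("full")
    P = build_compatibility_network("full", 4)
    lists = mc.build_transfer_lists(I, P)
    A = np.zeros((3, 16), dtype=int)
    A[0, 0] = 2000  # the only recipients with abundance
    A[0, 1] = 5
    state = mc.CommunityState(A)
    # gamma * summed recipient abundance; recipients of (H1, P1) with
    # abundance are only the 2000 plasmid-free H1 cells here
    assert mc.infection_rate(0, [1, 0, 0, 0], state, lists, table2) == pytest.approx(
        1e-5 * 2000
    )
    assert mc.infection_rate(0, [0, 0, 0, 0], state, lists, table2) == 0.0
    # no recipients with abundance -> zero
    lone = mc.CommunityState(np.zeros((3, 16), dtype=int))
    assert mc.infection_rate(0, [1, 0, 0, 0], lone, lists, table2) == 0.0


def test_total_rates_channels_and_sum(table2):
    I = build_infection_network("full")
    P = build_compatibility_network("full", 4)
    tensor = mc.build_propensity_tensor(I, P)
    lists = mc.build_transfer_lists(I, P, tensor)
    empty = mc.CommunityState(np.zeros((3, 16), dtype=int))
    totals = mc.total_rates(empty, table2, tensor, lists)
    assert all(v == 0 for v in totals.values())

    A = np.zeros((3, 16), dtype=int)
    A[0, 0] = 100
    totals = mc.total_rates(mc.CommunityState(A), table2, tensor, lists)
    assert totals["death"] == pytest.approx(0.12 * 100)

    rng = np.random.default_rng(1)
    A = rng.integers(0, 50, size=(3, 16))
    totals = mc.total_rates(mc.CommunityState(A), table2, tensor, lists)
    assert totals["total"] == pytest.approx(sum(totals[c] for c in mc.CHANNELS))


def test_total_rate_invariant_under_host_relabeling(table2):
    """Permuting host labels (with uniform traits) leaves R unchanged."""
    I = build_infection_network("full")
    P = build_compatibility_network("full", 4)
    tensor = mc.build_propensity_tensor(I, P)
    lists = mc.build_transfer_lists(I, P, tensor)
    rng = np.random.default_rng(2)
    A = rng.integers(0, 80, size=(3, 16))
    r1 = mc.total_rates(mc.CommunityState(A), table2, tensor, lists)["total"]
    r2 = mc.total_rates(mc.CommunityState(A[[2, 0, 1]]), table2, tensor, lists)["total"]
    assert r1 == pytest.approx(r2)


# ---------------------------------------------------------------------------
# propensity tensor and transfer lists

def test_two_plasmid_transfer_worked_example(one_host_two_plasmids):
    """Donor [1,1] -> recipient [0,0]: raw weight 1/2 for the double
    transfer, and the normalized column is (0.4, 0.4, 0.2)."""
    I, P = one_host_two_plasmids
    tensor = mc.build_propensity_tensor(I, P)
    r_idx, raw, prob = tensor.columns[((0, 3), (0, 0))]
    entries = dict(zip(r_idx.tolist(), raw.tolist()))
    assert entries == {1: 1.0, 2: 1.0, 3: 0.5}
    assert dict(zip(r_idx.tolist(), np.round(prob, 10).tolist())) == {
        1: 0.4, 2: 0.4, 3: 0.2,
    }
    # a donor with nothing new for the recipient yields no column
    assert ((0, 1), (0, 1)) not in tensor.columns


def test_tensor_columns_normalized_all_cells(canonical_networks):
    for (I, P) in canonical_networks.values():
        tensor = mc.build_propensity_tensor(I, P)
        assert tensor.columns, "every canonical cell admits some transfer"
        for r_idx, _raw, prob in tensor.columns.values():
            assert prob.sum() == pytest.approx(1.0, abs=1e-12)
            assert len(set(r_idx.tolist())) == len(r_idx)


def test_transfer_list_membership(canonical_networks):
    I, P = canonical_networks[("full", "full")]
    lists = mc.build_transfer_lists(I, P)
    p1 = mc.bitstring_to_index("1000")
    # within-host transfer to the plasmid-free subpopulation is allowed
    assert (0, 0) in lists.recipients_of((0, p1))
    # a recipient already carrying everything the donor has is excluded
    assert (1, p1) not in lists.recipients_of((0, p1))
    # all donors carry at least one plasmid
    assert all(p != 0 for (_h, p) in lists.donors)

    Im, Pm = canonical_networks[("modular", "full")]
    mlists = mc.build_transfer_lists(Im, Pm)
    # P1 cannot reach H3 under the modular infection network
    assert all(k != 2 for (k, _q) in mlists.recipients_of((0, p1)))
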