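"""Subpopulation profiles, per-capita event rates, and infection propensities.

The community is a table of subpopulations ``H[i, p]``: all individuals of
host ``i`` carrying exactly the plasmid profile ``p``. A profile is a binary
vector over plasmids (single copy per plasmid per cell). With ``n_b`` hosts
and ``n_p`` plasmids there are at most ``n_b * 2**n_p`` subpopulations.

Profile indexing convention: profile index ``j`` carries plasmid ``a`` iff
``(j >> a) & 1``. In the printed bitstring the *leftmost* character is P1,
so index 12 with four plasmids renders as ``"0011"`` — carrying P3 and P4.
Index 0 is always the plasmid-free profile, and profiles are enumerated in
integer-ascending order.

Five event channels drive the dynamics, each with a per-capita rate:

* death           mu_i
* growth          eta_{i,p} = eta_i * prod_{a in p} (1 - c_a)   (multiplicative
                  plasmid costs: a slight positive epistasis under co-infection)
* segregation     omega_{i,p} = e_i * eta_{i,p}  (0 for the plasmid-free profile)
* competition     xi_{i,p} = eta_{i,p} * (sum_j b_ij H_j) / K, with b_ii = 1 and
                  b_ij = a_ij + 1 for i != j, K a community-wide carrying capacity
* infection       phi_{i,p} = gamma_i * sum of recipient abundances in the
                  donor's transfer list (0 for plasmid-free profiles)

Conjugative transfer from donor (i, p) to recipient (k, q), producing
transconjugant (k, r), is possible iff (1) the donor carries plasmids,
(2) the donor has plasmids the recipient lacks, (3) every transferred
plasmid can infect host k, and (4) all plasmids in r are pairwise
compatible. Each feasible transfer set of size nu gets raw propensity
``1 / 2**(nu - 1)``; the propensities of each (donor, recipient) column are
then normalized to sum to 1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np

from .networks import CompatibilityNetwork, InfectionNetwork

__all__ = [
    "enumerate_profiles",
    "profile_index",
    "profile_bitstring",
    "bitstring_to_index",
    "profile_feasible",
    "feasibility_table",
    "TraitParameters",
    "table2_parameters",
    "CommunityState",
    "growth_rate",
    "segregation_rate",
    "competition_rate",
    "infection_rate",
    "total_rates",
    "PropensityTensor",
    "TransferLists",
    "build_propensity_tensor",
    "build_transfer_lists",
]

CHANNELS = ("death", "growth", "segregation", "competition", "infection")


# ---------------------------------------------------------------------------
# profiles

def enumerate_profiles(n_plasmids: int) -> np.ndarray:
    """All ``2**n_plasmids`` binary profiles, integer-ascending.

    Returns an array of shape ``(2**n_p, n_p)`` where row ``j``, column ``a``
    is 1 iff profile ``j`` carries plasmid ``a``. Row 0 is plasmid-free.
    """
    if n_plasmids < 0:
        raise ValueError("n_plasmids must be >= 0")
    idx = np.arange(2**n_plasmids, dtype=np.int64)
    bits = (idx[:, None] >> np.arange(n_plasmids)) & 1
    return bits.astype(np.uint8)


def profile_index(bits: Iterable[int]) -> int:
    """Integer encoding of a profile bit vector (element 0 = P1)."""
    return int(sum(int(b) << a for a, b in enumerate(bits)))


def profile_bitstring(bits: Iterable[int]) -> str:
    """Human-readable bitstring, leftmost character = P1 (e.g. ``"0011"``)."""
    return "".join(str(int(b)) for b in bits)


def bitstring_to_index(s: str) -> int:
    return profile_index(int(ch) for ch in s)


def profile_feasible(
    bits: Iterable[int],
    host: int,
    infection: InfectionNetwork,
    compatibility: CompatibilityNetwork,
) -> bool:
    """True iff every carried plasmid can infect ``host`` and all carried
    pairs are mutually compatible."""
    carried = [a for a, b in enumerate(bits) if b]
    I, P = infection.matrix, compatibility.matrix
    if any(I[host, a] == 0 for a in carried):
        return False
    return all(P[a, b] == 1 for a, b in itertools.combinations(carried, 2))


def feasibility_table(
    infection: InfectionNetwork, compatibility: CompatibilityNetwork
) -> np.ndarray:
    """Boolean table ``(n_hosts, 2**n_p)``: which profiles each host admits."""
    profiles = enumerate_profiles(infection.n_plasmids)
    n_hosts = infection.n_hosts
    table = np.zeros((n_hosts, len(profiles)), dtype=bool)
    for i in range(n_hosts):
        for j, bits in enumerate(profiles):
            table[i, j] = profile_feasible(bits, i, infection, compatibility)
    return table


# ---------------------------------------------------------------------------
# parameters and state

@dataclass(frozen=True)
class TraitParameters:
    """Host and plasmid trait parameters.

    Rates are per hour; ``costs`` are fractions of the growth rate in [0, 1);
    ``K`` is the community-wide carrying capacity in cells; ``competition``
    is the matrix a_ij (effect of host j on host i; the diagonal is unused
    because b_ii is fixed at 1).
    """

    growth: np.ndarray  # eta_i
    death: np.ndarray  # mu_i
    infection: np.ndarray  # gamma_i, per (cell * hour)
    segregation: np.ndarray  # e_i, dimensionless probability
    costs: np.ndarray  # c_alpha
    carrying_capacity: float  # K
    competition: np.ndarray  # a_ij

    def __post_init__(self):
        for name in ("growth", "death", "infection", "segregation", "costs"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        object.__setattr__(self, "competition", np.asarray(self.competition, dtype=float))
        n = self.n_hosts
        if not (self.death.shape == self.infection.shape == self.segregation.shape == (n,)):
            raise ValueError("per-host trait vectors must share one length")
        if self.competition.shape != (n, n):
            raise ValueError("competition matrix must be n_hosts x n_hosts")
        for name in ("growth", "death", "infection", "segregation"):
            if (getattr(self, name) < 0).any():
                raise ValueError(f"{name} rates must be >= 0")
        if ((self.costs < 0) | (self.costs >= 1)).any():
            raise ValueError("plasmid costs must lie in [0, 1)")
        if self.carrying_capacity <= 0:
            raise ValueError("carrying capacity must be positive")

    @property
    def n_hosts(self) -> int:
        return self.growth.shape[0]

    @property
    def n_plasmids(self) -> int:
        return self.costs.shape[0]

    @property
    def b_matrix(self) -> np.ndarray:
        """Competition kernel b: b_ii = 1, b_ij = a_ij + 1 for i != j."""
        b = self.competition + 1.0
        np.fill_diagonal(b, 1.0)
        return b

    def with_cost(self, cost: float) -> "TraitParameters":
        """Copy with a uniform plasmid cost (used by the cost sweep)."""
        return replace(self, costs=np.full(self.n_plasmids, float(cost)))


def table2_parameters(n_hosts: int = 3, n_plasmids: int = 4) -> TraitParameters:
    """Default uniform traits of the theoretical experiments.

    eta = 1 /h, mu = 0.12 /h, gamma = 1e-5 /(cell h), e = 1e-8, c = 0.3,
    K = 20000 cells, a_ij = 0.01 (interspecific), for any community size.
    """
    return TraitParameters(
        growth=np.ones(n_hosts),
        death=np.full(n_hosts, 0.12),
        infection=np.full(n_hosts, 1e-5),
        segregation=np.full(n_hosts, 1e-8),
        costs=np.full(n_plasmids, 0.3),
        carrying_capacity=20000.0,
        competition=np.full((n_hosts, n_hosts), 0.01),
    )


@dataclass
class CommunityState:
    """Integer abundance table over (host, profile) subpopulations."""

    abundance: np.ndarray  # (n_hosts, 2**n_p) int64
    time: float = 0.0

    def __post_init__(self):
        self.abundance = np.asarray(self.abundance, dtype=np.int64)
        if self.abundance.ndim != 2:
            raise ValueError("abundance must be a (n_hosts, n_profiles) table")
        if (self.abundance < 0).any():
            raise ValueError("abundances must be non-negative")

    @property
    def n_hosts(self) -> int:
        return self.abundance.shape[0]

    @property
    def n_profiles(self) -> int:
        return self.abundance.shape[1]

    @property
    def host_totals(self) -> np.ndarray:
        """H_i = sum_p H_{i,p}."""
        return self.abundance.sum(axis=1)

    @property
    def total(self) -> int:
        return int(self.abundance.sum())

    def copy(self) -> "CommunityState":
        return CommunityState(self.abundance.copy(), self.time)


# ---------------------------------------------------------------------------
# per-capita rates

def growth_rate(host: int, bits: Iterable[int], params: TraitParameters) -> float:
    """Realized per-capita growth rate eta_{i,p} with multiplicative costs."""
    rate = float(params.growth[host])
    for a, b in enumerate(bits):
        if b:
            rate *= 1.0 - params.costs[a]
    return rate


def segregation_rate(host: int, bits, params: TraitParameters) -> float:
    """Per-capita rate of growth-with-segregation-error, e_i * eta_{i,p}.

    Zero for the plasmid-free profile: there is nothing to lose, and the
    resulting event would be indistinguishable from plain growth.
    """
    bits = list(bits)
    if not any(bits):
        return 0.0
    return float(params.segregation[host]) * growth_rate(host, bits, params)


def competition_rate(
    host: int, bits, state: CommunityState, params: TraitParameters
) -> float:
    """Per-capita competition (density-dependent death) rate xi_{i,p}."""
    pressure = float(params.b_matrix[host] @ state.host_totals) / params.carrying_capacity
    return growth_rate(host, bits, params) * pressure


def infection_rate(
    host: int,
    bits,
    state: CommunityState,
    lists: "TransferLists",
    params: TraitParameters,
) -> float:
    """Per-capita conjugation rate phi_{i,p} of a donor subpopulation.

    gamma_i times the summed abundance of the donor's recipient set; zero for
    plasmid-free profiles (they have nothing to donate).
    """
    bits = list(bits)
    if not any(bits):
        return 0.0
    key = (host, profile_index(bits))
    recipients = lists.recipients_of(key)
    total = sum(int(state.abundance[k, q]) for (k, q) in recipients)
    return float(params.infection[host]) * total


def total_rates(
    state: CommunityState,
    params: TraitParameters,
    tensor: "PropensityTensor",
    lists: "TransferLists",
) -> dict[str, float]:
    """Channel totals R_D, R_G, R_S, R_C, R_I and their sum R.

    Each channel total is the per-capita rate times abundance, summed over
    subpopulations.
    """
    profiles = enumerate_profiles(_n_plasmids_of(state))
    out = {c: 0.0 for c in CHANNELS}
    for i in range(state.n_hosts):
        for j in range(state.n_profiles):
            h = int(state.abundance[i, j])
            if h == 0:
                continue
            bits = profiles[j]
            out["death"] += float(params.death[i]) * h
            out["growth"] += growth_rate(i, bits, params) * h
            out["segregation"] += segregation_rate(i, bits, params) * h
            out["competition"] += competition_rate(i, bits, state, params) * h
            out["infection"] += infection_rate(i, bits, state, lists, params) * h
    out["total"] = sum(out[c] for c in CHANNELS)
    return out


def _n_plasmids_of(state: CommunityState) -> int:
    n = state.n_profiles
    n_p = int(round(np.log2(n)))
    if 2**n_p != n:
        raise ValueError("profile axis length must be a power of two")
    return n_p


# ---------------------------------------------------------------------------
# transfer lists and propensity tensor

@dataclass
class TransferLists:
    """Donor subpopulations and, per donor, the recipients they can infect.

    Keys are ``(host, profile_index)`` pairs. Both within- and between-host
    transfer are included. Built over the full feasible catalog, so the
    lists remain valid as subpopulations appear or vanish during a run
    (absent subpopulations simply contribute zero abundance).
    """

    donors: list[tuple[int, int]]
    _recipients: dict[tuple[int, int], list[tuple[int, int]]]

    def recipients_of(self, donor: tuple[int, int]) -> list[tuple[int, int]]:
        return self._recipients.get(donor, [])


@dataclass
class PropensityTensor:
    """Sparse infection propensity tensor Gamma.

    ``columns`` maps a (donor, recipient) pair — each a ``(host,
    profile_index)`` tuple — to ``(transconjugant profile indices, raw
    weights, normalized weights)``. Raw weight for a transfer of ``nu``
    plasmids is ``1 / 2**(nu - 1)``; normalized weights of a column sum
    to 1.
    """

    columns: dict[
        tuple[tuple[int, int], tuple[int, int]],
        tuple[np.ndarray, np.ndarray, np.ndarray],
    ]
    normalized: bool = True

    def column(self, donor, recipient):
        """Return (transconjugant indices, normalized probabilities)."""
        entry = self.columns.get((tuple(donor), tuple(recipient)))
        if entry is None:
            return np.empty(0, dtype=np.int64), np.empty(0)
        idx, _raw, prob = entry
        return idx, prob


def _transfer_columns(infection, compatibility, donor_host, p_idx, recip_host, q_idx):
    """Enumerate feasible transconjugants for one (donor, recipient) pair.

    Yields (r_index, nu). Transfer sets are the non-empty subsets of the
    donor-only plasmids that can infect the recipient host and whose union
    with the recipient profile is pairwise compatible.
    """
    I, P = infection.matrix, compatibility.matrix
    donor_only = p_idx & ~q_idx
    transferable = [
        a for a in range(infection.n_plasmids)
        if (donor_only >> a) & 1 and I[recip_host, a]
    ]
    for nu in range(1, len(transferable) + 1):
        for s in itertools.combinations(transferable, nu):
            r_idx = q_idx
            for a in s:
                r_idx |= 1 << a
            carried = [a for a in range(infection.n_plasmids) if (r_idx >> a) & 1]
            if all(P[a, b] for a, b in itertools.combinations(carried, 2)):
                # r is I-feasible by construction (q feasible, s infectable)
                yield r_idx, nu


def build_propensity_tensor(
    infection: InfectionNetwork,
    compatibility: CompatibilityNetwork,
    feasible: Optional[np.ndarray] = None,
) -> PropensityTensor:
    """Construct the normalized propensity tensor for a network pair."""
    if feasible is None:
        feasible = feasibility_table(infection, compatibility)
    n_hosts, n_profiles = feasible.shape
    columns = {}
    for i in range(n_hosts):
        for p_idx in range(1, n_profiles):  # condition 1: donor is infected
            if not feasible[i, p_idx]:
                continue
            for k in range(n_hosts):
                for q_idx in range(n_profiles):
                    if not feasible[k, q_idx]:
                        continue
                    if not (p_idx & ~q_idx):  # condition 2
                        continue
                    entries = list(
                        _transfer_columns(infection, compatibility, i, p_idx, k, q_idx)
                    )
                    if not entries:
                        continue
                    r = np.array([e[0] for e in entries], dtype=np.int64)
                    raw = np.array([0.5 ** (e[1] - 1) for e in entries])
                    columns[((i, p_idx), (k, q_idx))] = (r, raw, raw / raw.sum())
    return PropensityTensor(columns)


def build_transfer_lists(
    infection: InfectionNetwork,
    compatibility: CompatibilityNetwork,
    tensor: Optional[PropensityTensor] = None,
) -> TransferLists:
    """Donor and recipient lists induced by the propensity tensor."""
    if tensor is None:
        tensor = build_propensity_tensor(infection, compatibility)
    recipients: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for (donor, recipient) in tensor.columns:
        recipients.setdefault(donor, []).append(recipient)
    for lst in recipients.values():
        lst.sort()
    donors = sorted(recipients)
    return TransferLists(donors, recipients)
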