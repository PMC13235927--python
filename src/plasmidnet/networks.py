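"""Infection and compatibility network structures.

Two binary networks constrain the community dynamics:

* the host–plasmid infection network ``I`` (bipartite incidence matrix,
  hosts × plasmids): ``I[i, a] = 1`` iff plasmid ``a`` can infect host ``i``;
* the plasmid–plasmid compatibility network ``P`` (symmetric, zero diagonal):
  ``P[a, b] = 1`` iff plasmids ``a`` and ``b`` can co-reside in one cell.
  Plasmids are self-incompatible (single copy per cell), hence the zero
  diagonal.

The canonical motifs used in the factorial design are small (3 hosts ×
4 plasmids) and stored as dense 0/1 integer arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "InfectionNetwork",
    "CompatibilityNetwork",
    "build_infection_network",
    "build_compatibility_network",
    "validate_network_pair",
    "summarize_structure",
    "save_matrix",
    "load_matrix",
]

INFECTION_STRUCTURES = ("full", "nested", "modular", "custom")
COMPATIBILITY_STRUCTURES = ("full", "modular", "hub", "custom")


def _as_binary(matrix) -> np.ndarray:
    m = np.asarray(matrix, dtype=np.int8)
    if m.ndim != 2:
        raise ValueError("network matrix must be 2-D")
    if not np.isin(m, (0, 1)).all():
        raise ValueError("network matrix entries must be 0 or 1")
    return m


@dataclass(frozen=True)
class InfectionNetwork:
    """Binary host × plasmid incidence matrix."""

    matrix: np.ndarray
    structure: str = "custom"

    def __post_init__(self):
        object.__setattr__(self, "matrix", _as_binary(self.matrix))
        if self.structure not in INFECTION_STRUCTURES:
            raise ValueError(f"unknown infection structure {self.structure!r}")
        self.matrix.setflags(write=False)

    @property
    def n_hosts(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_plasmids(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class CompatibilityNetwork:
    """Symmetric binary plasmid × plasmid matrix with zero diagonal."""

    matrix: np.ndarray
    structure: str = "custom"
    hub_index: Optional[int] = None

    def __post_init__(self):
        m = _as_binary(self.matrix)
        if m.shape[0] != m.shape[1]:
            raise ValueError("compatibility matrix must be square")
        if (np.diag(m) != 0).any():
            raise ValueError("plasmids are self-incompatible: diagonal must be 0")
        if (m != m.T).any():
            raise ValueError("compatibility matrix must be symmetric")
        object.__setattr__(self, "matrix", m)
        if self.structure not in COMPATIBILITY_STRUCTURES:
            raise ValueError(f"unknown compatibility structure {self.structure!r}")
        m.setflags(write=False)

    @property
    def n_plasmids(self) -> int:
        return self.matrix.shape[0]


def build_infection_network(
    structure: str, n_hosts: int = 3, n_plasmids: int = 4
) -> InfectionNetwork:
    """Construct one of the canonical infection-network motifs.

    ``full``
        every plasmid can infect every host (control).
    ``nested``
        stair-step specialization: H1 is susceptible to all four plasmids,
        H2 to {P1, P2, P3}, and the specialist H3 only to the generalist
        plasmid P1.
    ``modular``
        two peripheral modules bridged by a bridge host: H1 ← {P1, P2},
        H2 ← {P2, P3} (the bridge), H3 ← {P3, P4}.

    The named motifs are defined for 3 hosts × 4 plasmids; arbitrary
    matrices enter via :class:`InfectionNetwork` directly.
    """
    if structure not in ("full", "nested", "modular"):
        raise ValueError(f"unknown infection structure {structure!r}")
    if structure == "full":
        return InfectionNetwork(np.ones((n_hosts, n_plasmids), dtype=np.int8), "full")
    if (n_hosts, n_plasmids) != (3, 4):
        raise ValueError(
            f"the {structure!r} motif is defined for 3 hosts x 4 plasmids, "
            f"got {n_hosts}x{n_plasmids}"
        )
    if structure == "nested":
        m = [[1, 1, 1, 1], [1, 1, 1, 0], [1, 0, 0, 0]]
    else:  # modular
        m = [[1, 1, 0, 0], [0, 1, 1, 0], [0, 0, 1, 1]]
    return InfectionNetwork(np.array(m, dtype=np.int8), structure)


def build_compatibility_network(
    structure: str, n_plasmids: int = 4, hub_index: Optional[int] = None
) -> CompatibilityNetwork:
    """Construct one of the canonical compatibility-network motifs.

    ``full``
        all plasmid pairs compatible (control).
    ``modular``
        modules {P1, P2} and {P3, P4}: compatible within a module,
        incompatible between modules.
    ``hub``
        a sole hub plasmid is compatible with every other plasmid while all
        non-hub pairs are incompatible; ``hub_index`` selects the hub
        (0-based).

    The diagonal is always zero (self-incompatibility).
    """
    if structure == "full":
        m = np.ones((n_plasmids, n_plasmids), dtype=np.int8)
        np.fill_diagonal(m, 0)
        return CompatibilityNetwork(m, "full")
    if structure == "modular":
        if n_plasmids != 4:
            raise ValueError("the modular motif is defined for 4 plasmids")
        m = np.zeros((4, 4), dtype=np.int8)
        m[0, 1] = m[1, 0] = 1
        m[2, 3] = m[3, 2] = 1
        return CompatibilityNetwork(m, "modular")
    if structure == "hub":
        if hub_index is None:
            raise ValueError("hub structure requires hub_index")
        if not 0 <= hub_index < n_plasmids:
            raise ValueError(f"hub_index {hub_index} out of range for {n_plasmids} plasmids")
        m = np.zeros((n_plasmids, n_plasmids), dtype=np.int8)
        m[hub_index, :] = 1
        m[:, hub_index] = 1
        m[hub_index, hub_index] = 0
        return CompatibilityNetwork(m, "hub", hub_index)
    raise ValueError(f"unknown compatibility structure {structure!r}")


def validate_network_pair(infection, compatibility) -> list[str]:
    """Check a network pair for consistency; return a list of violations.

    An empty list means the pair is valid. Accepts network objects or raw
    matrices (the constructors already enforce binarity / symmetry / zero
    diagonal, so raw arrays are the way to audit untrusted input).
    """
    violations: list[str] = []
    I = np.asarray(getattr(infection, "matrix", infection))
    P = np.asarray(getattr(compatibility, "matrix", compatibility))
    if I.shape[1] != P.shape[0]:
        violations.append(
            f"dimension mismatch: infection network has {I.shape[1]} plasmids, "
            f"compatibility network has {P.shape[0]}"
        )
    for name, m in (("infection", I), ("compatibility", P)):
        if not np.isin(m, (0, 1)).all():
            violations.append(f"{name} matrix has non-binary entries")
    if (P != P.T).any():
        violations.append("compatibility matrix is asymmetric")
    if (np.diag(P) != 0).any():
        violations.append("compatibility matrix has nonzero diagonal")
    if getattr(infection, "structure", "custom") in ("full", "nested", "modular"):
        empty = np.flatnonzero(I.sum(axis=0) == 0)
        if empty.size:
            violations.append(f"plasmid(s) {empty.tolist()} have no susceptible host")
    return violations


def summarize_structure(
    infection: InfectionNetwork, compatibility: CompatibilityNetwork
) -> dict:
    """Degree/connectance summary plus feasible-profile counts per host."""
    from .model_core import feasibility_table  # deferred: avoids import cycle

    I, P = infection.matrix, compatibility.matrix
    feas = feasibility_table(infection, compatibility)
    return {
        "host_degree": I.sum(axis=1).tolist(),
        "plasmid_infection_degree": I.sum(axis=0).tolist(),
        "plasmid_compatibility_degree": P.sum(axis=1).tolist(),
        "infection_connectance": float(I.mean()),
        "compatibility_connectance": float(P[np.triu_indices(P.shape[0], 1)].mean())
        if P.shape[0] > 1
        else 0.0,
        "feasible_profiles_per_host": feas.sum(axis=1).tolist(),
    }


def save_matrix(path, network) -> None:
    """Write a network matrix as a plain-text CSV of 0/1 entries."""
    np.savetxt(path, network.matrix, fmt="%d", delimiter=",")


def load_matrix(path) -> np.ndarray:
    """Read a 0/1 matrix written by :func:`save_matrix`."""
    return np.atleast_2d(np.loadtxt(path, delimiter=",", dtype=np.int8))
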