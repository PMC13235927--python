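"""Validation machinery: a deterministic mean-field counterpart of the
stochastic model, and naive brute-force re-derivations for small systems.

The mean-field system treats subpopulation abundances as continuous and
replaces each stochastic event channel with its expected flow:

* growth adds ``eta_{i,p} H_{i,p}`` to the subpopulation itself;
* segregation adds ``omega_{i,p} H_{i,p}`` to the host's plasmid-free
  subpopulation (the actor is unchanged in the stochastic event, so this is
  pure inflow);
* death and competition remove ``mu_i H_{i,p}`` and ``xi_{i,p} H_{i,p}``;
* infection moves mass from recipient to transconjugant at the mass-action
  rate ``gamma_i H_{donor} H_{recipient}``, split over transconjugants by
  the normalized propensity column — exactly the expectation of the
  donor/recipient/transconjugant sampling scheme in the engine.

For a single plasmid-free host this collapses to logistic-type growth with
equilibrium ``H* = K (1 - mu / eta)``.

These tools are test/validation machinery, not a user-facing solver.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from . import model_core as mc
from .engine import CompiledSystem, compile_system
from .model_core import PropensityTensor, TraitParameters
from .networks import CompatibilityNetwork, InfectionNetwork

__all__ = [
    "MeanFieldSystem",
    "meanfield_derivatives",
    "integrate_meanfield",
    "logistic_equilibrium",
    "brute_force_tensor",
    "tensors_equal",
]


@dataclass
class MeanFieldSystem:
    """Continuous-abundance counterpart of one (I, P, params) triple."""

    system: CompiledSystem

    @classmethod
    def build(
        cls,
        infection: InfectionNetwork,
        compatibility: CompatibilityNetwork,
        params: TraitParameters,
    ) -> "MeanFieldSystem":
        return cls(compile_system(infection, compatibility, params))

    @property
    def n_slots(self) -> int:
        return self.system.n_hosts * self.system.n_profiles


def meanfield_derivatives(x: np.ndarray, mf: MeanFieldSystem) -> np.ndarray:
    """dH/dt per subpopulation slot for continuous abundances ``x``."""
    s = mf.system
    x = np.asarray(x, dtype=float)
    n_hosts, n_prof = s.n_hosts, s.n_profiles
    T = x.reshape(n_hosts, n_prof).sum(axis=1)
    F = (s.b @ T) / s.K
    dx = s.eta_s * x - s.mu_s * x - s.eta_s * x * F[s.host_of]
    # segregation inflow into each host's plasmid-free slot
    seg = (s.omega_s * x).reshape(n_hosts, n_prof).sum(axis=1)
    dx[np.arange(n_hosts) * n_prof] += seg
    # infection flows
    for d in range(len(x)):
        g = s.gamma_s[d] * x[d]
        if g == 0.0:
            continue
        for m in range(s.rec_ptr[d], s.rec_ptr[d + 1]):
            r_slot = s.rec_idx[m]
            flow = g * x[r_slot]
            if flow == 0.0:
                continue
            dx[r_slot] -= flow
            cum_prev = 0.0
            for c in range(s.col_ptr[m], s.col_ptr[m + 1]):
                p = s.trans_cum[c] - cum_prev
                cum_prev = s.trans_cum[c]
                dx[s.trans_idx[c]] += flow * p
    return dx


def integrate_meanfield(
    mf: MeanFieldSystem,
    x0: np.ndarray,
    t_span: tuple[float, float],
    t_eval: Optional[Sequence[float]] = None,
    rtol: float = 1e-8,
    atol: float = 1e-8,
):
    """Integrate the mean-field system; returns the scipy solution object.

    Small negative excursions from the integrator are clipped inside the
    derivative evaluation; the returned trajectories are clipped at zero.
    """
    x0 = np.asarray(x0, dtype=float).reshape(-1)
    if x0.shape[0] != mf.n_slots:
        raise ValueError("initial state length does not match the system")

    def rhs(_t, x):
        return meanfield_derivatives(np.clip(x, 0.0, None), mf)

    sol = solve_ivp(rhs, t_span, x0, t_eval=t_eval, rtol=rtol, atol=atol, method="LSODA")
    if not sol.success:
        raise RuntimeError(f"mean-field integration failed: {sol.message}")
    sol.y = np.clip(sol.y, 0.0, None)
    return sol


def logistic_equilibrium(eta: float, mu: float, K: float) -> float:
    """Closed-form single-host plasmid-free equilibrium K (1 - mu / eta)."""
    return K * (1.0 - mu / eta)


# ---------------------------------------------------------------------------
# brute-force tensor

def brute_force_tensor(
    infection: InfectionNetwork, compatibility: CompatibilityNetwork
) -> PropensityTensor:
    """Naive full triple loop over (transconjugant; donor; recipient).

    Checks the four transfer conditions directly on every triple of
    subpopulation profiles, independent of the optimized constructor in
    :mod:`plasmidnet.model_core`. Intended for small systems only.
    """
    n_p = infection.n_plasmids
    n_prof = 2**n_p
    n_hosts = infection.n_hosts
    if n_hosts * n_prof > 64:
        raise ValueError("brute-force tensor is limited to <= 64 subpopulation slots")
    I, P = infection.matrix, compatibility.matrix

    def feasible(host, idx):
        carried = [a for a in range(n_p) if (idx >> a) & 1]
        return all(I[host, a] for a in carried) and all(
            P[a, b] for a, b in itertools.combinations(carried, 2)
        )

    raw: dict = {}
    for i in range(n_hosts):
        for p in range(n_prof):
            for k in range(n_hosts):
                for q in range(n_prof):
                    for r in range(n_prof):
                        if p == 0:  # condition 1: donor carries plasmids
                            continue
                        if not (p & ~q):  # condition 2
                            continue
                        if not (feasible(i, p) and feasible(k, q)):
                            continue
                        s = r & ~q
                        if s == 0 or (r | q) != r or (q & ~r):
                            continue  # r must extend q by at least one plasmid
                        if s & ~p:
                            continue  # transferred plasmids must come from the donor
                        if any(not I[k, a] for a in range(n_p) if (s >> a) & 1):
                            continue  # condition 3
                        carried = [a for a in range(n_p) if (r >> a) & 1]
                        if any(
                            not P[a, b] for a, b in itertools.combinations(carried, 2)
                        ):
                            continue  # condition 4
                        nu = bin(s).count("1")
                        raw.setdefault(((i, p), (k, q)), []).append((r, 0.5 ** (nu - 1)))
    columns = {}
    for key, entries in raw.items():
        entries.sort()
        r_idx = np.array([e[0] for e in entries], dtype=np.int64)
        w = np.array([e[1] for e in entries])
        columns[key] = (r_idx, w, w / w.sum())
    return PropensityTensor(columns)


def tensors_equal(a: PropensityTensor, b: PropensityTensor, tol: float = 1e-12) -> bool:
    """Entry-by-entry comparison of two propensity tensors."""
    if set(a.columns) != set(b.columns):
        return False
    for key in a.columns:
        ra, rawa, pa = a.columns[key]
        rb, rawb, pb = b.columns[key]
        oa, ob = np.argsort(ra), np.argsort(rb)
        if not np.array_equal(ra[oa], rb[ob]):
            return False
        if not (
            np.allclose(rawa[oa], rawb[ob], atol=tol)
            and np.allclose(pa[oa], pb[ob], atol=tol)
        ):
            return False
    return True
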