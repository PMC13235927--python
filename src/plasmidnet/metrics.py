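"""Community-level summary metrics over trajectories and replicate ensembles.

Four metrics summarize an experiment:

1. relative host abundance  H_i / sum_j H_j;
2. plasmid prevalence       fraction of all individuals carrying a plasmid;
3. host population composition  per surviving host, the proportion of each
   plasmid profile, averaged across the replicates in which that host
   survived (hosts surviving in more than a threshold number of replicates
   only);
4. host coexistence probability  fraction of replicates with at least (or
   exactly) k host populations extant, as a function of time.

"Survived" means positive abundance at the final recorded snapshot.
Standard errors are taken across replicates (sample SD / sqrt(n)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import model_core as mc
from .engine import TrajectoryRecord
from .model_core import CommunityState

__all__ = [
    "ReplicateEnsemble",
    "relative_host_abundance",
    "plasmid_prevalence",
    "prevalence_summary",
    "host_composition",
    "coexistence_probability",
    "classify_coexistence",
    "tidy_metrics",
]


@dataclass
class ReplicateEnsemble:
    """Replicate trajectories sharing one experiment configuration."""

    trajectories: list[TrajectoryRecord]
    label: str = ""

    def __post_init__(self):
        if self.trajectories:
            shapes = {t.states.shape[1:] for t in self.trajectories}
            if len(shapes) != 1:
                raise ValueError("ensemble members disagree on community shape")

    def __len__(self) -> int:
        return len(self.trajectories)

    @property
    def final_states(self) -> list[CommunityState]:
        return [t.final_state for t in self.trajectories]


def relative_host_abundance(state: CommunityState) -> np.ndarray:
    """H_i over total community abundance; NaN vector if the community is empty."""
    totals = state.host_totals.astype(float)
    s = totals.sum()
    if s == 0:
        return np.full(state.n_hosts, np.nan)
    return totals / s


def plasmid_prevalence(state: CommunityState) -> np.ndarray:
    """Per plasmid, the fraction of all individuals carrying it."""
    n_p = mc._n_plasmids_of(state)
    total = state.total
    if total == 0:
        return np.full(n_p, np.nan)
    carriage = mc.enumerate_profiles(n_p).astype(float)  # (n_prof, n_p)
    per_profile = state.abundance.sum(axis=0).astype(float)  # over hosts
    return per_profile @ carriage / total


def prevalence_summary(ensemble: ReplicateEnsemble) -> pd.DataFrame:
    """Mean and SE of final plasmid prevalence across replicates.

    Replicates with an empty final community are excluded (prevalence
    undefined there).
    """
    rows = [plasmid_prevalence(s) for s in ensemble.final_states]
    values = np.array([r for r in rows if not np.isnan(r).any()])
    n = len(values)
    mean = values.mean(axis=0) if n else np.full(rows[0].shape, np.nan)
    se = values.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.full_like(mean, np.nan)
    return pd.DataFrame(
        {
            "plasmid": [f"P{a + 1}" for a in range(len(mean))],
            "mean_prevalence": mean,
            "se": se,
            "n_replicates": n,
        }
    )


def host_composition(
    ensemble: ReplicateEnsemble, min_surviving_replicates: int = 5
) -> pd.DataFrame:
    """Final within-host profile proportions, averaged over the replicates in
    which the host survived.

    Hosts surviving in *strictly more than* ``min_surviving_replicates``
    replicates are reported; averaging uses per-replicate proportions, not
    pooled counts. Columns: host, profile (bitstring), proportion.
    """
    if not ensemble.trajectories:
        raise ValueError("empty ensemble")
    finals = ensemble.final_states
    n_hosts, n_prof = finals[0].abundance.shape
    n_p = mc._n_plasmids_of(finals[0])
    bitstrings = [mc.profile_bitstring(b) for b in mc.enumerate_profiles(n_p)]
    records = []
    for i in range(n_hosts):
        props = []
        for s in finals:
            h = s.abundance[i].astype(float)
            if h.sum() > 0:
                props.append(h / h.sum())
        if len(props) <= min_surviving_replicates:
            continue
        mean_props = np.mean(props, axis=0)
        for j in range(n_prof):
            records.append(
                {
                    "host": f"H{i + 1}",
                    "profile": bitstrings[j],
                    "proportion": mean_props[j],
                    "n_surviving": len(props),
                }
            )
    return pd.DataFrame.from_records(
        records, columns=["host", "profile", "proportion", "n_surviving"]
    )


def _state_at(traj: TrajectoryRecord, t: float) -> np.ndarray:
    """Step-function lookup: last recorded state at time <= t (the final
    state persists beyond an early termination)."""
    idx = int(np.searchsorted(traj.times, t + 1e-9, side="right")) - 1
    idx = max(idx, 0)
    return traj.states[idx]


def coexistence_probability(
    ensemble: ReplicateEnsemble,
    k: int = 3,
    times: Optional[Sequence[float]] = None,
    exact: bool = False,
) -> pd.DataFrame:
    """Fraction of replicates with >= k (or exactly k) extant hosts vs time."""
    if not ensemble.trajectories:
        raise ValueError("empty ensemble")
    if times is None:
        cfg = ensemble.trajectories[0].config
        times = np.arange(0.0, cfg.t_max + 1e-9, cfg.record_interval)
    times = np.asarray(times, dtype=float)
    frac = np.zeros(len(times))
    for traj in ensemble.trajectories:
        for m, t in enumerate(times):
            alive = int((_state_at(traj, t).sum(axis=1) > 0).sum())
            ok = alive == k if exact else alive >= k
            frac[m] += ok
    frac /= len(ensemble)
    return pd.DataFrame({"time": times, "coexistence_probability": frac})


def classify_coexistence(traj: TrajectoryRecord) -> str:
    """``stable`` if >= 2 hosts are extant at the final snapshot;
    ``transient_only`` if >= 2 coexisted at some snapshot but not at the end;
    ``none`` otherwise."""
    alive = (traj.states.sum(axis=2) > 0).sum(axis=1)
    if alive[-1] >= 2:
        return "stable"
    if (alive >= 2).any():
        return "transient_only"
    return "none"


def tidy_metrics(ensemble: ReplicateEnsemble, label: Optional[str] = None) -> pd.DataFrame:
    """Long-format table of final-state metrics per replicate.

    Columns: experiment, replicate, time, metric, entity, value.
    """
    label = label if label is not None else ensemble.label
    rows = []
    for rep, traj in enumerate(ensemble.trajectories):
        s = traj.final_state
        t = float(traj.times[-1])
        rel = relative_host_abundance(s)
        for i, v in enumerate(rel):
            rows.append((label, rep, t, "relative_host_abundance", f"H{i + 1}", v))
        prev = plasmid_prevalence(s)
        for a, v in enumerate(prev):
            rows.append((label, rep, t, "plasmid_prevalence", f"P{a + 1}", v))
        rows.append((label, rep, t, "coexistence_class", "community",
                     {"none": 0.0, "transient_only": 1.0, "stable": 2.0}[
                         classify_coexistence(traj)]))
    return pd.DataFrame(
        rows, columns=["experiment", "replicate", "time", "metric", "entity", "value"]
    )
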