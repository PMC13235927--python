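"""Persistence of configurations and trajectories in SQLite.

Schema (readable with any generic SQLite tooling):

``runs``
    run_id INTEGER PRIMARY KEY, experiment TEXT, replicate INTEGER,
    seed INTEGER, config TEXT (JSON), termination TEXT, n_events INTEGER
``abundances``
    run_id INTEGER, time REAL (hours, on the recording grid), host INTEGER
    (0-based), profile TEXT (bitstring, leftmost = P1), profile_index
    INTEGER, abundance INTEGER; unique over (run_id, time, host, profile)

Zero-abundance rows are elided by default; readers re-densify from the
configuration's community shape.
"""

from __future__ import annotations

import json
import sqlite3
from pathlib import Path
from typing import Optional, Union

import numpy as np

from . import model_core as mc
from .engine import SimulationConfig, TrajectoryRecord
from .metrics import ReplicateEnsemble
from .model_core import CommunityState, TraitParameters
from .networks import CompatibilityNetwork, InfectionNetwork

__all__ = [
    "RunDatabase",
    "config_to_dict",
    "config_from_dict",
    "write_trajectory",
    "read_trajectory",
    "read_ensemble",
]

_SCHEMA = """
CREATE TABLE IF NOT EXISTS runs (
    run_id INTEGER PRIMARY KEY AUTOINCREMENT,
    experiment TEXT NOT NULL,
    replicate INTEGER NOT NULL,
    seed INTEGER NOT NULL,
    config TEXT NOT NULL,
    termination TEXT NOT NULL,
    n_events INTEGER NOT NULL DEFAULT 0
);
CREATE TABLE IF NOT EXISTS abundances (
    run_id INTEGER NOT NULL REFERENCES runs(run_id),
    time REAL NOT NULL,
    host INTEGER NOT NULL,
    profile TEXT NOT NULL,
    profile_index INTEGER NOT NULL,
    abundance INTEGER NOT NULL CHECK (abundance >= 0),
    UNIQUE (run_id, time, host, profile)
);
"""


class RunDatabase:
    """Thin wrapper over a SQLite trajectory store."""

    def __init__(self, path: Union[str, Path]):
        self.path = str(path)
        self.conn = sqlite3.connect(self.path)
        self.conn.executescript(_SCHEMA)
        self.conn.commit()

    def close(self) -> None:
        self.conn.close()

    def __enter__(self) -> "RunDatabase":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    def experiments(self) -> list[str]:
        rows = self.conn.execute("SELECT DISTINCT experiment FROM runs ORDER BY 1")
        return [r[0] for r in rows]


def config_to_dict(config: SimulationConfig) -> dict:
    p = config.params
    return {
        "infection": {
            "matrix": config.infection.matrix.tolist(),
            "structure": config.infection.structure,
        },
        "compatibility": {
            "matrix": config.compatibility.matrix.tolist(),
            "structure": config.compatibility.structure,
            "hub_index": config.compatibility.hub_index,
        },
        "params": {
            "growth": p.growth.tolist(),
            "death": p.death.tolist(),
            "infection": p.infection.tolist(),
            "segregation": p.segregation.tolist(),
            "costs": p.costs.tolist(),
            "carrying_capacity": p.carrying_capacity,
            "competition": p.competition.tolist(),
        },
        "initial_state": config.initial_state.abundance.tolist(),
        "t_max": config.t_max,
        "record_interval": config.record_interval,
        "seed": config.seed,
        "stop_mode": config.stop_mode,
    }


def config_from_dict(d: dict) -> SimulationConfig:
    infection = InfectionNetwork(
        np.array(d["infection"]["matrix"], dtype=np.int8), d["infection"]["structure"]
    )
    comp = d["compatibility"]
    compatibility = CompatibilityNetwork(
        np.array(comp["matrix"], dtype=np.int8), comp["structure"], comp.get("hub_index")
    )
    p = d["params"]
    params = TraitParameters(
        growth=p["growth"],
        death=p["death"],
        infection=p["infection"],
        segregation=p["segregation"],
        costs=p["costs"],
        carrying_capacity=p["carrying_capacity"],
        competition=p["competition"],
    )
    return SimulationConfig(
        infection,
        compatibility,
        params,
        CommunityState(np.array(d["initial_state"], dtype=np.int64)),
        d["t_max"],
        d["record_interval"],
        d["seed"],
        d.get("stop_mode"),
    )


def write_trajectory(
    db: RunDatabase,
    record: TrajectoryRecord,
    experiment: str = "",
    replicate: int = 0,
    elide_zeros: bool = True,
) -> int:
    """Persist one trajectory; returns its run id."""
    cur = db.conn.execute(
        "INSERT INTO runs (experiment, replicate, seed, config, termination, n_events)"
        " VALUES (?, ?, ?, ?, ?, ?)",
        (
            experiment,
            replicate,
            int(record.seed),
            json.dumps(config_to_dict(record.config)),
            record.termination,
            int(record.n_events),
        ),
    )
    run_id = cur.lastrowid
    n_hosts, n_prof = record.states.shape[1:]
    n_p = int(round(np.log2(n_prof)))
    bitstrings = [mc.profile_bitstring(b) for b in mc.enumerate_profiles(n_p)]
    rows = []
    for t, A in zip(record.times, record.states):
        for i in range(n_hosts):
            for j in range(n_prof):
                a = int(A[i, j])
                if a == 0 and elide_zeros:
                    continue
                rows.append((run_id, float(t), i, bitstrings[j], j, a))
    db.conn.executemany(
        "INSERT INTO abundances (run_id, time, host, profile, profile_index, abundance)"
        " VALUES (?, ?, ?, ?, ?, ?)",
        rows,
    )
    db.conn.commit()
    return run_id


def read_trajectory(db: RunDatabase, run_id: int) -> TrajectoryRecord:
    """Reload one trajectory, re-densifying elided zero rows."""
    row = db.conn.execute(
        "SELECT seed, config, termination, n_events FROM runs WHERE run_id = ?",
        (run_id,),
    ).fetchone()
    if row is None:
        raise KeyError(f"run {run_id} not found")
    seed, config_json, termination, n_events = row
    config = config_from_dict(json.loads(config_json))
    n_hosts = config.initial_state.n_hosts
    n_prof = config.initial_state.n_profiles
    times = [
        r[0]
        for r in db.conn.execute(
            "SELECT DISTINCT time FROM abundances WHERE run_id = ? ORDER BY time",
            (run_id,),
        )
    ]
    t_index = {t: m for m, t in enumerate(times)}
    states = np.zeros((len(times), n_hosts, n_prof), dtype=np.int64)
    for t, host, j, a in db.conn.execute(
        "SELECT time, host, profile_index, abundance FROM abundances WHERE run_id = ?",
        (run_id,),
    ):
        states[t_index[t], host, j] = a
    return TrajectoryRecord(
        np.array(times), states, termination, seed, config, n_events
    )


def read_ensemble(db: RunDatabase, experiment: str) -> ReplicateEnsemble:
    """Reload all replicates of one experiment, ordered by replicate index.

    Raises if the code is absent or if its runs were produced under
    heterogeneous settings (different horizon, grid, or community shape).
    """
    runs = db.conn.execute(
        "SELECT run_id FROM runs WHERE experiment = ? ORDER BY replicate, run_id",
        (experiment,),
    ).fetchall()
    if not runs:
        raise KeyError(f"experiment {experiment!r} not found in {db.path}")
    trajectories = [read_trajectory(db, r[0]) for r in runs]
    keys = {
        (
            t.config.t_max,
            t.config.record_interval,
            t.config.initial_state.abundance.shape,
            t.config.infection.matrix.tobytes(),
            t.config.compatibility.matrix.tobytes(),
        )
        for t in trajectories
    }
    if len(keys) != 1:
        raise ValueError(f"heterogeneous configurations under experiment {experiment!r}")
    return ReplicateEnsemble(trajectories, experiment)
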