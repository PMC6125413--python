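"""The true perception-action loop (generative process).

The loop couples an environment — initial state distribution p(e0),
controlled Markov dynamics p(e'|a,e) and sensor dynamics p(s|e) — with an
agent, i.e. an action-generation rule p(a_t | m_t) operating on a perfect
memory m_t of all past sensor values and actions.

Time convention (used consistently across the package): the sensor value
s_0 arrives at t = 0, the first action a_1 is taken at t = 1, and ranges
written ``t:T`` are inclusive of both ends.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .probtables import Categorical, CondTable, FiniteSpace

__all__ = [
    "EnvironmentSpec",
    "History",
    "AgentContract",
    "StepRecord",
    "memory_update",
    "step_environment",
    "run_loop",
    "ENVIRONMENT_JSON_FORMAT",
]

#: Shape of the environment JSON serialization (documented, hand-validated).
ENVIRONMENT_JSON_FORMAT = {
    "spaces": {"E": ["<labels>"], "S": ["<labels>"], "A": ["<labels>"]},
    "init": ["<probability per E label>"],
    "trans": {"<a>,<e>": ["<probability per E label>"]},
    "sensor": {"<e>": ["<probability per S label>"]},
}

#: An agent is its action-generation rule: History -> Categorical over A.
AgentContract = Callable[["History"], Categorical]


@dataclass
class EnvironmentSpec:
    """True PA-loop dynamics over finite labeled spaces."""

    E: FiniteSpace
    S: FiniteSpace
    A: FiniteSpace
    init: Categorical          # p(e0)
    trans: CondTable           # p(e' | a, e), conditioners (A, E)
    sensor: CondTable          # p(s | e), conditioner (E,)

    def __post_init__(self):
        if self.init.space is not self.E and self.init.space.labels != self.E.labels:
            raise ValueError("init distribution is not over E")
        if self.trans.target.labels != self.E.labels or tuple(
            s.labels for s in self.trans.conditioners
        ) != (self.A.labels, self.E.labels):
            raise ValueError("trans must be p(e'|a,e) with conditioners (A, E)")
        if self.sensor.target.labels != self.S.labels or tuple(
            s.labels for s in self.sensor.conditioners
        ) != (self.E.labels,):
            raise ValueError("sensor must be p(s|e) with conditioner (E,)")

    # -- JSON round trip -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "spaces": {
                "E": list(self.E.labels),
                "S": list(self.S.labels),
                "A": list(self.A.labels),
            },
            "init": self.init.probs.tolist(),
            "trans": {
                f"{a},{e}": self.trans.row(a, e).probs.tolist()
                for a in self.A.labels
                for e in self.E.labels
            },
            "sensor": {e: self.sensor.row(e).probs.tolist() for e in self.E.labels},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EnvironmentSpec":
        for key in ("spaces", "init", "trans", "sensor"):
            if key not in d:
                raise ValueError(f"environment JSON missing key {key!r}")
        sp = d["spaces"]
        for key in ("E", "S", "A"):
            if key not in sp or not isinstance(sp[key], list):
                raise ValueError(f"environment JSON: spaces.{key} must be a label list")
        E = FiniteSpace("E", tuple(sp["E"]))
        S = FiniteSpace("S", tuple(sp["S"]))
        A = FiniteSpace("A", tuple(sp["A"]))
        trans = CondTable.from_rows(
            E, (A, E),
            {(a, e): d["trans"][f"{a},{e}"] for a in A.labels for e in E.labels},
        )
        sensor = CondTable.from_rows(S, (E,), {e: d["sensor"][e] for e in E.labels})
        return cls(E, S, A, Categorical(E, np.asarray(d["init"], float)), trans, sensor)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "EnvironmentSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class History:
    """Perfect memory m_t = (s_0..s_{t-1}; a_1..a_{t-1}).

    The stored (s, a) prefix is the trajectory prefix itself, so memory is
    lossless by construction.
    """

    sensors: tuple[str, ...] = ()
    actions: tuple[str, ...] = ()

    def __post_init__(self):
        if self.sensors and len(self.actions) != len(self.sensors) - 1:
            raise ValueError(
                f"history with {len(self.sensors)} sensors must hold "
                f"{len(self.sensors) - 1} actions, got {len(self.actions)}"
            )
        if not self.sensors and self.actions:
            raise ValueError("history cannot hold actions without sensors")

    @property
    def t(self) -> int:
        """The current time step: number of recorded sensor values."""
        return len(self.sensors)

    @classmethod
    def empty(cls) -> "History":
        return cls((), ())


def memory_update(m: History, s, a=None, *, S: FiniteSpace | None = None,
                  A: FiniteSpace | None = None) -> History:
    """Append (s, a) to the memory; ``a`` is absent for the t=0→1 step.

    Deterministic concatenation: the memory CPT is an indicator.  When the
    sensor/action spaces are supplied the labels are checked against them.
    """
    s = str(s)
    if S is not None:
        S.index(s)
    if m.t == 0:
        if a is not None:
            raise ValueError("the initial memory step records only s_0")
        return History((s,), ())
    if a is None:
        raise ValueError("steps after t=1 require the preceding action")
    a = str(a)
    if A is not None:
        A.index(a)
    return History(m.sensors + (s,), m.actions + (a,))


def step_environment(env: EnvironmentSpec, e, a, rng: np.random.Generator):
    """One environment transition: e' ~ p(·|a,e), then s' ~ p(·|e')."""
    e_next = env.trans.row(a, e).sample(rng)
    s_next = env.sensor.row(e_next).sample(rng)
    return e_next, s_next


@dataclass
class StepRecord:
    t: int
    e: str
    s: str
    a: str | None          # None at t = 0
    m: History             # memory state *after* incorporating this step

    def to_jsonl(self) -> str:
        return json.dumps({"t": self.t, "e": self.e, "s": self.s, "a": self.a})


def run_loop(
    env: EnvironmentSpec,
    agent: AgentContract,
    T: int,
    rng: np.random.Generator,
    e0: str | None = None,
) -> list[StepRecord]:
    """Simulate t = 0..T respecting the causal order s_0 → m_1 → a_1 → e_1.

    Returns one record per time step (T+1 records).  Record ``t`` carries
    the memory state m_{t+1}, i.e. the history available to the *next*
    action choice.  Bit-identical trajectories under the same seed.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    e = env.init.sample(rng) if e0 is None else str(e0)
    s = env.sensor.row(e).sample(rng)
    m = memory_update(History.empty(), s, S=env.S)
    records = [StepRecord(0, e, s, None, m)]
    for t in range(1, T + 1):
        dist = agent(m)
        if not isinstance(dist, Categorical) or dist.space.labels != env.A.labels:
            raise ValueError(
                f"agent returned an invalid action distribution at t={t}"
            )
        a = dist.sample(rng)
        e, s = step_environment(env, e, a, rng)
        m = memory_update(m, s, a, S=env.S, A=env.A)
        records.append(StepRecord(t, e, s, a, m))
    return records
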