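"""Synthetic environments and matched generative models.

Everything here is generated programmatically from a seed — no data
files.  The environment family covers the situations the intrinsic
motivations are meant to distinguish: a deterministic two-state world
(``det2``), its noisy-sensor variant (``noisy2``, flip probability 0.1),
a 1-D grid with slip noise, a T-maze with a context cue, and fully
random Dirichlet-sampled dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genmodel import (
    DirichletBlocks,
    GenerativeModel,
    ParameterBelief,
    ParameterPoint,
)
from .paloop import EnvironmentSpec
from .probtables import Categorical, CondTable, FiniteSpace

__all__ = [
    "FixtureSpec",
    "make_fixture",
    "det2",
    "noisy2",
    "grid",
    "tmaze",
    "random_environment",
    "two_state_ensemble",
    "env_to_parameter_point",
    "generative_model_for",
    "ensemble_model_for",
]


@dataclass
class FixtureSpec:
    kind: str                      # det2 | noisy2 | grid | tmaze | random
    seed: int = 0
    size: int = 3                  # grid cells / random space size
    slip: float = 0.1
    sizes: tuple[int, int, int] = (2, 2, 2)   # random: (|E|, |S|, |A|)
    concentration: float = 1.0

    def __post_init__(self):
        if self.kind not in ("det2", "noisy2", "grid", "tmaze", "random"):
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if not 0.0 <= self.slip <= 0.5:
            raise ValueError("slip must lie in [0, 0.5]")
        if self.kind == "grid" and self.size < 2:
            raise ValueError("grid needs at least 2 cells")
        if self.kind == "random" and any(n < 2 for n in self.sizes):
            raise ValueError("random spaces need size >= 2")


def make_fixture(spec: FixtureSpec) -> EnvironmentSpec:
    if spec.kind == "det2":
        return det2()
    if spec.kind == "noisy2":
        return noisy2()
    if spec.kind == "grid":
        return grid(spec.size, spec.slip)
    if spec.kind == "tmaze":
        return tmaze()
    return random_environment(spec.sizes, spec.concentration, spec.seed)


def _two_state(sensor_rows) -> EnvironmentSpec:
    E = FiniteSpace("E", ("x0", "x1"))
    S = FiniteSpace("S", ("x0", "x1"))
    A = FiniteSpace("A", ("flip", "stay"))
    trans = CondTable.from_rows(E, (A, E), {
        ("stay", "x0"): [1, 0], ("stay", "x1"): [0, 1],
        ("flip", "x0"): [0, 1], ("flip", "x1"): [1, 0],
    })
    sensor = CondTable.from_rows(S, (E,), sensor_rows)
    return EnvironmentSpec(E, S, A, Categorical.point_mass(E, "x0"),
                           trans, sensor)


def det2() -> EnvironmentSpec:
    """Two states, identity sensor, deterministic stay/flip actions."""
    return _two_state({"x0": [1, 0], "x1": [0, 1]})


def noisy2() -> EnvironmentSpec:
    """det2 with sensor flip probability 0.1."""
    return _two_state({"x0": [0.9, 0.1], "x1": [0.1, 0.9]})


def grid(n: int, slip: float) -> EnvironmentSpec:
    """1-D grid: left/right moves succeed with probability 1 − slip,
    otherwise the agent stays; the ends clamp.  Identity sensor."""
    labels = tuple(f"c{i}" for i in range(n))
    E = FiniteSpace("E", labels)
    S = FiniteSpace("S", labels)
    A = FiniteSpace("A", ("left", "right"))
    rows = {}
    for i in range(n):
        for a, delta in (("left", -1), ("right", +1)):
            row = np.zeros(n)
            j = min(max(i + delta, 0), n - 1)
            row[j] += 1.0 - slip
            row[i] += slip
            rows[(a, labels[i])] = row
    trans = CondTable.from_rows(E, (A, E), rows)
    sensor = CondTable.from_rows(S, (E,), {
        lab: np.eye(n)[i] for i, lab in enumerate(labels)})
    return EnvironmentSpec(E, S, A, Categorical.point_mass(E, labels[0]),
                           trans, sensor)


def tmaze() -> EnvironmentSpec:
    """T-maze with a hidden context and a cue location.

    The context (which arm is 'indicated') is fixed per episode and
    invisible except at the cue location, where the sensor reveals it.
    """
    ctxs, poss = ("L", "R"), ("center", "left", "right", "cue")
    labels = tuple(f"{c}:{p}" for c in ctxs for p in poss)
    E = FiniteSpace("E", labels)
    S = FiniteSpace("S", ("ambig", "arm_left", "arm_right", "cue_L", "cue_R"))
    A = FiniteSpace("A", ("go_center", "go_left", "go_right", "go_cue"))
    goto = {"go_center": "center", "go_left": "left", "go_right": "right",
            "go_cue": "cue"}
    rows = {}
    for c in ctxs:
        for p in poss:
            for a, target in goto.items():
                row = np.zeros(len(labels))
                row[E.index(f"{c}:{target}")] = 1.0
                rows[(a, f"{c}:{p}")] = row
    trans = CondTable.from_rows(E, (A, E), rows)
    srow = {}
    for c in ctxs:
        for p in poss:
            row = np.zeros(len(S))
            if p == "cue":
                row[S.index(f"cue_{c}")] = 1.0
            elif p == "left":
                row[S.index("arm_left")] = 1.0
            elif p == "right":
                row[S.index("arm_right")] = 1.0
            else:
                row[S.index("ambig")] = 1.0
            srow[f"{c}:{p}"] = row
    sensor = CondTable.from_rows(S, (E,), srow)
    init = np.zeros(len(labels))
    init[E.index("L:center")] = 0.5
    init[E.index("R:center")] = 0.5
    return EnvironmentSpec(E, S, A, Categorical(E, init), trans, sensor)


def random_environment(sizes, concentration, seed) -> EnvironmentSpec:
    """All rows Dirichlet-sampled with symmetric concentration, seeded."""
    n_e, n_s, n_a = sizes
    rng = np.random.default_rng(seed)
    E = FiniteSpace("E", tuple(f"e{i}" for i in range(n_e)))
    S = FiniteSpace("S", tuple(f"s{i}" for i in range(n_s)))
    A = FiniteSpace("A", tuple(f"a{i}" for i in range(n_a)))
    c = float(concentration)
    init = Categorical(E, rng.dirichlet(np.full(n_e, c)))
    trans = CondTable(E, (A, E), np.stack([
        np.stack([rng.dirichlet(np.full(n_e, c)) for _ in range(n_e)])
        for _ in range(n_a)
    ]))
    sensor = CondTable(S, (E,), np.stack([
        rng.dirichlet(np.full(n_s, c)) for _ in range(n_e)]))
    return EnvironmentSpec(E, S, A, init, trans, sensor)


def two_state_ensemble() -> list[EnvironmentSpec]:
    """Four two-state worlds that differ only in what action 'flip' does.

    'stay' keeps the state in every world; 'flip' switches the state
    always / never / with probability 0.7 / with probability 0.3.  Only
    deliberate use of 'flip' distinguishes the worlds, and separating
    the two stochastic ones takes repeated trials — the setting where
    knowledge seeking visibly beats undirected exploration.
    """
    envs = []
    for p_flip in (1.0, 0.0, 0.7, 0.3):
        env = _two_state({"x0": [1, 0], "x1": [0, 1]})
        table = env.trans.table.copy()
        ai = env.A.index("flip")
        table[ai, 0] = [1 - p_flip, p_flip]
        table[ai, 1] = [p_flip, 1 - p_flip]
        envs.append(EnvironmentSpec(env.E, env.S, env.A, env.init,
                                    CondTable(env.E, (env.A, env.E), table),
                                    env.sensor))
    return envs


def env_to_parameter_point(env: EnvironmentSpec, Ehat: FiniteSpace,
                           Shat: FiniteSpace, Ahat: FiniteSpace
                           ) -> ParameterPoint:
    """Read a true environment as one parameter point of the model
    (requires matching space sizes; labels are mapped positionally)."""
    if len(Ehat) != len(env.E):
        raise ValueError("Ehat size must match the environment state space")
    return ParameterPoint(
        CondTable(Shat, (Ehat,), env.sensor.table.copy()),
        CondTable(Ehat, (Ahat, Ehat), env.trans.table.copy()),
        Categorical(Ehat, env.init.probs.copy()),
    )


def generative_model_for(env: EnvironmentSpec, n: int = 2,
                         concentration: float = 1.0,
                         Ehat_size: int | None = None,
                         xi1: np.ndarray | None = None,
                         cap: int = 1_000_000) -> GenerativeModel:
    """Dirichlet-backend model matched to an environment's sensor and
    action spaces.  ``xi1`` optionally pins the sensor-model prior (e.g.
    to a confident, correct one); defaults to flat."""
    n_e = Ehat_size if Ehat_size is not None else len(env.E)
    Ehat = FiniteSpace("Ehat", tuple(f"h{i}" for i in range(n_e)))
    Shat = FiniteSpace("Shat", env.S.labels)
    Ahat = FiniteSpace("Ahat", env.A.labels)
    blocks = DirichletBlocks.flat(n_e, len(Shat), len(Ahat), concentration)
    if xi1 is not None:
        blocks = DirichletBlocks(np.asarray(xi1, float), blocks.xi2, blocks.xi3)
    return GenerativeModel(Ehat, Shat, Ahat,
                           ParameterBelief.from_dirichlet(blocks),
                           ("rolling", n), cap=cap)


def ensemble_model_for(envs: list[EnvironmentSpec], n: int = 2,
                       weights=None, cap: int = 1_000_000) -> GenerativeModel:
    """Ensemble-backend model whose points are the given environments."""
    ref = envs[0]
    Ehat = FiniteSpace("Ehat", ref.E.labels)
    Shat = FiniteSpace("Shat", ref.S.labels)
    Ahat = FiniteSpace("Ahat", ref.A.labels)
    points = [env_to_parameter_point(e, Ehat, Shat, Ahat) for e in envs]
    return GenerativeModel(Ehat, Shat, Ahat,
                           ParameterBelief.from_points(points, weights),
                           ("rolling", n), cap=cap)
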